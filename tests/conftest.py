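import numpy as np
import pytest

from brcakit import signatures, simulate


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """A tiny indexed FASTA with known sequence for catalog construction."""
    import pyfaidx

    path = tmp_path_factory.mktemp("ref") / "toy.fa"
    seq1 = "AACATGCGTGCTA"
    seq2 = "GGNTACGTACGT"
    path.write_text(f">chr1\n{seq1}\n>chr2\n{seq2}\n")
    return pyfaidx.Fasta(str(path))


@pytest.fixture(scope="session")
def small_catalog_truth():
    """A 50-sample catalog simulated from 3 sparse signatures + background."""
    spec = simulate.CatalogSimSpec(
        n_samples=50, mutations_per_sample=1000, K=3, seed=7
    )
    return simulate.simulate_catalog(spec)


@pytest.fixture(scope="session")
def noiseless_catalog_truth():
    spec = simulate.CatalogSimSpec(
        n_samples=40, mutations_per_sample=2000, K=2, noise="none", seed=11
    )
    return simulate.simulate_catalog(spec)


@pytest.fixture(scope="session")
def background():
    return signatures.default_background()


@pytest.fixture(scope="session")
def sv_callset_truth():
    calls, truth = simulate.simulate_sv_callset(simulate.SVSimSpec(seed=3))
    return calls, truth
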