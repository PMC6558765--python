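"""Background-anchored sparse mutational-signature factorization.

The mutation count matrix M (samples x 96) is modeled as

    M ~ alpha0 beta0 + alpha beta

where ``beta0`` is a fixed background signature representing replication
errors accumulated during normal cell division (present in every tumor),
``alpha0`` its per-sample exposures, ``beta`` (K x 96) the discovered
signatures, and ``alpha`` (n x K) their exposures.  Discovered signatures are
estimated under an L1 (LASSO) penalty that drives small channel loadings to
exactly zero, and the number of signatures K and penalty weight lambda are
selected by repeated bi-cross-validation: hold out a random row-block x
column-block of M, fit on the remaining cells, and score squared prediction
error on the held-out block.

Fitting alternates exact nonnegative least squares for the exposures with
nonnegative coordinate-descent LASSO steps for the signatures; signature rows
are renormalized to sum to one after each outer iteration, with the
compensating scale absorbed into the exposure columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import CHANNELS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# background signature
# ---------------------------------------------------------------------------

def default_background() -> np.ndarray:
    """A smooth germline-like background spectrum over the 96 channels.

    Built as a broad base rate over all channels plus strongly elevated C>T
    rates at NpCpG contexts (spontaneous deamination of methylated CpG, the
    dominant replication-associated process), mildly elevated C>T elsewhere.
    Normalized to sum to 1.  This is a packaged synthetic stand-in for a
    human-germline mutation spectrum, adequate for simulation and testing.
    """
    w = np.ones(96)
    for j, label in enumerate(CHANNELS):
        sub = label[2:5]
        if sub == "C>T":
            w[j] = 4.0
            if label[6] == "G":  # NpCpG context
                w[j] = 20.0
        elif sub == "T>C":
            w[j] = 2.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Fitted background-anchored sparse signature model.

    Active signature rows sum to 1; a component the LASSO has shrunk away
    entirely is left as an all-zero row with zero exposure (see
    ``active_components``).
    """

    beta0: np.ndarray            # (96,) fixed background, sums to 1
    beta: np.ndarray             # (K, 96) discovered signatures, rows sum to 1
    alpha0: np.ndarray           # (n,) background exposures
    alpha: np.ndarray            # (n, K) signature exposures
    K: int
    lam: float
    objective_history: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def active_components(self) -> np.ndarray:
        return self.beta.sum(axis=1) > 0

    def reconstruct(self) -> np.ndarray:
        return np.outer(self.alpha0, self.beta0) + self.alpha @ self.beta

    def signatures_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names or [f"signature_{i + 1}" for i in range(self.K)]
        rows = np.vstack([self.beta0, self.beta])
        return pd.DataFrame(rows, index=["background"] + list(names), columns=list(CHANNELS))

    def exposures_frame(self, sample_ids=None, names: list[str] | None = None) -> pd.DataFrame:
        names = names or [f"signature_{i + 1}" for i in range(self.K)]
        mat = np.column_stack([self.alpha0, self.alpha])
        idx = sample_ids if sample_ids is not None else range(len(self.alpha0))
        return pd.DataFrame(mat, index=idx, columns=["background"] + list(names))


@dataclass
class BiCVResult:
    """Bi-cross-validation grid of mean held-out squared errors."""

    grid: pd.DataFrame           # long format: K, lam, mse
    chosen_K: int
    chosen_lambda: float
    repeats: int


@dataclass
class ExposureSummary:
    """Per-sample exposures (including background), fractions, and ratios."""

    exposures: pd.DataFrame      # columns: background + signature names
    fractions: pd.DataFrame      # exposures / row totals

    def ratio_to_background(self, name: str) -> pd.Series:
        return self.exposures[name] / self.exposures["background"]


# ---------------------------------------------------------------------------
# numerical core
# ---------------------------------------------------------------------------

def _as_matrix(catalog) -> np.ndarray:
    M = catalog.to_numpy(dtype=float) if isinstance(catalog, pd.DataFrame) else np.asarray(catalog, float)
    if M.ndim != 2:
        raise ValueError("catalog must be 2-D (samples x channels)")
    return M


def _nnls_rows(B: np.ndarray, M: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Row-wise nonnegative least squares: min ||m_i - a_i B||^2 over a_i >= 0.

    ``B`` is (p x J); returns (n x p).  With a binary ``mask`` (n x J), only
    unmasked cells of each row enter that row's regression.  Rows whose
    unconstrained LS solution is already nonnegative skip the active-set
    solver (the design is shared across rows without a mask).
    """
    n = M.shape[0]
    p = B.shape[0]
    A = np.zeros((n, p))
    Bt = B.T  # (J x p)
    if mask is None:
        # shared design fast path
        G = B @ B.T
        C = M @ B.T
        try:
            unc = np.linalg.solve(G, C.T).T
        except np.linalg.LinAlgError:
            unc = np.full((n, p), -1.0)
        ok = (unc >= 0).all(axis=1)
        A[ok] = unc[ok]
        for i in np.flatnonzero(~ok):
            A[i], _ = nnls(Bt, M[i])
        return A
    for i in range(n):
        w = mask[i].astype(bool)
        if not w.any():
            continue
        A[i], _ = nnls(Bt[w], M[i, w])
    return A


def _cd_beta_update(
    M: np.ndarray,
    alpha0: np.ndarray,
    beta0: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    lam: float,
    mask: np.ndarray | None,
    sweeps: int = 2,
) -> np.ndarray:
    """Nonnegative LASSO coordinate descent on the signature matrix.

    Minimizes ||W o (M - alpha0 beta0 - alpha beta)||^2 + lam * sum|beta|
    over beta >= 0 with everything else fixed; one closed-form soft-threshold
    update per (signature, channel), vectorized over channels.
    """
    R = M - np.outer(alpha0, beta0)  # (n, J)
    K = beta.shape[0]
    W = mask if mask is not None else None
    for _ in range(sweeps):
        for k in range(K):
            ak = alpha[:, k]  # (n,)
            # partial residual excluding signature k
            E = R - alpha @ beta + np.outer(ak, beta[k])
            if W is None:
                c = ak @ E                        # (J,)
                h = float(ak @ ak)
                hvec = np.full(E.shape[1], h)
            else:
                c = (ak[:, None] * W * E).sum(axis=0)
                hvec = ((ak ** 2)[:, None] * W).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                newrow = np.where(hvec > 0, np.maximum(0.0, (c - lam / 2.0) / hvec), beta[k])
            beta[k] = newrow
    return beta


def _objective(M, alpha0, beta0, alpha, beta, lam, mask) -> float:
    R = M - np.outer(alpha0, beta0) - alpha @ beta
    if mask is not None:
        R = R * mask
    return float((R ** 2).sum() + lam * np.abs(beta).sum())


def _normalize_rows(beta: np.ndarray, alpha: np.ndarray) -> None:
    """Renormalize signature rows to sum 1, rescaling exposure columns.

    A row that the LASSO has driven entirely to zero stays zero (an inactive
    component with zero exposure); reseeding such rows would let a spare
    component drift into a duplicate of the fixed background.
    """
    for k in range(beta.shape[0]):
        s = beta[k].sum()
        if s > 0:
            beta[k] /= s
            alpha[:, k] *= s
        else:
            alpha[:, k] = 0.0


def _nndsvd_init(R: np.ndarray, K: int) -> np.ndarray:
    """Nonnegative double-SVD initialization of K signature rows from R >= 0."""
    U, s, Vt = np.linalg.svd(np.maximum(R, 0.0), full_matrices=False)
    beta = np.zeros((K, R.shape[1]))
    for k in range(min(K, len(s))):
        v = Vt[k]
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        beta[k] = vp if vp.sum() >= vn.sum() else vn
    return beta


def fit(
    catalog,
    beta0: np.ndarray,
    K: int,
    lam: float,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
    restarts: int = 5,
    mask: np.ndarray | None = None,
    cd_sweeps: int = 2,
) -> SignatureModel:
    """Fit the background-anchored sparse model M ~ alpha0 beta0 + alpha beta.

    Parameters
    ----------
    catalog
        Samples x 96 count matrix (DataFrame or array).
    beta0
        Fixed background signature (sums to 1; never modified).
    K
        Number of signatures to discover in addition to the background.
    lam
        Nonnegative LASSO weight on the discovered signatures.
    seed, restarts
        The first start uses a nonnegative double-SVD initialization; the
        remaining ``restarts - 1`` starts are random; the best final
        objective is kept.
    mask
        Optional binary matrix marking cells that participate in the fit
        (zeros are held out); used by bi-cross-validation.

    Returns
    -------
    SignatureModel with the per-iteration penalized objective in
    ``objective_history`` (non-increasing up to the renormalization step).

    Notes
    -----
    The optimization runs on the catalog divided by its mean per-sample
    total, so that the LASSO weight has a scale-free meaning (lambda values
    of order 0.05-0.15 exert real shrinkage regardless of sequencing depth);
    exposures are rescaled to mutation counts on output, and the recorded
    objective is in the normalized units.
    """
    M = _as_matrix(catalog)
    n, J = M.shape
    beta0 = np.asarray(beta0, float)
    if beta0.shape != (J,):
        raise ValueError(f"beta0 must have length {J}")
    if not np.isclose(beta0.sum(), 1.0, atol=1e-6):
        raise ValueError("beta0 must sum to 1")
    if K < 1 or K > J:
        raise ValueError(f"K must be in [1, {J}], got {K}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if n == 0:
        raise ValueError("catalog is empty")

    rng = np.random.default_rng(seed)
    best: SignatureModel | None = None

    scale = M.sum() / n if M.sum() > 0 else 1.0
    M = M / scale

    # initial background exposures: per-row LS coefficient on beta0 alone
    b0sq = float(beta0 @ beta0)

    for r in range(max(1, restarts)):
        if mask is None:
            a0 = np.maximum(0.0, M @ beta0 / b0sq)
        else:
            denom = (mask * beta0 ** 2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a0 = np.where(denom > 0, np.maximum(0.0, (mask * M * beta0).sum(axis=1) / denom), 0.0)
        R0 = np.maximum(M - np.outer(a0, beta0), 0.0)
        if r == 0:
            beta = _nndsvd_init(R0, K)
        else:
            beta = rng.dirichlet(np.ones(J), size=K)
        alpha = np.zeros((n, K))
        _normalize_rows(beta, alpha)

        history: list[float] = []
        converged = False
        for it in range(max_iter):
            B_full = np.vstack([beta0, beta])
            A = _nnls_rows(B_full, M, mask)
            a0, alpha = A[:, 0], A[:, 1:].copy()
            beta = _cd_beta_update(M, a0, beta0, alpha, beta, lam, mask, sweeps=cd_sweeps)
            _normalize_rows(beta, alpha)
            obj = _objective(M, a0, beta0, alpha, beta, lam, mask)
            history.append(obj)
            if it > 0:
                prev = history[-2]
                if prev - obj < tol * max(prev, 1.0):
                    converged = True
                    break
        model = SignatureModel(
            beta0=beta0, beta=beta, alpha0=a0 * scale, alpha=alpha * scale,
            K=K, lam=lam, objective_history=history, converged=converged,
        )
        if best is None or history[-1] < best.objective_history[-1]:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def bi_cross_validate(
    catalog,
    beta0: np.ndarray,
    K_grid,
    lambda_grid,
    repeats: int = 20,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    max_iter: int = 30,
    tol: float = 1e-3,
    restarts: int = 1,
) -> BiCVResult:
    """Choose (K, lambda) by repeated bi-cross-validation.

    Each repeat holds out a random row-block x column-block of the catalog
    (about ``holdout_fraction`` of rows and of columns, at least one each),
    fits the model on the remaining cells with zero weight on the held-out
    block, and scores mean squared prediction error on the held-out cells.
    Grid entries are means over repeats.  Selection follows the
    one-standard-error rule: among pairs whose mean error is within one
    Monte-Carlo standard error of the grid minimum, the smallest K (then
    largest lambda) is chosen — a surplus signature moves held-out error by
    a noise-level amount, while a missing one inflates it severalfold, so
    near-ties resolve toward parsimony and sparsity.
    """
    M = _as_matrix(catalog)
    n, J = M.shape
    K_grid = sorted(set(int(k) for k in K_grid))
    lambda_grid = sorted(set(float(l) for l in lambda_grid))
    if not K_grid or not lambda_grid:
        raise ValueError("K_grid and lambda_grid must be nonempty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n_hold_rows = max(1, int(round(holdout_fraction * n)))
    n_hold_cols = max(1, int(round(holdout_fraction * J)))
    if n_hold_rows >= n or n_hold_cols >= J:
        raise ValueError("holdout block would cover an entire axis")

    rng = np.random.default_rng(seed)
    errs = {(K, lam): [] for K in K_grid for lam in lambda_grid}
    for _ in range(repeats):
        rows = rng.choice(n, size=n_hold_rows, replace=False)
        cols = rng.choice(J, size=n_hold_cols, replace=False)
        mask = np.ones((n, J))
        mask[np.ix_(rows, cols)] = 0.0
        held = mask == 0
        fit_seed = int(rng.integers(2 ** 31 - 1))
        for K in K_grid:
            for lam in lambda_grid:
                model = fit(
                    M, beta0, K, lam, seed=fit_seed, mask=mask,
                    max_iter=max_iter, tol=tol, restarts=restarts,
                )
                pred = model.reconstruct()
                errs[(K, lam)].append(float(((M - pred)[held] ** 2).mean()))

    records = [
        {
            "K": K,
            "lam": lam,
            "mse": float(np.mean(errs[(K, lam)])),
            "se": float(np.std(errs[(K, lam)], ddof=1) / np.sqrt(repeats)) if repeats > 1 else 0.0,
        }
        for K in K_grid for lam in lambda_grid
    ]
    grid = pd.DataFrame.from_records(records)
    i_min = int(grid["mse"].values.argmin())
    threshold = grid["mse"].iloc[i_min] + grid["se"].iloc[i_min] + 1e-12
    candidates = grid.loc[grid["mse"] <= threshold]
    order = candidates.sort_values(["K", "lam"], ascending=[True, False])
    best = order.iloc[0]
    return BiCVResult(
        grid=grid, chosen_K=int(best["K"]), chosen_lambda=float(best["lam"]), repeats=repeats
    )


def refit_exposures(
    catalog, beta0: np.ndarray, fixed_beta: np.ndarray, names: list[str] | None = None
) -> ExposureSummary:
    """Nonnegative least-squares exposures for a fixed signature set.

    ``beta0`` and ``fixed_beta`` are held fixed; alpha0 and alpha are fit per
    sample by NNLS.  Returns exposures (background first), per-sample
    fractions, and ratio-to-background accessors.
    """
    M = _as_matrix(catalog)
    beta0 = np.asarray(beta0, float)
    fixed_beta = np.atleast_2d(np.asarray(fixed_beta, float))
    if fixed_beta.shape[1] != M.shape[1] or beta0.shape[0] != M.shape[1]:
        raise ValueError("signature dimensions do not match the catalog")
    if not np.allclose(fixed_beta.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("fixed_beta rows must sum to 1")
    B_full = np.vstack([beta0, fixed_beta])
    A = _nnls_rows(B_full, M)
    names = names or [f"signature_{i + 1}" for i in range(fixed_beta.shape[0])]
    idx = catalog.index if isinstance(catalog, pd.DataFrame) else pd.RangeIndex(M.shape[0])
    exposures = pd.DataFrame(A, index=idx, columns=["background"] + list(names))
    totals = exposures.sum(axis=1)
    fractions = exposures.div(totals.where(totals > 0, 1.0), axis=0)
    return ExposureSummary(exposures=exposures, fractions=fractions)


# ---------------------------------------------------------------------------
# comparison utilities
# ---------------------------------------------------------------------------

def cosine_similarity(sig_a, sig_b) -> float:
    """Cosine similarity between two nonnegative signature vectors."""
    a = np.asarray(sig_a, float)
    b = np.asarray(sig_b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("signatures must be nonnegative")
    return float(a @ b / (na * nb))


def match_signatures(true_beta: np.ndarray, fitted_beta: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of fitted to true signatures by cosine."""
    true_beta = np.atleast_2d(true_beta)
    fitted_beta = np.atleast_2d(fitted_beta)
    sims = np.array([
        [
            cosine_similarity(t, f) if f.sum() > 0 else 0.0
            for f in fitted_beta
        ]
        for t in true_beta
    ])
    pairs = []
    used_t, used_f = set(), set()
    flat = sorted(
        ((sims[i, j], i, j) for i in range(sims.shape[0]) for j in range(sims.shape[1])),
        reverse=True,
    )
    for s, i, j in flat:
        if i in used_t or j in used_f:
            continue
        pairs.append((i, j, float(s)))
        used_t.add(i)
        used_f.add(j)
    return sorted(pairs)


def reconstruction_mse(catalog, model: SignatureModel) -> float:
    """Mean squared residual of M - alpha0 beta0 - alpha beta over all cells."""
    M = _as_matrix(catalog)
    R = M - model.reconstruct()
    return float((R ** 2).mean())


def exposure_column_means(exposure_table: pd.DataFrame) -> pd.Series:
    """Per-signature mean exposure across samples (plain column averages)."""
    return exposure_table.mean(axis=0)
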