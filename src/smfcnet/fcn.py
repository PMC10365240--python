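"""Construction of functional connectivity networks (FCNs) from ROI time series.

Three network families are built from one subject's BOLD-like time-series
matrix (rows = time points, columns = ROIs):

* the dense Pearson-correlation network ``P``;
* weighted-sparse-representation (WSR) networks ``W`` at a grid of sparsity
  priors ``lambda``, in which each ROI's signal is regressed on all others
  under a correlation-weighted L1 penalty solved by ADMM;
* sparsity-guided networks ``M = G * P``, where ``G`` is the binarized
  symmetric support of ``W`` — the topology comes from the sparse model, the
  edge weights from Pearson correlation.

A proportional hard-threshold alternative (keep the strongest ``100-q`` % of
edges of ``|P|``) is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TimeSeriesMatrix",
    "WSRResult",
    "FCNStack",
    "dyadic_grid",
    "normalize_series",
    "pearson_matrix",
    "penalty_weights",
    "solve_wsr",
    "binarize_symmetric_support",
    "sparsity_guided_fcn",
    "build_fcn_stack",
    "hard_threshold_stack",
    "network_density",
    "GuidedFCNTransform",
    "HardThresholdTransform",
]

#: entries of W with absolute value below this are treated as exact zeros
SUPPORT_EPS = 1e-5

#: default hard-threshold discard percentages (percent of edges removed)
HARD_THRESHOLD_PERCENTS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass
class TimeSeriesMatrix:
    """One subject's normalized ROI time series (L time points x N ROIs).

    Columns are centered and scaled to unit Euclidean norm, so the Gram
    matrix ``X.T @ X`` is exactly the matrix of sample Pearson correlations.
    """

    values: np.ndarray
    roi_ids: list[str]
    subject_id: str = ""
    label: int | None = None

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class WSRResult:
    """Solution of the weighted sparse representation problem at one lambda."""

    W: np.ndarray
    lam: float
    converged: bool
    n_iter: int
    objective: float


@dataclass
class FCNStack:
    """A stack of d sparsified connectivity matrices for one subject."""

    M: np.ndarray  # (d, N, N)
    lam_grid: np.ndarray  # (d,) sparsity priors (or discard percents)
    subject_id: str = ""
    label: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.M.shape[0]

    def densities(self) -> np.ndarray:
        return np.array([network_density(m) for m in self.M])


def dyadic_grid(lo: int = -4, hi: int = 5) -> np.ndarray:
    """Powers of two ``2**lo .. 2**hi`` — the default sparsity-prior grid."""
    if hi < lo:
        raise ValueError(f"empty grid: lo={lo} > hi={hi}")
    return 2.0 ** np.arange(lo, hi + 1)


def normalize_series(
    raw: np.ndarray,
    roi_ids: list[str] | None = None,
    subject_id: str = "",
    label: int | None = None,
) -> TimeSeriesMatrix:
    """Center each column and scale it to unit Euclidean norm.

    Under this convention the dot product of two columns equals their sample
    Pearson correlation, so downstream correlation matrices are plain Gram
    matrices.

    Raises
    ------
    ValueError
        If the input has fewer than 2 rows, contains non-finite values, or
        any column is constant (zero variance).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D time-by-ROI matrix, got shape {raw.shape}")
    L, N = raw.shape
    if L < 2:
        raise ValueError(f"need at least 2 time points, got L={L}")
    if not np.all(np.isfinite(raw)):
        bad = np.argwhere(~np.isfinite(raw))
        raise ValueError(f"non-finite values at (row, col) {bad[:5].tolist()}")
    centered = raw - raw.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"constant column(s) with zero variance at indices {zero.tolist()}")
    values = centered / norms
    if roi_ids is None:
        roi_ids = [f"ROI{j + 1}" for j in range(N)]
    if len(roi_ids) != N:
        raise ValueError(f"{len(roi_ids)} ROI labels for {N} columns")
    return TimeSeriesMatrix(values=values, roi_ids=list(roi_ids), subject_id=subject_id, label=label)


def pearson_matrix(ts: TimeSeriesMatrix) -> np.ndarray:
    """Pearson correlation matrix ``P = X.T @ X`` of normalized series.

    Symmetric with unit diagonal; entries clipped to [-1, 1] against
    floating-point overshoot.
    """
    X = ts.values
    P = X.T @ X
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return P


def penalty_weights(P: np.ndarray, sigma: float = 0.2) -> np.ndarray:
    """Correlation-dependent L1 penalty weights ``C_ji = exp(-P_ji**2 / sigma)``.

    Strongly correlated pairs receive a small penalty (their edge is cheap to
    keep); near-zero correlations receive weight ~1. ``sigma`` controls the
    attenuation speed of the weight with correlation strength.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    P = np.asarray(P, dtype=float)
    return np.exp(-(P**2) / sigma)


def _wsr_objective(X: np.ndarray, W: np.ndarray, C: np.ndarray, lam: float) -> float:
    return 0.5 * np.linalg.norm(X - X @ W, "fro") ** 2 + lam * np.abs(C * W).sum()


def solve_wsr(
    ts: TimeSeriesMatrix,
    C: np.ndarray,
    lam: float,
    rho: float = 1.0,
    max_iter: int = 500,
    abstol: float = 1e-8,
    reltol: float = 1e-6,
) -> WSRResult:
    """Weighted sparse representation of every ROI by all the others.

    Solves ``min_W 0.5 * ||X - X W||_F^2 + lam * ||C * W||_1`` subject to
    ``diag(W) = 0`` with ADMM (splitting ``W = Z``; the L1 prox is an
    elementwise soft-threshold at ``lam * C / rho``, and the diagonal
    constraint is folded into the prox step). The zero diagonal makes column
    ``i``'s problem identical to regressing signal ``x_i`` on the dictionary
    of all other ROI signals.

    Returns the exactly-sparse splitting variable ``Z``. On hitting the
    iteration budget the best (final) iterate is returned with
    ``converged=False`` and a warning.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("penalty weights must be strictly positive")
    X = ts.values
    N = X.shape[1]
    G = X.T @ X
    # (G + rho I) is SPD; one Cholesky serves every iteration
    cho = np.linalg.cholesky(G + rho * np.eye(N))
    thresh = lam * C / rho
    Z = np.zeros((N, N))
    U = np.zeros((N, N))
    n2 = float(N)  # sqrt(N*N)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rhs = G + rho * (Z - U)
        W = np.linalg.solve(cho.T, np.linalg.solve(cho, rhs))
        Z_old = Z
        V = W + U
        Z = np.sign(V) * np.maximum(np.abs(V) - thresh, 0.0)
        np.fill_diagonal(Z, 0.0)
        U = U + W - Z
        r = np.linalg.norm(W - Z, "fro")
        s = rho * np.linalg.norm(Z - Z_old, "fro")
        eps_pri = n2 * abstol + reltol * max(np.linalg.norm(W, "fro"), np.linalg.norm(Z, "fro"))
        eps_dual = n2 * abstol + reltol * rho * np.linalg.norm(U, "fro")
        if r <= eps_pri and s <= eps_dual:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WSR ADMM did not converge in {max_iter} iterations (lam={lam:g}); "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    obj = _wsr_objective(X, Z, C, lam)
    return WSRResult(W=Z, lam=lam, converged=converged, n_iter=it, objective=obj)


def binarize_symmetric_support(W: np.ndarray, eps: float = SUPPORT_EPS) -> np.ndarray:
    """Binary symmetric support of a sparse coefficient matrix.

    An edge (i, j) is present iff either direction's coefficient exceeds
    ``eps`` in magnitude (OR symmetrization — the support of ``|W| + |W.T|``).
    The diagonal is forced to zero. Idempotent on {0,1} matrices.
    """
    if eps < 0:
        raise ValueError(f"eps must be nonnegative, got {eps}")
    A = np.abs(np.asarray(W, dtype=float))
    G = ((A > eps) | (A.T > eps)).astype(np.int8)
    np.fill_diagonal(G, 0)
    return G


def sparsity_guided_fcn(P: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Mask the Pearson matrix with a binary topology: ``M = G * P``.

    Retained entries equal the corresponding Pearson correlations exactly
    (signed); removed entries are zero.
    """
    P = np.asarray(P, dtype=float)
    G = np.asarray(G)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs G {G.shape}")
    return np.where(G != 0, P, 0.0)


def network_density(M: np.ndarray, eps: float = 0.0) -> float:
    """Fraction of off-diagonal upper-triangle entries that are nonzero."""
    N = M.shape[0]
    iu = np.triu_indices(N, k=1)
    return float(np.mean(np.abs(M[iu]) > eps))


def build_fcn_stack(
    ts: TimeSeriesMatrix,
    lam_grid: np.ndarray | None = None,
    sigma: float = 0.2,
    eps: float = SUPPORT_EPS,
    **admm_kwargs,
) -> FCNStack:
    """Sparsity-guided FCN stack ``{M^{lam_k} = G^{lam_k} * P}`` over a lambda grid.

    The default dyadic grid ``2**-4 .. 2**5`` yields d = 10 networks whose
    density is non-increasing in lambda.
    """
    if lam_grid is None:
        lam_grid = dyadic_grid()
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.ndim != 1 or lam_grid.size == 0:
        raise ValueError("lam_grid must be a non-empty 1-D array")
    if np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lam_grid must be strictly increasing")
    P = pearson_matrix(ts)
    C = penalty_weights(P, sigma)
    M = np.empty((lam_grid.size, ts.n_rois, ts.n_rois))
    diag: dict = {"converged": [], "n_iter": [], "objective": []}
    for k, lam in enumerate(lam_grid):
        res = solve_wsr(ts, C, lam, **admm_kwargs)
        G = binarize_symmetric_support(res.W, eps)
        M[k] = sparsity_guided_fcn(P, G)
        diag["converged"].append(res.converged)
        diag["n_iter"].append(res.n_iter)
        diag["objective"].append(res.objective)
    return FCNStack(M=M, lam_grid=lam_grid, subject_id=ts.subject_id, label=ts.label, diagnostics=diag)


def hard_threshold_stack(
    P: np.ndarray,
    percents: tuple[float, ...] | list[float] = HARD_THRESHOLD_PERCENTS,
    subject_id: str = "",
    label: int | None = None,
) -> FCNStack:
    """Proportionally thresholded networks: discard the weakest q% of edges.

    For each percent ``q``, the ``floor((1 - q/100) * E)`` off-diagonal edge
    pairs of largest ``|P|`` are retained (E = N(N-1)/2 total pairs); ties in
    magnitude are broken by lexicographic (i, j) order for determinism. The
    diagonal is zeroed; retained entries keep their signed correlations.
    """
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    percents = np.asarray(percents, dtype=float)
    if np.any((percents < 0) | (percents >= 100)):
        raise ValueError("discard percents must lie in [0, 100)")
    iu, ju = np.triu_indices(N, k=1)
    vals = np.abs(P[iu, ju])
    n_edges = vals.size
    # descending |value|; lexicographic (i, j) among ties -> stable sort on
    # index order after primary sort key
    order = np.lexsort((ju, iu, -vals))
    M = np.zeros((percents.size, N, N))
    for k, q in enumerate(percents):
        keep = int(np.floor((1.0 - q / 100.0) * n_edges))
        sel = order[:keep]
        M[k, iu[sel], ju[sel]] = P[iu[sel], ju[sel]]
        M[k] += M[k].T
    return FCNStack(M=M, lam_grid=percents, subject_id=subject_id, label=label)


class GuidedFCNTransform(BaseEstimator, TransformerMixin):
    """Transformer: raw ROI time series -> sparsity-guided FCN stacks.

    Stateless (``fit`` only validates parameters). ``transform`` maps a list
    of L x N raw time-series arrays (or ``TimeSeriesMatrix``) to an array of
    shape ``(n_subjects, d, N, N)`` suitable for :class:`SMFCNetClassifier`.

    Parameters
    ----------
    lam_grid : array-like or None
        Strictly increasing sparsity priors; ``None`` selects the dyadic
        grid ``2**-4 .. 2**5`` (d = 10).
    sigma : float
        Penalty-weight attenuation parameter (default 0.2).
    eps : float
        Magnitude below which WSR coefficients count as zero.
    """

    def __init__(self, lam_grid=None, sigma: float = 0.2, eps: float = SUPPORT_EPS,
                 rho: float = 1.0, max_iter: int = 500):
        self.lam_grid = lam_grid
        self.sigma = sigma
        self.eps = eps
        self.rho = rho
        self.max_iter = max_iter

    def fit(self, X, y=None):
        grid = dyadic_grid() if self.lam_grid is None else np.asarray(self.lam_grid, float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lam_grid must be strictly increasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.lam_grid_ = grid
        return self

    def transform(self, X):
        if not hasattr(self, "lam_grid_"):
            self.fit(X)
        stacks = [self.transform_one(x) for x in X]
        return np.stack([s.M for s in stacks])

    def transform_one(self, x) -> FCNStack:
        ts = x if isinstance(x, TimeSeriesMatrix) else normalize_series(np.asarray(x))
        grid = dyadic_grid() if self.lam_grid is None else np.asarray(self.lam_grid, float)
        return build_fcn_stack(ts, grid, sigma=self.sigma, eps=self.eps,
                               rho=self.rho, max_iter=self.max_iter)


class HardThresholdTransform(BaseEstimator, TransformerMixin):
    """Transformer: raw ROI time series -> proportionally hard-thresholded stacks."""

    def __init__(self, percents=HARD_THRESHOLD_PERCENTS):
        self.percents = percents

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        out = []
        for x in X:
            ts = x if isinstance(x, TimeSeriesMatrix) else normalize_series(np.asarray(x))
            P = pearson_matrix(ts)
            out.append(hard_threshold_stack(P, self.percents).M)
        return np.stack(out)
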