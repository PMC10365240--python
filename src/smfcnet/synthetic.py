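"""Synthetic cohorts of ROI time series with known connectivity structure.

Two groups of subjects are sampled from zero-mean multivariate normal
distributions whose covariance (or precision) matrices share a sparse
random off-diagonal support, with a chosen set of "discriminative" edges
whose strength differs between groups by a fixed effect size. Optional
AR(1) filtering adds temporal autocorrelation while preserving the
stationary cross-sectional covariance. Dimensions default to the emulated
resting-state cohort: two groups of 57 and 68 subjects, 120 ROIs, 140 time
points.

Gaussian signals of this kind stand in for band-passed BOLD averages; no
hemodynamic model is attempted. Every stage of the pipeline (correlation
estimation, sparse-topology recovery, classification, occlusion mapping)
can be validated against the generator's ground-truth edge sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fcn import TimeSeriesMatrix, normalize_series

__all__ = ["CohortSpec", "make_group_covariances", "sample_cohort"]

_PD_MARGIN = 1e-8


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    ``effect_size`` is the covariance difference planted on each
    discriminative edge (group 1 minus group 0). ``planting`` selects
    whether structure lives in the covariance itself (directly visible to
    Pearson correlation) or in the precision matrix (the ground truth for
    conditional-dependence recovery). ``noise_sd`` adds white measurement
    noise on top of the latent signal. ``temporal_corr`` is the AR(1)
    coefficient of the temporal filter.
    """

    n_per_group: tuple[int, int] = (57, 68)
    n_rois: int = 120
    series_length: int = 140
    base_density: float = 0.1
    n_discriminative_edges: int = 10
    effect_size: float = 0.3
    noise_sd: float = 0.0
    temporal_corr: float = 0.0
    seed: int = 0
    planting: str = "covariance"

    def __post_init__(self):
        if min(self.n_per_group) < 1 or self.n_rois < 2 or self.series_length < 2:
            raise ValueError("cohort dimensions out of range")
        if not 0 <= self.base_density <= 1:
            raise ValueError(f"base_density must lie in [0, 1], got {self.base_density}")
        if not 0 <= self.temporal_corr < 1:
            raise ValueError("temporal_corr must lie in [0, 1)")
        if self.planting not in ("covariance", "precision"):
            raise ValueError(f"unknown planting mode {self.planting!r}")
        n_pairs = self.n_rois * (self.n_rois - 1) // 2
        if self.n_discriminative_edges > n_pairs:
            raise ValueError("more discriminative edges than ROI pairs")


def _shrink_to_pd(A: np.ndarray, what: str) -> np.ndarray:
    """Repeatedly shrink off-diagonal entries until the matrix is PD."""
    A = A.copy()
    factor = 1.0
    while np.linalg.eigvalsh(A)[0] <= _PD_MARGIN:
        off = A - np.diag(np.diag(A))
        A = np.diag(np.diag(A)) + 0.9 * off
        factor *= 0.9
    if factor < 1.0:
        warnings.warn(f"{what} off-diagonal entries shrunk by {factor:.3g} "
                      "to restore positive definiteness", RuntimeWarning,
                      stacklevel=3)
    return A


def make_group_covariances(spec: CohortSpec):
    """Build the two group covariance matrices and their ground-truth edges.

    A shared Erdos-Renyi support at ``base_density`` defines the baseline
    off-diagonal structure (values uniform in +/-[0.15, 0.35]);
    ``n_discriminative_edges`` randomly chosen pairs then differ between
    groups by ``effect_size``. In precision mode the same construction is
    applied to the precision matrix and inverted (then rescaled to unit
    diagonal), so the true conditional-dependence support is sparse while
    marginal correlations spread along paths. Both matrices are forced
    positive definite: the baseline by shrinking its off-diagonal values,
    the group difference by shrinking the effect size (each with a warning).

    Returns ``(cov0, cov1, truth)`` where ``truth`` has the baseline edge
    list, the discriminative edge list, and the realized effect size.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_rois
    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    n_pairs = len(pairs)
    n_base = int(round(spec.base_density * n_pairs))
    base_sel = rng.choice(n_pairs, size=n_base, replace=False)
    base = np.eye(N)
    for idx in base_sel:
        i, j = pairs[idx]
        v = rng.uniform(0.15, 0.35) * rng.choice([-1.0, 1.0])
        base[i, j] = base[j, i] = v
    base = _shrink_to_pd(base, "baseline")

    disc_sel = rng.choice(n_pairs, size=spec.n_discriminative_edges, replace=False)
    disc_edges = [pairs[idx] for idx in disc_sel]

    effect = spec.effect_size
    while True:
        shifted = base.copy()
        for i, j in disc_edges:
            shifted[i, j] += effect
            shifted[j, i] += effect
        if np.linalg.eigvalsh(shifted)[0] > _PD_MARGIN or effect == 0:
            break
        effect *= 0.9
    if effect != spec.effect_size:
        warnings.warn(f"effect size shrunk from {spec.effect_size:g} to "
                      f"{effect:g} to keep the group covariance positive "
                      "definite", RuntimeWarning, stacklevel=2)

    if spec.planting == "precision":
        cov0, cov1 = np.linalg.inv(base), np.linalg.inv(shifted)
        for c in (cov0, cov1):
            dinv = 1.0 / np.sqrt(np.diag(c))
            c *= np.outer(dinv, dinv)
    else:
        cov0, cov1 = base, shifted

    truth = {
        "base_edges": [pairs[idx] for idx in base_sel],
        "discriminative_edges": disc_edges,
        "effect_size": effect,
    }
    return cov0, cov1, truth


def _sample_series(rng, cov: np.ndarray, L: int, phi: float) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((L, cov.shape[0])) @ chol.T
    if phi == 0:
        return innov
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, L):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def sample_cohort(spec: CohortSpec):
    """Draw the labeled cohort as normalized :class:`TimeSeriesMatrix` objects.

    Each subject is an L x N multivariate normal draw from its group's
    covariance; with ``temporal_corr = phi > 0`` the series follow the
    stationary AR(1) recursion ``x_t = phi x_{t-1} + sqrt(1-phi^2) e_t``,
    which leaves the cross-sectional covariance unchanged. White noise of
    sd ``noise_sd`` is added before the columns are centered and scaled to
    unit norm.

    Returns ``(subjects, y, truth)``: the subject list, the 0/1 label
    array (group 1 = positive class), and the ground-truth edge dict of
    :func:`make_group_covariances`.
    """
    rng = np.random.default_rng(spec.seed)
    cov0, cov1, truth = make_group_covariances(spec)
    subjects: list[TimeSeriesMatrix] = []
    labels = []
    roi_ids = [f"ROI{j + 1}" for j in range(spec.n_rois)]
    for label, (cov, n_subj) in enumerate(zip((cov0, cov1), spec.n_per_group)):
        for s in range(n_subj):
            x = _sample_series(rng, cov, spec.series_length, spec.temporal_corr)
            if spec.noise_sd > 0:
                x = x + spec.noise_sd * rng.standard_normal(x.shape)
            subjects.append(normalize_series(
                x, roi_ids=roi_ids, subject_id=f"g{label}_s{s:03d}", label=label))
            labels.append(label)
    return subjects, np.asarray(labels), truth
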