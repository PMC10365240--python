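"""Occlusion-based importance of connections and brain regions.

A trained ensemble's test accuracy is re-measured after zeroing out one
functional connection (both symmetric entries, in all d matrices of every
subject's stack) or one region (its whole row and column). The accuracy
drop relative to the unoccluded ensemble is the importance of that edge or
region. Region drops are passed through an exponential and min-max
normalized to a contribution score in [0, 1]:

    D_n = exp(ACC - ACC_masked_n),   C_n = (D_n - min D) / (max D - min D).

All accuracies are fractions; evaluation reuses the stored nested-CV fold
structure, so every subject is only ever scored by classifiers that never
saw it in training, and no weights are updated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .evaluation import NestedCVResult, ensemble_accuracy

__all__ = [
    "edge_pairs",
    "edge_importance",
    "region_contribution",
    "top_k_report",
]


def edge_pairs(n_rois: int) -> list[tuple[int, int]]:
    """All unordered ROI pairs (i, j), i < j — N(N-1)/2 of them."""
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def _ensemble_checksum(result: NestedCVResult) -> float:
    total = 0.0
    for rep in result.ensembles:
        for fe in rep:
            for clf in fe.classifiers:
                net = getattr(clf, "network_", None)
                if net is not None:
                    total += net.parameter_checksum()
    return total


def edge_importance(result: NestedCVResult, X, y) -> pd.DataFrame:
    """Accuracy drop from occluding each functional connection.

    For every unordered ROI pair, entries (i, j) and (j, i) are zeroed in
    all d matrices of every subject's stack and the ensemble's mean
    majority-vote test accuracy is recomputed; the drop from the unoccluded
    accuracy (in percentage points) is that connection's contribution.

    Returns a DataFrame with columns ``roi_i``, ``roi_j`` (0-based, i < j)
    and ``accuracy_drop`` (percent), one row per pair.
    """
    X = np.asarray(X)
    n_rois = X.shape[-1]
    before = _ensemble_checksum(result)
    base = ensemble_accuracy(result, X, y)
    rows = []
    for i, j in edge_pairs(n_rois):
        Xo = X.copy()
        Xo[..., i, j] = 0.0
        Xo[..., j, i] = 0.0
        acc = ensemble_accuracy(result, Xo, y)
        rows.append((i, j, (base - acc) * 100.0))
    assert _ensemble_checksum(result) == before, "occlusion must not update weights"
    return pd.DataFrame(rows, columns=["roi_i", "roi_j", "accuracy_drop"])


def region_contribution(result: NestedCVResult, X, y) -> pd.DataFrame:
    """Normalized contribution of each ROI from row/column occlusion.

    Region n's row and column are zeroed in all d matrices of every stack;
    ``D_n = exp(ACC - ACC_masked_n)`` with accuracies as fractions, and
    ``C_n`` min-max normalizes D over regions. If every region produces the
    same drop the normalization is undefined and C is reported as all zeros
    with a warning.

    Returns a DataFrame with columns ``roi`` (0-based), ``accuracy_masked``,
    ``D`` and ``C``.
    """
    X = np.asarray(X)
    n_rois = X.shape[-1]
    before = _ensemble_checksum(result)
    base = ensemble_accuracy(result, X, y)
    acc_masked = np.empty(n_rois)
    for n in range(n_rois):
        Xo = X.copy()
        Xo[..., n, :] = 0.0
        Xo[..., :, n] = 0.0
        acc_masked[n] = ensemble_accuracy(result, Xo, y)
    assert _ensemble_checksum(result) == before, "occlusion must not update weights"
    D = np.exp(base - acc_masked)
    span = D.max() - D.min()
    if span == 0:
        warnings.warn("all regions produced identical accuracy drops; "
                      "contributions are undefined and reported as 0",
                      RuntimeWarning, stacklevel=2)
        C = np.zeros(n_rois)
    else:
        C = (D - D.min()) / span
    return pd.DataFrame({"roi": np.arange(n_rois), "accuracy_masked": acc_masked,
                         "D": D, "C": C})


def top_k_report(table: pd.DataFrame, k: int,
                 roi_names: list[str] | None = None) -> pd.DataFrame:
    """Top-k connections by accuracy drop, ties broken by (i, j) order.

    ROI indices in the output are 1-based (atlas convention); when
    ``roi_names`` is given, name columns are attached.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} table rows")
    ranked = table.sort_values(
        ["accuracy_drop", "roi_i", "roi_j"], ascending=[False, True, True],
        kind="mergesort").head(k).reset_index(drop=True)
    out = ranked.copy()
    out["roi_i_index"] = out["roi_i"] + 1
    out["roi_j_index"] = out["roi_j"] + 1
    if roi_names is not None:
        out["roi_i_name"] = [roi_names[i] for i in ranked["roi_i"]]
        out["roi_j_name"] = [roi_names[j] for j in ranked["roi_j"]]
    return out
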