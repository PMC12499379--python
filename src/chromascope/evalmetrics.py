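"""Map-comparison metrics: Pearson, distance-stratified correlation, AUROC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata

from chromascope.matrixio import ContactMatrix, LogFoldMatrix

__all__ = [
    "pearson_map",
    "distance_stratified_corr",
    "recovery_auroc",
    "StratifiedCorrelation",
]


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, (ContactMatrix, LogFoldMatrix)) else np.asarray(m, float)


@dataclass
class StratifiedCorrelation:
    """Per-diagonal Pearson r, indexed by genomic separation."""

    distance: np.ndarray     # bp
    r: np.ndarray            # NaN where a diagonal is constant or too short


def pearson_map(a, b) -> float:
    """Pearson r over unmasked upper-triangle entries of two maps.

    Returns NaN when either input is constant over the compared entries.
    """
    A, B = _values(a), _values(b)
    if A.shape != B.shape:
        raise ValueError("maps must share shape")
    iu = np.triu_indices(A.shape[0])
    x, y = A[iu], B[iu]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    return float(pearsonr(x, y).statistic)


def distance_stratified_corr(a, b, min_pairs: int = 3,
                             resolution: int | None = None) -> StratifiedCorrelation:
    """Pearson r between the matching diagonals of two maps, per separation."""
    A, B = _values(a), _values(b)
    if A.shape != B.shape:
        raise ValueError("maps must share shape")
    if resolution is None:
        resolution = getattr(a, "resolution", 1)
    n = A.shape[0]
    rs = np.full(n, np.nan)
    for d in range(n):
        x = np.diagonal(A, offset=d)
        y = np.diagonal(B, offset=d)
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if x.size < min_pairs or np.all(x == x[0]) or np.all(y == y[0]):
            continue
        rs[d] = pearsonr(x, y).statistic
    return StratifiedCorrelation(np.arange(n) * resolution, rs)


def recovery_auroc(scores, truth) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2).

    Computed from the rank-sum (Mann-Whitney) identity, so it is exact under
    ties.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
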