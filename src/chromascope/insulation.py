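"""Insulation scoring, TAD boundary calling, differential-insulation analysis.

Two insulation notions coexist deliberately. ``diamond_insulation`` is the
standard sliding-diamond score (mean cross-boundary contact in a window),
whose local minima mark TAD boundaries. ``insulation_profile`` is the
boundary-strength ratio

    INSUL = (L + R + Const) / (M + Const)

where, for a window of ``w`` bins on each side of bin ``i``, L and R are the
mean intensities of the two intra-side square blocks, M is the mean of the
cross block, and Const is the average intensity of the map (mean over nonzero
unmasked entries — zeros in a sparse contact map are unobserved pairs, not
observed absences). Higher INSUL means a stronger boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chromascope.errors import DegenerateInputError
from chromascope.matrixio import BinTable, ContactMatrix, LogFoldMatrix, pool

__all__ = [
    "InsulationProfile",
    "BoundarySet",
    "DifferentialInsulation",
    "insulation_profile",
    "diamond_insulation",
    "tad_boundaries",
    "boundary_insul",
    "differential_insulation",
]


@dataclass
class InsulationProfile:
    """Per-bin INSUL ratio; NaN where a full window does not fit."""

    bins: BinTable
    insul: np.ndarray
    window_bins: int
    const: float


@dataclass
class BoundarySet:
    """Sorted TAD boundary bin indices with their insulation depths."""

    positions: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class DifferentialInsulation:
    """Perturbed-minus-original insulation peak and its same-sign width."""

    delta: np.ndarray
    peak_position: int | None
    peak_value: float
    peak_sign: int | None          # +1 / -1, None for a null peak
    impact_width: int
    arm_left: int = 0
    arm_right: int = 0

    @property
    def is_null(self) -> bool:
        return self.peak_sign is None


def map_const(values: np.ndarray) -> float:
    """Average intensity of the map: mean over nonzero unmasked entries."""
    finite = values[~np.isnan(values)]
    nonzero = finite[finite != 0]
    if nonzero.size == 0:
        return 0.0
    return float(nonzero.mean())


def insulation_profile(m: ContactMatrix | LogFoldMatrix,
                       window_bins: int = 50,
                       const: float | None = None) -> InsulationProfile:
    """Boundary-strength INSUL ratio at every bin with full window support.

    For bin ``i`` with window ``w``: L = mean over [i-w, i) x [i-w, i),
    R = mean over (i, i+w] x (i, i+w], M = mean over [i-w, i) x (i, i+w];
    INSUL = (L + R + Const) / (M + Const). Masked entries are excluded from
    every mean.
    """
    n = m.n_bins
    w = int(window_bins)
    if n <= 2 * w:
        raise ValueError(f"matrix of {n} bins too small for window of {w} bins")
    V = m.values
    if const is None:
        const = map_const(V)
    insul = np.full(n, np.nan)
    if const == 0.0 and not np.any(np.nan_to_num(V)):
        raise DegenerateInputError("all-zero matrix: INSUL is 0/0 everywhere")
    with np.errstate(invalid="ignore"):
        for i in range(w, n - w):
            left = V[i - w:i, i - w:i]
            right = V[i + 1:i + w + 1, i + 1:i + w + 1]
            mid = V[i - w:i, i + 1:i + w + 1]
            L = np.nanmean(left) if np.any(~np.isnan(left)) else np.nan
            R = np.nanmean(right) if np.any(~np.isnan(right)) else np.nan
            M = np.nanmean(mid) if np.any(~np.isnan(mid)) else np.nan
            denom = M + const
            if denom == 0:
                continue
            insul[i] = (L + R + const) / denom
    return InsulationProfile(m.bins, insul, w, const)


def diamond_insulation(m: ContactMatrix | LogFoldMatrix,
                       window_bins: int = 40) -> np.ndarray:
    """Sliding-diamond insulation track: mean cross-boundary contact at each bin.

    Undefined (NaN) at the edges where the full diamond does not fit; no
    shrunken windows.
    """
    n = m.n_bins
    w = int(window_bins)
    if w < 1:
        raise ValueError("window must span at least 1 bin")
    V = m.values
    score = np.full(n, np.nan)
    with np.errstate(invalid="ignore"):
        for i in range(w, n - w):
            block = V[i - w:i, i + 1:i + w + 1]
            if np.any(~np.isnan(block)):
                score[i] = np.nanmean(block)
    return score


def tad_boundaries(m: ContactMatrix | LogFoldMatrix,
                   resolution: int | None = None,
                   window: int = 1_000_000,
                   delta_bins: int = 3,
                   min_depth: float = 0.0) -> BoundarySet:
    """Call TAD boundaries as delta-vector minima of the diamond insulation track.

    The matrix is pooled to ``resolution`` first if coarser than its own
    (defaults: 25-kb bins, 1-Mb window). The delta vector at bin ``i`` is the
    mean diamond score over ``delta_bins`` bins upstream minus the mean over
    ``delta_bins`` downstream; a boundary sits where delta crosses zero
    downward, i.e. at a local minimum of the track. ``min_depth`` optionally
    discards shallow minima (depth relative to flanking delta amplitude).
    """
    if resolution is not None and resolution > m.resolution:
        if resolution % m.resolution:
            raise ValueError("target resolution must be a multiple of the matrix's")
        m = pool(m, resolution // m.resolution)
    res = m.resolution
    w = max(2, int(round(window / res)))
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    track = diamond_insulation(m, window_bins=w)
    n = track.size
    d = int(delta_bins)
    delta = np.full(n, np.nan)
    with np.errstate(invalid="ignore"):
        for i in range(d, n - d):
            up = track[i - d:i]
            down = track[i + 1:i + d + 1]
            if np.any(~np.isnan(up)) and np.any(~np.isnan(down)):
                delta[i] = np.nanmean(up) - np.nanmean(down)
    positions, scores = [], []
    for i in range(n - 1):
        if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
            continue
        if delta[i] >= 0 > delta[i + 1]:
            # delta crosses zero downward: pick the deeper of the two bins
            cand = i if np.nan_to_num(track[i], nan=np.inf) <= \
                np.nan_to_num(track[i + 1], nan=np.inf) else i + 1
            depth = delta[i] - delta[i + 1]
            if depth >= min_depth:
                positions.append(cand)
                scores.append(float(depth))
    return BoundarySet(np.asarray(positions, dtype=np.int64),
                       np.asarray(scores, dtype=np.float64))


def boundary_insul(m: ContactMatrix | LogFoldMatrix,
                   boundaries: BoundarySet,
                   window_bins: int = 50) -> np.ndarray:
    """INSUL ratio evaluated at each boundary; boundaries without full-window
    support are skipped (NaN) with a warning."""
    import warnings

    profile = insulation_profile(m, window_bins=window_bins)
    out = np.full(len(boundaries), np.nan)
    for k, pos in enumerate(boundaries.positions):
        if np.isnan(profile.insul[pos]):
            warnings.warn(f"boundary at bin {pos} lacks full window support; skipped")
        else:
            out[k] = profile.insul[pos]
    return out


def differential_insulation(orig: InsulationProfile,
                            pert: InsulationProfile,
                            center: int | None = None,
                            half_window: int | None = None) -> DifferentialInsulation:
    """Perturbed-minus-original insulation peak around ``center``.

    The peak is the extremum of ``|delta|`` within ``center +/- half_window``
    (the full profile when unset). The impact width counts the contiguous bins
    around the peak sharing the peak's sign, the peak included; the two arms
    are recorded separately. Identical profiles yield a null-peak record.
    """
    if orig.insul.shape != pert.insul.shape:
        raise ValueError("profiles must share bins")
    delta = pert.insul - orig.insul
    n = delta.size
    lo, hi = 0, n
    if center is not None and half_window is not None:
        lo = max(0, center - half_window)
        hi = min(n, center + half_window + 1)
    window = np.nan_to_num(delta[lo:hi], nan=0.0)
    if window.size == 0 or np.all(window == 0):
        return DifferentialInsulation(delta, None, 0.0, None, 0)
    k = int(np.argmax(np.abs(window)))
    peak = lo + k
    peak_value = float(delta[peak])
    sign = 1 if peak_value > 0 else -1

    def same_sign(x: float) -> bool:
        return not np.isnan(x) and (x > 0) == (sign > 0) and x != 0

    left = 0
    j = peak - 1
    while j >= 0 and same_sign(delta[j]):
        left += 1
        j -= 1
    right = 0
    j = peak + 1
    while j < n and same_sign(delta[j]):
        right += 1
        j += 1
    return DifferentialInsulation(delta, peak, peak_value, sign,
                                  impact_width=left + right + 1,
                                  arm_left=left, arm_right=right)
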