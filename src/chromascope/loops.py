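"""Chromatin loops: nesting hierarchy, valency, categories and a naive caller.

A loop ``a`` is a sub-loop of ``b`` when ``b.lower <= a.lower < a.upper <=
b.upper`` and the two are not identical. Main-loops are loops enclosed by no
other; the valency of a main-loop counts every loop nested within it at any
depth. Identical coordinate pairs would nest in each other, so duplicates are
removed (with a warning) before the hierarchy is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import poisson

from chromascope.matrixio import LogFoldMatrix

__all__ = [
    "Loop",
    "LoopHierarchy",
    "is_subloop",
    "loop_hierarchy",
    "classify_loops",
    "loop_stats",
    "naive_loop_caller",
    "read_bedpe",
    "write_bedpe",
]


@dataclass(frozen=True)
class Loop:
    """A point-to-point contact with anchor coordinates lower < upper (bp)."""

    chrom: str
    lower: int
    upper: int
    score: float = np.nan
    category: str = "unset"      # PP / EP / EE / other / unset

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError(f"loop must have lower < upper, got ({self.lower}, {self.upper})")

    @property
    def size(self) -> int:
        return self.upper - self.lower


@dataclass
class LoopHierarchy:
    """Main-/sub-loop structure: parents, main flags, and per-main valencies."""

    loops: list[Loop]
    parent: list[int | None]      # index of the smallest enclosing loop
    is_main: np.ndarray
    valency: dict[int, int]       # main-loop index -> count of nested loops

    @property
    def main_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.is_main) if m]


def is_subloop(a: Loop, b: Loop) -> bool:
    """True iff ``a`` nests strictly inside ``b`` (identical pairs excluded)."""
    if a.chrom != b.chrom:
        return False
    if (a.lower, a.upper) == (b.lower, b.upper):
        return False
    return b.lower <= a.lower < a.upper <= b.upper


def loop_hierarchy(loops: list[Loop]) -> LoopHierarchy:
    """Build the main-loop/sub-loop hierarchy.

    Each loop's parent is its smallest enclosing loop (ties broken by size,
    then lower coordinate, then input order — intervals may partially
    overlap, so enclosers need not form a chain). Candidates are scanned in
    increasing size order, so the first encloser found is the parent.
    """
    chroms = {lp.chrom for lp in loops}
    if len(chroms) > 1:
        raise ValueError("loop_hierarchy expects loops on a single chromosome")
    seen: dict[tuple[int, int], int] = {}
    uniq: list[Loop] = []
    for lp in loops:
        key = (lp.lower, lp.upper)
        if key in seen:
            warnings.warn(f"duplicate loop {key} removed before hierarchy construction")
            continue
        seen[key] = len(uniq)
        uniq.append(lp)
    by_size = sorted(range(len(uniq)),
                     key=lambda i: (uniq[i].size, uniq[i].lower, i))
    parent: list[int | None] = [None] * len(uniq)
    for i in range(len(uniq)):
        for j in by_size:
            if uniq[j].size < uniq[i].size:
                continue
            if j != i and is_subloop(uniq[i], uniq[j]):
                parent[i] = j
                break
    is_main = np.array([p is None for p in parent], dtype=bool)
    # valency counts every loop nested in the main by the coordinate rule,
    # at any depth — mains may partially overlap, so parent chains alone
    # would undercount
    lowers = np.array([lp.lower for lp in uniq])
    uppers = np.array([lp.upper for lp in uniq])
    valency = {}
    for i in np.flatnonzero(is_main):
        inside = (lowers >= uniq[i].lower) & (uppers <= uniq[i].upper)
        valency[int(i)] = int(inside.sum()) - 1       # exclude the main itself
    return LoopHierarchy(uniq, parent, is_main, valency)


def _label_anchor(chrom: str, pos: int, pad: int, promoters, enhancers) -> str:
    lo, hi = pos - pad, pos + pad
    if promoters is not None and promoters.overlaps(chrom, lo, hi):
        return "P"
    if enhancers is not None and enhancers.overlaps(chrom, lo, hi):
        return "E"
    return "O"


def classify_loops(loops: list[Loop], promoters, enhancers,
                   anchor_pad: int = 10_000) -> list[Loop]:
    """Assign PP / EP / EE / other categories from anchor overlaps.

    Each anchor is a ``+/- anchor_pad`` window around the loop coordinate;
    an anchor overlapping both a promoter and an enhancer counts as promoter
    (promoter precedence). ``promoters``/``enhancers`` are
    :class:`chromascope.annotations.IntervalIndex` objects (or anything with
    an ``overlaps(chrom, start, end)`` method).
    """
    out = []
    for lp in loops:
        la = _label_anchor(lp.chrom, lp.lower, anchor_pad, promoters, enhancers)
        lb = _label_anchor(lp.chrom, lp.upper, anchor_pad, promoters, enhancers)
        pair = "".join(sorted(la + lb))
        category = {"PP": "PP", "EP": "EP", "EE": "EE"}.get(pair, "other")
        out.append(replace(lp, category=category))
    return out


def loop_stats(h: LoopHierarchy, region_length: int) -> dict:
    """Figure-level summary: loop density, main-loop size, size per valency.

    ``mean_size_per_valency`` is the ratio of the mean main-loop size to the
    mean valency over main-loops (valency-0 main-loops included in both
    means). With no main-loops the means are NaN sentinels.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    n = len(h.loops)
    count_per_mb = n / (region_length / 1e6)
    mains = h.main_indices
    if not mains:
        return {"count_per_mb": count_per_mb,
                "mean_main_size": np.nan,
                "mean_valency": np.nan,
                "mean_size_per_valency": np.nan}
    sizes = np.array([h.loops[i].size for i in mains], dtype=float)
    vals = np.array([h.valency[i] for i in mains], dtype=float)
    mean_valency = vals.mean()
    mean_size = sizes.mean()
    spv = mean_size / mean_valency if mean_valency > 0 else np.nan
    return {"count_per_mb": count_per_mb,
            "mean_main_size": float(mean_size),
            "mean_valency": float(mean_valency),
            "mean_size_per_valency": float(spv)}


def naive_loop_caller(lf: LogFoldMatrix, p_threshold: float = 0.01,
                      min_separation: int = 3, ring_inner: int = 2,
                      ring_outer: int = 5, nominal_depth: float = 100.0,
                      min_fold: float = 1.5) -> list[Loop]:
    """Donut-enrichment loop caller for synthetic log-fold maps.

    Candidate pixels are strict local maxima of the fold-space map at
    separations of at least ``min_separation`` bins. Each is scored by a
    one-sided Poisson test of the pixel against the mean of a surrounding
    ring (radii ``ring_inner``..``ring_outer``), both scaled by
    ``nominal_depth`` pseudo-reads; calls with p <= ``p_threshold`` and fold
    enrichment >= ``min_fold`` over the ring are returned, score = p.

    This is deliberately simple plumbing for planted-bump maps, not a
    replacement for production callers trained on experimental Hi-C.
    """
    F = np.exp(lf.values)
    n = lf.n_bins
    calls: list[Loop] = []
    r = ring_outer
    for i in range(n):
        for j in range(i + min_separation, n):
            c = F[i, j]
            if np.isnan(c):
                continue
            i0, i1 = max(0, i - ring_inner), min(n, i + ring_inner + 1)
            j0, j1 = max(0, j - ring_inner), min(n, j + ring_inner + 1)
            patch = F[i0:i1, j0:j1]
            if np.nanmax(patch) > c or np.sum(patch == np.nanmax(patch)) > 1:
                continue                      # not a strict local maximum
            I0, I1 = max(0, i - r), min(n, i + r + 1)
            J0, J1 = max(0, j - r), min(n, j + r + 1)
            ring = F[I0:I1, J0:J1].copy()
            ring[(i0 - I0):(i1 - I0), (j0 - J0):(j1 - J0)] = np.nan
            ring_vals = ring[~np.isnan(ring)]
            if ring_vals.size < 4:
                continue
            lam = max(ring_vals.mean(), 1e-12) * nominal_depth
            k = c * nominal_depth
            p = float(poisson.sf(np.ceil(k) - 1, lam))
            if p <= p_threshold and c / max(ring_vals.mean(), 1e-12) >= min_fold:
                calls.append(Loop(lf.bins.chrom,
                                  int(lf.bins.start[i]),
                                  int(lf.bins.start[j]),
                                  score=p))
    return calls


def read_bedpe(path) -> list[Loop]:
    """Read loops from BEDPE (chrom1 start1 end1 chrom2 start2 end2 [name score]).

    The anchor midpoints become the loop's lower/upper coordinates.
    """
    loops = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        c1, s1, e1, c2, s2, e2 = row[:6]
        if c1 != c2:
            continue                         # trans contacts out of scope
        score = float(row[7]) if len(row) > 7 else np.nan
        lo, up = (s1 + e1) // 2, (s2 + e2) // 2
        if lo > up:
            lo, up = up, lo
        loops.append(Loop(str(c1), int(lo), int(up), score=score))
    return loops


def write_bedpe(loops: list[Loop], path, anchor_half: int = 5_000) -> None:
    """Write loops as BEDPE with ``+/- anchor_half`` anchor intervals."""
    with open(path, "w") as fh:
        for k, lp in enumerate(loops):
            fh.write("\t".join(map(str, [
                lp.chrom, max(0, lp.lower - anchor_half), lp.lower + anchor_half,
                lp.chrom, max(0, lp.upper - anchor_half), lp.upper + anchor_half,
                f"loop_{k}_{lp.category}", lp.score])) + "\n")
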