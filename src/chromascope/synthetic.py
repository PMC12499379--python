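"""Synthetic contact maps with planted ground truth.

The generator plants the three structures the analysis modules measure — an
A/B checkerboard, TAD blocks separated by boundaries, and nested Gaussian
loop bumps — on a zero log-fold baseline (the power-law distance decay lives
in the expected vector, mirroring the log-fold-over-background map
representation), then optionally draws Poisson counts at a configurable
sequencing depth. ``make_tracks`` emits ATAC/CTCF tracks consistent with the
planted structure so the surrogate predictor can reconstruct it: an
accessibility plateau over A bins with peaks at loop anchors, and CTCF peaks
at boundaries and anchors.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chromascope.loops import Loop, loop_hierarchy
from chromascope.matrixio import BinTable, ContactMatrix, LogFoldMatrix
from chromascope.tracks import Track

__all__ = ["SimConfig", "GroundTruth", "make_truth", "render_logfold",
           "sample_counts", "make_tracks"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    The defaults emulate a 6.4-Mb region at 25-kb bins: eight ~0.8-Mb TADs
    grouped pairwise into ~1.6-Mb A/B compartment blocks (compartment
    switches coincide with TAD boundaries, as they do in real maps), with
    nested loops planted in the two outermost TADs. ``loop_valencies`` gives,
    per loop-bearing TAD, the number of sub-loops nested inside that TAD's
    main loop. Contrasts are log-fold amplitudes.
    """

    n_bins: int = 256
    resolution: int = 25_000
    n_tads: int = 8
    tads_per_block: int = 2                    # TADs per compartment block
    loop_valencies: tuple[int, ...] = (1, 1)   # placed in the outermost TADs
    checkerboard_contrast: float = 0.6
    tad_contrast: float = 0.4
    loop_contrast: float = 1.5
    sigma_loop: float = 2.0                    # bins
    decay_exponent: float = 1.0
    track_step: int = 1_000                    # bp
    atac_plateau_a: float = 1.5
    atac_plateau_b: float = 0.2
    atac_peak: float = 3.0
    ctcf_peak: float = 3.0
    anchor_margin: int = 3                     # bins between TAD edge and main anchor
    nest_offset: int = 5                       # bins between successive nested anchors


@dataclass
class GroundTruth:
    """Planted structure: labels, boundaries, loops and their contrasts."""

    config: SimConfig
    labels: np.ndarray            # per-bin "A"/"B"
    boundaries: np.ndarray        # internal TAD boundary bin indices, sorted
    loops: list[Loop]             # bp coordinates, planted nesting
    decay_exponent: float
    contrasts: dict
    seed: int

    @property
    def bins(self) -> BinTable:
        return BinTable.uniform(self.config.n_bins, self.config.resolution)

    def anchor_bins(self) -> np.ndarray:
        res = self.config.resolution
        bins = sorted({lp.lower // res for lp in self.loops} |
                      {lp.upper // res for lp in self.loops})
        return np.asarray(bins, dtype=np.int64)

    def main_loop_count(self) -> int:
        if not self.loops:
            return 0
        return int(loop_hierarchy(self.loops).is_main.sum())


def make_truth(config: SimConfig = SimConfig(), seed: int = 0) -> GroundTruth:
    """Draw a reproducible planted ground truth from the config and seed.

    TAD boundaries sit at jittered equal spacings; compartment labels
    alternate over runs of ``tads_per_block`` TADs, so every compartment
    switch coincides with a TAD boundary. Loop-bearing TADs are the first
    and last (maximally separated, so anchor pairs never bridge TADs), each
    holding one main loop with the configured number of nested sub-loops.
    """
    cfg = config
    n = cfg.n_bins
    if cfg.n_tads > n // 4:
        raise ValueError("more TADs than the bin count can support")
    if len(cfg.loop_valencies) > cfg.n_tads:
        raise ValueError("more loop-bearing TADs than TADs")
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, n, cfg.n_tads + 1).astype(int)[1:-1]
    bounds = np.clip(bounds + rng.integers(-2, 3, size=bounds.size), 2, n - 3)
    bounds = np.unique(bounds)
    tad_edges = np.concatenate([[0], bounds, [n]])
    labels = np.empty(n, dtype=object)
    phase = int(rng.integers(0, 2))
    for t in range(tad_edges.size - 1):
        block = t // cfg.tads_per_block
        labels[tad_edges[t]:tad_edges[t + 1]] = \
            "A" if (block + phase) % 2 == 0 else "B"
    res = cfg.resolution
    # spread loop-bearing TADs as far apart as possible
    n_tads = tad_edges.size - 1
    order = [0, n_tads - 1] + list(range(1, n_tads - 1))
    loops: list[Loop] = []
    for k, valency in enumerate(cfg.loop_valencies):
        t = order[k]
        lo_bin = int(tad_edges[t]) + cfg.anchor_margin
        hi_bin = int(tad_edges[t + 1]) - 1 - cfg.anchor_margin
        if hi_bin - lo_bin < 2 * cfg.nest_offset * valency + 3:
            raise ValueError("TAD too small for the requested loop nesting")
        for level in range(valency + 1):
            p = lo_bin + level * cfg.nest_offset
            q = hi_bin - level * cfg.nest_offset
            loops.append(Loop("chr1", p * res, q * res))
    contrasts = {"checkerboard": cfg.checkerboard_contrast,
                 "tad": cfg.tad_contrast,
                 "loop": cfg.loop_contrast}
    return GroundTruth(cfg, labels, bounds.astype(np.int64), loops,
                       cfg.decay_exponent, contrasts, seed)


def render_logfold(truth: GroundTruth) -> LogFoldMatrix:
    """Deterministic log-fold map of the planted structure on a zero baseline."""
    cfg = truth.config
    n = cfg.n_bins
    res = cfg.resolution
    s = np.where(truth.labels == "A", 1.0, -1.0)
    values = truth.contrasts["checkerboard"] * np.outer(s, s) \
        if truth.contrasts["checkerboard"] else np.zeros((n, n))
    values = values.astype(float)
    edges = np.concatenate([[0], truth.boundaries, [n]])
    for k in range(edges.size - 1):
        a, b = int(edges[k]), int(edges[k + 1])
        values[a:b, a:b] += truth.contrasts["tad"]
    grid = np.arange(n)
    for lp in truth.loops:
        p, q = lp.lower // res, lp.upper // res
        gp = np.exp(-((grid - p) ** 2) / (2 * cfg.sigma_loop ** 2))
        gq = np.exp(-((grid - q) ** 2) / (2 * cfg.sigma_loop ** 2))
        values += truth.contrasts["loop"] * (np.outer(gp, gq) + np.outer(gq, gp))
    bins = BinTable.uniform(n, res)
    return LogFoldMatrix(bins, values, res, expected=None)


def sample_counts(lf: LogFoldMatrix, decay_exponent: float = 1.0,
                  depth: float = 100.0, seed: int = 0) -> ContactMatrix:
    """Poisson contact counts around the planted map with power-law decay.

    Counts are drawn independently per upper-triangle pair with mean
    ``depth * d^(-decay_exponent) * exp(lf)`` (separation ``d`` in bins,
    floored at 1) and mirrored to the lower triangle.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = lf.n_bins
    rng = np.random.default_rng(seed)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    d_eff = np.maximum(d, 1.0)
    mu = depth * d_eff ** (-decay_exponent) * np.exp(np.nan_to_num(lf.values))
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(mu[iu])
    counts = counts + np.triu(counts, 1).T
    counts[~lf.mask, :] = np.nan
    counts[:, ~lf.mask] = np.nan
    return ContactMatrix(lf.bins, counts, lf.resolution, mask=lf.mask.copy())


def make_tracks(truth: GroundTruth) -> dict[str, Track]:
    """ATAC/CTCF tracks consistent with the planted structure.

    ATAC: plateau ``atac_plateau_a`` over A bins (``atac_plateau_b`` over B)
    plus a single ``atac_peak`` sample at the center of every loop-anchor
    bin, so silencing that 1-kb piece deletes the anchor. CTCF: ``ctcf_peak``
    samples at the centers of boundary and anchor bins, flat elsewhere.
    """
    cfg = truth.config
    n = cfg.n_bins
    per_bin = cfg.resolution // cfg.track_step
    if per_bin < 1 or cfg.resolution % cfg.track_step:
        raise ValueError("track_step must divide the resolution")
    atac = np.repeat(np.where(truth.labels == "A",
                              cfg.atac_plateau_a, cfg.atac_plateau_b), per_bin)
    ctcf = np.zeros(n * per_bin)

    def center(b: int) -> int:
        return b * per_bin + per_bin // 2

    for b in truth.anchor_bins():
        atac[center(int(b))] = cfg.atac_peak
        ctcf[center(int(b))] = cfg.ctcf_peak
    for b in truth.boundaries:
        ctcf[center(int(b))] = cfg.ctcf_peak
    return {"atac": Track("chr1", 0, cfg.track_step, atac),
            "ctcf": Track("chr1", 0, cfg.track_step, ctcf)}
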