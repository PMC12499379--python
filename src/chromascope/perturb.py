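"""In-silico perturbation of signal tracks and impact-score screening.

The perturbation operators edit ATAC/CTCF tracks or raw sequence (silencing,
enhancer activation, Gaussian CTCF peak addition, segment-shuffle sequence
permutation, global fold-change scaling). A predictor maps tracks to a
log-fold contact map; :class:`SurrogatePredictor` is a deterministic
mechanistic stand-in that composes three responses:

* a compartment field: product of bounded z-scores of the smoothed ATAC
  signal, weight ``kappa_comp``;
* loop bumps: 2-D Gaussians at pairs of anchor bins (accessible CTCF sites:
  CTCF above ``theta_ctcf`` AND ATAC above ``theta_atac``) within ``d_max``,
  weight ``kappa_loop``;
* insulation steps: ``-kappa_ins`` per boundary strictly between the two
  bins, capped at ``boundary_cap``; boundaries are the CTCF sites left
  unpaired — sites that are inaccessible (ATAC below ``theta_atac``) or have
  no partner site within ``d_max``. Silencing the ATAC signal under an
  anchor therefore both removes its loop bumps and turns the site into an
  insulating boundary, the way an extrusion barrier without a partner
  behaves.

Identical inputs give bit-identical outputs, so the screening workflow —
silence each 1-kb fragment, re-predict, take the mean absolute difference
over a scale-sized window centered on the fragment — is exactly reproducible.
The top decile of fragments per scale forms the HIS (high-impact-score)
subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from chromascope.matrixio import BinTable, LogFoldMatrix
from chromascope.tracks import Track

__all__ = [
    "silence_region",
    "activate_enhancers",
    "add_ctcf_peak",
    "permute_sequence",
    "global_scale",
    "SurrogateConfig",
    "SurrogatePredictor",
    "surrogate_predict",
    "impact_score",
    "screen",
    "ScreenResult",
]


# ---------------------------------------------------------------- operators

def silence_region(track: Track, region: tuple[int, int]) -> Track:
    """Zero the signal on genomic ``region = (lo, hi)``; elsewhere unchanged."""
    out = track.copy()
    i0, i1 = out.index_range(*region)
    out.values[i0:i1] = 0.0
    return out


def activate_enhancers(track: Track, regions, donor: Track | None = None,
                       mode: str = "replace_if_greater", fold: float = 1.1) -> Track:
    """Activate enhancer regions by donor replacement or fold-change scaling.

    ``replace_if_greater`` takes the pointwise max of track and donor on each
    region (the donor peak replaces the original only where greater);
    ``fold`` multiplies the region by ``fold``.
    """
    out = track.copy()
    if mode == "replace_if_greater":
        if donor is None:
            raise ValueError("replace_if_greater requires a donor track")
        if (donor.chrom, donor.start, donor.step, donor.values.size) != \
           (track.chrom, track.start, track.step, track.values.size):
            raise ValueError("donor track must be aligned to the target track")
        for lo, hi in regions:
            i0, i1 = out.index_range(lo, hi)
            out.values[i0:i1] = np.maximum(out.values[i0:i1], donor.values[i0:i1])
    elif mode == "fold":
        if fold <= 0:
            raise ValueError("fold must be positive")
        for lo, hi in regions:
            i0, i1 = out.index_range(lo, hi)
            out.values[i0:i1] *= fold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def add_ctcf_peak(track: Track, motif: tuple[int, int],
                  peak_value: float = 1000.0, extension: int = 30) -> Track:
    """Add a Gaussian CTCF peak over a motif, combined by pointwise max.

    The peak is centered on the motif midpoint with support width equal to
    the motif length extended by ``extension`` bp on each side (the Gaussian
    sigma is one sixth of the support, so the profile decays to ~1% of the
    apex at the support edge). The original signal wins wherever larger.
    """
    lo, hi = motif
    support = (hi - lo) + 2 * extension
    mid = (lo + hi) / 2.0
    sigma = support / 6.0
    out = track.copy()
    i0, i1 = out.index_range(int(mid - support / 2), int(np.ceil(mid + support / 2)))
    if i0 == i1:
        return out
    pos = out.start + (np.arange(i0, i1) + 0.5) * out.step
    profile = peak_value * np.exp(-((pos - mid) ** 2) / (2 * sigma ** 2))
    profile[np.abs(pos - mid) > support / 2] = 0.0
    out.values[i0:i1] = np.maximum(out.values[i0:i1], profile)
    return out


def permute_sequence(seq: str, region: tuple[int, int],
                     segment: int = 16, seed: int = 0) -> str:
    """Shuffle the order of fixed-size segments within ``region``.

    The region is cut into consecutive ``segment``-bp pieces (a trailing
    remainder stays in place) and the pieces are permuted with the given
    seed; sequence outside the region is untouched.
    """
    lo, hi = region
    if hi - lo < 2 * segment:
        raise ValueError("region must hold at least two segments")
    n_seg = (hi - lo) // segment
    pieces = [seq[lo + k * segment: lo + (k + 1) * segment] for k in range(n_seg)]
    order = np.random.default_rng(seed).permutation(n_seg)
    shuffled = "".join(pieces[k] for k in order)
    return seq[:lo] + shuffled + seq[lo + n_seg * segment:]


def global_scale(track: Track, fold: float) -> Track:
    """Multiply every track value by ``fold`` (> 0)."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    out = track.copy()
    out.values *= fold
    return out


# ---------------------------------------------------- surrogate predictor

@dataclass(frozen=True)
class SurrogateConfig:
    """Weights and thresholds of the mechanistic surrogate predictor.

    Defaults are tuned so synthetic maps show a visible checkerboard, TAD
    steps and loop bumps at the analysis scales; all are free parameters.
    """

    kappa_comp: float = 0.4        # compartment-field weight
    kappa_loop: float = 1.5        # loop-bump apex (log-fold units)
    kappa_ins: float = 0.3         # insulation decrement per crossed boundary
    sigma_loop: float = 2.0        # loop-bump width, bins
    theta_ctcf: float = 2.0        # CTCF level defining a site
    theta_atac: float = 2.0        # focal ATAC peak level an anchor needs
                                   # (above plateau-level accessibility)
    d_max: int = 1_000_000         # max anchor-pair span, bp
    boundary_cap: int = 3          # cap on counted crossed boundaries
    smooth_halfwidth: int = 100_000  # ATAC smoothing half-width, bp


def _bin_stat(track: Track, lo: int, n_bins: int, resolution: int, stat: str):
    """Per-bin mean or max of a track over [lo, lo + n_bins*resolution)."""
    out = np.zeros(n_bins)
    for b in range(n_bins):
        i0, i1 = track.index_range(lo + b * resolution, lo + (b + 1) * resolution)
        if i1 > i0:
            seg = track.values[i0:i1]
            out[b] = seg.max() if stat == "max" else seg.mean()
    return out


def surrogate_predict(tracks: dict[str, Track], window: tuple[str, int, int],
                      resolution: int,
                      config: SurrogateConfig = SurrogateConfig()) -> LogFoldMatrix:
    """Deterministic log-fold contact map from ATAC and CTCF tracks."""
    chrom, lo, hi = window
    if (hi - lo) % resolution:
        raise ValueError("window length must be a multiple of the resolution")
    n = (hi - lo) // resolution
    atac, ctcf = tracks["atac"], tracks["ctcf"]
    atac_mean = _bin_stat(atac, lo, n, resolution, "mean")
    atac_max = _bin_stat(atac, lo, n, resolution, "max")
    ctcf_max = _bin_stat(ctcf, lo, n, resolution, "max")

    # compartment field: bounded z-score of smoothed accessibility
    sigma_bins = max(config.smooth_halfwidth / resolution, 1e-9)
    smooth = gaussian_filter1d(atac_mean, sigma=sigma_bins, mode="nearest")
    sd = smooth.std()
    s = np.tanh((smooth - smooth.mean()) / sd) if sd > 0 else np.zeros(n)
    logM = config.kappa_comp * np.outer(s, s)

    # CTCF sites split into loop anchors (accessible, partnered within d_max)
    # and insulating boundaries (the rest)
    sites = np.flatnonzero(ctcf_max > config.theta_ctcf)
    accessible = sites[atac_max[sites] > config.theta_atac]
    max_span = config.d_max // resolution
    pairs = [(p, q) for ai, p in enumerate(accessible)
             for q in accessible[ai + 1:] if q - p <= max_span]
    anchor_set = {p for pr in pairs for p in pr}
    bound = np.zeros(n, dtype=bool)
    bound[[s for s in sites if s not in anchor_set]] = True

    # insulation: -kappa_ins per boundary strictly between the two bins
    cum = np.concatenate([[0], np.cumsum(bound)])
    i_idx = np.arange(n)
    lo_ij = np.minimum.outer(i_idx, i_idx)
    hi_ij = np.maximum.outer(i_idx, i_idx)
    n_between = np.maximum(cum[hi_ij] - cum[lo_ij + 1], 0)
    logM -= config.kappa_ins * np.minimum(n_between, config.boundary_cap)

    # loop bumps at anchor pairs
    grid = np.arange(n)
    for p, q in pairs:
        gp = np.exp(-((grid - p) ** 2) / (2 * config.sigma_loop ** 2))
        gq = np.exp(-((grid - q) ** 2) / (2 * config.sigma_loop ** 2))
        logM += config.kappa_loop * (np.outer(gp, gq) + np.outer(gq, gp))

    bins = BinTable.uniform(n, resolution, chrom=chrom, origin=lo)
    return LogFoldMatrix(bins, logM, resolution, expected=None)


class SurrogatePredictor:
    """Callable predictor contract wrapping :func:`surrogate_predict`."""

    def __init__(self, config: SurrogateConfig = SurrogateConfig()):
        self.config = config

    def __call__(self, tracks: dict[str, Track], window: tuple[str, int, int],
                 resolution: int) -> LogFoldMatrix:
        return surrogate_predict(tracks, window, resolution, self.config)


# ----------------------------------------------------------- impact screen

def impact_score(orig: LogFoldMatrix, pert: LogFoldMatrix,
                 window_bins: tuple[int, int] | None = None) -> float:
    """Mean absolute prediction difference over a bin window (default: all)."""
    if orig.values.shape != pert.values.shape:
        raise ValueError("matrices must share shape")
    diff = np.abs(pert.values - orig.values)
    if window_bins is not None:
        b0, b1 = window_bins
        diff = diff[b0:b1, b0:b1]
    vals = diff[~np.isnan(diff)]
    return float(vals.mean()) if vals.size else 0.0


@dataclass
class ScreenResult:
    """Per-fragment impact scores and HIS membership across scales."""

    table: pd.DataFrame            # chrom start end category impact@S his@S ...
    scales: list[int]

    def his_members(self, scale: int) -> pd.DataFrame:
        return self.table[self.table[f"his@{scale}"]]

    def category_fractions(self, scale: int) -> pd.Series:
        his = self.his_members(scale)
        if his.empty:
            return pd.Series(dtype=float)
        return his["category"].value_counts(normalize=True)


def _clipped_window(center: int, scale: int, span_lo: int, span_hi: int,
                    resolution: int) -> tuple[int, int]:
    half = scale // 2
    lo = center - half
    hi = center + half
    if lo < span_lo:
        lo, hi = span_lo, min(span_hi, span_lo + scale)
    elif hi > span_hi:
        lo, hi = max(span_lo, span_hi - scale), span_hi
    lo = span_lo + ((lo - span_lo) // resolution) * resolution
    hi = lo + ((hi - lo) // resolution) * resolution
    return lo, hi


def screen(predictor, tracks: dict[str, Track], chrom_span: tuple[str, int, int],
           fragment_size: int = 1_000, scales: list[int] | None = None,
           bins_per_scale: int = 64,
           categories: pd.DataFrame | None = None) -> ScreenResult:
    """Silence every fragment in turn and score the prediction change per scale.

    For each scale a window of that genomic size (``bins_per_scale`` bins,
    clipped and shifted to stay inside ``chrom_span``) is centered on the
    fragment; the impact score is the mean absolute difference between the
    baseline and the silenced-fragment prediction over that window. Per scale
    the top decile of fragments by impact forms the HIS subset; ties at the
    decile boundary break by impact rank then genomic coordinate.
    """
    chrom, span_lo, span_hi = chrom_span
    if scales is None:
        scales = [256_000]
    frag_starts = np.arange(span_lo, span_hi, fragment_size, dtype=np.int64)
    baseline_cache: dict[tuple, LogFoldMatrix] = {}
    records = []
    for fs in frag_starts:
        fe = min(int(fs) + fragment_size, span_hi)
        center = (int(fs) + fe) // 2
        silenced = dict(tracks)
        silenced["atac"] = silence_region(tracks["atac"], (int(fs), fe))
        rec = {"chrom": chrom, "start": int(fs), "end": fe}
        for scale in scales:
            resolution = max(tracks["atac"].step, scale // bins_per_scale)
            lo, hi = _clipped_window(center, scale, span_lo, span_hi, resolution)
            key = (lo, hi, resolution)
            if key not in baseline_cache:
                baseline_cache[key] = predictor(tracks, (chrom, lo, hi), resolution)
            base = baseline_cache[key]
            pert = predictor(silenced, (chrom, lo, hi), resolution)
            rec[f"impact@{scale}"] = impact_score(base, pert)
        records.append(rec)
    table = pd.DataFrame(records)
    if categories is not None:
        table = table.merge(categories[["chrom", "start", "category"]],
                            on=["chrom", "start"], how="left")
        table["category"] = table["category"].fillna("other")
    else:
        table["category"] = "other"
    n = len(table)
    k = max(1, int(np.ceil(n / 10)))
    for scale in scales:
        order = table.sort_values([f"impact@{scale}", "start"],
                                  ascending=[False, True], kind="mergesort")
        his_idx = order.index[:k]
        table[f"his@{scale}"] = False
        table.loc[his_idx, f"his@{scale}"] = True
    return ScreenResult(table, list(scales))
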