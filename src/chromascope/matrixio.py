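"""Contact-matrix containers, IO, balancing and observed/expected transforms.

Matrices are dense, symmetric, per-chromosome numpy arrays carried alongside a
cool-convention bin table. Masked (invalid) bins hold NaN in every row/column
they touch — never a silent zero — and are excluded from all means. Two text
formats are supported: sparse upper-triangle triplets (``bin1 bin2 count``
with a companion ``chrom start end`` bin table) and whitespace-separated dense
matrices for small fixtures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from chromascope.errors import ConvergenceError, DegenerateInputError, ParseError

__all__ = [
    "BinTable",
    "ContactMatrix",
    "LogFoldMatrix",
    "read_bin_table",
    "read_contacts",
    "write_contacts",
    "ice_balance",
    "filter_low_coverage_bins",
    "pool",
    "expected_by_distance",
    "log_fold_oe",
]


@dataclass(frozen=True)
class BinTable:
    """Genomic bins tiling one chromosome, 0-based half-open.

    Every bin spans ``resolution`` bp except possibly the last, which may be
    truncated at the chromosome end.
    """

    chrom: str
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.shape != end.shape or start.ndim != 1:
            raise ValueError("start/end must be matching 1-D arrays")
        if np.any(end <= start):
            raise ValueError("bins must have positive length")
        if np.any(start[1:] != end[:-1]):
            raise ValueError("bins must tile the chromosome without gaps or overlap")

    def __len__(self) -> int:
        return self.start.size

    @property
    def resolution(self) -> int:
        return int(self.end[0] - self.start[0])

    @classmethod
    def uniform(cls, n_bins: int, resolution: int, chrom: str = "chr1",
                origin: int = 0, chrom_end: int | None = None) -> "BinTable":
        start = origin + resolution * np.arange(n_bins, dtype=np.int64)
        end = start + resolution
        if chrom_end is not None:
            end[-1] = min(end[-1], chrom_end)
        return cls(chrom, start, end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})


def read_bin_table(path) -> BinTable:
    """Read a 3-column ``chrom start end`` TSV (single chromosome)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ParseError(f"bin table must cover one chromosome, found {list(chroms)}")
    return BinTable(chroms[0], df["start"].to_numpy(), df["end"].to_numpy())


def _check_symmetric(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact map with validity mask.

    ``mask[i]`` is True for valid bins; invalid bins carry NaN across their
    row and column. ``values`` are raw counts when ``balanced`` is False and
    bias-corrected intensities afterwards.
    """

    bins: BinTable
    values: np.ndarray
    resolution: int
    mask: np.ndarray = None
    balanced: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_symmetric(self.values)
        if len(self.bins) != self.values.shape[0]:
            raise ValueError("bin table and matrix size disagree")
        if self.mask is None:
            self.mask = ~np.all(np.isnan(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.balanced:
            with np.errstate(invalid="ignore"):
                if np.any(self.values[~np.isnan(self.values)] < 0):
                    raise ValueError("unbalanced contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def with_mask(self, mask: np.ndarray) -> "ContactMatrix":
        """Return a copy with ``mask`` applied; invalid rows/columns set NaN."""
        mask = np.asarray(mask, dtype=bool)
        values = self.values.copy()
        values[~mask, :] = np.nan
        values[:, ~mask] = np.nan
        return replace(self, values=values, mask=mask)


@dataclass
class LogFoldMatrix:
    """Symmetric log fold-change of contacts over the distance-decay expected."""

    bins: BinTable
    values: np.ndarray
    resolution: int
    expected: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_symmetric(self.values)
        if self.mask is None:
            self.mask = ~np.all(np.isnan(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def read_contacts(path, format: str = "triplet", bins: BinTable | None = None,
                  bins_path=None, resolution: int | None = None,
                  chrom: str = "chr1") -> ContactMatrix:
    """Read a contact matrix from text.

    ``triplet`` expects upper-triangle ``bin1<TAB>bin2<TAB>count`` rows plus a
    bin table (``bins`` or ``bins_path``); the lower triangle is mirrored.
    ``dense`` expects a whitespace-separated symmetric matrix; a uniform bin
    table is synthesized when none is given (``resolution`` defaults to 1).
    """
    if format == "triplet":
        if bins is None:
            if bins_path is None:
                raise ValueError("triplet format requires a bin table")
            bins = read_bin_table(bins_path)
        n = len(bins)
        values = np.zeros((n, n), dtype=np.float64)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"expected 3 fields, got {len(parts)}", lineno)
                try:
                    i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ParseError(str(exc), lineno) from None
                if not (0 <= i < n and 0 <= j < n):
                    raise ParseError(
                        f"bin index ({i},{j}) outside bin table of {n} bins", lineno)
                values[i, j] = c
                values[j, i] = c
        return ContactMatrix(bins, values, bins.resolution)
    elif format == "dense":
        values = np.loadtxt(path, ndmin=2)
        _check_symmetric(values)
        if bins is None:
            res = resolution if resolution is not None else 1
            bins = BinTable.uniform(values.shape[0], res, chrom=chrom)
        return ContactMatrix(bins, values, bins.resolution)
    raise ValueError(f"unknown format {format!r}")


def write_contacts(m: ContactMatrix, path, format: str = "triplet",
                   bins_path=None) -> None:
    """Write ``m`` as upper-triangle triplets (nonzero entries) or dense text."""
    if format == "triplet":
        buf = io.StringIO()
        iu = np.triu_indices(m.n_bins)
        vals = m.values[iu]
        keep = ~np.isnan(vals) & (vals != 0)
        for i, j, c in zip(iu[0][keep], iu[1][keep], vals[keep]):
            buf.write(f"{i}\t{j}\t{c:.10g}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
        if bins_path is not None:
            m.bins.to_frame().to_csv(bins_path, sep="\t", header=False, index=False)
    elif format == "dense":
        np.savetxt(path, m.values, fmt="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")


def ice_balance(m: ContactMatrix, max_iter: int = 200,
                tol: float = 1e-5) -> ContactMatrix:
    """Iteratively correct coverage bias so valid-row marginals equalize.

    Classic ICE: alternately divide by the row/column marginals until the
    coefficient of variation of the valid-row sums falls below ``tol``. Bins
    with an all-zero marginal cannot be balanced and are masked up front. The
    multiplicative bias vector is retained on the result.

    Raises :class:`ConvergenceError` after ``max_iter`` sweeps, reporting the
    final CV, and :class:`DegenerateInputError` for an all-zero matrix.
    """
    if m.balanced:
        raise ValueError("matrix is already balanced")
    mask = m.mask.copy()
    W = m.values.copy()
    with np.errstate(invalid="ignore"):
        marg0 = np.nansum(np.nan_to_num(W), axis=1)
    mask &= marg0 > 0
    if not mask.any():
        raise DegenerateInputError("all-zero matrix cannot be balanced")
    W[~mask, :] = np.nan
    W[:, ~mask] = np.nan
    bias = np.ones(m.n_bins)
    bias[~mask] = np.nan
    cv = np.inf
    for _ in range(max_iter):
        s = np.nansum(W, axis=1)
        sv = s[mask]
        mean = sv.mean()
        cv = sv.std() / mean
        if cv <= tol:
            return ContactMatrix(m.bins, W, m.resolution, mask=mask,
                                 balanced=True, bias=bias)
        scale = np.where(mask & (s > 0), s / mean, 1.0)
        bias *= scale
        W /= np.outer(scale, scale)
    raise ConvergenceError(
        f"ICE did not converge in {max_iter} iterations (row-sum CV {cv:.3g} > {tol:g})")


def filter_low_coverage_bins(m: ContactMatrix, min_nonzero: int = 10) -> ContactMatrix:
    """Mask bins whose row carries fewer than ``min_nonzero`` nonzero entries."""
    with np.errstate(invalid="ignore"):
        nonzero = np.nansum(np.nan_to_num(m.values) != 0, axis=1)
    keep = m.mask & (nonzero >= min_nonzero)
    return m.with_mask(keep)


def _block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    n = values.shape[0]
    n_out = -(-n // factor)
    padded = np.full((n_out * factor, n_out * factor), np.nan)
    padded[:n, :n] = values
    blocks = padded.reshape(n_out, factor, n_out, factor)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pad blocks
        return np.nanmean(np.nanmean(blocks, axis=3), axis=1)


def pool(m: ContactMatrix | LogFoldMatrix, factor: int):
    """Average-pool a matrix by ``factor`` in 2-D, coarsening the resolution.

    A trailing partial block is averaged over its actual members. Masked
    entries are excluded from block means; an output bin is masked only when
    every source bin in it was masked.
    """
    if factor < 2:
        raise ValueError("pooling factor must be >= 2")
    n = m.n_bins
    n_out = -(-n // factor)
    values = _block_mean(m.values, factor)
    starts = m.bins.start[::factor][:n_out]
    ends = np.append(m.bins.start[factor::factor], m.bins.end[-1])[:n_out]
    bins = BinTable(m.bins.chrom, starts, ends)
    mask = np.array([m.mask[k * factor:(k + 1) * factor].any() for k in range(n_out)])
    values[~mask, :] = np.nan
    values[:, ~mask] = np.nan
    values = (values + values.T) / 2.0  # guard fp asymmetry from nanmean order
    if isinstance(m, LogFoldMatrix):
        exp = np.array([np.nanmean(m.expected[k * factor:(k + 1) * factor])
                        for k in range(n_out)]) if m.expected is not None else None
        return LogFoldMatrix(bins, values, m.resolution * factor, exp, mask=mask)
    return ContactMatrix(bins, values, m.resolution * factor, mask=mask,
                         balanced=m.balanced)


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean contact value per genomic-separation diagonal.

    Entry ``d`` is the mean over valid bin pairs at separation ``d`` bins;
    masked pairs are excluded. Separations with no valid pair yield NaN.
    """
    n = m.n_bins
    out = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(m.values, offset=d)
        if np.any(~np.isnan(diag)):
            out[d] = np.nanmean(diag)
    return out


def log_fold_oe(m: ContactMatrix, expected: np.ndarray | None = None,
                pseudocount: float = 0.0) -> LogFoldMatrix:
    """Natural-log fold of observed contacts over the distance-decay expected.

    ``values[i, j] = log((m[i,j] + pc) / (expected[|i-j|] + pc))``; masked
    bins propagate as NaN. ``expected`` defaults to
    :func:`expected_by_distance` of ``m`` itself.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if expected is None:
        expected = expected_by_distance(m)
    expected = np.asarray(expected, dtype=np.float64)
    n = m.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp_mat = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log((m.values + pseudocount) / (exp_mat + pseudocount))
    values[~m.mask, :] = np.nan
    values[:, ~m.mask] = np.nan
    return LogFoldMatrix(m.bins, values, m.resolution, expected, mask=m.mask.copy())
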