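"""Fixed-step genomic signal tracks (ATAC, CTCF, CpG density) and bedGraph IO."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from chromascope.errors import ParseError

__all__ = ["Track", "read_bedgraph", "write_bedgraph"]


@dataclass
class Track:
    """Signal sampled at a fixed step along one chromosome.

    ``values[k]`` covers the half-open interval
    ``[start + k*step, start + (k+1)*step)``.
    """

    chrom: str
    start: int
    step: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.step < 1:
            raise ValueError("step must be >= 1 bp")

    @property
    def end(self) -> int:
        return self.start + self.step * self.values.size

    def index_range(self, lo: int, hi: int) -> tuple[int, int]:
        """Sample indices whose intervals intersect genomic [lo, hi)."""
        if lo >= hi:
            return 0, 0
        i0 = max(0, (lo - self.start) // self.step)
        i1 = min(self.values.size, -(-(hi - self.start) // self.step))
        return int(i0), int(max(i0, i1))

    def copy(self) -> "Track":
        return replace(self, values=self.values.copy())

    def bin_means(self, resolution: int) -> np.ndarray:
        """Mean signal per ``resolution``-bp bin (resolution a multiple of step)."""
        if resolution % self.step:
            raise ValueError("resolution must be a multiple of the track step")
        f = resolution // self.step
        n = self.values.size // f
        return self.values[: n * f].reshape(n, f).mean(axis=1)


def read_bedgraph(path, step: int | None = None) -> Track:
    """Read a single-chromosome bedGraph into a fixed-step track.

    The step defaults to the most common interval length; intervals are
    rasterized onto the grid (constant value across each interval).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        raise ParseError("empty bedGraph")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ParseError(f"bedGraph must cover one chromosome, found {list(chroms)}")
    lengths = (df["end"] - df["start"]).to_numpy()
    if step is None:
        step = int(np.bincount(lengths).argmax())
    origin = int(df["start"].min())
    n = -(-(int(df["end"].max()) - origin) // step)
    values = np.zeros(n)
    for row in df.itertuples(index=False):
        i0 = (row.start - origin) // step
        i1 = -(-(row.end - origin) // step)
        values[i0:i1] = row.value
    return Track(str(chroms[0]), origin, step, values)


def write_bedgraph(track: Track, path, skip_zero: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            if skip_zero and v == 0:
                continue
            s = track.start + k * track.step
            fh.write(f"{track.chrom}\t{s}\t{s + track.step}\t{v:.6g}\n")
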