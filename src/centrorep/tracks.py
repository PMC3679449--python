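"""Binned per-chromosome tracks and bedGraph / bin-table I/O.

All tracks share the same layout: a fixed ``bin_width`` and one value per
half-open bin ``[k*bin_width, (k+1)*bin_width)`` on each chromosome.
Float tracks mark missing bins with NaN; read-count tracks are integer
and complete.  Missing bins are never imputed: every downstream stage
receiving NaN emits NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeLayout, ParameterError

__all__ = [
    "BinnedTrack",
    "ReadCounts",
    "TimingMap",
    "CopyNumberProfile",
    "RatioTrack",
    "DiffTrack",
    "EnrichmentTrack",
    "GridMismatchError",
    "read_bedgraph",
]


class GridMismatchError(ValueError):
    """Two tracks do not share the same bin grid."""


@dataclass
class BinnedTrack:
    """A per-chromosome vector of bin values on a common grid."""

    bin_width: int
    data: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        self.data = {str(c): np.asarray(v) for c, v in self.data.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.chroms])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chroms == other.chroms
            and all(len(self.data[c]) == len(other.data[c]) for c in self.chroms)
        )

    def require_same_grid(self, other: "BinnedTrack") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"bin grids differ between {self.label!r} and {other.label!r}"
            )

    def bin_index(self, pos: int) -> int:
        return int(pos) // self.bin_width

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][self.bin_index(pos)])

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.data[chrom]), dtype=np.int64) * self.bin_width

    def copy_with(self, data: dict[str, np.ndarray], label: str | None = None) -> "BinnedTrack":
        return type(self)(self.bin_width, data, self.label if label is None else label)

    # ---- I/O -------------------------------------------------------------

    def to_bedgraph(self, path: str | Path, precision: int = 6) -> None:
        """Write as bedGraph; NaN bins are skipped (bedGraph is sparse)."""
        with open(path, "w") as fh:
            if self.label:
                fh.write(f'track type=bedGraph name="{self.label}"\n')
            for chrom in self.chroms:
                vals = self.data[chrom]
                starts = self.bin_starts(chrom)
                for s, v in zip(starts, vals):
                    if np.isnan(float(v)):
                        continue
                    fh.write(f"{chrom}\t{s}\t{s + self.bin_width}\t{float(v):.{precision}g}\n")

    def to_bintable(self, path: str | Path) -> None:
        """Write a dense TSV of (chrom, start, end, value); NaN written as NA."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tvalue\n")
            for chrom in self.chroms:
                vals = self.data[chrom]
                starts = self.bin_starts(chrom)
                for s, v in zip(starts, vals):
                    sval = "NA" if np.isnan(float(v)) else repr(float(v))
                    fh.write(f"{chrom}\t{s}\t{s + self.bin_width}\t{sval}\n")


def read_bedgraph(
    path: str | Path,
    bin_width: int,
    layout: GenomeLayout | None = None,
    cls: type[BinnedTrack] | None = None,
    label: str = "",
) -> BinnedTrack:
    """Read a bedGraph written on a fixed bin grid back into a track.

    Bins absent from the file become NaN.  If *layout* is given the grid is
    sized from chromosome lengths; otherwise from the last interval seen
    per chromosome.
    """
    records: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            records.setdefault(chrom, []).append((int(start), float(value)))
    data: dict[str, np.ndarray] = {}
    chroms = layout.names if layout is not None else list(records)
    for chrom in chroms:
        recs = records.get(chrom, [])
        if layout is not None:
            n = layout.n_bins(chrom, bin_width)
        else:
            n = max(s for s, _ in recs) // bin_width + 1 if recs else 0
        vals = np.full(n, np.nan)
        for start, value in recs:
            vals[start // bin_width] = value
        data[chrom] = vals
    track_cls = cls or BinnedTrack
    return track_cls(bin_width, data, label)


@dataclass
class ReadCounts(BinnedTrack):
    """Integer sequencing read counts per bin for one sample (S, G2, IP, input)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, vals in self.data.items():
            if not np.issubdtype(vals.dtype, np.integer):
                raise ParameterError(f"read counts for {chrom!r} must be integer")
            if (vals < 0).any():
                raise ParameterError(f"negative read count on {chrom!r}")

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.data.values()))


@dataclass
class TimingMap(BinnedTrack):
    """Per-bin replication time T(x) in minutes."""


@dataclass
class CopyNumberProfile(BinnedTrack):
    """Relative copy number r(x) on the sort-seq scale, bounded in [1, 2]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, vals in self.data.items():
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 1.0 - 1e-9 or finite.max() > 2.0 + 1e-9):
                raise ParameterError(
                    f"copy-number profile on {chrom!r} outside [1, 2]"
                )


@dataclass
class RatioTrack(BinnedTrack):
    """Raw depth-normalized S/G2 ratio; NaN where the coverage filter failed."""


@dataclass
class DiffTrack(BinnedTrack):
    """Per-bin difference between two copy-number profiles (A − B)."""


@dataclass
class EnrichmentTrack(BinnedTrack):
    """Depth-normalized ChIP IP/input ratio; NaN where input coverage is low."""
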