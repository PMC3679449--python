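"""Genome coordinate frame, replication origins, and mutant parameterization.

The coordinate frame is a set of chromosomes, each with a single point
centromere.  All positions are 0-based base pairs; binned tracks use
half-open bins ``[start, start + bin_width)``.  Centromere distances are
reported in kb throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "OriginSet", "MutantSpec", "ParameterError"]

ORIGIN_COLUMNS = ["chrom", "pos", "t_mean", "t_sigma", "competence"]


class ParameterError(ValueError):
    """Raised when a parameter violates its documented precondition."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths and centromere positions.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Mapping from chromosome name to centromere position (bp).
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ParameterError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has non-positive length {length}")
            if name not in self.centromeres:
                raise ParameterError(f"no centromere recorded for chromosome {name!r}")
            cen = self.centromeres[name]
            if not 0 <= cen < length:
                raise ParameterError(f"centromere of {name!r} at {cen} outside [0, {length})")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def centromere_distance_kb(self, chrom: str, pos) -> np.ndarray | float:
        """Distance from *pos* (bp) to the centromere of *chrom*, in kb."""
        cen = self.centromeres[chrom]
        return np.abs(np.asarray(pos, dtype=float) - cen) / 1000.0

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.length(chrom) // bin_width)

    def bin_starts(self, chrom: str, bin_width: int) -> np.ndarray:
        return np.arange(self.n_bins(chrom, bin_width), dtype=np.int64) * bin_width

    def to_bed(self, path: str | Path) -> None:
        """Write centromere point positions as a 3-column BED file."""
        with open(path, "w") as fh:
            for name, _ in self.chromosomes:
                cen = self.centromeres[name]
                fh.write(f"{name}\t{cen}\t{cen + 1}\tCEN_{name}\n")


@dataclass
class OriginSet:
    """Replication origins with firing-time parameters.

    ``table`` columns: ``chrom`` (str), ``pos`` (bp), ``t_mean`` (min,
    mean firing time), ``t_sigma`` (min, firing-time spread), ``competence``
    (probability that the origin fires at all in a given cell).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ORIGIN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParameterError(f"origin table missing columns {missing}")
        t = self.table
        if (t["t_mean"] < 0).any() or (t["t_sigma"] < 0).any():
            raise ParameterError("firing-time parameters must be non-negative")
        if ((t["competence"] < 0) | (t["competence"] > 1)).any():
            raise ParameterError("competence must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def validate_positions(self, layout: GenomeLayout) -> None:
        for chrom, sub in self.table.groupby("chrom"):
            length = layout.length(str(chrom))
            if ((sub["pos"] < 0) | (sub["pos"] >= length)).any():
                raise ParameterError(f"origin outside chromosome {chrom!r} bounds")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def centromere_distances_kb(self, layout: GenomeLayout) -> np.ndarray:
        cens = self.table["chrom"].map(layout.centromeres).to_numpy(dtype=float)
        return np.abs(self.table["pos"].to_numpy(dtype=float) - cens) / 1000.0

    def copy(self) -> "OriginSet":
        return OriginSet(self.table.copy(deep=True))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OriginSet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, row in self.table.iterrows():
                fh.write(f"{row.chrom}\t{int(row.pos)}\t{int(row.pos) + 1}\tori_{i}\t{row.t_mean:.3f}\n")


@dataclass(frozen=True)
class MutantSpec:
    """Pericentromeric initiation-delay parameterization.

    Origins whose centromere distance is at most ``cutoff_kb`` have their
    mean firing time increased by ``delay_min`` minutes; this is the
    kinetochore-DDK-loss perturbation applied to a wild-type origin set.
    """

    cutoff_kb: float
    delay_min: float

    def __post_init__(self) -> None:
        if self.cutoff_kb < 0 or self.delay_min < 0:
            raise ParameterError("cutoff and delay must be non-negative")
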