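"""Synthetic genomes, origin sets, and noisy sequencing-count tracks.

Everything downstream (profile reconstruction, delay-cutoff inference,
ChIP peak statistics) is exercised against data from this module, which
emulates a multi-chromosome budding-yeast-like genome: one point
centromere per chromosome, an origin at each centromere plus
origin-rich pericentromeres, arm origins at regular spacing, firing
times graded from early at centromeres to late on arms, Poisson
sequencing noise, and a mutant mode that delays pericentromeric
initiation and depletes pericentromeric ChIP enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeLayout, MutantSpec, OriginSet, ParameterError
from .tracks import CopyNumberProfile, ReadCounts

__all__ = [
    "make_genome",
    "apply_mutant",
    "simulate_sortseq_counts",
    "simulate_chip_counts",
    "DEFAULT_MUTANT",
]

# Hidden-truth mutant used in recovery tests and the demo: initiation of
# origins within 17.5 kb of a centromere is delayed by 10 min.
DEFAULT_MUTANT = MutantSpec(cutoff_kb=17.5, delay_min=10.0)

# Firing-time gradient: earliest at the centromere, latest on distal arms.
T_EARLY = 10.0  # min, centromere-proximal origins
T_LATE = 35.0  # min, most distal arm origins

# Mean read-depth normalizer: genome-average relative copy number of a
# uniformly sampled S-phase population, so S and G2 totals are comparable.
GENOME_MEAN_CN = 1.5

# ChIP generator defaults: peak fold-amplitude over background, fractional
# reduction of pericentromeric peaks in the mutant, and the decay length
# of that reduction.  With these values the wild-type/mutant enrichment
# ratio falls below a 10% excess ~20 kb from the centromere.
CHIP_AMPLITUDE = 5.0
CHIP_RHO = 0.3
CHIP_LAMBDA_KB = 20.0
KERNEL_HALF_WIDTH = 1000  # bp, triangular peak kernel


def make_genome(
    n_chrom: int = 4,
    chrom_length: int = 400_000,
    origin_spacing: int = 40_000,
    seed: int = 0,
    peri_offsets: tuple[int, ...] = (17_500,),
    t_sigma: float = 4.0,
    competence: float = 1.0,
    t_jitter_sd: float = 1.0,
) -> tuple[GenomeLayout, OriginSet]:
    """Build a synthetic genome layout and its replication-origin set.

    Each chromosome carries a mid-chromosome centromere with an origin
    placed exactly on it, arm origins every ``origin_spacing`` bp on a grid
    anchored at the centromere, and additional pericentromeric origins at
    ``±peri_offsets`` bp (the origin-rich pericentromere).  Mean firing
    times rise linearly with centromere distance from ``T_EARLY`` to
    ``T_LATE`` over a half-chromosome, with seeded N(0, t_jitter_sd) jitter
    on non-pericentromeric origins.
    """
    if n_chrom < 1:
        raise ParameterError("n_chrom must be at least 1")
    if chrom_length <= 0 or origin_spacing <= 0:
        raise ParameterError("chromosome length and origin spacing must be positive")
    if origin_spacing >= chrom_length:
        raise ParameterError("origin_spacing must be smaller than chrom_length")
    rng = np.random.default_rng(seed)
    chromosomes = []
    centromeres = {}
    rows = []
    d_scale = chrom_length / 2.0 / 1000.0  # kb over which firing times grade
    for k in range(n_chrom):
        name = f"chr{k + 1}"
        chromosomes.append((name, chrom_length))
        cen = chrom_length // 2
        centromeres[name] = cen
        positions = set()
        first = cen % origin_spacing
        positions.update(range(first, chrom_length, origin_spacing))
        for off in peri_offsets:
            for p in (cen - off, cen + off):
                if 0 <= p < chrom_length:
                    positions.add(p)
        for pos in sorted(positions):
            dist_kb = abs(pos - cen) / 1000.0
            t = T_EARLY + (T_LATE - T_EARLY) * min(dist_kb / d_scale, 1.0)
            if dist_kb > max((o / 1000.0 for o in peri_offsets), default=0.0):
                t = max(0.0, t + rng.normal(0.0, t_jitter_sd))
            rows.append((name, int(pos), t, t_sigma, competence))
    origins = OriginSet(
        pd.DataFrame(rows, columns=["chrom", "pos", "t_mean", "t_sigma", "competence"])
    )
    layout = GenomeLayout(tuple(chromosomes), centromeres)
    origins.validate_positions(layout)
    return layout, origins


def apply_mutant(origins: OriginSet, layout: GenomeLayout, spec: MutantSpec) -> OriginSet:
    """Delay initiation of origins within ``spec.cutoff_kb`` of a centromere.

    Returns a new origin set; the input is untouched.  Exactly the origins
    with centromere distance ≤ cutoff get ``t_mean`` increased by
    ``spec.delay_min``.
    """
    out = origins.copy()
    dist = out.centromere_distances_kb(layout)
    mask = dist <= spec.cutoff_kb
    out.table.loc[mask, "t_mean"] = out.table.loc[mask, "t_mean"] + spec.delay_min
    return out


def simulate_sortseq_counts(
    profile: CopyNumberProfile, depth: float, seed: int
) -> tuple[ReadCounts, ReadCounts]:
    """Poisson sort-seq read counts for sorted S and G2–M samples.

    G2 bins are Poisson(depth); S bins are Poisson(depth * r(x) / 1.5),
    where 1.5 is the genome-mean copy number of a uniformly sampled
    S-phase population, so both samples have comparable totals.
    """
    if depth <= 0:
        raise ParameterError("depth must be positive")
    for chrom, vals in profile.data.items():
        if not np.isfinite(vals).all() or vals.min() < 1.0 - 1e-9 or vals.max() > 2.0 + 1e-9:
            raise ParameterError(f"profile on {chrom!r} must be finite and within [1, 2]")
    rng = np.random.default_rng(seed)
    s_data, g2_data = {}, {}
    for chrom in profile.chroms:
        r = profile.data[chrom]
        s_data[chrom] = rng.poisson(depth * r / GENOME_MEAN_CN).astype(np.int64)
        g2_data[chrom] = rng.poisson(depth, size=len(r)).astype(np.int64)
    bw = profile.bin_width
    return ReadCounts(bw, s_data, "S"), ReadCounts(bw, g2_data, "G2")


def chip_expected_enrichment(
    layout: GenomeLayout,
    peak_positions: list[tuple[str, int]],
    amplitude: float = CHIP_AMPLITUDE,
    mutant_reduction: tuple[float, float] | None = None,
    bin_width: int = 1000,
) -> dict[str, np.ndarray]:
    """Noise-free expected IP/input enrichment e(x) of the ChIP generator.

    ``e(x) = 1 + Σ_peaks A_p · kernel(x − p)`` with a triangular kernel of
    half-width 1 kb.  In mutant mode each peak's amplitude is multiplied by
    ``1 − rho · exp(−dist_to_cen / lambda_c)`` with
    ``mutant_reduction = (rho, lambda_c_kb)``.
    """
    rho, lam_kb = (0.0, 1.0) if mutant_reduction is None else mutant_reduction
    if not 0.0 <= rho <= 1.0:
        raise ParameterError("rho must lie in [0, 1]")
    if lam_kb <= 0:
        raise ParameterError("lambda_c must be positive")
    e = {c: np.ones(layout.n_bins(c, bin_width)) for c in layout.names}
    for chrom, pos in peak_positions:
        if chrom not in e:
            raise ParameterError(f"peak on unknown chromosome {chrom!r}")
        if not 0 <= pos < layout.length(chrom):
            raise ParameterError(f"peak at {pos} outside chromosome {chrom!r}")
        amp = amplitude
        if mutant_reduction is not None:
            d = float(layout.centromere_distance_kb(chrom, pos))
            amp = amplitude * (1.0 - rho * np.exp(-d / lam_kb))
        x = layout.bin_starts(chrom, bin_width).astype(float)
        kern = np.clip(1.0 - np.abs(x - pos) / KERNEL_HALF_WIDTH, 0.0, None)
        e[chrom] = e[chrom] + amp * kern
    return e


def simulate_chip_counts(
    layout: GenomeLayout,
    peak_positions: list[tuple[str, int]],
    amplitude: float = CHIP_AMPLITUDE,
    mutant_reduction: tuple[float, float] | None = None,
    depth: float = 300.0,
    seed: int = 0,
    bin_width: int = 1000,
) -> tuple[ReadCounts, ReadCounts]:
    """Poisson ChIP read counts: IP ~ Poisson(depth·e(x)), input ~ Poisson(depth)."""
    if depth <= 0:
        raise ParameterError("depth must be positive")
    e = chip_expected_enrichment(layout, peak_positions, amplitude, mutant_reduction, bin_width)
    rng = np.random.default_rng(seed)
    ip_data = {c: rng.poisson(depth * v).astype(np.int64) for c, v in e.items()}
    in_data = {c: rng.poisson(depth, size=len(v)).astype(np.int64) for c, v in e.items()}
    return ReadCounts(bin_width, ip_data, "IP"), ReadCounts(bin_width, in_data, "input")
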