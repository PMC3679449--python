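"""ChIP enrichment statistics and small count-based assays.

Covers four related analyses: fold enrichment from ChIP-qPCR panels
(IP/whole-cell-extract ratios anchored to a control locus in a reference
condition), genome-wide IP/input enrichment tracks with threshold-based
peak calling, regression of between-strain peak-enrichment ratios on
centromere distance, and exact count statistics for the microscopy-scale
assays: sister-chromatid two-dot percentages (Wilson intervals, Fisher
exact comparisons) and half-sectored-colony chromosome-loss rates with
an additive-scale synergy check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .genome import GenomeLayout, ParameterError
from .timing_inference import DecayFit, fit_exponential_decay
from .tracks import EnrichmentTrack, ReadCounts

__all__ = [
    "fold_enrichment",
    "enrichment_track",
    "find_peaks",
    "PeakSet",
    "peak_ratio_regression",
    "two_dot_fraction",
    "loss_rate",
    "MeasurementError",
]

DEFAULT_MIN_INPUT = 10
DEFAULT_MIN_SEPARATION_KB = 2.0


class MeasurementError(ValueError):
    """Raised on an unusable measurement (e.g. zero whole-cell-extract signal)."""


# ---------------------------------------------------------------------------
# ChIP-qPCR fold enrichment


def fold_enrichment(
    panel: pd.DataFrame,
    control_locus: str,
    reference_condition: str,
) -> pd.DataFrame:
    """Fold enrichment of each (locus, condition) over the reference control.

    ``panel`` columns: ``locus``, ``condition``, ``ip``, ``wce`` and
    optionally ``cen_dist_kb``.  fold(locus, cond) =
    (ip/wce at locus, cond) / (ip/wce at control locus, reference
    condition); the reference control is exactly 1 by construction.  An
    arbitrary anchoring point (e.g. a specific time point) is supported by
    encoding it in the condition label.
    """
    required = {"locus", "condition", "ip", "wce"}
    if not required.issubset(panel.columns):
        raise ParameterError(f"panel must have columns {sorted(required)}")
    if (panel["wce"] <= 0).any() or (panel["ip"] < 0).any():
        raise MeasurementError("IP must be non-negative and WCE positive")
    out = panel.copy()
    out["ip_over_wce"] = out["ip"] / out["wce"]
    ref = out[(out["locus"] == control_locus) & (out["condition"] == reference_condition)]
    if len(ref) != 1:
        raise ParameterError(
            "panel must contain exactly one (control locus, reference condition) row"
        )
    out["fold"] = out["ip_over_wce"] / float(ref["ip_over_wce"].iloc[0])
    return out


# ---------------------------------------------------------------------------
# ChIP-seq enrichment and peaks


def enrichment_track(
    ip: ReadCounts, inp: ReadCounts, min_input: int = DEFAULT_MIN_INPUT
) -> EnrichmentTrack:
    """Depth-normalized per-bin IP/input ratio; missing where input is low."""
    ip.require_same_grid(inp)
    total_ip, total_in = ip.total(), inp.total()
    if total_ip == 0 or total_in == 0:
        raise MeasurementError("a sample with zero total reads cannot be normalized")
    scale = total_in / total_ip
    data = {}
    for chrom in ip.chroms:
        ic = ip.data[chrom].astype(float)
        nc = inp.data[chrom].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = scale * ic / nc
        ratio[nc < min_input] = np.nan
        data[chrom] = ratio
    return EnrichmentTrack(ip.bin_width, data, label="IP/input")


@dataclass
class PeakSet:
    """Called enrichment peaks: apex position, height, centromere distance."""

    table: pd.DataFrame  # columns: chrom, pos, height, cen_dist_kb

    def __len__(self) -> int:
        return len(self.table)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in self.table.iterrows():
                fh.write(
                    f"{row.chrom}\t{int(row.pos)}\t{int(row.pos) + 1}\t"
                    f"peak_{i}\t{row.height:.4f}\n"
                )


def find_peaks(
    track: EnrichmentTrack,
    layout: GenomeLayout,
    threshold: float | None = None,
    min_separation_kb: float = DEFAULT_MIN_SEPARATION_KB,
) -> PeakSet:
    """Threshold-plus-separation peak calling on an enrichment track.

    Apexes are strict local maxima with height at least ``threshold``
    (default 1.5 × the genome-wide track median).  Among maxima closer
    than ``min_separation_kb`` the higher apex is retained, ties going to
    the leftmost.
    """
    if threshold is None:
        allv = track.all_values()
        threshold = 1.5 * float(np.nanmedian(allv))
    min_sep_bp = min_separation_kb * 1000.0
    rows = []
    for chrom in track.chroms:
        vals = track.data[chrom]
        n = len(vals)
        candidates = []
        for i in range(n):
            v = vals[i]
            if not np.isfinite(v) or v < threshold:
                continue
            left = vals[i - 1] if i > 0 else -np.inf
            right = vals[i + 1] if i < n - 1 else -np.inf
            left = left if np.isfinite(left) else -np.inf
            right = right if np.isfinite(right) else -np.inf
            if v > left and v > right:
                candidates.append((i, v))
        # resolve separation conflicts by height (desc), ties leftmost
        kept: list[tuple[int, float]] = []
        for i, v in sorted(candidates, key=lambda t: (-t[1], t[0])):
            pos = i * track.bin_width
            if all(abs(pos - j * track.bin_width) >= min_sep_bp for j, _ in kept):
                kept.append((i, v))
        for i, v in sorted(kept):
            pos = i * track.bin_width
            rows.append(
                (chrom, pos, float(v), float(layout.centromere_distance_kb(chrom, pos)))
            )
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "pos", "height", "cen_dist_kb"]))


def peak_ratio_regression(
    peaks: PeakSet,
    track_a: EnrichmentTrack,
    track_b: EnrichmentTrack,
    lam0: float = 10.0,
) -> tuple[pd.DataFrame, DecayFit]:
    """Between-strain enrichment ratio at each peak, regressed on centromere distance.

    ``ratio = track_a / track_b`` at each apex called on ``track_a``; the
    excess ``ratio − 1`` is fitted with an exponential decay against
    centromere distance.  Peaks whose apex is missing in either track are
    dropped (their count is the difference in table lengths).
    """
    rows = []
    for _, row in peaks.table.iterrows():
        a = track_a.value_at(row.chrom, int(row.pos))
        b = track_b.value_at(row.chrom, int(row.pos))
        if not (np.isfinite(a) and np.isfinite(b)) or b <= 0:
            continue
        rows.append((row.chrom, int(row.pos), float(row.cen_dist_kb), a / b))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "cen_dist_kb", "ratio"])
    fit = fit_exponential_decay(
        table["cen_dist_kb"].to_numpy(), table["ratio"].to_numpy() - 1.0, lam0
    )
    return table, fit


# ---------------------------------------------------------------------------
# Count-based assays


def _check_counts(events: int, total: int) -> None:
    if total <= 0:
        raise ParameterError("total count must be positive")
    if not 0 <= events <= total:
        raise ParameterError("event count must lie in [0, total]")


def two_dot_fraction(counts: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sister-dot percentages with Wilson intervals and pairwise Fisher tests.

    ``counts`` columns: ``condition``, ``two_dot``, ``total``.  Returns a
    per-condition table (proportion, Wilson score interval) and a long
    table of two-sided Fisher exact p-values for every condition pair.
    """
    rows = []
    for _, row in counts.iterrows():
        _check_counts(int(row.two_dot), int(row.total))
        lo, hi = proportion_confint(int(row.two_dot), int(row.total), alpha=alpha, method="wilson")
        rows.append((row.condition, int(row.two_dot), int(row.total),
                     row.two_dot / row.total, float(lo), float(hi)))
    summary = pd.DataFrame(
        rows, columns=["condition", "two_dot", "total", "proportion", "ci_low", "ci_high"]
    )
    pair_rows = []
    for i in range(len(summary)):
        for j in range(i + 1, len(summary)):
            a, b = summary.iloc[i], summary.iloc[j]
            _, p = stats.fisher_exact(
                [[a.two_dot, a.total - a.two_dot], [b.two_dot, b.total - b.two_dot]],
                alternative="two-sided",
            )
            pair_rows.append((a.condition, b.condition, float(p)))
    pairs = pd.DataFrame(pair_rows, columns=["condition_a", "condition_b", "p_fisher"])
    return summary, pairs


def loss_rate(
    counts: pd.DataFrame,
    control: str | None = None,
    single_a: str | None = None,
    single_b: str | None = None,
    double: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict | None]:
    """Chromosome-loss rates from half-sectored colony counts.

    ``counts`` columns: ``strain``, ``sectored``, ``total``.  The rate is
    sectored/total — loss in the first division after plating.  Every
    strain pair is compared with a two-sided Fisher exact test.  If the
    four strain roles are named, a synergy report is returned: the double
    perturbation is synergistic when its excess rate over the control
    exceeds the sum of the single-perturbation excess rates.
    """
    rows = []
    for _, row in counts.iterrows():
        _check_counts(int(row.sectored), int(row.total))
        rows.append((row.strain, int(row.sectored), int(row.total), row.sectored / row.total))
    summary = pd.DataFrame(rows, columns=["strain", "sectored", "total", "rate"])
    pair_rows = []
    for i in range(len(summary)):
        for j in range(i + 1, len(summary)):
            a, b = summary.iloc[i], summary.iloc[j]
            _, p = stats.fisher_exact(
                [[a.sectored, a.total - a.sectored], [b.sectored, b.total - b.sectored]],
                alternative="two-sided",
            )
            pair_rows.append((a.strain, b.strain, float(p)))
    pairs = pd.DataFrame(pair_rows, columns=["strain_a", "strain_b", "p_fisher"])
    synergy = None
    if all(x is not None for x in (control, single_a, single_b, double)):
        r = summary.set_index("strain")["rate"]
        excess_a = r[single_a] - r[control]
        excess_b = r[single_b] - r[control]
        excess_double = r[double] - r[control]
        synergy = {
            "excess_single_a": float(excess_a),
            "excess_single_b": float(excess_b),
            "excess_double": float(excess_double),
            "additive_expectation": float(excess_a + excess_b),
            "synergistic": bool(excess_double > excess_a + excess_b),
        }
    return summary, pairs, synergy
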