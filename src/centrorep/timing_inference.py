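"""Origin-level replication delays and the pericentromeric delay-cutoff fit.

Two strains' copy-number profiles are compared at origin positions to
obtain per-origin delays, which decay with distance from the centromere;
an exponential-decay regression summarizes that trend.  The delay-cutoff
fit asks the mechanistic question directly: which origins had their
initiation delayed?  It searches a grid of (cutoff distance D, delay
delta), delays every wild-type origin within D of its centromere by
delta, recomputes the model profile, and scores it against the observed
mutant profile over pericentromeric bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genome import GenomeLayout, MutantSpec, OriginSet, ParameterError
from .replication_model import KineticsParams, copy_number_profile, replication_time
from .sortseq_pipeline import anchor_values, smooth_profile
from .synthetic_data import apply_mutant
from .tracks import CopyNumberProfile

__all__ = [
    "OriginDelayTable",
    "DecayFit",
    "DelayFit",
    "origin_delays",
    "delay_distance_regression",
    "fit_delay_cutoff",
    "FitError",
]

DEFAULT_SCORING_WINDOW_KB = 100.0


class FitError(ValueError):
    """Raised when a regression cannot be fitted on its input."""


@dataclass
class OriginDelayTable:
    """Per-origin replication delays between two strains.

    ``table`` columns: ``origin_id``, ``chrom``, ``pos``, ``cen_dist_kb``,
    ``delay_cn`` (copy-number units, wt − mut at the origin bin) and
    ``delay_min`` (= delay_cn × S_dur).  ``n_dropped`` counts origins whose
    bin was missing in either profile.
    """

    table: pd.DataFrame
    S_dur: float
    n_dropped: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay regression y(d) = a·exp(−d/lam) + c."""

    a: float
    lam: float
    c: float
    rss: float

    def predict(self, dist_kb) -> np.ndarray:
        return self.a * np.exp(-np.asarray(dist_kb, float) / self.lam) + self.c


@dataclass
class DelayFit:
    """Result of the pericentromeric delay-cutoff grid search."""

    cutoff_kb: float
    delay_min: float
    flagged_origin_ids: list[int]
    objective: float
    grid: pd.DataFrame = field(repr=False)


def origin_delays(
    wt: CopyNumberProfile,
    mut: CopyNumberProfile,
    origins: OriginSet,
    layout: GenomeLayout,
    S_dur: float,
) -> OriginDelayTable:
    """Evaluate the wt − mut profile difference at each origin's bin.

    The copy-number difference converts to minutes by multiplying with the
    S-phase duration.  Origins whose bin is missing in either profile are
    dropped and counted in ``n_dropped``.
    """
    wt.require_same_grid(mut)
    rows = []
    n_dropped = 0
    dists = origins.centromere_distances_kb(layout)
    for (i, row), dist in zip(origins.table.iterrows(), dists):
        b = wt.bin_index(row.pos)
        w, m = float(wt.data[row.chrom][b]), float(mut.data[row.chrom][b])
        if not (np.isfinite(w) and np.isfinite(m)):
            n_dropped += 1
            continue
        delay_cn = w - m
        rows.append((i, row.chrom, int(row.pos), float(dist), delay_cn, delay_cn * S_dur))
    table = pd.DataFrame(
        rows, columns=["origin_id", "chrom", "pos", "cen_dist_kb", "delay_cn", "delay_min"]
    )
    return OriginDelayTable(table, S_dur=S_dur, n_dropped=n_dropped)


def fit_exponential_decay(
    dist_kb: np.ndarray, y: np.ndarray, lam0: float = 10.0
) -> DecayFit:
    """Least-squares fit of y = a·exp(−d/lam) + c, deterministic given data."""
    dist_kb = np.asarray(dist_kb, float)
    y = np.asarray(y, float)
    if len(dist_kb) < 4:
        raise FitError("need at least 4 points for the decay regression")
    if np.unique(dist_kb).size < 2:
        raise FitError("degenerate design: all points at the same distance")
    a0 = float(y.max())
    if np.allclose(y, 0.0):
        return DecayFit(0.0, lam0, 0.0, 0.0)

    def f(d, a, lam, c):
        return a * np.exp(-d / lam) + c

    popt, _ = curve_fit(
        f,
        dist_kb,
        y,
        p0=(a0, lam0, 0.0),
        bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    rss = float(np.sum((y - f(dist_kb, *popt)) ** 2))
    return DecayFit(float(popt[0]), float(popt[1]), float(popt[2]), rss)


def delay_distance_regression(table: OriginDelayTable, lam0: float = 10.0) -> DecayFit:
    """Regression of per-origin delay (minutes) on centromere distance (kb)."""
    return fit_exponential_decay(
        table.table["cen_dist_kb"].to_numpy(), table.table["delay_min"].to_numpy(), lam0
    )


def fit_delay_cutoff(
    wt_origins: OriginSet,
    layout: GenomeLayout,
    mut_profile: CopyNumberProfile,
    params: KineticsParams,
    D_grid_kb,
    delta_grid_min,
    scoring_window_kb: float = DEFAULT_SCORING_WINDOW_KB,
    smooth_window_kb: float | None = None,
    normalization: str = "quantile",
) -> DelayFit:
    """Grid search for the delayed-origin cutoff recapitulating the mutant profile.

    For each candidate (D, delta), wild-type origins within D kb of their
    centromere are delayed by delta minutes, the deterministic kinetics
    model produces a profile, the profile is put on the same normalized
    scale as the observed one (and smoothed with ``smooth_window_kb`` if
    the observation was), and the sum of squared deviations from
    ``mut_profile`` is accumulated over defined bins within
    ``scoring_window_kb`` of a centromere.  Ties break toward the smallest
    D, then the smallest delta, so the minimal delayed set consistent with
    the data is reported.
    """
    D_grid = sorted(float(d) for d in D_grid_kb)
    delta_grid = sorted(float(d) for d in delta_grid_min)
    if not D_grid or not delta_grid:
        raise ParameterError("D and delta grids must be non-empty")
    bw = mut_profile.bin_width
    masks = {}
    for chrom in mut_profile.chroms:
        x = mut_profile.bin_starts(chrom)
        near = layout.centromere_distance_kb(chrom, x) <= scoring_window_kb
        masks[chrom] = near & np.isfinite(mut_profile.data[chrom])

    records = []
    best = None
    for D in D_grid:
        for delta in delta_grid:
            delayed = apply_mutant(wt_origins, layout, MutantSpec(D, delta))
            timing = replication_time(layout, delayed, params, bin_width=bw)
            model = copy_number_profile(timing, params)
            if smooth_window_kb is not None:
                model = smooth_profile(model, smooth_window_kb)
            model_vals = anchor_values(model.all_values(), method=normalization)
            obj = 0.0
            offset = 0
            for chrom in mut_profile.chroms:
                n = len(mut_profile.data[chrom])
                mv = model_vals[offset : offset + n]
                offset += n
                m = masks[chrom]
                obj += float(np.sum((mv[m] - mut_profile.data[chrom][m]) ** 2))
            records.append((D, delta, obj))
            if best is None or obj < best[2] - 1e-12:
                best = (D, delta, obj)
    D_hat, delta_hat, obj = best
    dist = wt_origins.centromere_distances_kb(layout)
    flagged = [int(i) for i, d in zip(wt_origins.table.index, dist) if d <= D_hat]
    grid = pd.DataFrame(records, columns=["cutoff_kb", "delay_min", "objective"])
    return DelayFit(D_hat, delta_hat, flagged, obj, grid)
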