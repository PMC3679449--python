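"""Sort-seq profile reconstruction: S/G2 ratio, normalization, smoothing, peaks.

The pipeline mirrors how replication-timing profiles are built from
sorted-cell sequencing: per-bin S-phase read counts are taken relative to
G2–M counts after depth normalization, the raw ratio track is rescaled to
the relative copy-number interval [1.0, 2.0], smoothed within each
chromosome, and compared between strains as a difference track.  Bins
failing the coverage filter are carried as missing (NaN) through every
stage and are never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .genome import ParameterError
from .tracks import CopyNumberProfile, DiffTrack, RatioTrack, ReadCounts

__all__ = [
    "compute_ratio",
    "normalize_profile",
    "anchor_values",
    "smooth_profile",
    "differential_profile",
    "profile_peaks",
    "DegenerateInputError",
]

DEFAULT_MIN_COUNT = 10
DEFAULT_SMOOTH_WINDOW_KB = 15.0


class DegenerateInputError(ValueError):
    """Raised when a track has no dynamic range to normalize."""


def compute_ratio(s: ReadCounts, g2: ReadCounts, min_count: int = DEFAULT_MIN_COUNT) -> RatioTrack:
    """Depth-normalized per-bin S / G2 read-count ratio.

    Each sample is first scaled to equal totals so the ratio is free of
    sequencing depth; bins whose raw G2 count is below ``min_count`` are
    marked missing (NaN) and no division is performed there.
    """
    s.require_same_grid(g2)
    total_s, total_g2 = s.total(), g2.total()
    if total_s == 0 or total_g2 == 0:
        raise DegenerateInputError("a sample with zero total reads cannot be normalized")
    scale = total_g2 / total_s
    data = {}
    for chrom in s.chroms:
        sc = s.data[chrom].astype(float)
        gc = g2.data[chrom].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = scale * sc / gc
        ratio[gc < min_count] = np.nan
        data[chrom] = ratio
    return RatioTrack(s.bin_width, data, label="S/G2")


def anchor_values(
    values: np.ndarray, method: str = "quantile", anchor_source: np.ndarray | None = None
) -> np.ndarray:
    """Rescale raw ratio values onto the [1.0, 2.0] copy-number scale.

    ``"quantile"`` maps the 1st/99th percentiles of the defined values to
    1.0/2.0; ``"mean"`` maps the mean to 1.5 with unit slope per relative
    unit.  Both clip to [1.0, 2.0]; NaNs pass through.  When
    ``anchor_source`` is given, the anchors are estimated from it (e.g. a
    noise-reduced copy of the track) but applied to ``values``: per-bin
    counting noise widens raw-ratio quantiles and would otherwise compress
    the recovered scale.
    """
    src = values if anchor_source is None else anchor_source
    defined = src[np.isfinite(src)]
    if method == "quantile":
        lo, hi = np.percentile(defined, [1.0, 99.0])
        if hi - lo < 1e-12:
            raise DegenerateInputError("constant track: zero interquantile range")
        out = 1.0 + (values - lo) / (hi - lo)
    elif method == "mean":
        m = defined.mean()
        if m <= 0:
            raise DegenerateInputError("non-positive mean ratio")
        out = values / m * 1.5
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return np.clip(out, 1.0, 2.0)


def _rolling_mean(vals: np.ndarray, nbins: int) -> np.ndarray:
    return pd.Series(vals).rolling(nbins, center=True, min_periods=1).mean().to_numpy()


def normalize_profile(
    raw: RatioTrack,
    method: str = "quantile",
    label: str = "",
    anchor_window_kb: float = DEFAULT_SMOOTH_WINDOW_KB,
) -> CopyNumberProfile:
    """Rescale a raw ratio track to the bounded [1.0, 2.0] profile scale.

    The anchors are computed genome-wide (at least 100 defined bins
    required) on a centered-rolling-mean copy of the track spanning
    ``anchor_window_kb`` so that per-bin counting noise does not inflate
    the quantile span; the resulting affine map is applied to the raw
    values per chromosome, and missing bins stay missing.
    """
    allv = raw.all_values()
    if np.isfinite(allv).sum() < 100:
        raise ParameterError("need at least 100 defined bins to normalize")
    nbins = max(1, int(round(anchor_window_kb * 1000.0 / raw.bin_width)))
    anchor_src = np.concatenate(
        [_rolling_mean(raw.data[c], nbins) for c in raw.chroms]
    )
    anchored = anchor_values(allv, method=method, anchor_source=anchor_src)
    data = {}
    offset = 0
    for chrom in raw.chroms:
        n = len(raw.data[chrom])
        data[chrom] = anchored[offset : offset + n]
        offset += n
    return CopyNumberProfile(raw.bin_width, data, label=label or raw.label)


def smooth_profile(
    profile: CopyNumberProfile, window_kb: float = DEFAULT_SMOOTH_WINDOW_KB
) -> CopyNumberProfile:
    """Centered moving average within each chromosome.

    The window is ``window_kb`` kilobases, rounded to an odd number of
    bins; missing bins are excluded from neighboring window means and stay
    missing themselves.  No bleed across chromosome boundaries.
    """
    window_bp = window_kb * 1000.0
    if window_bp < profile.bin_width:
        raise ParameterError("smoothing window must be at least one bin wide")
    nbins = int(round(window_bp / profile.bin_width))
    if nbins % 2 == 0:
        nbins += 1
    data = {}
    for chrom in profile.chroms:
        vals = profile.data[chrom]
        sm = (
            pd.Series(vals)
            .rolling(nbins, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        sm[~np.isfinite(vals)] = np.nan
        data[chrom] = sm
    return CopyNumberProfile(profile.bin_width, data, label=profile.label)


def differential_profile(a: CopyNumberProfile, b: CopyNumberProfile) -> DiffTrack:
    """Per-bin difference a − b between two strains' profiles.

    Defined only where both inputs are defined; anti-symmetric in its
    arguments.
    """
    a.require_same_grid(b)
    data = {c: a.data[c] - b.data[c] for c in a.chroms}
    label = f"{a.label or 'A'} - {b.label or 'B'}"
    return DiffTrack(a.bin_width, data, label=label)


def profile_peaks(
    profile: CopyNumberProfile, min_prominence: float = 0.02
) -> list[tuple[str, int]]:
    """Local maxima of the profile, per chromosome.

    Returns ``(chrom, bin_start)`` positions of maxima with prominence at
    least ``min_prominence`` copy-number units.  Peaks of replication-
    timing profiles mark active origins, so on clean input each returned
    position falls within a bin of an origin.  NaN stretches split the
    search into independent segments.
    """
    peaks: list[tuple[str, int]] = []
    for chrom in profile.chroms:
        vals = profile.data[chrom]
        finite = np.isfinite(vals)
        # scan contiguous defined segments independently
        boundaries = np.flatnonzero(np.diff(finite.astype(int)) != 0) + 1
        start = 0
        for end in list(boundaries) + [len(vals)]:
            if finite[start:end].any() and finite[start]:
                idx, _ = signal.find_peaks(vals[start:end], prominence=min_prominence)
                peaks.extend((chrom, int((start + i) * profile.bin_width)) for i in idx)
            start = end
    return peaks
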