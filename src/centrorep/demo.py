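"""End-to-end demonstration pipeline on synthetic data.

Runs the whole analysis chain — simulate a wild-type and a
pericentromeric-delay mutant, reconstruct both sort-seq profiles, form
the differential track, extract origin delays and their distance
regression, fit the delayed-origin cutoff, simulate and analyze the
cohesin ChIP pair — and writes every intermediate to an output
directory.  All randomness derives from the configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import chip_stats, sortseq_pipeline, synthetic_data, timing_inference
from .config import load_config
from .genome import MutantSpec
from .replication_model import KineticsParams, copy_number_profile, replication_time

log = logging.getLogger("centrorep")

__all__ = ["run_demo", "reconstruct_profile", "synthetic_pair"]


def reconstruct_profile(s_counts, g2_counts, cfg_sortseq, label=""):
    """compute_ratio -> normalize -> smooth, with the configured options."""
    raw = sortseq_pipeline.compute_ratio(s_counts, g2_counts, cfg_sortseq["min_count"])
    prof = sortseq_pipeline.normalize_profile(
        raw, method=cfg_sortseq["normalization"], label=label
    )
    return sortseq_pipeline.smooth_profile(prof, cfg_sortseq["smooth_window_kb"])


def synthetic_pair(cfg: dict, seed: int):
    """Simulate the WT / mutant sort-seq experiment pair from a config.

    Returns (layout, wt_origins, wt_profile, mut_profile, params) where the
    profiles went through the full reconstruction pipeline.
    """
    g = cfg["genome"]
    layout, origins = synthetic_data.make_genome(
        g["n_chrom"], g["chrom_length"], g["origin_spacing"], seed=seed,
        peri_offsets=tuple(g["peri_offsets"]), t_sigma=g["t_sigma"],
        competence=g["competence"], t_jitter_sd=g["t_jitter_sd"],
    )
    params = KineticsParams(**cfg["kinetics"])
    spec = MutantSpec(cfg["mutant"]["cutoff_kb"], cfg["mutant"]["delay_min"])
    mut_origins = synthetic_data.apply_mutant(origins, layout, spec)
    bw = cfg["sortseq"]["bin_width"]
    depth = cfg["sortseq"]["depth"]
    profiles = {}
    for name, oset, sub_seed in (("wt", origins, seed + 1), ("mut", mut_origins, seed + 2)):
        truth = copy_number_profile(
            replication_time(layout, oset, params, bin_width=bw), params, label=name
        )
        s_counts, g2_counts = synthetic_data.simulate_sortseq_counts(truth, depth, sub_seed)
        profiles[name] = reconstruct_profile(s_counts, g2_counts, cfg["sortseq"], label=name)
    return layout, origins, profiles["wt"], profiles["mut"], params


def run_demo(config_path=None, outdir: str | Path = "centrorep_demo", seed: int | None = None) -> dict:
    """Run the full synthetic analysis chain and write all outputs to *outdir*."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("demo: resolved config %s", json.dumps(cfg))

    layout, origins, wt_prof, mut_prof, params = synthetic_pair(cfg, seed)
    layout.to_bed(outdir / "centromeres.bed")
    origins.to_tsv(outdir / "origins.tsv")
    wt_prof.to_bedgraph(outdir / "wt_profile.bedgraph")
    mut_prof.to_bedgraph(outdir / "mut_profile.bedgraph")

    diff = sortseq_pipeline.differential_profile(wt_prof, mut_prof)
    diff.to_bedgraph(outdir / "diff_profile.bedgraph")

    delays = timing_inference.origin_delays(wt_prof, mut_prof, origins, layout, params.S_dur)
    delays.to_tsv(outdir / "origin_delays.tsv")
    decay = timing_inference.delay_distance_regression(delays)

    log.info("demo: fitting delay cutoff over %d x %d grid",
             len(cfg["fit"]["D_grid_kb"]), len(cfg["fit"]["delta_grid_min"]))
    fit = timing_inference.fit_delay_cutoff(
        origins, layout, mut_prof, params,
        cfg["fit"]["D_grid_kb"], cfg["fit"]["delta_grid_min"],
        scoring_window_kb=cfg["fit"]["scoring_window_kb"],
        smooth_window_kb=cfg["sortseq"]["smooth_window_kb"],
        normalization=cfg["sortseq"]["normalization"],
    )

    # cohesin-like ChIP pair: peaks at regular spacing on every chromosome
    c = cfg["chip"]
    peak_positions = [
        (chrom, int(pos))
        for chrom, length in layout.chromosomes
        for pos in np.arange(c["peak_spacing"] // 2, length, c["peak_spacing"])
    ]
    ip_wt, in_wt = synthetic_data.simulate_chip_counts(
        layout, peak_positions, c["amplitude"], None, c["depth"], seed + 3
    )
    ip_mut, in_mut = synthetic_data.simulate_chip_counts(
        layout, peak_positions, c["amplitude"], (c["rho"], c["lambda_kb"]),
        c["depth"], seed + 4,
    )
    track_wt = chip_stats.enrichment_track(ip_wt, in_wt, c["min_input"])
    track_mut = chip_stats.enrichment_track(ip_mut, in_mut, c["min_input"])
    peaks = chip_stats.find_peaks(track_wt, layout, c["threshold"], c["min_separation_kb"])
    peaks.to_bed(outdir / "chip_peaks.bed")
    ratio_table, ratio_fit = chip_stats.peak_ratio_regression(peaks, track_wt, track_mut)
    ratio_table.to_csv(outdir / "peak_ratios.tsv", sep="\t", index=False)

    report = {
        "seed": seed,
        "n_origins": len(origins),
        "delay_fit": {
            "cutoff_kb": fit.cutoff_kb,
            "delay_min": fit.delay_min,
            "n_flagged_origins": len(fit.flagged_origin_ids),
            "objective": fit.objective,
        },
        "delay_decay_regression": {"a_min": decay.a, "lambda_kb": decay.lam, "c_min": decay.c},
        "n_chip_peaks": len(peaks),
        "chip_ratio_regression": {
            "a": ratio_fit.a, "lambda_kb": ratio_fit.lam, "c": ratio_fit.c,
        },
        "profile_bounds": {
            "wt_max": float(np.nanmax(wt_prof.all_values())),
            "wt_min": float(np.nanmin(wt_prof.all_values())),
            "mut_max": float(np.nanmax(mut_prof.all_values())),
            "mut_min": float(np.nanmin(mut_prof.all_values())),
        },
    }
    (outdir / "fit.json").write_text(json.dumps(report["delay_fit"], indent=2))
    (outdir / "summary.json").write_text(json.dumps(report, indent=2))
    return report
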