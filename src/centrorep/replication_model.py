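"""Replication kinetics: origin firing times -> timing maps -> copy-number profiles.

The deterministic model is the classic min-rule for bidirectional forks
moving at constant velocity v: a locus x is replicated at

    T(x) = min_i ( t_i + |x - x_i| / v )

over origins i with firing times t_i at positions x_i.  The stochastic
mode draws per-cell firing times from a truncated normal, drops
incompetent origins per cell, applies the min rule, and averages over
cells.  A sorted S-phase population sampled uniformly across S phase
sees a locus replicated at time T with relative copy number

    r(x) = 2 - T(x) / S_dur,   clipped to [1, 2],

which is the sort-seq scale.  A brute-force lattice fork simulation is
provided as an independent oracle for the analytic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeLayout, OriginSet, ParameterError
from .tracks import CopyNumberProfile, TimingMap

__all__ = [
    "KineticsParams",
    "ModelError",
    "replication_time",
    "copy_number_profile",
    "lattice_fork_oracle",
]

DEFAULT_BIN_WIDTH = 1000


class ModelError(ValueError):
    """Raised when the kinetics model cannot be evaluated on its input."""


@dataclass(frozen=True)
class KineticsParams:
    """Fork kinetics and S-phase population parameters.

    v
        Fork velocity in kb/min.
    S_dur
        S-phase duration in minutes; also the copy-number conversion factor.
    mode
        ``"deterministic"`` (seedless, exact) or ``"stochastic"``
        (Monte-Carlo over cells).
    n_cells
        Monte-Carlo sample size in stochastic mode.
    """

    v: float = 1.5
    S_dur: float = 40.0
    mode: str = "deterministic"
    n_cells: int = 500

    def __post_init__(self) -> None:
        if self.v <= 0 or self.S_dur <= 0:
            raise ParameterError("v and S_dur must be positive")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be at least 1")
        if self.mode not in ("deterministic", "stochastic"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def _min_rule(x: np.ndarray, pos: np.ndarray, t: np.ndarray, v_bp: float) -> np.ndarray:
    # pairwise (origins x bins) travel times; fine at desk scale
    arrival = t[:, None] + np.abs(x[None, :] - pos[:, None]) / v_bp
    return arrival.min(axis=0)


def replication_time(
    layout: GenomeLayout,
    origins: OriginSet,
    params: KineticsParams,
    bin_width: int = DEFAULT_BIN_WIDTH,
    seed: int | None = None,
) -> TimingMap:
    """Per-bin replication time T(x), evaluated at bin starts.

    Deterministic mode applies the min rule with each origin's mean firing
    time.  Stochastic mode samples ``n_cells`` cells: firing times are drawn
    from Normal(t_mean, t_sigma) truncated at 0, each origin fires with
    probability ``competence``, and a cell's chromosome with no competent
    origin replicates uniformly at ``S_dur``; the reported map is the
    per-bin mean over cells.
    """
    origins.validate_positions(layout)
    v_bp = params.v * 1000.0
    data: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for chrom in layout.names:
        sub = origins.for_chrom(chrom)
        x = layout.bin_starts(chrom, bin_width).astype(float)
        if params.mode == "deterministic":
            if len(sub) == 0:
                raise ModelError(f"chromosome {chrom!r} has no origins")
            data[chrom] = _min_rule(
                x, sub["pos"].to_numpy(float), sub["t_mean"].to_numpy(float), v_bp
            )
        else:
            data[chrom] = _stochastic_chrom(x, sub, params, v_bp, rng)
    return TimingMap(bin_width, data, label="T")


def _stochastic_chrom(x, sub, params, v_bp, rng) -> np.ndarray:
    n_ori = len(sub)
    if n_ori == 0:
        return np.full(len(x), params.S_dur)
    mu = sub["t_mean"].to_numpy(float)
    sigma = sub["t_sigma"].to_numpy(float)
    comp = sub["competence"].to_numpy(float)
    pos = sub["pos"].to_numpy(float)
    acc = np.zeros(len(x))
    for _ in range(params.n_cells):
        t = np.where(
            sigma > 0,
            stats.truncnorm.rvs(
                -mu / np.where(sigma > 0, sigma, 1.0), np.inf, loc=mu,
                scale=np.where(sigma > 0, sigma, 1.0), random_state=rng,
            ),
            mu,
        )
        fires = rng.random(n_ori) < comp
        if not fires.any():
            acc += params.S_dur
            continue
        acc += _min_rule(x, pos[fires], t[fires], v_bp)
    return acc / params.n_cells


def copy_number_profile(
    timing: TimingMap, params: KineticsParams, label: str = ""
) -> CopyNumberProfile:
    """Map replication times to the sort-seq relative copy-number scale."""
    data = {
        chrom: np.clip(2.0 - vals / params.S_dur, 1.0, 2.0)
        for chrom, vals in timing.data.items()
    }
    return CopyNumberProfile(timing.bin_width, data, label=label)


def lattice_fork_oracle(
    layout: GenomeLayout,
    origins: OriginSet,
    params: KineticsParams,
    dt: float = 0.1,
    dx: int = 200,
) -> TimingMap:
    """Brute-force time-stepped bidirectional fork propagation on a site lattice.

    Sites are spaced ``dx`` bp apart; time advances in steps of ``dt``
    minutes.  An unreplicated site replicates when its origin's firing time
    has passed, or when an adjacent site has been replicated for at least
    ``dx / v`` minutes.  Agrees with :func:`replication_time` within one
    lattice step, ``dt + dx / v``, everywhere (deterministic mode only).
    """
    v_bp = params.v * 1000.0
    if v_bp * dt > dx:
        raise ParameterError(f"CFL violation: v*dt = {v_bp * dt:.1f} bp > dx = {dx} bp")
    hop = dx / v_bp  # minutes for a fork to traverse one site
    data: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        sub = origins.for_chrom(chrom)
        if len(sub) == 0:
            raise ModelError(f"chromosome {chrom!r} has no origins")
        n_sites = layout.n_bins(chrom, dx)
        fire_time = np.full(n_sites, np.inf)
        idx = np.minimum(sub["pos"].to_numpy(np.int64) // dx, n_sites - 1)
        for i, t0 in zip(idx, sub["t_mean"].to_numpy(float)):
            fire_time[i] = min(fire_time[i], t0)
        rep = np.full(n_sites, np.inf)
        t = 0.0
        t_max = float(sub["t_mean"].max()) + n_sites * hop + dt
        while np.isinf(rep).any() and t <= t_max:
            # candidate replication time for each still-unreplicated site:
            # its own firing, or a fork arriving from either neighbor
            cand = fire_time.copy()
            cand[1:] = np.minimum(cand[1:], rep[:-1] + hop)
            cand[:-1] = np.minimum(cand[:-1], rep[1:] + hop)
            new = np.isinf(rep) & (cand <= t)
            rep[new] = cand[new]  # exact event time, discovered on the dt grid
            t += dt
        data[chrom] = rep
    return TimingMap(dx, data, label="T_lattice")
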