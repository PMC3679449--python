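# Methods

This note records the models, parameter choices, numerical conventions
and known limitations of `centrorep`, in the order data flow through the
package.

## Replication kinetics

A chromosome is a 1-D interval with origins at positions `x_i`,
characterized by a mean firing time `t_mean` (min), a firing-time spread
`t_sigma` (min) and a competence (the probability that the origin fires
at all in a given cell).  Forks move bidirectionally at constant
velocity `v` and are absorbed at chromosome ends; there is no
checkpoint feedback, no rate-limiting-factor recycling, and no
re-replication.

*Deterministic mode* applies the min-rule

    T(x) = min_i ( t_mean_i + |x − x_i| / v )

exactly, evaluated at bin starts; it is seedless and is the default in
tests and fitting.  *Stochastic mode* draws per-cell firing times from a
normal truncated at 0, drops incompetent origins per cell
(chromosomes with no competent origin in a cell replicate at `S_dur`),
applies the min-rule per cell and averages over `n_cells` (default 500,
seeded).

Defaults `v = 1.5 kb/min` and `S_dur = 40 min` are order-of-magnitude
budding-yeast values; both are configurable and every inferred delay is
reported in copy-number units alongside minutes so the `S_dur`
conversion is always explicit.

The copy-number map assumes cells are sampled uniformly across S-phase
progression in the sorted S gate, giving the linear `r = 2 − T/S_dur`
clipped to [1, 2].  This is the simplest population model consistent
with a gate spanning S phase; a non-uniform gate would bend the map
monotonically but not move peak positions.

### Lattice oracle

`lattice_fork_oracle` is an independent brute-force check: sites spaced
`dx` bp, time steps `dt` min, a site replicating either when its
origin's firing time has passed or one lattice-hop time `dx/v` after a
neighbor.  Event times are recorded exactly (firing time, neighbor time
+ hop) and the stepping only discovers them, so the discrepancy against
the analytic map is bounded by one lattice step `dt + dx/v` (origin
positions snap to sites) rather than accumulating per hop.  `v·dt > dx`
is rejected.  Property tests compare the two routes on random origin
sets.

## Synthetic genome and mutant

The default genome is 4 chromosomes × 400 kb (16 × 500 kb for demo-scale
runs), centromeres mid-chromosome.  Origins sit on a regular 40-kb grid
anchored at each centromere — guaranteeing an origin on the centromere —
plus pericentromeric origins at ±17.5 kb.  The pericentromeric
augmentation reflects the origin-rich neighborhoods of point
centromeres and sets the spatial resolution at which an
initiation-delay cutoff is identifiable: with origins only every 40 kb,
any cutoff between 0 and 40 kb would delay the same single origin and
the fit could not localize the boundary.

Mean firing times grade linearly with centromere distance from 10 min
(centromere-proximal) to 35 min (most distal), clamped, with seeded
N(0, 1 min) jitter on arm origins; the gradient makes every centromeric
region early-replicating, qualitatively matching the organism.  Firing
spread defaults to `t_sigma = 4 min`, competence to 1.

The mutant ("kinetochore-DDK-loss") parameterization delays `t_mean` of
exactly the origins within `cutoff_kb` of a centromere by `delay_min`.
The default hidden truth used in recovery tests is cutoff 17.5 kb,
delay 10 min.

## Sequencing noise

Sort-seq counts are Poisson: G2 bins at rate `depth`, S bins at rate
`depth · r(x)/1.5`, the 1.5 being the genome-mean copy number of a
uniformly sampled S population so both samples have comparable totals.
Default depth is 300 reads per 1-kb bin — a deliberately desk-scale
choice; depth, bin size and sort purity are not constrained by any
published value and are exposed in the configuration.  No mappability
or GC bias is modelled beyond an optional multiplicative per-bin bias
hook; counts are independent across bins.

ChIP counts are Poisson around `depth · e(x)` (IP) and `depth` (input),
with `e(x) = 1 + Σ_p A_p · kernel(x − p)` and a triangular kernel of
1-kb half-width.  In mutant mode each peak amplitude is multiplied by
`1 − ρ·exp(−d/λ_c)` with `d` the peak's centromere distance.  Defaults
`A = 5`, `ρ = 0.3`, `λ_c = 20 kb` place the wild-type/mutant enrichment
ratio's 10%-excess crossing at ~20 kb, i.e. the depletion is
pericentromere-confined.

## Profile reconstruction

`compute_ratio` scales both samples to equal totals and takes the
per-bin S/G2 ratio; bins with raw G2 count below `min_count = 10` are
missing (NaN).  Missing bins propagate through every stage and are
never imputed.

`normalize_profile` maps the genome-wide 1st/99th percentiles of the
ratio to 1.0/2.0 and clips — quantile anchoring is robust to outlier
bins; a mean→1.5 anchoring is available behind the `normalization`
option.  The anchors are *estimated* on a centered rolling-mean copy of
the track (window equal to the display smoothing window, 15 kb): per-bin
counting noise at depth 300 inflates the raw quantile span by roughly
half and would otherwise compress the recovered scale systematically.
The resulting affine map is applied to the raw per-bin values.

`smooth_profile` is a centered moving average (default 15 kb, rounded
to an odd bin count), computed within chromosomes only, excluding
missing bins from window means.  A moving average was chosen for being
deterministic and parameter-transparent.

`profile_peaks` reports per-chromosome local maxima above a prominence
floor (default 0.02 copy-number units); on noise-free profiles each
peak falls within one bin of an origin.

### Accuracy convention

Profiles are recovered up to the affine display anchoring (the [1, 2]
display scale stretches the truth's dynamic range), and display
smoothing flattens origin apexes of the truth itself.  Reconstruction
accuracy is therefore quoted as RMSE against the truth carried through
the same anchoring-and-smoothing convention, with differences converted
back to true copy-number units by undoing the display stretch.  Under
the default conditions (depth 300, 4 × 400 kb genome) this RMSE is
0.035–0.045 copy-number units across seeds.

## Delay inference

`origin_delays` evaluates the wild-type-minus-mutant profile difference
at each origin's bin (copy-number units) and converts to minutes via
`S_dur`; origins with a missing bin in either profile are dropped and
counted.  `delay_distance_regression` fits `a·exp(−d/λ) + c` by
Levenberg–Marquardt from the deterministic start `(max delay, 10 kb,
0)`; an all-zero input short-circuits to a flat fit, and designs with a
single distinct distance are rejected.

`fit_delay_cutoff` grid-searches `(D, δ)` (defaults: D from 0 to 50 kb
in 2.5-kb steps, δ from 0 to 30 min in 2.5-min steps), each candidate
evaluated by delaying the wild-type origins within `D`, recomputing the
deterministic model profile, passing it through the same smoothing and
anchoring as the observed profile, and summing squared deviations over
defined bins within 100 kb of a centromere.  Arm bins carry no
information about a pericentromeric delay and would only dilute the
objective; the window is configurable.  Ties break toward the smallest
`D`, then the smallest `δ`, so the minimal delayed-origin set
consistent with the data is reported; the flagged set is by definition
every origin within `D̂`.  A single genome-wide `(D, δ)` is fitted —
the parsimonious reading when one cutoff range describes all
chromosomes — with per-chromosome variation left to the configurable
scoring window rather than extra parameters.

On noise-free input the grid objective is zero exactly at the
generating parameters (and at any cutoff delaying the same origin set,
resolved by the tie-break); at depth 300 the recovered cutoff lands
within one grid step of the truth in ≥ 90% of seeded replicates.

## ChIP statistics

Fold enrichment from qPCR panels is `(IP/WCE at locus, condition)`
divided by the same quantity at a designated control locus in a
reference condition; the reference anchor is exactly 1 by construction,
and alternative anchorings (e.g. a specific time point) are expressed
through condition labels.

Enrichment tracks are depth-normalized IP/input ratios with low-input
bins missing.  Peak calling is deliberately minimal and auditable:
strict local maxima above a threshold (default 1.5 × the genome median)
with a minimum apex separation (default 2 kb), higher apex winning and
ties going left.

`peak_ratio_regression` fits the exponential decay to `ratio − 1`
against centromere distance.  The `ratio − 1` statistic is not exactly
exponential when the generator's amplitude reduction is strong — its
apparent decay length is compressed by a factor that grows with
`ρ·A/(1+A)` near the centromere — so the fitted `λ` underestimates
`λ_c` by ~15% at the generator defaults (within the ±20% recovery
tolerance) and by more for stronger depletion.  The regression is kept
on `ratio − 1` because that is the natural display statistic; users
needing an unbiased decay length can fit `1 − 1/ratio`, which is exactly
exponential under this generator.

## Count assays

Two-dot cohesion fractions get Wilson score intervals (95% default) and
two-sided Fisher exact tests for all condition pairs; the Fisher
implementation is cross-checked in the tests against a full
hypergeometric enumeration written independently.  Chromosome-loss
rates are half-sectored colonies over total — loss at the first
division after plating; full fluctuation analysis is out of scope.
Synergy between two perturbations is declared on the additive scale:
the double perturbation's excess rate over control exceeding the sum of
the single excesses.  Exact tests were preferred throughout because the
assays live in the small-count regime where asymptotic tests misbehave.

## Problem sizes

Tests and the acceptance script run on the 4 × 400 kb genome at 1-kb
bins and depth 300 (1,600 bins, 48 origins), the scale at which every
recovery property above was calibrated; the demo configuration scales
the same machinery to 16 × 500 kb.

## Limitations

- The generator's Poisson, bias-free counts lack mappability structure,
  GC trends, repeat collapse and sort impurity; passing recovery tests
  demonstrates correctness of the estimators under the stated noise
  model, not robustness to real-library artifacts.
- The uniform-S-gate population model and the truncated-normal firing
  distribution are modelling choices isolated behind `KineticsParams`
  and the origin table; other firing-time families plug in by changing
  per-origin parameters.
- The delay-cutoff family assumes a sharp distance threshold shared
  genome-wide; graded or chromosome-specific delays are deliberately
  out of scope (a per-origin free-delay deconvolution is not
  identifiable at these depths).
- Raw colony and cell counts from the motivating microscopy assays are
  not bundled; the statistics modules implement the procedures and are
  validated on synthetic counts only.
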