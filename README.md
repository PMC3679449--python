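# centrorep

Tools for studying how kinetochores advance DNA replication timing and
enrich cohesin at pericentromeres, built around the budding-yeast
situation in which the Dbf4-dependent kinase (DDK) is recruited to
kinetochores and acts on replication origins within a short distance of
the centromere.

The package is aimed at genomicists who want to (i) reconstruct
replication-timing profiles from sort-seq read counts, (ii) ask *which*
origins had their initiation delayed in a mutant — as opposed to being
replicated late passively by forks from delayed neighbors — and
(iii) quantify pericentromeric ChIP enrichment changes and the
small-count cohesion and chromosome-loss assays that accompany such
studies.  Because the raw sequencing data behind such experiments are
rarely at hand, a synthetic-data generator reproduces the statistical
structure of every input, so the whole chain is testable end to end.

## The model

Replication kinetics follow the classic min-rule for bidirectional forks
at constant velocity `v`: with origins at positions `x_i` firing at
times `t_i`, a locus `x` replicates at

    T(x) = min_i ( t_i + |x − x_i| / v ).

A sorted S-phase cell population sampled uniformly across an S phase of
duration `S` sees a locus with replication time `T` at relative copy
number

    r(x) = 2 − T(x) / S,   bounded in [1, 2],

which is the sort-seq scale: early loci approach 2.0, late loci 1.0.
Sort-seq profiles are reconstructed as depth-normalized per-bin S/G2
read-count ratios, rescaled so that the 1st/99th percentiles anchor at
1.0/2.0, and smoothed with a 15-kb moving average.

The central inference is the **delay-cutoff fit**: delay all wild-type
origins within `D` kb of their centromere by `δ` minutes, recompute the
model profile, and score it against the observed mutant profile over
pericentromeric bins; the best `(D̂, δ̂)` on a grid identifies the set of
origins whose initiation was actually delayed.  Per-origin delays are
also regressed on centromere distance with an exponential decay
`a·exp(−d/λ) + c`, and the same regression family summarizes
between-strain ChIP peak-enrichment ratios.

## Worked example

The `demo` subcommand runs the full chain on synthetic data — a 4 × 400 kb
genome with mid-chromosome centromeres, origins every 40 kb plus
pericentromeric origins at ±17.5 kb, and a mutant that delays initiation
of origins within 17.5 kb of centromeres by 10 minutes — then tries to
recover that perturbation from noisy sequencing counts:

```sh
centrorep demo --seed 7 --outdir demo_out
```

prints (abridged):

```json
{
  "delay_fit": {
    "cutoff_kb": 17.5,
    "delay_min": 10.0,
    "n_flagged_origins": 12
  },
  "delay_decay_regression": {
    "a_min": 12.6,
    "lambda_kb": 31.4
  },
  "n_chip_peaks": 160,
  "chip_ratio_regression": {
    "a": 0.39,
    "lambda_kb": 12.8
  },
  "profile_bounds": {
    "wt_max": 1.944,
    "mut_max": 1.961
  }
}
```

Reading this: from read counts at a mean depth of 300 per 1-kb bin, the
grid fit recovered the generating cutoff (17.5 kb) and delay (10 min)
exactly — the 12 flagged origins are precisely the pericentromeric ones.
The per-origin delay regression decays with distance from the
centromere, the wild-type cohesin-like ChIP track yields 160 peaks, and
their wild-type/mutant enrichment ratio decays over ~13 kb (an
underestimate of the generating 20 kb expected for the ratio−1
statistic; see `docs/methods.md`).  Both reconstructed profiles stay
within the [1.0, 2.0] sort-seq bounds.  `demo_out/` holds the profiles
and difference track (bedGraph), the origin-delay table (TSV), the fit
report (JSON) and the called peaks (BED).

Each stage is also available separately (`simulate`, `model`, `profile`,
`diff`, `fitdelay`, `chip`, `stats`) and as plain library functions.

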