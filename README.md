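# paleospd

Summed probability distributions (SPDs) of archaeological radiocarbon and
tree-ring dates, for relative palaeodemography — the "dates as data"
approach, in which the amount of datable material deposited per year is
taken as proportional to population size.

The package is aimed at archaeologists and palaeodemographers who want to

* calibrate radiocarbon determinations against an IntCal-style curve and
  extract highest-density regions,
* clean heterogeneous date archives with auditable, order-fixed filter
  rules (error thresholds, duplicate laboratory numbers, county trimming,
  study-window overlap),
* control investigation bias by binning same-site dates into occupation
  phases before summation,
* treat exactly dated tree-ring specimens as degenerate ("spike")
  distributions so both proxies flow through identical binning and SPD
  machinery, and
* compare the resulting series against independent, period-resolved
  population reconstructions by area-equalized scaling.

A synthetic-data generator with known demographic truth (a boom-bust
trajectory peaking near AD 1300) makes every stage testable end-to-end
without any external downloads.

## The method

A determination x ± σ (¹⁴C years BP) is calibrated against a curve
(μ(t), σ_c(t)) on an annual calendar grid t (cal BP):

    p(t) ∝ φ( x ; μ(t), √(σ² + σ_c(t)²) ),   Σ_t p(t) = 1,

where φ is the Normal density.  A tree-ring cutting date with calendar
year k₀ enters as the degenerate distribution Pr(X = k₀) = 1.

Within each site, dates are clustered by single-linkage agglomeration cut
at height h = 100 years on their uncalibrated age (radiocarbon) or
calendar year (tree-ring): dates chained by consecutive gaps ≤ h form one
site-phase bin.  The densities inside a bin are averaged, and the SPD is
the pointwise sum of bin averages, so each occupation phase — not each
date — contributes unit mass:

    SPD(t) = Σ_b (1/|b|) Σ_{i∈b} p_i(t),   Σ_t SPD(t) = n_bins.

The tree-ring SPD is smoothed with a centre-aligned 21-year Gaussian
kernel (sd 5 years).  For regions with an independent population
reconstruction P(t) (persons, piecewise-constant over periods), the SPD
is rescaled by k = Σ_t P(t) / Σ_t SPD(t) over the shared window, making
the areas under both curves equal so shapes can be compared directly.

## Worked example

`examples/boom_bust_recovery.py` samples 500 tree-ring dated events from
a boom-bust population peaking at AD 1300, builds and smooths the SPD,
and reads the demographic signal back:

```
true population peak: AD 1300
recovered SPD peak:   AD 1304  (error +4 years)
post-peak AD 1300-1600 trend: -5.74e-03 per year (decline)
SPD mass 500.0 over 500 singleton site-phases
```

The recovered peak lands 4 years from the truth and the post-peak trend
is negative: the two directional claims a dates-as-data proxy is expected
to support.  The SPD mass equals the number of site-phases exactly
(mass bookkeeping is conserved through binning and smoothing).

The other examples cover single-date calibration with HPD regions
(`calibrate_and_hpd.py`), cleaning a contaminated archive with an exact
audit trail (`clean_and_bin.py`), and the full multi-region pipeline with
count matrix and proxy comparisons (`full_pipeline.py`).

A thin CLI wraps the same library calls:

```sh
paleospd simulate --seed 5 --out sim/
paleospd filter --radiocarbon sim/radiocarbon.csv --treering sim/treering.csv \
         --curve sim/curve.txt --out filtered/
paleospd spd --treering filtered/treering_filtered.csv --curve sim/curve.txt \
         --smooth --out tr_spd.csv
paleospd run-all --config run.yaml --out out/
```

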