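# Methods

This note documents the models, conventions and numerical choices behind
paleospd, and what the synthetic-data experiments do and do not show.

## Calendar conventions

All internal calendar arithmetic is integer years cal BP with
BP = 1950 − AD and astronomical year numbering (year 0 exists), so BC
years are handled without a discontinuity.  The anchors AD 201 ↔ 1749 BP
and AD 1798 ↔ 152 BP follow directly.  Calendar windows are closed
intervals: the study window 1750–150 BP contains both endpoints, and
window overlap is closed-interval intersection.  Inclusive bounds were
chosen because the alternatives (half-open on either side) silently drop
boundary dates and make "overlaps the window" ambiguous for single-year
regions.

## Calibration

A determination x ± σ is mapped to a density over an annual calendar grid
by p(t) ∝ φ(x; μ(t), √(σ² + σ_c(t)²)), with (μ, σ_c) linearly
interpolated onto the annual grid first (endpoints preserved exactly).
Defaults and tolerances:

* **Normalization** is on by default: each date's density sums to 1
  before binning, so every date carries equal weight in a bin average.
  `normalize=False` keeps the raw per-year Normal density values for
  workflows that want unnormalized summation; both conventions exist in
  the field and the choice measurably changes SPD shape near calibration
  plateaus.
* **Support trimming**: each tail is cut where it holds < 5 × 10⁻⁷ of
  the total mass (so ≥ 1 − 10⁻⁶ is kept), then the density is
  renormalized.  The trim bounds are recorded in the density's metadata.
  The tolerance is far below any interpretable precision; its purpose is
  bounded memory on long curves.
* **Off-curve guard**: if the measurement is more than 10 combined
  standard deviations from the curve everywhere, calibration raises
  rather than returning a numerically meaningless density.

The 95% region used by the window-overlap filter is a highest-density
region, not a central interval: grid years are ranked by mass (ties
broken toward the older year, for determinism) and taken greedily until
the target mass is reached, then merged into maximal contiguous
intervals.  Central intervals misrepresent the multimodal densities that
wiggly calibration curves produce.

## Cleaning rules

Radiocarbon filters run in a fixed order: non-archaeological flag →
error thresholds → duplicate laboratory numbers → county trim →
calibrated-window overlap.  Each stage's removals are counted in a
`FilterReport` whose totals always reconcile
(retained + removed + deduplicated = input).

* The error rule removes dates with 1σ error above 300 ¹⁴C years **or**
  above 25% of the uncalibrated age.  The disjunctive reading is the
  default because it is the stricter, more common hygiene convention;
  the conjunctive reading (`error_rule="both"`) is implemented because
  the phrasing that motivates the rule is genuinely ambiguous.
* Duplicate lab numbers whose (age, σ, county) fully agree collapse to
  one record (counted as deduplicated); any disagreement removes every
  record bearing that number, because there is no principled way to pick
  the correct one.  The kept representative is chosen by a deterministic
  sort key so the retained set is independent of input order.
* County strings are normalized (case-fold, whitespace collapse,
  mandatory two-letter state suffix) before any join; malformed county
  strings assign a record to no region with a logged warning rather than
  an error, since provenance defects should surface in audits, not
  abort a run.

Tree-ring filters keep cutting symbols (B, G, L, c, r, each optionally
with a trailing '+') and near-cutting symbols (v, v+), then apply the
county and window rules.  The classifier is total: every string maps to
exactly one of cutting / near-cutting / other.

## Binning and SPD construction

Single-linkage clustering within a site, cut at height h = 100 years, is
implemented by sorting the site's keys and splitting where a consecutive
gap exceeds h — equivalent to transitive closure over pairs with
|kᵢ − kⱼ| ≤ h (property-tested against that brute-force oracle,
including gaps exactly equal to h, which merge).  Phases are indexed from
1 by descending mean key so "phase 1" is the oldest.

Bin averages are pointwise means on the union grid (absent years count
as zero), and the SPD is the pointwise sum of bin averages over the
requested window; mass falling outside the window is reported as
`clipped_mass` in the metadata rather than silently lost.  With
normalized inputs and no clipping, total SPD mass equals the number of
bins — the central bookkeeping invariant, tested to 10⁻⁶ end-to-end and
10⁻⁹ for individual operations.

## Smoothing

The tree-ring SPD (an annual spike train) is smoothed with a
centre-aligned Gaussian kernel, default 21-year window with sd 5 years,
weights w(i) ∝ exp(−i²/2sd²) normalized to sum 1.  At the series edges
the kernel is truncated to the available years and renormalized — this
keeps constant series exactly constant, where zero-padding would
manufacture spurious edge declines, precisely the artefact the analysis
is designed to avoid.  Receiver-side renormalization alone does not
conserve total mass when mass sits near an edge, so the smoothed series
is finally rescaled by one global factor to the input's total; the
combination conserves mass exactly, leaves constants fixed, and leaves
an interior impulse equal to the normalized kernel.  The radiocarbon SPD
is **not** smoothed by default (calibration already smears it over
decades); smoothing either series is a configuration switch.

## Scaling and comparison

Period-resolved population estimates are expanded to an annual
piecewise-constant series, a period's estimate applying to every year in
[start, end).  Area-equalized scaling multiplies the SPD by
k = Σ person-years / Σ SPD mass over the shared window, after which the
two areas agree exactly (tested to 10⁻⁹); `k` is recorded in the series
metadata.  Comparison output is deliberately descriptive — peak years,
per-century means, first sustained post-peak decline (10 consecutive
negative smoothed first differences), and the sign-agreement fraction of
smoothed first differences — with no significance machinery, because the
underlying comparison is about directionality, not hypothesis testing.

## Synthetic data

The generator adopts deposition ∝ population as its simulation law.  Its
boom-bust default — floor 100, cubic rise from AD 600 to a peak of
10,000 at AD 1300, exponential decline at 0.015/yr, span AD 600–1600 —
emulates a sharply peaked trajectory: an accelerating building boom
followed by a collapse that halves the population roughly every 46
years, which is what the region's reconstructions and tree-ring date
distributions look like.  A flatter (quadratic) rise was considered and
rejected at design time as unrepresentative of the emulated histories.
Measurement: radiocarbon ages are drawn from
Normal(μ(t), √(σ_m² + σ_c²)) and rounded to integer years, with σ_m
uniform on 20–60 ¹⁴C years; near-cutting tree-ring dates are offset 0–3
years before the event; optional "wiggly" curves μ(t) = t + A·sin(2πt/P)
mimic calibration plateaus and cliffs.

Two conditioning choices matter for interpretation:

* Clean radiocarbon draws are rejection-sampled (deterministically from
  the seeded generator) to satisfy σ ≤ 0.25·x and 150 ≤ x ≤ 1750 BP.
  This guarantees that cleaning removals are governed solely by the
  injected contaminants, so filter audits have exact expectations; it
  also means the generator's "clean" records are slightly
  better-behaved than real archives.
* Contaminants are injected at exact configured counts, each built to
  fail precisely one rule (the first it reaches in the filter order).

What passing the synthetic experiments shows: the pipeline's arithmetic
and bookkeeping are correct, and under the stated generative law the
method recovers a boom-bust signal at realistic sample sizes.  What it
does not show: robustness to taphonomic loss, spatially structured
investigation bias, or real calibration-curve structure — the generator
has optional hooks (wiggly curves; thinning can be emulated by custom
population tables) but the defaults do not model these.

## Problem sizes

The replicate study uses 100 seeded replicates of 500 site-phases per
proxy (singleton sites, so the phase count is exact), the HPD coverage
check 10,000 simulated dates at σ = 25, and the binning oracle 1,000
random sites of up to 12 dates on a 50-year lattice (making exact-h gaps
common).  These sizes give binomial standard errors well inside the
stated tolerances while keeping a full run in tens of seconds on one
CPU.

## Known limitations

* No Bayesian sequence/phase modelling, marine or mixed curves, or
  reservoir corrections; the calibration model is the standard
  independent-Normal one.
* County-level region assignment is configuration, not GIS; records with
  unparseable counties are excluded from all regions.
* The comparison statistics are descriptive; Monte-Carlo SPD
  significance envelopes are out of scope.
* The boom-bust recovery property is measured at its stated threshold
  with modest margin; smaller samples or flatter trajectories will not
  localize the peak to ±50 years reliably.
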