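# Methods notes

## Scope and data model

The package covers the numerical path from raw per-mouse measurements to
study endpoints. It deliberately starts *after* image analysis and
cytometry gating: region-of-interest radiances, gated population
percentages and MFIs are consumed as given. All volumes are mm³ from the
caliper formula V = L·W²/2; all times are integer days relative to tumor
irradiation, with negative days allowed for pre-treatment measurements.

The day-0 anchor for percent-change scoring is the day-0 volume when
measured; otherwise the nearest measurement within the two days before
irradiation. Mice with no usable anchor, or with a single measurement, are
carried through every table as `excluded`/`unevaluable` rather than
dropped, so cohort denominators stay auditable.

Duplicate (mouse, site, day) rows in input tables are a hard error. The
alternative — silently averaging — hides upstream data faults, which in
caliper datasets are almost always transcription errors.

## mRECIST scoring

ΔV_d = 100·(V_d − V_start)/V_start at each measured day d ≥ 0. The running
average is the count-based mean of ΔV over measured days in [0, d]. The
sum-over-days/d form seen in daily-sampling write-ups is ill-defined at
d = 0 and under-counts on the irregular 2–3-day schedules real studies use;
the count-based mean is the convention of the originating murine-RECIST
methodology and reduces to the literal form for daily sampling. The literal
denominator remains available (`denominator="day"`, with ΔV̄₀ := 0) so both
conventions can be compared on the same data.

BR and BAR are minima over measured days ≥ `min_day` (default 7; some
murine-RECIST variants use 10 — it is a parameter for exactly that reason).
Thresholds are strict inequalities applied in precedence order
mCR → mPR → mSD → mPD. The boundary case BR = −95, BAR = −40 therefore
classifies as mPR: it fails mCR's strict bounds but satisfies mPR's. The
category regions are nested-overlapping, which is why ordered evaluation —
not mutual exclusion — defines the call.

## Survival endpoints

Events are recorded at the first *measured* day with volume at or above the
threshold; no interpolation between measurement days. Measured-day
granularity is what produces half-day group medians (even-n medians of
integer event days), which interpolation would destroy. A curve crossing at
day 0 is an event at time 0. Welfare exits and study-end exits are
censorings; only threshold crossings are events.

Cumulative (bilateral) volume sums the two sides on the union of measured
days: a side missing a day contributes its last observed value, days before
a side's first measurement contribute 0. Kaplan–Meier estimation and the
Mantel–Cox logrank test come from lifelines; the median convention is the
smallest event time with S(t) ≤ 0.5, reported as not-reached (inf) when the
survivor function never falls that far. When neither group has any event the
logrank is returned as (0, 1) with a warning instead of raising, since
all-censored arms are a legitimate outcome of effective treatment.

AUC integrates volume over [0, study_end] by the trapezoid rule. Curves
ending early are extended horizontally at the last measured value and
flagged `extended`; this partially corrects for informative dropout (the
fastest-growing mice exit first, and simply truncating their integrals
would make aggressive tumors look better). The AUC is not normalized by
study length. A curve measured beyond study_end contributes the linearly
interpolated boundary value so the window is exact.

The local-response criterion takes the nadir as the minimum post-treatment
volume (first occurrence) and V_max as the maximum over days up to and
including the nadir day — "decrease" is relative to the preceding peak, not
a later regrowth maximum. The 50% boundary is inclusive (a 50%-or-more
decrease responds).

## Bioluminescence positivity

Corrected signal is radiance minus the empty-well background, clamped at 0
and flagged — instruments can legitimately read below background, and an
unevaluable flag is more honest than a negative luminosity. The fold change
divides the hottest draining node by its *same-station* contralateral node
(stations are harvested as matched bilateral pairs). A zero contralateral
signal makes the mouse unevaluable rather than infinitely positive. The
cutoff is strict fold > 4, the exact fold-change equivalent of a 300%
increase over the non-draining node; it is a parameter, and cohort
positivity is monotone non-increasing in it.

## Gated statistics

The decision procedure mirrors standard preclinical practice: per-group
Grubbs screening (single pass, two-sided, at most one removal — iterated
Grubbs inflates false exclusions), a Shapiro–Wilk gate at α = 0.05 requiring
*every* group to look normal, then dispatch by group count and branch.
Pairwise comparisons after one-way ANOVA use the pooled within-group
variance (df = N − k) with Holm–Šidák step-down correction; the
nonparametric side uses Dunn's tie-corrected z statistics with Bonferroni
multiplicity over all pairs, the classical form of that post-hoc. Groups
smaller than 3 cannot be normality-tested and fall to the nonparametric
branch with a warning. Mann–Whitney is exact for combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation. Fisher's exact p
sums hypergeometric probabilities of all margin-fixed tables no more likely
than the observed one; the test suite checks it against full enumeration.

Grubbs' critical value, G = ((n−1)/√n)·√(t²/(n−2+t²)) with
t = t₁₋α/(2n),n−2, and Dunn's post-hoc are implemented from their closed
forms; no installed dependency provides them.

## Simulator

The generator emulates the measurement process, not tumor biology: a
three-times-a-week schedule (week offsets 0/2/4), mean-one multiplicative
log-normal noise of coefficient of variation `noise_cv` (default 0.15), a
1 mm³ caliper detection floor, and humane-endpoint truncation. Growth is
exponential — the simplest law matching monotone control curves; Gompertz
flattening is out of scope. Defaults are calibrated to the modelled study
conditions: mean initial volume 80 mm³ at irradiation, and growth rate
g = 0.19/day (doubling ≈ 3.6 days) so a noise-free control crosses
1000 mm³ at day 13.3, i.e. at the day-14 measurement — matching an
untreated-arm median time-to-1000 mm³ of 14 days. Regression runs at
0.25/day; transient responders regress for 7 days (nadir ≈ −83%, landing in
mPR territory) before regrowing, keeping the three classes distinct under
mRECIST (non → mPD, transient → mPR, durable → mCR). A deeper or longer
transient regression would legitimately score mCR — best response is a
*best*, not a final, response — but would be useless as a separate simulated
class.

Truncation: the scheduled measurement that would exceed the burden limit
(1500 mm³ single, 2000 mm³ cumulative for bilateral cohorts) is not
emitted; the curve ends at the previous measured day with
`exit_reason="welfare"`. Emitted tables therefore never contain a volume
above the limit.

Reproducibility: one integer seed; per-mouse substreams are spawned from a
`SeedSequence`, so cohorts are byte-identical across runs and resilient to
partial re-simulation. The bioluminescence generator plants tumor signal in
one random draining station of each positive mouse at `signal_ratio` times
the baseline node signal, with the same noise model.

What passing tests on simulated data do *not* show: the simulator has no
measurement-day jitter, no inter-mouse growth-rate heterogeneity beyond the
initial-volume draw, no spontaneous regression or rejection, and noise
independent across days (real caliper error is partly persistent per
operator). Conclusions about the *engines* transfer to real data;
conclusions about power or variability of a specific in-vivo design do not.

## Numerical conventions

* Ties in the nadir and in best responses resolve to the first occurrence.
* Waterfall tables sort by BAR descending; unevaluable mice sort last.
* Response rates are percentages of evaluable mice.
* The pipeline's provenance file echoes every analysis parameter and the
  seed, but not the output directory, so identical configurations yield
  byte-identical bundles wherever they are written.
* Problem sizes in the acceptance script (cohorts of 12–200 mice, 1000
  null simulations for the type-I check) are chosen as the smallest sizes
  at which the binomial/empirical error bands are meaningfully narrow.

## Known limitations

* No Cox regression, competing risks, or KM confidence bands — point
  estimates, medians and logrank only.
* Two-way ANOVA support covers the factorial dispatch and pooled pairwise
  comparisons; it does not implement within-cell post-hoc families.
* The per-experiment control normalization assumes the control group is
  present in every batch; cross-batch imputation is out of scope.
* Clinical RECIST 1.1 (sum of diameters) semantics are intentionally not
  implemented; the murine volume-based variant is a different instrument.
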