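# preclin

Quantitative endpoints for preclinical tumor radio(immuno)therapy studies.

Mouse efficacy experiments produce caliper growth curves, ex vivo lymph-node
bioluminescence readings, and flow-cytometry/cytokine summary tables. Turning
those into the endpoints that support a treatment claim — response
classification, time-to-volume survival, growth AUC, nodal metastasis calls,
normalized immunophenotype metrics, and correctly dispatched significance
tests — involves a surprising number of conventions that are usually buried
in a Methods paragraph and a spreadsheet. `preclin` implements that whole
chain as a tested, scriptable library, plus a cohort simulator so every stage
can be exercised without animal data.

## What it computes

**Tumor volumes.** From caliper length L (largest diameter) and perpendicular
width W, V = L·W²/2 (mm³). Days are integers relative to the day of tumor
irradiation (day 0); pre-irradiation days are negative.

**Murine mRECIST.** For each mouse, the percent volume change from the
irradiation-day anchor,

    ΔV_d = 100 · (V_d − V_start) / V_start,

and its running average ΔV̄_d over measured days in [0, d]. Best response
BR = min ΔV_d and best average response BAR = min ΔV̄_d, both over days ≥ 7.
The call uses strict thresholds in precedence order: **mCR** (BR < −95 and
BAR < −40), **mPR** (BR < −50 and BAR < −20), **mSD** (BR < 35 and BAR < 30),
else **mPD**. Mice without a usable anchor or without a day ≥ 7 measurement
are *unevaluable*, never silently dropped.

**Survival endpoints.** Time for the primary (or cumulative bilateral) tumor
volume to reach 500 or 1000 mm³; the event day is the first measured day at
or above threshold (no interpolation), otherwise right-censored at the last
observed day. Kaplan–Meier product-limit curves with the S(t) ≤ 0.5 median
convention, and Mantel–Cox logrank comparisons (via lifelines).

**Growth AUC.** Trapezoidal integral of volume over the study window; curves
that end early are extended horizontally at the last measured value (last
value carried forward), so mice that reach the endpoint still contribute.

**Local response.** A mouse is a responder when its post-irradiation nadir is
≤ 50% of the preceding peak volume (nadir ≤ 0.5·V_max).

**Lymph-node metastasis.** Background-corrected average radiance
(p/s/cm²/sr); the draining node with the highest corrected signal over the
same-station contralateral node gives the fold change; fold > 4 — a 300%
increase — calls the node positive.

**Normalizations.** Absolute counts from "% of total", per-mg tumor counts,
percent-of-control within experiment batches, isotype-corrected MFI
(negatives kept, flagged), reference-gene expression ratios, and transwell
migration indices.

**Gated statistics.** Grubbs single-pass outlier screen; Shapiro–Wilk
normality gate at α = 0.05; dispatch to unpaired t / one- or two-way ANOVA
with Holm–Šidák correction, or Mann–Whitney / Kruskal–Wallis with Dunn's
post-hoc; two-sided Fisher's exact test for contingency tables.

**Simulator.** Cohorts mix three responder classes — exponential
non-responders, transient responders (regression, then regrowth), and durable
complete responders regressing to the 1 mm³ caliper detection floor — with
multiplicative log-normal measurement noise, an every-2–3-day schedule, and
humane-endpoint truncation at 1500 mm³ (single) / 2000 mm³ (cumulative).

## Worked example

```bash
preclin simulate --n-mice 6 --mixture 0.4 0.3 0.3 --noise-cv 0.15 \
    --seed 11 --group demo --out demo.csv
preclin mrecist demo.csv --out demo_mrecist.csv
preclin survival demo.csv --threshold 1000 --out demo_surv.csv
```

prints

```
mouse_id group         br        bar call
demo-003  demo 307.419172 131.155377  mPD
demo-005  demo 226.128222 105.854115  mPD
demo-002  demo -85.929654 -50.347640  mPR
demo-004  demo -98.709851 -89.747238  mCR
demo-001  demo -98.745565 -90.966690  mCR
demo-000  demo -98.853747 -91.137224  mCR
demo: n=6, events=3, KM median=not reached
```

Six simulated mice, waterfall-ordered by BAR: two progress (BR > 0, mPD), one
regresses by 86% at best (mPR), and three regress below 5% of their starting
volume with deeply negative running averages (mCR). Three mice reached
1000 mm³ (events); with half the arm still below threshold at follow-up end
the KM median is not reached.

The same stages are available as library calls (`simulate_cohort`,
`score_curve`, `time_to_threshold`, `km_estimate`, `cohort_positivity`,
`compare_groups`, ...) and as one orchestrated run:
`preclin report --config config.yaml` writes per-mouse tables, group
summaries, and a provenance file echoing every parameter and seed.

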