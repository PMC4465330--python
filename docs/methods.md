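# Methods

## The monitoring problem

A premature-piglet cohort is monitored from birth to 96 h: continuous heart
rate, systemic SpO2 and abdominal StO2 sampled nominally every 2 s, enteral
feeds every 3 h starting at 48 h (total parenteral nutrition before that),
blood drawn every 6 h for plasma I-FABP and SAA, and a necropsy at death or
study end giving an ordinal histologic NEC score (0–6 here) and jejunal
I-FABP western-blot densitometry.  Animals fall into three severity groups:
fulminant NEC (f-NEC — symptomatic within 6 h of the first feed, dead by
18 h after feeds), non-fulminant NEC (nf-NEC — signs 18–24 h after feeds,
some surviving to 96 h), and No-NEC.  All time is fractional hours since
birth, so feeds and draws land on exact grid points.

The pipeline asks three questions of these data: does pre-symptomatic
abdominal StO2 separate the groups (baselines, pooled epoch means, an
epoch-level ROC over the pre-feed window); does the splanchnic response to
the first feeds differ (the peri-prandial variability statistic); and does
plasma I-FABP confirm and grade the injury (trajectories, a draw-level ROC,
and the tissue-densitometry correlation at necropsy).

## Preprocessing

Raw streams are averaged into 1-minute epochs.  An epoch with fewer than
half its nominal samples (15 of 30 at 2-s sampling) is marked missing and
never interpolated — robustness to probe dropouts without fabricating data.
A per-animal baseline is the mean of non-missing epochs in the first hour of
its own recording (the probe is placed within ~2 h of birth; "baseline" is
not otherwise defined numerically, so the first recorded hour is this
package's convention, recorded in output metadata).  Group trajectories
summarize per-animal 3-h block means; an animal contributes at grid time t
only while alive, with a strict boundary (`death_h > t`), because a dying
animal's final instants would bias the group mean.  SEM is sample-SD/√n,
absent for n < 2.

## Peri-prandial variability

For each of the first two feeds (48 h, 51 h), the windows are the 15 epochs
before and after the feed; the statistic is `|post − pre| / pre × 100`, and
an animal's value is the mean over its usable windows (≥ 8 of 15 epochs
each).  The pre-feed window mean is the reference level — the birth baseline
is hours stale by 48 h, and the statistic probes the response to the feed
itself.  Unsigned change is the default because "variability" is a magnitude
notion and both groups report positive percentages; signed averaging is
available behind a flag.  The statistic is scale-invariant and symmetric
between dips and surges.

## NIRS calibration

The monitor interrogates a mixed vascular bed, ~30 % arterial / 70 % venous,
so the validation reference is `REF = 0.3·SaO2 + 0.7·ScvO2` from CO-oximetry
of simultaneously drawn arterial and central-venous blood at four FiO2
plateaus.  The calibration model is ordinary least squares of measured StO2
on REF with a shared slope and a stratum-specific intercept for meconium
presence (meconium is an optical chromophore; no functional form beyond an
offset is assumed).  Pearson r over all plateaus, and r², are the
diagnostics; the corrected reading is the inverse affine map clamped to
[0, 100] %.  Calibration is off by default in the main pipeline — the
screening analyses use raw monitor readings — and available behind a flag.

## ROC screening

Empirical ROC over all achievable confusion matrices, with candidate
thresholds at midpoints between consecutive distinct score values (plus the
two degenerate ends), so the chosen cutoff falls between the classes it
separates.  Orientation is part of the contract: StO2 is lower-is-positive
(`score < t` ⇒ NEC), I-FABP higher-is-positive.  The operating cutoff
maximizes Youden's J; ties prefer sensitivity (screening context), then the
smaller threshold magnitude.  AUC is the trapezoidal area (vertices sorted
by false-positive rate, ties by sensitivity), which equals the normalized
Mann-Whitney U.

The observation unit matters and is explicit: StO2 screening is epoch-level
over hours 0–48 (pre-feed, pre-symptomatic — the window in which screening
is useful), I-FABP draw-level over t ≥ 48 h; per-animal aggregation (mean
epoch value; peak draw) is available for both.  Animal-level sensitivity at
the printed granularity (e.g. 97 % with 21 positive animals) is not
reproducible from counts of 21, which is why the per-observation unit is the
default.  Note the draw-level I-FABP ROC is non-concave: early post-feed NEC
draws are below healthy levels, so global AUC understates the usefulness of
the upper-tail cutoff.

## Biomarkers and statistics

I-FABP summaries: per-group 6-h grid means/SEMs; pre-feed pooled mean
(t < 48 h); post-feed peak = mean over animals of each animal's maximum draw
at t ≥ 48 h.  Pooled NEC vs No-NEC means are over post-feed draws (pre-feed
levels carry no injury signal and would dilute the contrast); per-animal
pooling is a flag.  The necropsy correlation is Spearman's rho with mid-rank
ties between densitometry and NEC score.  The pre-mortem I-FABP dip
(final draw lower than the prior in some dying animals) is represented in
the generator but enters no statistic.

Group comparisons are normality-gated: Shapiro-Wilk per group at α = 0.05 on
analysis-unit values (per-animal statistics, never raw samples); all normal
⇒ parametric (one-way ANOVA, Tukey-HSD post-hoc when the global test
rejects with ≥ 3 groups; Welch t for two groups), otherwise rank-based
(Kruskal-Wallis; pairwise Mann-Whitney with Holm adjustment).  Repeated
time-gridded input is collapsed to per-animal means before gating.  The
post-hoc choice (Tukey) and the two-sample fallbacks are this package's
conventions.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions, and every downstream stage is validated against it.

**Vitals.**  Per group and channel, a piecewise-linear mean curve over
0–96 h, flat across the first hour so the baseline is exact by construction
(StO2 64.9 / 74.2 / 79.5 %; SpO2 53.1 / 77.5 / 89.4 %; HR 163 / 166 /
135 bpm for f-NEC / nf-NEC / No-NEC).  Each animal adds a whole-curve offset
drawn N(0, between-animal SD) — the "±" of the baseline table — plus AR(1)
noise on the 2-s grid (StO2: stationary SD 4 %, φ = 0.995 per 2 s, i.e.
slow vasomotor drift with ~17-min time constant).  StO2 additionally dips
after each feed by a group-scaled fraction of the pre-feed level, recovering
exponentially (τ = 5 min) over the 15-min post-feed window.

**Censoring.**  f-NEC: symptoms U(48.5, 54) h, death U(54, 66] h; nf-NEC:
symptoms U(66, 72) h, survival to 96 h with probability 5/14, otherwise
death 4–8 h after symptoms; No-NEC: none.  No vitals sample, feed or draw is
ever generated past death (draws may fall on the death time itself).

**Biomarkers.**  I-FABP mean level is flat at the group baseline (0.04 /
0.01 / 0.09 ng/mL), rises linearly from a group-specific onset after the
first feed toward a plateau, and the final draw of a dying animal is reduced
by 25 % (protein exhaustion / venous congestion just before death).
Multiplicative lognormal noise, mean-1 corrected so expectations follow the
kinetic curve, floored at zero.  SAA is identical across groups — low before
feeds, linear rise after — so the control analysis finds nothing, as it
should.  Necropsy: scores drawn from group-specific ordinal supports
(No-NEC {0,1}, nf-NEC {2..4}, f-NEC {4..6}); densitometry = 100 − 12·score +
Gaussian noise, floored at 0 AU.  The validation experiment draws per-FiO2
SaO2/ScvO2 plateaus (hypoxic step lowest) and a monitor response
`measured = ref + noise` by default.

**Calibration of free constants.**  Anchored values (baselines, event
windows, group sizes, FiO2 steps, composite weights, I-FABP pre-feed levels)
are fixed by the study design.  The remaining free constants were solved
once, at design time, so that the *expected* pipeline outputs equal the
cohort-level design values, and then frozen: post-baseline StO2 knot levels
(pooled epoch means 69 / 71.9 / 78.4 % under censoring, solved by exact
minute-level integration over the death distribution), feed-dip amplitudes
(0.318 NEC, 0.187 No-NEC, solved from the folded-normal expectation of the
window statistic with the exact AR(1) window-mean covariance, targets
10.1 % / 6.3 %), I-FABP rise rates/onsets (f-NEC peak mean 1.87 ng/mL;
nf-NEC reaching 3.03 ng/mL by 96 h with pooled post-feed NEC mean
0.66 ng/mL), the No-NEC assay spread (lognormal σ = 0.35, placing the
draw-level Youden cutoff at 0.25 ng/mL), densitometry noise SD 17.35 AU
(cohort Spearman rho −0.79) and plateau noise SD 12.38 % (R² ≈ 0.77).
Within-animal epoch-level variance is a modelling choice, not a measured
quantity, and is documented as such.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: motion/contact artifacts and probe
dropouts (coverage handling is exercised only synthetically), non-Gaussian
heavy-tailed monitor noise, circadian or treatment-related structure,
litter effects (litter ids are bookkeeping only), correlations between
channels within an animal, and any mechanistic physiology linking StO2,
feeds and I-FABP — group structure is imposed, not emergent.

## Numerical choices and edge cases

Epoch boundaries are half-open `[start, start + 1 min)`; a sample exactly at
a feed time belongs to the post-window epoch but receives no dip (the dip is
strictly post-feed).  Death boundaries: vitals and feeds strictly before
death, draws up to and including it, trajectory grid strictly after
(`death > t`).  CSV round-trips are exact: full-precision float formatting
on write and round-trip float parsing on read; missing events are empty
cells.  ROC thresholds at score midpoints; Youden ties break toward
sensitivity, then smaller magnitude.  Degenerate inputs raise typed errors
(single-class labels, zero-variance reference or correlate, < 3 plateaus
per stratum, slope 0 on inversion) rather than returning NaN.

## Problem sizes

Replicate-averaged results (scripts/acceptance.py, tests/test_acceptance.py)
use 20 replicate cohorts of 38 animals with full 2-s streams (~17 M samples
per cohort) and 50 replicate validation sets; the normality-gate null
calibration uses 2000 simulated three-group datasets.  These sizes keep each
replicate a few seconds on one CPU while leaving Monte-Carlo error well
inside the comparison bands.
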