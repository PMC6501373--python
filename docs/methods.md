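# Methods

## Study model

The package models a two-arm randomized crossover of SpO₂ alarm
strategies during automated FiO₂ control. Each subject is monitored on
a uniform 5-s grid for up to 6 days; the strategy alternates every
24 h, with the first-day strategy drawn from a balanced-block table of
size 4 (every complete block of four subjects contains two tight and
two loose first days, randomly ordered; a partial trailing block is a
prefix of one more balanced permutation). Outcomes are pooled per
subject over all analyzed days under each strategy — ratios of summed
numerators over summed denominators, hourly medians pooled across all
contributed hours — never the mean of per-day values, and the unit of
analysis is the within-subject difference (tight − loose). Days whose
recorded alarm settings differ from the assigned strategy are excluded
as protocol violations, and subjects with fewer than two analyzed days
or with no analyzed day under one strategy are excluded from pairing;
the accounting identity *assigned = analyzed + violations + not
completed + excluded-subject days* is asserted on every run.

## Alarm semantics

A strategy is (low threshold, high threshold, delay). A violation is a
valid sample strictly outside a threshold. The annunciator activates at
the sample at which the violation has persisted for the full delay,
counting each 5-s sample as 5 s of violation — so a run of exactly
`delay` seconds annunciates on its last sample and contributes a
one-sample audible residue. The alarm sounds until the first subsequent
valid in-range sample. One valid in-range sample resets the persistence
timer. Invalid samples pause the timer without resetting it (and do not
silence an active alarm); `invalid_resets=True` switches to the
stricter reset behaviour. These conventions follow common bedside
monitor behaviour; monitors differ in whether a sub-sample in-range
excursion merges re-alarms, and the one-sample reset used here is a
documented choice. Low and high alarms are tracked independently; all
intervals are half-open `[start, end)` in sample indices.

Two denominator conventions coexist deliberately: the alarm *rate*
divides by valid monitored hours (an alarm can only be counted when the
signal is valid), while the audible *fraction* divides by total
monitored time (the annunciator occupies wall-clock time regardless of
later dropouts). Exposure percentages use valid samples as denominator;
how dropout time should enter these denominators is not standardized,
and this choice is stated rather than hidden.

## Exposure definitions

SpO₂ is integer-valued (device resolution), so "> 98%" is exactly
SpO₂ ≥ 99 on the integer scale. Hyperoxemia requires supplemental
oxygen: FiO₂ > 0.21 with a ±0.005 tolerance absorbing the floating
representation of 21%. Normoxemia is SpO₂ 86–96%, or > 96% while on
room air. Prolonged episodes are maximal predicate runs strictly longer
than 1 min / 3 min; a dropout splits an episode by default
(`split_on_invalid=False` bridges gaps that contain only invalid
samples). Hour partitioning for the hourly medians anchors at the
series start, not clock midnight. Histograms use 1%-integer bins over
valid samples with FiO₂ > 0.21 and sum to 100% of that subset.

## Synthetic cohort

The generator emulates the statistical regime of intubated neonates in
the first week of life under closed-loop control; parameters, defaults
and rationale:

| parameter | default | rationale |
|---|---|---|
| target range | 88–95 % | prevailing unit preference for this population |
| noise | AR(1), stationary SD 1.2 %, lag-1 corr exp(−5 s/τ) | unimodal in-range histogram; τ couples the noise memory to the controller |
| controller time constant τ | 100 s | closed-loop pull-back on the minute scale |
| controller gain | 0.012 ΔFiO₂ per % SpO₂ error | FiO₂ excursions of ~0.1–0.2 during deep desaturations |
| desaturation rate | 8 /h | a few audible alarms per hour under the tight strategy |
| desaturation duration | log-normal, median 25 s, σ 0.5; 2% tail at median 120 s, σ 0.4; min 10 s | most events shorter than 1 min; roughly one minute-scale hypoxemic episode per day |
| desaturation depth | 2% below range + Exp(mean 2.5), capped 18 | mostly shallow dips; sub-percent % time < 80 with occasional deep events |
| hyperoxemic drifts | 0.3 /h, median 60 s, peak ∈ [97, 100] | rare by design under automated control |
| dropout | 2% of samples in ~30-s runs | probe artifacts |
| FiO₂ baseline | linear 0.33 → 0.25 over the study | weaning course |
| manual adjustments | Poisson, 2/day, ±0.02 steps | infrequent caregiver intervention |

SpO₂ is composed as `round(clip(midpoint + AR-noise, envelopes))`:
desaturation envelopes (15% fall, ≥ 70% plateau at the nadir, 15%
recovery) via `min()`, hyperoxemic envelopes via `max()`. Event
arrivals are Poisson; an arrival inside the previous event is deferred
to just after it with a two-sample gap, so every arrival yields one
distinct episode and the realized event count remains an unbiased
Poisson draw — pure superposition would merge overlaps and bias any
rate-recovery check low by roughly the occupancy fraction. Invalid
samples hold the last valid SpO₂ value but are excluded from all
computations; manual-adjustment flags step the FiO₂ baseline but do not
feed back into the SpO₂ process.

Every random stream is seeded from `(seed, subject_index)`, so a
subject's log is reproducible independent of cohort size or order.

**What the generator is not.** It reproduces statistical structure, not
physiology: no lung mechanics, no oxygen transport, no true titration
algorithm (the controller emulation is an explicit stand-in and is not
any commercial device's algorithm), no pulse-rate or signal-quality
alarms (the invalid-sample fraction is reported as a proxy). Passing
tests therefore demonstrate that the detection, metric and inference
machinery is correct on data with the assumed structure — not that any
particular clinical effect size would be observed in patients, and the
synthetic cohort is not calibrated to reproduce any specific cohort's
outcome magnitudes.

## Statistics

* **Wilcoxon signed-rank** (scipy-backed): zeros dropped by the classic
  convention (Pratt behind a flag); exact null distribution for n ≤ 25
  with tie-free |d|, otherwise normal approximation with continuity and
  tie correction; an all-zero difference vector returns p = 1 with a
  warning.
* **Test selection**: Shapiro–Wilk on the differences at α = 0.05
  chooses paired *t* vs Wilcoxon, making the conventional "as
  appropriate" rule explicit; degenerate inputs (n < 3, constant
  differences) fall back to the rank test. The choice is recorded per
  metric in the results.
* **Hodges–Lehmann CI**: the estimate is the median of the Walsh
  averages; the CI takes the (C+1)-th smallest/largest Walsh average
  with C the largest value whose signed-rank CDF at (1−level)/2 is not
  exceeded — exact CDF by the subset-sum recursion for n ≤ 25, normal
  approximation beyond. The interval is slightly conservative (achieved
  coverage ≈ 95.2% at n = 15) and degenerates to the full Walsh range
  when n is too small for the requested level.
* **Power**: Monte-Carlo draws of n within-subject percent changes from
  Normal(effect, SD²) with a vectorized two-sided paired *t* (Wilcoxon
  available, looped); the 75%-SD figure is interpreted as the SD of the
  within-subject percent change, the only reading under which a 50%
  reduction with 20 subjects yields power > 0.80. The noncentral-*t*
  closed form (noncentrality √n·effect/SD) is the analytic companion.
* Significance is two-sided p < 0.05 throughout; no multiplicity
  adjustment is applied (one primary effectiveness outcome, the rest
  descriptive).

## Numerical and testing choices

Test problem sizes are chosen to exercise each property at meaningful
scale while keeping the default suite fast: oracle equivalence against
a naive per-sample state machine on 1,000 random short series;
CI coverage on 1,000 simulated n = 15 datasets (binomial 3-SE bounds);
event-rate recovery on 102 simulated subject-days using a dedicated
configuration (quiet baseline, nadirs ≥ 6% below range) in which
signal-level detection at SpO₂ < 85 identifies every injected event, so
the comparison is against the nominal Poisson rate without confounding
by noise-induced runs. Monte-Carlo assertions use 3-SE tolerances with
fixed seeds.

## Known limitations

* Pooled episodes are detected day-by-day, so an episode spanning a
  midnight boundary is counted once per day it touches.
* The loose-strategy residual alarm rate in the clinic is dominated by
  signal-quality alarms, which are out of scope here; simulated loose
  rates are therefore near zero.
* The synthetic FiO₂ range (≈ 0.23–0.45 at defaults) covers the typical
  course but not extreme escalation.
* `percent_reduction` on published medians is display arithmetic; the
  inferential quantity is the Hodges–Lehmann difference of pooled
  per-subject values.
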