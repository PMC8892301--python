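# Methods

This note documents the definitions, the generative model behind the
synthetic cohort, the numerical conventions, and the design choices that
were genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Wear, quality and adherence definitions

An **epoch** is one 15-second device record (HR, RR, ST, activity class,
per-channel confidence, battery). An epoch is classified **worn** iff
HR > 25 beats/min and ST > 25 °C — both strict inequalities, reading the
thresholds as exceedances. Confidence acceptance is inclusive
(HR conf ≥ 85 %, RR conf ≥ 80 %): a value exactly at the manufacturer's
threshold is acceptable. These two conventions are deliberate and are
exercised by boundary tests.

Per calendar day (midnight-to-midnight, device-local; the protocol is
waking-hours wear with overnight charging, so days do not straddle
midnight):

* wear time = worn epochs × 15 s / 3600 (every record counts as a full
  epoch; partial epochs at session edges are not modelled);
* signal quality (per channel) = mean confidence over worn epochs;
* data quality (per channel) = 100 × (worn epochs with acceptable
  confidence) / (worn epochs);
* ST data quality = the same with "HR acceptable OR RR acceptable", hence
  always ≥ each channel's own data quality (the validity sets are supersets);
* vital-sign summaries = worn-epoch means; ambulatory % = ambulatory worn
  epochs / worn epochs.

On a day with zero worn epochs these quantities are undefined and reported
as NaN, never 0 — they are defined "when worn", and coding them as 0 would
bias pooled aggregates.

A day is **worn** when wear time ≥ a minimum-wear policy threshold
(inclusive). The default is 1 h — the loosest value of the protocol's stated
1–16 h range, since the originating analysis does not say which threshold
produced its adherence table — and the full sweep is exposed
(`days_worn_sweep`) as a sensitivity analysis. Weekly wear categories are
lower-inclusive 7-day bins with 35 days (= 5 full weeks) assigned to the
">5" bin so the six labels partition 0–42. **Missing-day occasions** count
maximal runs of non-worn days strictly between the first and last worn day;
never-worn tails are not occasions (stopping participation is one decision,
not one occasion per remaining day). This gap-counting reading is consistent
with reported medians of 2–3 occasions alongside ~32 days worn.

Participant-level qualities and vitals pool **epochs**, implemented as
wear-time-weighted means of daily values (daily wear time is proportional
to the worn-epoch count, so the weighted mean equals a flat pass over all
worn epochs — a test asserts this identity). The alternative, an unweighted
mean of daily values, would up-weight short days; epoch pooling weights days
by evidence.

**Battery-depletion attribution.** The flag "depleted during wear" is
operationalized as: the day's final record was worn and battery ≤ 1 %. A
non-worn day immediately after such a day is attributed to battery depletion
(a flat module that was not recharged); all other non-worn days are
non-wear. The originating analysis reports the event without a detection
rule; this rule makes it decidable from the data alone, and the generator's
truth table lets tests measure the attribution's agreement (≥ 99 % required
at default conditions).

## Synthetic cohort generator

Defaults are the emulated study conditions: 35 AECOPD + 49 Stable
participants, 42-day protocol, 15-s epochs, waking window 07:00–22:00.

Schedule: each day is missing entirely with a per-participant propensity
p_i ~ Beta(mean·k, (1−mean)·k), k = 3, with group means 0.24 (AECOPD) and
0.12 (Stable). The Beta propensity (rather than one homogeneous rate) is
what produces the heavy-tailed adherence distribution reported in practice
(mean ≈ 32 days but median ≈ 37) and the group gap in >5-week wear. On a
present day a single wear episode of N(12, 1) h (participant mean itself
N(12, 1.8) h across participants) is placed uniformly in the window;
non-wear is absence of records. An optional off-body mode appends
powered-but-doffed records (HR < 25, ST ≈ 22 °C) to exercise the wear
classifier; it is off by default.

Vitals: HR = participant baseline + 2·cos(2π(t−16 h)/24) + 15·[ambulatory]
+ N(0, 3) per epoch. Baselines are N(84, 10) between participants after
subtracting the analytic mean of the circadian and activity terms over the
wear window, so the expected worn-epoch HR equals `hr_mean` — this is what
lets a recovery test compare the pipeline's cohort mean HR against the
parameter within 3 Monte-Carlo SEs. RR and ST are analogous without a
circadian term (RR 20 ± 3 between / 1.5 within; ST 34.2 ± 0.9 / 0.3).
Ambulatory fraction is Beta-distributed per participant around group means
0.10 (AECOPD) / 0.135 (Stable).

Confidence: channel confidence = base (HR 92 %, RR 88 %) + regime-specific
linear BMI effect + participant offset N(0, 5) + epoch noise N(0, 8),
clipped to [0, 100]. In the Stable-like regime HR confidence rises with BMI
(+0.5 %/(kg/m²), better electrode contact); in the AECOPD-like regime RR
confidence falls with adiposity (−0.5 %/(kg/m²)). Only the sign/monotonicity
of these links is asserted anywhere; the linear-on-percent form is the
simplest that yields it. The participant-level offset is essential: without
it, averaging ~10⁵ epochs would drive the BMI–quality Spearman ρ to ±1,
which no real cohort shows. The bases were chosen so data-quality medians
land in the low-to-mid 80s (Φ((92−85)/8) ≈ 0.81, Φ((88−80)/8) ≈ 0.84).

Battery: 100 % at donning, linear 6 %/h drain (≈ 28 % left after 12 h). With
probability 0.0015/day the module starts part-charged and dies mid-wear;
the stream truncates with the final epoch at ≤ 1 % battery and the next day
is missing (flat, not recharged).

Metadata: BMI N(25.2, 6.0) / N(28.0, 6.7) per group; chest and waist
circumference are linear in BMI plus noise (so the waist–quality correlation
emerges through BMI); MRC grades follow the reported group frequencies.

What the generator does **not** emulate: within-day wear breaks (one episode
per day), autocorrelated or non-Gaussian epoch noise, activity-dependent
confidence artefacts, seasonal or day-of-week structure, and withdrawal
(every simulated participant contributes data). Passing recovery tests
therefore show the pipeline is correct and well-calibrated under this
skeleton, not that the device or cohort behaves this way.

## Statistics

* **Fisher exact (authored here):** two-sided by probability ordering — the
  sum of hypergeometric probabilities of all tables with the observed
  margins no more probable than the observed table. Log-gamma arithmetic;
  ties in probability are included using a 1e−7 relative guard; any zero
  margin gives p = 1 by convention. Verified in tests against an
  exact-rational enumeration oracle and against an independent
  implementation, exhaustively for all tables with total ≤ 40.
* **Welch t** (unequal variances, Welch–Satterthwaite df) is used wherever a
  two-sample t test is routed — the safer default when group variances are
  not known to be equal.
* **Mann–Whitney U:** midranks; exact enumeration when the pooled n ≤ 12
  with no ties, else normal approximation with tie and continuity
  corrections.
* **Routing:** categorical → Fisher; continuous → Shapiro–Wilk per group at
  α = 0.05, both normal → Welch t with mean (SD) summaries, otherwise
  Mann–Whitney with median (IQR); groups with n < 3 fall back to
  Mann–Whitney. Ordinal rows (MRC grade, weekly wear categories) are
  compared bin-vs-rest with Fisher. Null-calibration tests check the routed
  procedure's type-I error at the study's group sizes.
* **Quantiles** by linear interpolation between order statistics (the
  numpy default), stated so medians/IQRs are reproducible.
* **Spearman ρ:** Pearson on midranks, p from the t approximation with
  n − 2 df; a constant vector has undefined ρ (NaN), not 0.
* **p formatting:** "<.001" below .001, ">.99" above .99; three decimals
  below .01 or when two-decimal rounding is borderline (third digit 4–5),
  else two, without a leading zero. Published tables mix 2- and 3-decimal
  precision inconsistently (".04" vs ".045"), so a single deterministic rule
  was adopted; numeric comparisons in tests use rounded values, not strings.
* **No multiple-testing adjustment** — one unadjusted p per row, as is
  conventional for feasibility tables; the report footer says so.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; per-participant streams
use seeds spawned from the master seed, so cohorts are byte-reproducible and
any participant can be regenerated alone. The test suite runs one
default-condition cohort (84 participants × 42 days ≈ 8.4 M epochs, shared
session fixture) for the invariant and recovery checks; the
slope-sign-recovery test uses 100 replicate cohorts at 3 protocol days,
since participant-level signal quality is dominated by the participant
confidence offset rather than the epoch count. The exhaustive Fisher
equivalence check covers all ~1.3 × 10⁵ tables with total ≤ 40; run/gap
operators are checked against brute-force scans on 10 000 random vectors.

## Known limitations

* Calendar-day boundaries assume no overnight wear; a cohort instructed to
  wear the device while sleeping would need day re-anchoring.
* Battery-depletion attribution can only flag the day *after* a mid-wear
  depletion; a participant who both depleted and independently chose not to
  wear the next day is indistinguishable from the depletion case.
* The epoch CSV dialect is an artifact convention; native device export
  formats are not parsed.
* Confidence values are consumed as given; the proprietary confidence
  algorithm is not modelled.
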