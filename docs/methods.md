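# Methods

This note records the statistical machinery the package implements, the
choices made where the design was genuinely open, and what the synthetic
observer does and does not emulate.

## Trial classification and measures

The primary allocation maps each (stimulus, something?, arrow?) pattern
to an SDT class.  Seven patterns are defined: arrow with yes/yes (hit) or
no/no (miss); non-arrow with yes/yes (false alarm) or yes/no (correct
rejection — observers treated the task as arrow detection, so
acknowledging a non-arrow as "something but not the arrow" is a correct
rejection); absent with yes/yes or yes/no (false alarms) or no/no
(correct rejection).  Two patterns are *not* defined: arrow with yes/no,
and non-arrow with no/no.  We take the allocation literally and leave
them unclassified (`strict_table1=True`); the permissive completion
(miss/correct rejection respectively) is available as a sensitivity
switch.  The pattern "arrow yes, something no" is logically inconsistent
with the question hierarchy; it is classified `ILLOGICAL` under every
scheme, excluded from every measure denominator, and feeds only the
illogical-rate exclusion rule.

Single-question schemes: the arrow-question scheme scores arrow trials as
signal against the arrow response with absent trials supplying false
alarms (non-arrow trials carry no truth value and are unclassified); the
something-question scheme scores arrow and non-arrow trials as signal
against the something response.  These are reconstructions of a
supplementary definition and are flagged as such.

Hit and false-alarm rates are raw ratios.  No correction constants are
added anywhere: the non-parametric measures Pr = H − F and
Br = F/(1 − Pr) are finite for all attainable rates except Pr = 1, which
is reported as undefined rather than patched.  The parametric d′ and c
are provided only for the concordance comparison and clamp extreme rates
to [1/(2N), 1 − 1/(2N)] per cell.

PcU is the proportion of correct left/right responses among arrow trials
denied on both questions; PCm is the count of double-acknowledged,
direction-wrong arrow trials over all arrow trials.  Both carry their
denominator as `n` and an undefined flag when it is empty.  PCm's
numerator and denominator are injectable predicates so alternative
variants can be scored; the default is the primary definition.

## Contrasts and frequentist tests

All deltas are active − sham within participant, time and measure.  The
temporal contrast is early-minus-late:
mean(Δ@30, Δ@70) − mean(Δ@150, Δ@190).  When a member cell is undefined
the participant's phase mean uses the defined members (strict dropping is
a switch); a participant with an entirely undefined phase is dropped and
logged.  Fine-grained single-time contrasts (default 30 vs 190 ms) are
gated on the primary contrast showing p < 0.05 or BF ≥ 3 or ≤ 1/3,
mirroring the pre-registered decision rule.

t-tests are classical one-sample tests (two-sided p, 95% CI); the paired
test is implemented, and asserted, as the one-sample test of the
differences.  Cohen's d is mean/SD of the analysis vector.  A
zero-variance vector yields an infinite t and is flagged degenerate
rather than erroring.  Within-subject condition SEs use subject-centering
across the k = 10 mode × time cells with the √(k/(k−1)) bias correction.

## Bayes factors

Likelihood: the observed mean difference is modelled as a shifted, scaled
t density (SE and df of the vector), honouring small-sample uncertainty;
a normal likelihood is a config switch because the originating
calculator lineage admits either.  Priors on the population mean:

- **Half-normal from zero** (`BF_main`): SD = |orthogonal active-vs-sham
  mean difference| / 2.  The verbal rule "variance equal to half the mean
  difference" cannot hold literally (a variance cannot equal a signed
  difference); the SD convention is the default and variance = |diff|/2
  is a sensitivity option.  A zero orthogonal contrast makes the prior
  degenerate and the BF undefined (logged, never silently patched).
  Both prior directions are always evaluated; "early > late" (stronger
  early suppression) corresponds to the negative direction of the
  early-minus-late vector.  The negative-direction engine reflects the
  data, making direction anti-symmetry exact.
- **Uniform** (`BF_uni`): PrC uses width 0.5 (threshold 0.5 down to 0);
  PcU uses chance-to-peak, where the peak is the maximum group-mean PcU
  over the ten mode × time cells after PcU-scope exclusions.  Other
  measures have no principled range and report no uniform BF.
- **JZS** (`BF_jzs`): one-sample Cauchy(0, 0.707) prior on standardized
  effect size, computed as the noncentral-t marginal; cross-checked in
  the tests against an independent g-integral implementation and a
  brute-force Riemann oracle.

Quadrature is adaptive with relative tolerance 1e-6 and an integration
limit of 10 prior SDs; results are asserted invariant to doubling the
limit.  The sequential stopping rule stops at the first BF ≥ 3
(support) or ≤ 1/3 (null), both inclusive; its operating characteristics
under the null and under a modest effect are simulated by
`analysis/04_optional_stopping.py` and reported, not assumed.

## Exclusion rules and scopes

Order of application: blink filter (trial level) → participant screens
(same-button ≥ 75% of unseen trials, inclusive; all detection responses
negative under a condition; illogical rate strictly > 2.5%) → the PcU
chance rule → per-vector Chauvenet.  The chance rule tests pooled sham
PcU with z = (PcU − 0.5)/√(0.25/n) (null binomial SD — the rule names
only a cumulative normal, so the null SD is a documented assumption) and
retains only one-tailed p < 0.05; it removes the participant from PcU
analyses *only*.  Chauvenet fits a normal to the full analysis vector
(sample mean and SD, candidate point included, single pass) and excludes
points whose two-tailed exceedance probability times n falls below 0.5;
the density-based reading of "likelihood" is a config switch.  Chauvenet
exclusions remove a point from one vector only.

Caveat recorded here deliberately: classical Chauvenet is subject to
masking — adding a far larger outlier inflates the fitted SD and can
un-flag a previously flagged point — so the decision set is not monotone
under vector extension.  The tests assert the properties that do hold:
affine invariance and scale invariance of the single-outlier case.

## The synthetic observer

One evidence channel e ~ N(μ, 1) drives both detection questions through
two ordered criteria (something at c_s, arrow at c_a ≥ c_s, which makes
illogical patterns impossible without lapses); an independent channel
with sensitivity d_dir drives left/right, correct with probability
Φ(d_dir/√2).  Lapses flip each response independently (rate ≤ 5%,
default ≤ 1%) and are the sole source of illogical responses.  Active
TMS adds per-timing offsets: d_signal ≤ 0 on the evidence mean of
stimulus-present trials only (pure noise cannot be suppressed; effective
strength is floored at 0), d_criteria on both criteria, and
d_direction ≤ 0 on the direction channel.

Per-participant signal strength is not drawn — it is *calibrated* by
bisection on the closed-form psychometric function to sham PrC = 0.5,
exactly as the task calibrated stimulus luminance.  Defaults encode the
study conditions: sham PrC ≈ 0.5; wide individual spread in direction
sensitivity (base 0.91, SD 0.5) so 'unseen' capacity is ≈ 0.65 under the
110 ms pulse and the chance rule excludes a realistic minority of
observers; the 110 ms pulse suppresses PrC by ≈ 0.08 and PcU by ≈ 0.09;
early pulses add sensitivity suppression (early-vs-late PrC ≈ −0.06,
PcU ≈ −0.03); late pulses relax the criteria.  TMS effects scale per
participant by a factor ~ N(1, 0.4) truncated at 0.  One modelling
limitation is worth noting: because Br couples to sensitivity (early
suppression of non-arrow evidence removes false alarms), the synthetic
BrC early-vs-late contrast is several times larger than the study's,
with the correct late-dominant sign; the generator reproduces the sign
pattern, not the BrC magnitude.  Additive direction suppression can also
saturate at d = 0 for strongly affected observers, which attenuates mean
contrasts relative to the no-floor arithmetic — the defaults were chosen
against simulated (not just analytic) deltas for this reason.

What the generator does *not* emulate: phosphenes, reaction times,
luminance/pixel structure, sequential or learning effects, criterion
drift within sessions, and any dependence of the direction channel on
the awareness channel (the independence is a deliberate minimal
structure that realizes above-chance unseen discrimination, not a claim
about mechanism).  Passing recovery tests therefore show that the
pipeline detects the sign pattern it targets in data with this factorial
shape and noise level — not that real cortex behaves like the model.

## Problem sizes

The default analyses use a 50-participant synthetic cohort (96,000
trials, the study's scale).  The parameter-recovery study uses cohorts
of n = 40 with 100 cohorts per arm in the test suite and 60 per arm in
the acceptance script — enough for recovery-rate SEs of a few percent
while keeping runtimes to minutes.  Bayes-factor engines are validated
on a 104-point grid against dense-grid integration.
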