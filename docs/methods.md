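# Methods

This note documents the models implemented in `tymbal`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## The duty-cycle statistic

A click event is an (onset, duration) pair. For a window `[t, t + W)` with
`W = 100 ms` (configurable), the members are the clicks whose **onset** falls
in the window; the duty cycle is

    DC(t) = mean(member durations, clipped at t + W) × count / W × 100.

Clipping durations at the window end makes the statistic well defined for
long events (a continuous noise burst scores exactly 100) and bounds DC at
100 for any non-overlapping click set. Because membership is by onset, the
identity DC = Σ durations / W × 100 holds exactly; this algebraic identity is
property-tested. The value reported for an individual comes from the window
with the **maximum click count** (not maximum DC), earliest window on ties,
taken across all of the individual's recordings — so a window of many short
clicks can beat a window of fewer, longer ones, and a test pins that
behavior. The window grid steps by 1 ms by default (configurable down to one
sample); exact time-shift invariance of the score holds for shifts on the
step grid, while sub-step shifts can change edge clipping by at most one
click's worth.

## Click synthesis

Clicks are damped sinusoids with a linear frequency ramp (active half-cycle
90→45 kHz, passive 45→90 kHz; qualitative values, exposed as config) under a
raised-cosine on/off taper. The taper is zero at the *continuous* segment
boundaries and the waveform is sampled at bin centers, so edge samples carry
small nonzero energy; with literal zero edge samples ~8 µs of every click is
invisible to any threshold detector, which at 150 clicks per window biases
the scored duty cycle by −1.2 points — more than the ±1-point synthesis
contract. Defaults: duration 0.3 ms, damping 1500 /s, taper fraction 0.04,
amplitude 0.8 of full scale with ±8% per-click jitter (seeded). Only click
timing and duration are load-bearing for the statistics; the waveshape is a
conventional transient model, not a biomechanical one.

A modulation cycle (MC) template holds an 8 ms active half, 8 ms passive
half, and 4 ms silent interval (20 ms period, five MCs per 100 ms window).
The half durations are not published for these species; 8 + 8 + 4 ms was
chosen so that a 45% target (150 clicks per window → 30 clicks/MC at 0.3 ms)
fits without click overlap, with headroom to ~78%. Clicks split evenly
between halves (odd remainder to the active half) and are uniformly spaced
within each half.

Synthesized click trains ramp up in per-MC click count to a plateau that
realizes the male's target maximum duty cycle over the final analysis
window, emulating the rise of a tactile-evoked tymbal response and making
"maximum window" a meaningful selection. Per-male targets are drawn from
truncated normal distributions: *B. trigona* N(41, 13²) on [21, 67]
(published mean ± SD and observed range), *C. arizonensis* N(30, 11²) on
[11, 49] (published mean ± SD and maximum; the lower bound is not published
and is set symmetric about the mean, which leaves the truncated mean at 30).

## Click detection

The envelope is the rectified signal under a centered boxcar (20 µs default):
long enough to bridge the ultrasonic carrier's zero crossings, and — unlike
an analytic-signal (Hilbert) envelope, whose kernel tails decay only
hyperbolically and smear a 0.3 ms click to ~0.8 ms at low thresholds — it
falls to zero within half a window of a click edge. Events are seeded where
the envelope exceeds `threshold_factor` (default 5) times the noise floor,
estimated as 1.4826 × a low envelope quantile (default 0.10), floored at an
absolute minimum (10⁻³ of full scale) so digitally silent input cannot
produce a zero threshold. A low quantile rather than the median keeps the
estimate on the silent portion of the recording even when sound occupies
most of it, as it does near 70% duty cycle. Event boundaries are then
extended to a lower hysteresis threshold (0.2 × threshold), refined by
linear subsample interpolation, and corrected for the boxcar's known
half-window widening. Events closer than 20 µs merge; events shorter than
0.1 ms are dropped. An optional high-pass filter (off by default; the
synthesis has no low-frequency noise) supports field recordings.

On synthetic ground truth this detector recovers every click (count exact,
onsets within 0.1 ms) and the scored duty cycle agrees with scoring the
ground-truth schedule directly within ±0.7 points across targets 5–70%.

## Playback stimuli

Five categories: silence, 10%, 25%, 45% duty cycle, and band-limited white
noise (10–100 kHz, flat spectrum, seeded; band edges are conventions, not
published values). Emissions last 600 ms followed by 2.4 s of silence; a
session presents each category at least twice in a seeded uniform shuffle.
Stimulus duty cycle is defined over the 100 ms analysis window: the window's
click budget (e.g. 33 clicks for 10%) is spread as evenly as possible over
the five MCs per window, rather than rounding a per-MC count, which would
quantize the realized duty cycle in 1.5-point steps. The last partial MC of
an emission is truncated. Absolute level (80 dB peSPL at 20 cm) is hardware
metadata; digitally the peak sample maps to −6 dBFS by default, with the
field calibration carried as a config constant.

## Behavioral generator

Playback trials: each presentation responds with a per-category Bernoulli
probability; responders draw an exponential latency at hazard
`baseline_hazard × rate_ratio(category)` truncated to the 3.0 s horizon
(emission + silent interval), non-responders are censored at the horizon.
Defaults: response probabilities 0.05 / 0.15 / 0.35 / 0.67 / 0.68 for
silence / 10% / 25% / 45% / white noise — the last two are the published
response fractions, the first three are placeholders consistent with females
responding less often to low duty cycles; rate ratios 0.16 / 0.51 / 1 / 2.1
for 10% / 25% / 45% / white noise (0.16 and 2.1 published; 0.51 is one
consistent reading of the published 45-vs-25 contrast, configurable);
baseline hazard 2.0 /s, consistent with responders acting well under a
second.

This Bernoulli-plus-truncated-exponential mixture reproduces the observed
*marginals* but is a cure-rate model: across categories with different
response probabilities the hazards are **not** proportional, so a Cox fit on
these trials estimates an attenuated ratio (e.g. ~1.2 for white noise at any
sample size, not the generating 2.1). The pipeline's preference study
reports that fit as-is — matching what the analysis of such an experiment
would see. Parameter *recovery* of the rate ratios is demonstrated through
`simulate_latencies`, the standard censoring model (exponential time, event
iff before the horizon), under which the Cox estimator is consistent; tests
verify |bias| < 0.05 on the log scale at 1000 events/group and ≥90% CI
coverage at 500/group. Mate choice is multinomial: with probability
`p_any_mating` (0.28 for *B. trigona*, 7/25 observed; 1.0 for
*C. arizonensis*, 8/8) a male is chosen proportional to condition weights
(defaults S++ 5 : S+ 2 : S− 0, consistent with the observed 5/2/0 outcome;
equal weights for the two *C. arizonensis* conditions).

What passing tests do *not* show about real data: no background noise,
reverberation, or amplitude variation with distance; no per-female random
effects or response-probability heterogeneity; latencies are exponential by
construction; and the MC template is a stand-in, not a measured exemplar.

## Statistical analyses

* **Response GLM** — fixed-effects logistic regression on category
  indicators fitted by IRLS (convergence when the max coefficient change
  < 10⁻⁸, cap 50 iterations). The model is saturated, so fitted
  probabilities equal observed proportions (closed-form check, and verified
  against an independent GLM implementation). Categories with a single
  outcome are flagged as complete separation. The original analysis names a
  mixed model but fits a plain `glm` with no stated random-effect structure;
  a fixed-effects model is implemented and the discrepancy documented here.
* **Post hoc contrasts** — all-pairs Wald z tests on coefficient
  differences, Bonferroni-adjusted, capped at 1. Tukey's studentized-range
  test is not well defined for a GLM from the available description;
  Bonferroni is the conservative adjustment the original analysis states it
  used where P-values were adjusted.
* **Cox model** — Newton iterations on the Breslow partial likelihood
  (ties are measure-zero under the exponential generator), censored records
  in risk sets only, 95% CIs `exp(β ± 1.96 SE)`, reference 45% duty cycle.
  Coefficients diverging past |β| > 15 flag monotone likelihood. Verified
  against independent implementations, including on heavily tied data.
* **Exact tests** — Fisher 2×2 and Freeman–Halton 2×3 by complete
  enumeration of same-margin tables in exact integer arithmetic
  (p = Σ probabilities ≤ observed, with 10⁻⁷ relative slack against float
  ties, applied as an integer inequality so arbitrarily large counts cannot
  overflow). The 2×3 enumeration is capped at 10⁷ tables.
* **Variance comparison** — z on the variance difference with
  Var(s²) ≈ 2s⁴/(n−1), two-sided normal p, Wald CI. The originally reported
  z/CI pair cannot be attributed to a specific formulation or units, so this
  implementation documents its own and makes no claim of reproducing that
  CI.

## Problem sizes and determinism

Default study sizes mirror the field design: 30 + 12 males (0.4 s recordings
— long enough for a ramp plus a full analysis window at the 20 ms MC
period), 54 females × 10 presentations, 25 + 8 choice trials. Recovery tests
scale up only where the claim is asymptotic (500–1000 events/group for Cox,
10⁴ trials for choice proportions). Every stochastic step takes an explicit
integer seed; pipeline stages spawn sub-seeds from the run seed, and a run
is bit-reproducible from (config, seed).

## Known limitations

* The detector is validated against synthetic ground truth only; equivalence
  to the commercial detector used on the original recordings cannot be
  established (its parameters are unpublished).
* Duty cycles above ~78% cannot be synthesized with the default MC template
  (clicks would overlap), and above ~70% inter-click gaps approach the
  envelope smoother length.
* The preference analysis has no per-female random effect; with repeated
  presentations per female the simulated trials are independent, which real
  trials are not.
* The 2×2 tables behind the original pairwise mate-choice p-values are not
  reconstructible from the published description; the implementation reports
  p for whatever table it is given.
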