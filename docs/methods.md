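# Methods

## Task model

A dual 2-back block is two simultaneous 145-trial stimulus streams with
a common 3.330 s trial window: 9 grid positions (visuospatial) and 11
spoken digits (auditory-verbal). Trial *i* is a **target** when its
stimulus equals the stimulus at trial *i − 2*; a **lure** when it is not
a target but repeats the stimulus at lag 1 or lag 3, the standard n±1
lure construction. The design fixes at most 40 targets per block and
modality and a lure fraction of 0.2 of all trials; we read that fraction
as lures / n_trials, so a 145-trial block carries exactly
`round(0.2 × 145) = 29` lures (the alternative reading, a fraction of
non-targets, is obtained by passing a rescaled `lure_rate`).

### Sequence construction

Target positions are drawn uniformly without replacement from the
eligible indices (≥ 2), lure positions uniformly from the remaining
indices (≥ 1). The stream is then built left to right: a target copies
the stimulus two trials back; a lure copies lag 1 or lag 3 (random
order), skipping a lag that would silently create a target; a filler is
drawn uniformly from the alphabet minus the values at lags 1, 2 and 3 —
sampling directly from the explicitly computed allowed set, which is
distributionally identical to rejection sampling but cannot stall. At
alphabet sizes 9 and 11 the allowed set is never empty; a forced-lure
collision (both lags equal to the 2-back value) is possible but rare, in
which case the whole construction retries (≤ 100) before raising a
constraint-infeasibility error naming the failing trial index. With an
alphabet of 3 and all repeats forbidden the fourth trial is provably
infeasible, which the error path tests exploit. Re-annotating the
emitted stimuli reproduces the generator's flags exactly; this
generator/annotator agreement is asserted over 1,000 seeds.

The two modalities come from distinct substreams of one seed, so their
target placements are independent and may coincide, as in the original
task software.

## Synthetic cohort

The simulator stands in for a 31-subject crossover in which each subject
receives all five sound conditions (silence, 240 Hz pure tone, 10/16/40
Hz binaural beats) in an independently randomized order, one condition
per time block. No trial-level data from the original study are
available, so the generator's defaults are calibration choices fixed
once against the published group descriptive statistics and not
treated as estimates of any participant's true parameters.

**Response model.** Responding is Bernoulli with log-odds additive in:
a per-subject baseline (hit and false-alarm logits drawn from normals),
a per-block training slope, a half-block fatigue contrast, a lure odds
multiplier (false alarms only), and a per-condition shift. A logistic
model was chosen over an evidence-accumulation model because the scoring
stage consumes only response flags and latencies, and additivity makes
every configured effect analytically checkable (e.g. a negative hit
fatigue slope yields a negative expected delta hit rate by
monotonicity). Fatigue enters as a half-block indicator rather than a
continuous trend so the configured effect *is* the second-minus-first
half contrast the scoring stage measures.

**Latencies.** Lognormal, truncated at the 3.330 s trial window:
`rt = min(3.330, exp(N(μ, σ²)))` with μ additive in subject location,
per-block training, a half-block shift, condition, and the covariates
age (+0.006 log-s per year above 30.84) and standardized sound volume
(−0.02 log-s per SD) — signs matching the reported positive age and
negative volume associations.

**Defaults** (population means; logit or log scale):

| quantity | visuospatial | auditory-verbal | rationale |
|---|---|---|---|
| hit logit | 1.59 (≈0.83) | 2.04 (≈0.89) | published group H means |
| FA logit | −3.00 | −2.50 | marginal FA ≈ 0.06 / 0.11 *after* Jensen inflation from the 0.8 logit SD and the ×2 lure odds on 29/105 non-targets |
| lure odds multiplier | ×2 (lognormal) | same | lures invite false alarms |
| training slope (hit) | +0.10 / block | same | gradual improvement over blocks |
| fatigue (hit) | −0.35 | −0.10 | negative visuospatial, near-zero verbal hit deltas |
| fatigue (FA) | −0.15 | +0.20 | opposite-signed FA deltas by modality |
| rt location | 0.33 (≈1.47 s) | 0.40 (≈1.56 s) | group RT means; verbal slower |
| rt scale σ | 0.33 | 0.295 | within-block RT SD ≈ 0.50 / 0.46 s |
| rt half shift | −0.034 | −0.020 | responses speed up within a block |

Age is truncated-normal 30.84 ± 6.16 on [19, 42]; sex Bernoulli with
17:14 female:male odds; volume a per-subject standardized constant, as
in a design where loudness is set once per participant. Condition
shifts default to zero except three directional effects (lower verbal
hits under the 10 Hz beat, more verbal false alarms under the pure tone,
faster visuospatial responding under the 10 Hz beat), encoding the
reported direction of the cohort-level findings; their magnitudes are
illustrative, not estimates.

**What the simulator does not model:** feedback-driven within-block
adaptation, response-window spillover or duplicate keypresses,
evidence-accumulation dynamics (so RT–accuracy coupling arises only
through shared subject-level parameters), EEG or mood channels, and
carry-over between blocks beyond the training trend. Passing tests
therefore validate the pipeline's arithmetic and the recovery of
*configured* effects, not any claim about real binaural-beat effects.

## Scoring conventions

* Half-block split by trial index: first half = trials 1–72, the odd
  trial goes to the second half (trials have fixed duration, so index
  and wall-clock splits coincide up to that one trial).
* Latency summaries pool all responded trials (hits and false alarms) by
  default; `rt_pool="hits_only"` restricts to hits. The SD uses n−1.
* *A*′ and *B*″ use the standard mirrored piecewise formulas for H < F;
  no loglinear or 1/(2N) correction is applied to extreme rates —
  *B*″ cells with H, F ∈ {0, 1} are reported missing, which matches the
  reduced cell sizes seen in published tables of this design.
* WM = 2(H − F) is linear, so group-mean WM equals 2(mean H − mean F)
  exactly; the test suite asserts both this identity and its *failure*
  for the nonlinear *A*′.
* Ranks across the five conditions are midranks; rank 1 = smallest by
  default (the Friedman test is invariant to the direction; only table
  cosmetics change).

## Inference

* One-sample *t* on deltas: `t = mean / (sd/√n)`, df = n−1, two-sided;
  summary-statistic and raw-vector forms agree by construction. A
  degenerate sd = 0 sample reports p = 0 (mean ≠ 0) or p = 1.
* Pearson: `t = r√((n−2)/(1−r²))`, df = n−2.
* Friedman: within-row midranks, chi-square with the standard tie
  correction, df = k−1; fully tied data report χ² = 0, p = 1. Verified
  against both `scipy.stats.friedmanchisquare` and a brute-force
  re-derivation.
* Bonferroni post hocs: pairwise paired *t* on within-subject
  differences with `p_adj = min(1, m·p_raw)`, m = k(k−1)/2 — the
  pairwise-error-term variant, chosen over a pooled error term and
  documented as such.
* Repeated-measures ANOVA (pingouin backend): Mauchly's W is reported;
  when sphericity is rejected at 0.05 the F degrees of freedom are
  multiplied by the Greenhouse–Geisser ε̂ computed from the sample
  covariance of the repeated measures (ε̂ clamped to [1/(k−1), 1]). At
  k = 2 sphericity is vacuous, ε̂ = 1 and F = t² of the paired test.
* Covariate adjustment and unbalanced layouts route to the
  random-intercept mixed model with a logged note: between-subject
  covariates are collinear with fixed subject effects in the classical
  within-subject sum-of-squares decomposition, so the mixed model is the
  estimable analogue. Covariates are mean-centred.
* Mixed model (statsmodels MixedLM, REML): fixed effects condition,
  modality, their interaction, sex, age, volume, with treatment coding
  against the silence and visuospatial references; Wald χ² per term;
  factors collapsed to one level are dropped from the formula;
  non-convergence is flagged in the result, never silently discarded.
* All tests two-sided at α = 0.05. P values print with three decimals
  and as "<0.0005" below that threshold. The "manually optimized" model
  search of typical reports is irreproducible; one canonical model per
  analysis is fixed instead, with term selection exposed in config.

## Problem sizes and numerical choices

The test suite runs the full default cohort (31 × 5 × 2 × 145 = 44,950
rows per modality) once for the structural checks; distributional checks
use 500 simulated blocks (parameter recovery, dual-modality target
independence at block-level Monte-Carlo SEs) and 10,000 null delta
vectors (type-I error at 0.05 ± 0.006), sizes chosen so 3-SE bands are
decisive while the suite stays fast. Reported rates and indices round to
3 decimals; CIs are two-sided t-based 95% intervals (the CI convention
of the published tables is unstated; the t-based form reproduces their
printed bounds at 2 decimals).

## Known limitations

Calibration magnitudes are choices, not estimates; condition effects
are directional illustrations; the simulator's independence assumptions
(trials conditionally independent given the profile) understate serial
autocorrelation in real responding; and the rm-ANCOVA is deliberately a
mixed model rather than a classical SS decomposition (see above), so its
p values will differ slightly from legacy ANCOVA software on the same
data.
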