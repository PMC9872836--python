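# Methods

## Generative model

Each simulated trial is a two-boundary Wiener diffusion with unbiased start
point `a/2`, drift `v`, noise scale `s = 0.1` (the conventional scaling,
consistent with drift magnitudes ≈ 0.1, boundaries ≈ 0.07–0.08 and
non-decision times ≈ 0.2–0.35 s), and absorbing boundaries at `0` (error)
and `a` (correct). The response time is the first-passage time plus the
non-decision time `T_er`; decisions that would land beyond the 1.5 s
response window are censored as non-responses.

The observer's parameters encode two distinct generative claims:

- **Drift is additive in the cue components and linear in gap size**:
  `v = (v_base + space_valid·dv_space + feature_valid·dv_feature) ·
  gap/gap_ref`. There is deliberately no interaction term, so
  `v(SvFv) − v(SvFi) = v(SiFv) − v(SiFi)` exactly.
- **Boundary separation and non-decision time are properties of the whole
  cue object**, looked up per SvFv/SvFi/SiFv/SiFi, independent of the gap.

### Default parameter values

Defaults reproduce the Experiment-1 (70/10/10/10) pattern of group means:

- `dv_space = dv_feature = 0.043`, `v_base = 0.0655`, chosen so the
  unweighted valid/invalid marginals of the four cells are 0.13 and 0.087
  on both dimensions at the reference gap.
- `gap_ref_deg = 0.12`, the stable titrated gap size in that design, so the
  nominal drifts are the drifts actually in play near staircase equilibrium.
- `a_by_object = {SvFv 0.0833, SvFi 0.0713, SiFv 0.0763, SiFi 0.0703}`,
  whose four marginals round to 0.080/0.071 (feature) and 0.077/0.073
  (space), with the wholly valid cue most conservative.
- `ter_by_object = {SvFv 0.21, SvFi 0.25, SiFv 0.25, SiFi 0.27}` s. The
  four target marginals (0.24/0.27 feature, 0.22/0.25 space) are mutually
  inconsistent as marginals of a single 2×2 table (the two pairs sum to
  0.51 and 0.47, which must be equal), so no cell assignment can reproduce
  all of them; this least-squares compromise preserves both 0.03 s validity
  differences exactly, hits each marginal within 0.01 s, and keeps the
  wholly-valid cue fastest.
- Contamination: `gaze_loss_rate = 0.15` (reported gaze exclusions run
  ≈ 11–16% of trials), `nonresponse_rate = 0.0075`, and a
  `guess_rate = 0.02` admixture of uniform-RT coin-flip guesses standing in
  for attentional lapses. Gaze flags are independent Bernoulli marks: no
  gaze trajectories are modelled, so gaze exclusion in the pipeline is
  unbiased by construction, which real fixation breaks need not be.

## Schedules and titration

Cue-object counts are stratified exactly (probability × 560 trials must be
an integer; rejected otherwise), gap sides balanced 50/50 within cue
object, delays drawn uniformly from {500, 1000, 1500} ms, order shuffled by
the session seed. Sessions are 7 blocks × 80 trials; block 0 is generated
from the same distribution and dropped at preprocessing, like the human
practice block.

The staircase evaluates pooled accuracy every 15 trials over the most
recent 15 trials (a trailing, non-overlapping window — whether the original
procedure was trailing or cumulative is not documented; trailing reacts
faster and is the conventional reading of "evaluated every 15 trials").
Non-responses count as incorrect. Accuracy above 0.70 multiplies the gap by
0.8; below 0.60 by 1.2; band edges inclusive leave it unchanged; the gap is
clamped to [0.05, 0.5]°. The initial gap is 0.5° (the ceiling), matching
the observed early-session approach to the maximum. Titration runs on all
trials before any exclusion. The titration band check uses a calibrated
cue-neutral observer whose accuracy is pinned to 95% at the gap ceiling;
with the linear gap→drift link the accuracy logit is proportional to gap,
so the floor accuracy is then ≈ 57% — the two endpoints cannot be set
independently under this link, and bracketing the band is what matters.

## Numerics

- **First-passage sampling** is Euler–Maruyama (default `dt = 1 ms`) with a
  Brownian-bridge within-step crossing test, which removes the leading
  O(√dt) boundary-crossing bias. Validation against the closed-form moments
  uses `dt = 0.5 ms` and n = 50,000 trials per parameter point; agreement is
  required within 3 Monte-Carlo SEs (the SE of VRT uses the empirical fourth
  central moment, since correct-RT distributions are skewed).
- **EZ forward equations** use `MDT = (a/2v)·tanh(va/2s²)` and an
  overflow-safe form of the VRT expression valid for either drift sign; for
  `|va/s²| < 1e-5` the analytic limits `MDT → a²/4s²`, `VRT → a⁴/24s⁴`
  (series-joined) apply. Forward and inverse are exact mutual inverses to
  double precision; the test grid requires < 1e-8 relative round-trip error.
- **Edge corrections**: accuracies of exactly 0, ½ or 1 are replaced by
  `1/2n`, `½ + 1/2n`, `1 − 1/2n` using the cell's trial count, with a
  warning and a flag on the estimate.
- **JZS Bayes factor**: adaptive quadrature of the noncentral-t likelihood
  against the Cauchy(0, 0.707) prior on the standardized effect, split at
  the likelihood peak, relative tolerance ~1e-9 per half; cross-checked
  against an independent implementation to 1e-4 in tests.
- **Generalized eta squared** uses the fully-within formulation
  `SS_effect / (SS_effect + SS_subjects + all within-error SS)`; with all
  factors at two levels no sphericity correction exists to apply.
- **Within-participant SEM** is Cousineau normalization (subtract the
  subject mean, add the grand mean) with the Morey `√(k/(k−1))` factor.

## Preprocessing and the "robust" EZ variant

Exclusions run in order: practice block → gaze-contaminated trials →
non-responses → optionally responses faster than a cutoff (0.25 s
reproduces the published robustness check; it applies to correct and error
trials alike, which the original description leaves open). The report gives
per-stage percentages relative to trials entering the stage. Cell variance
uses the n−1 denominator. Subjects with fewer than 2 correct trials in any
cell are dropped (a configurable generalization of excluding a participant
with a single correct trial in one condition). "Robust" EZ is realized as
this contaminant trimming before the closed-form inversion; the full
guessing-mixture estimator is out of scope.

## Parameter recovery

Recovery cohorts hold the gap at `gap_ref` (titration off) so each cell's
generating `(v, a, T_er)` is exact. With 31 subjects × 480 analyzed trials
under the default observer, contamination and the robust cutoff, pooled
group-mean absolute bias is well under 10% for all three parameters when
averaged over a few cohorts; the smallest cells (10% × 480 = 48 trials per
subject) dominate the seed-to-seed noise. Residual drift underestimation of
a few percent traces to surviving uniform guesses inflating VRT — exactly
the contaminant class the trimming targets, removed only partially at a
0.25 s cutoff.

## Problem sizes

Suite defaults: Monte-Carlo moment checks at n = 50,000 trials per grid
point (18 points), recovery at 3 cohorts of 31 subjects, null-calibration
of the ANOVA at 2,000 replicates of 31 subjects, staircase-equilibrium runs
of 5,000 trials with a 500-trial burn-in. These sizes put Monte-Carlo error
well below every asserted tolerance while keeping the full suite in the
low minutes on one core.

## Known limitations

- The simulator draws non-responses as an independent Bernoulli process and
  via window censoring; real non-responses may correlate with difficulty.
- Gaze contamination is a flag, not a gaze process; interactions between
  fixation breaks and behavior are not modelled.
- Across-trial variability parameters of the full Ratcliff model (starting
  point, drift variability) are intentionally absent — the EZ mapping
  assumes them away, and the generator honors the EZ assumptions.
- Inclusion Bayes factors over ANOVA model spaces and cross-experiment
  mixed ANOVAs are not implemented; pairwise JZS Bayes factors are.
- Passing recovery on this generator shows the pipeline is correct under
  the model's assumptions; it cannot certify those assumptions for real
  observers.
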