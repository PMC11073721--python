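# Methods

This package reconstructs, as tested software, the behavioral analysis
of a numerical-Stroop experiment run under online 10 Hz rTMS: staged
trial cleaning, classical reaction-time statistics, and a
drift-diffusion decomposition of the RT distributions. Because no raw
trial data are distributed with the study it emulates, the package
includes a synthetic-study generator with a known generative truth, so
that every downstream stage can be validated by parameter and effect
recovery rather than by comparison to irreproducible group statistics.

## The task and design being emulated

Participants see two single digits (1–9, numerical distance 1–8) and
report by button press which is numerically larger. Font size induces
the size-congruency manipulation: congruent (larger digit in larger
font), incongruent (reversed), neutral (equal fonts). The schedule
comprises a visit-1 practice block (48 trials, 24 congruent / 24
incongruent), four scanner blocks of the same composition, a visit-2
practice block of 72 trials (24 per congruency level including
neutral), and four visit-2 stimulation blocks of 72 trials under active
or sham rTMS — two consecutive blocks per arm, arm order
counterbalanced across participants. Stimulation trials carry a pulse
triplet at 220/320/420 ms after stimulus onset (design metadata), and a
robotic-holder coil-to-target deviation is recorded per trial.

## Diffusion model

Decisions are modelled as a Wiener process with unit diffusion
coefficient between two absorbing boundaries:

* `v` — drift rate (evidence/s), signed toward the correct (upper)
  boundary;
* `a` — boundary separation (evidence units);
* `t0` — non-decision time (s): encoding plus motor execution;
* `w` — relative start point, fixed at 0.5 (the model has no bias
  parameter);
* `p_c` — contaminant proportion, fixed at 0.05 and not estimated.

The first-passage density is evaluated with the standard small-time /
large-time series pair; the branch needing fewer terms for an absolute
truncation error of 1e-12 (on the standardised density) is taken, which
keeps the full density's error far below the documented 1e-7 contract.
The defective densities for the two boundaries integrate to the
closed-form absorption probabilities,
`P(upper) = (1 − e^{−2vaw}) / (1 − e^{−2va})`, and these identities are
tested by quadrature.

Observed trials follow a two-component mixture: with probability
`1 − p_c` the diffusion process, with probability `p_c` a contaminant
process uniform in RT over the cell's observed RT span and equally
likely to be correct or incorrect. A per-trial likelihood floor of
1e-29 (applied before the log) keeps zero-density RTs (e.g. RT < t0
with `p_c = 0`) from producing −∞.

### Fitting

Each participant × congruency × stimulation cell is fit independently
(all three parameters free per cell; a shared-`a`/`t0` variant exists as
a config option). The search is Nelder–Mead over a smooth
reparameterisation — `v` free, `a = exp(θ)`, `t0 = t0_max · σ(θ)` —
with 5 restarts (one seeded at the EZ-style moment inversion, four
jittered) and tolerance 1e-6. `t0_max` is the cell's **median** observed
RT, not the minimum: under the contaminant mixture a single uniform
contaminant below the true `t0` would otherwise cap the estimate below
truth, while the likelihood itself already penalises any `t0` above
genuine decision RTs (the diffusion density vanishes there, leaving
those trials only the small contaminant likelihood).

The EZ-style initialiser inverts accuracy, mean and variance of correct
RTs in closed form; accuracies of 0/1 are shrunk by `1/(2n)`, and the
chance-level branch returns the driftless limits (`v = 0`,
`a = (24·Var)^{1/4}`, using `E[T] = a²/4` and `Var[T] = a⁴/24` for the
unbiased driftless process).

### Group inference

Fitted drift rates enter a 3 (Congruency) × 2 (Stimulation)
repeated-measures ANOVA implemented from sums of squares, reporting F,
dfs, p, partial η², and a Greenhouse–Geisser-corrected p whose ε uses
Box's formula on the effect-contrast covariance (the R `car`
convention; validated against a frozen `car::Anova` computation).
Post-hocs are paired active-vs-sham t-tests within each congruency
level, reported both unadjusted (the conventional post-hoc value) and
Holm-adjusted. Standard repeated-measures dfs are reported throughout;
no attempt is made to reproduce any particular software's approximate
denominator dfs.

## Cleaning cascades

Practice/scanner RT track: missed trials (no response) → incorrect
trials → RTs above mean + 2.5 SD. Stimulation sessions prepend a coil
filter (deviation ≥ 3 mm, inclusive). The accuracy track — also used
for the diffusion fits, which need error RTs — removes only the coil
and missed stages. Each cascade emits a report whose row accounting
(`rows_in` of stage k+1 = `rows_in − rows_removed` of stage k) is an
enforced invariant.

Numerical choice: the trial-level trim uses the population SD (ddof=0)
of the trials entering the stage. With the sample SD, a single extreme
trial among n kept trials can never exceed mean + 2.5 SD once n ≤ 8
(the largest attainable z is `(n−1)/√n`), which would silently
deactivate the trim on small cells. The trim's moment basis is
per-participant by default (global and per-participant-per-condition
are available); group-level participant exclusions (cell mean above
group mean + 2 SD in ≥ 4 of 6 cells; SCE strictly above group mean +
2.5 SD) use the sample SD and include the candidate in the group
statistics.

## Classical statistics

* Derived statistics: SCE = RT(incongruent) − RT(congruent),
  facilitation = RT(neutral) − RT(congruent), interference =
  RT(incongruent) − RT(neutral); the identity SCE = facilitation +
  interference is a tested invariant. Stimulation effect % =
  100·(active − sham)/sham, negative = faster under active.
* Mixed models on trial-level correct RTs use statsmodels `MixedLM`
  with a participant random intercept and sum-to-zero factor coding, so
  each Wald term tests the factor's average effect; the df method
  (Wald χ²/df, large-sample denominator) is recorded in the output
  rather than matched to any published F's denominator df. Post-hocs
  are Bonferroni-corrected pairwise paired comparisons on participant
  condition means.
* SCE-type scores enter a 2 (Stimulation, within) × 2 (Order, between)
  split-plot ANOVA computed through difference scores — exact for a
  two-level within factor; with unequal groups the within effect tests
  the unweighted mean of group means.
* Numerical distance is categorised as small (1–3) vs large (4–8) and
  tested in a Distance × Stimulation within-subject ANOVA.
* The exploratory covariate regression uses backward selection on OLS:
  repeatedly drop the least significant predictor while its p ≥ 0.10
  (configurable), after removing constant and perfectly collinear
  columns with warnings. With p_out = 1 the full model is kept; with
  p_out = 0 only the intercept survives.
* Accuracy is summarised but never modelled; a guard refuses accuracy
  models when overall accuracy exceeds 97% (near ceiling) unless
  forced.

## Synthetic-data generator

The generator is first-class, tested code. Its defaults emulate the
study's printed behavior and were fixed once:

| quantity | default | rationale |
|---|---|---|
| participants | 15 | completers entering the diffusion analysis |
| sham drifts (C/I/N) | 2.8 / 1.9 / 2.4 | reproduce ≈439/492/457 ms cell means |
| boundary `a` | 1.1 | with the drifts above, ≈88–96% accuracy |
| non-decision `t0` | 0.26 s | same calibration |
| congruent-active drift boost | +0.5 | the study's reported effect, congruent cells only |
| distance drift slope | 0.14 /digit | reproduces a ≈20 ms small-vs-large RT gap |
| intensity dose-response | 0.2 drift/SD | active-cell drift rises with stimulation intensity, giving an intensity-predicted stimulation effect of the reported magnitude |
| practice schedule | `a` ×1.45→1.0, `t0` ×1.12→1.0 | early caution: slow but accurate practice blocks |
| miss rate | 3% | between the two printed session rates |
| contaminants `p_c` | 5% on [0.2, 3.0] s | assumed proportion; window spans the plausible response range |
| coil excursion rate | 2.1%, jitter σ = 1 mm | printed removal fraction |
| between-participant SD (v, a, t0) | 0.3, 0.1, 0.03 | realistic group heterogeneity for inference tests |

Practice is modelled as boundary-based caution rather than reduced
drift: the emulated pattern — early blocks slow *and* near-ceiling
accurate, later stimulation blocks faster at ≈88% — is a speed-accuracy
tradeoff, which drift scaling cannot produce. Drift- and
t0-practice-factors remain supported fields. One residual mismatch is
documented: simulated practice error rates sit near 9% rather than the
printed ≈2%, because the strong printed distance effect bounds
attainable accuracy on close digit pairs; the stimulation-session
cleaning fractions match the printed cascade closely.

What the generator does **not** emulate: sequential effects
(post-error slowing, block fatigue), RT autocorrelation, left/right
response biases, digit-identity effects beyond distance, and any
fMRI/physiological coupling. Passing recovery tests therefore shows the
estimators are correct and adequately powered under an idealised
diffusion world with realistic contamination — not that the model is
true of any participant.

## Validation studies and problem sizes

`numstroop.validation` holds the studies run identically by the test
suite and `scripts/acceptance.py`:

* density vs a 10⁶-path Euler–Maruyama histogram (dt = 1e-4) at the
  reference set (v=1, a=1.5, t0=0.2), compared at five grid times in
  the distribution body where the sampler's O(√dt) crossing bias stays
  well under 1%; bin-curvature is removed by comparing Simpson bin
  averages;
* normalisation of the defective densities over a v × a × w grid;
* simulator-vs-closed-form checks (absorption probability, driftless
  mean first-passage time) at 10⁵ paths with a documented small Euler
  allowance;
* parameter recovery: 20 replicates of 1000-trial cells at
  (v=1.5, a=1.2, t0=0.25, p_c=0.05);
* end-to-end interaction power: 20 seeded studies of 15 participants
  with 1000 trials/cell, all cells equal except +0.5 drift in
  congruent-active, through simulate → clean → fit → ANOVA; and a
  type-I study of 200 reduced-size null replicates (6 participants, 48
  trials/cell). The power/null studies use 2 optimizer restarts rather
  than the default 5: at these trial counts the EZ seed starts near
  the optimum and extra restarts only add runtime.

Replicate counts and sizes are the studies' design choices, balancing
Monte-Carlo precision against the cost of a single-CPU run.

## Known limitations

* No across-trial variability parameters (sv, st0, sz) and no
  dual-stage accumulation model — three parameters plus contaminants,
  as specified.
* No hierarchical/Bayesian estimation; cells are fit independently, so
  small cells (≈48 trials) carry substantial estimation noise and a
  mild upward drift bias in near-ceiling cells.
* The split-plot ANOVA is specialised to 2×2; the mixed-model dfs are
  large-sample.
* The Euler sampler's hitting-time bias is O(√dt); oracle comparisons
  account for it explicitly rather than applying a boundary-shift
  correction.
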