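# Methods

`gazecone` implements the cone-width analysis of three-alternative
forced-choice (3AFC) sound-localization experiments: the kind of study in
which a listener hears a voice whose azimuth is varied from −40° to +40°
while viewing a face (with direct gaze, with eyes closed, or no face at
all) and reports whether the voice came from the left, the middle, or the
right.  The quantity of interest is the **cone width**: the range of
azimuths a participant perceives as central.  A visual stimulus that
captures sound localization (the ventriloquism effect) widens this cone,
and socially salient direct eye gaze is expected to widen it further.

## The psychometric model

For one participant in one visual condition, response probabilities are
modeled with two opposed logistic curves and the middle category as their
complement:

```
L(x) = 1 / (1 + exp( βL (x − μL)))        (decreasing in azimuth x)
R(x) = 1 / (1 + exp(−βR (x − μR)))        (increasing)
M(x) = 1 − L(x) − R(x)
```

so predicted proportions sum to one identically.  The four parameters
(μL, μR in degrees; βL, βR in probability per degree, positive in any
accepted fit) are estimated by minimizing the sum of squared residuals
between observed and predicted response proportions over all azimuths and
all three categories simultaneously — the three curves are not independent,
and the joint least-squares criterion respects that.  The loss is plain,
equally weighted SSE on proportions; this is the simplest criterion that is
monotone-equivalent to the residual variance across the three curves, and
whether per-category count weighting would change anything materially is
one of the open modeling choices we resolved in favor of simplicity.

Optimization uses the Nelder–Mead simplex (the classic fminsearch variant:
reflection 1, expansion 2, contraction ½, shrink ½; initial simplex by
perturbing each start coordinate by 5%).  Because simulation studies here
require tens of thousands of fits, the simplex is implemented *batched*:
one numpy pass per iteration advances every active fit at once.  The unit
tests verify vertex-for-vertex agreement with
`scipy.optimize.minimize(method="Nelder-Mead")`.

Five restarts are run per fit: one data-driven start (midpoints at the
0.5-crossings of the empirical left/right proportions by linear
interpolation, slope 0.2/deg) and four jittered copies (SD 5° on midpoints,
0.05/deg on slopes, seeded); the lowest-SSE converged restart is kept.
Default tolerances: simplex parameter spread ≤ 1e−6, loss spread ≤ 1e−10,
at most 2000 iterations per restart.

Two numerical subtleties deserve note:

* **Ridge non-identifiability.**  When a category transition falls between
  two sampled azimuths (e.g., responses flip completely between −20° and
  −10°), the steepness is unidentified upward: the loss is flat in β and
  the simplex never collapses in that direction.  All restarts nonetheless
  agree on the loss to many digits.  A fit whose restarts exhaust the
  iteration budget but agree on the loss to within 1e−8 is therefore
  accepted as converged-in-loss; the returned curve is the one the data
  determine.
* **Simplex-boundary overshoot.**  With ~10 trials per cell, the
  unconstrained least-squares optimum routinely predicts a middle
  proportion a few thousandths *below* zero at the edge azimuths.  The
  acceptance check "middle non-negative at every design azimuth" is
  applied with a tolerance of 0.01 so that these numerically trivial
  excursions do not masquerade as unfittable participants, while
  substantively negative predictions still fail.

A fit is declared a failure ("unable to fit", triggering whole-participant
exclusion) when: no restart converges under either criterion; a fitted
slope is non-positive; the predicted middle proportion is below −0.01 at a
design azimuth; a crossing is missing; or the width is non-positive.

## Cone width

The cone width is `x_right − x_left`, where `x_left` solves L(x) = M(x)
and `x_right` solves R(x) = M(x).  Crossings are located by sign-change
bracketing on a 0.1° grid over ±90° (wider than the stimulus range, since
fitted crossings may fall outside ±40°) followed by bisection to 1e−4°.
Only transversal crossings in the curve's own direction count — the left
curve crossing the middle curve downward, the right curve upward — which
selects the crossing on the relevant side when logistic tails re-cross far
from the cone and ignores floating-point plateaus where two vanishing
tails are numerically equal.  If a curve pair crosses more than once in
the same direction, the crossing nearest 0° is used.

## Exclusion rules

Three participant-level rules, applied wholesale (a participant failing in
one condition is removed from all conditions):

1. **Vigilance**: more than 20% of catch trials failed (strict; exactly
   20% is retained).
2. **Edge accuracy**: accuracy below 80% (strict) at either ±40° azimuth
   in any condition.  "Correct" means reporting the matching side; middle
   responses are incorrect.  The rule is applied per condition by default
   (the stricter reading); pooling across conditions is available via
   `QCConfig(edge_pooled=True)`.
3. **Fit failure**, as defined above — assessed only for participants who
   pass the first two rules, mirroring the sequential order in which such
   exclusions are conventionally reported.

## Group-level inference

The response table holds one cone width per participant × condition.  The
model is a linear mixed model with fixed effects for condition (and, for
two-group designs, ethnicity and the condition × ethnicity interaction), a
random intercept per participant, and no random slopes.  All models are
fitted by **maximum likelihood**, not REML: significance is assessed by
likelihood-ratio tests between nested fixed-effect structures, and REML
log-likelihoods are not comparable across such structures.  The LRT
statistic is 2·ΔlogLik truncated at zero, with df equal to the difference
in fixed-parameter count.  The likelihood optimization is delegated to
`statsmodels.MixedLM`; the model specifications, nesting checks, LRT, and
contrasts are implemented here.

Post-hoc pairwise condition contrasts are estimated-marginal-mean
differences: design rows per condition averaged over an equally weighted
grid of the other factors, with standard errors from the fixed-effect
covariance of the fitted model.  t statistics and Wald confidence
intervals use residual degrees of freedom, defined as observations −
fixed parameters − participants.  No multiplicity adjustment is applied
to the post-hoc p-values.  For balanced paired two-condition data the
mixed-model contrast reduces exactly to the mean within-participant
difference; this identity is asserted in the test suite.

## The synthetic observer

Because no public trial-level dataset accompanies this design, the
generator is a first-class module.  An observer has two category
boundaries (default ±10°, the audio-only reference state) and a shared
transition slope (default 0.25/deg).  Visual conditions widen both
boundary magnitudes cumulatively:

| condition    | widening per boundary        | default |
|--------------|------------------------------|---------|
| baseline     | none                         | 0°      |
| eyes_closed  | `face_widening`              | 2.0°    |
| direct_gaze  | `face_widening` + `capture_widening` | 2.0° + 1.5° |

so the gaze effect on cone width is ≈ 2 × 1.5° = 3°, and the face-vs-
baseline effect ≈ 4° — magnitudes chosen to be realistic for this
paradigm.  Responses are drawn from the implied trinomial with a lapse
rate of 0.02 mixing in uniformly random responses.  The fitted model has
no lapse parameter, so the lapse acts as deliberate mild misspecification;
at these settings it biases recovered widths by well under a degree.

Between-participant heterogeneity is a single normal shift (SD 3°) added
to both boundary magnitudes — a random intercept on cone width, matching
the inference model's structure.  The shift is truncated below so that
boundary magnitudes stay ≥ 4° and every condition's true cone remains
well-defined; with the default SD this clips roughly 2% of draws.  No
per-participant variance is published for this paradigm, so the SD is a
package default, not an empirical value.

Ground-truth cone widths are computed from the *lapse-free* generating
curves with the same crossing solver the analysis uses, so recovery checks
compare like with like.  Contaminant participants for QC testing come in
three modes, each built to trip one exclusion rule: `random_responder`
(uniform responses; caught by edge accuracy at ~33%), `side_biased` (one
side with probability 0.9 everywhere; caught at the opposite edge),
`vigilance_failer` (fails each catch trial with probability 0.5; honest
otherwise).  Attentive participants pass each catch trial with
probability 0.98.

Designs: `exp1` is 9 azimuths × 2 conditions × 10 trials (180
experimental trials) + 12 vigilance trials per participant; `exp2` adds a
9 × 10 audio-only baseline block (270 + 12 trials).

### What the generator does not emulate

Real online data differ in ways the generator deliberately ignores:
heterogeneous headphone quality (which distorts the effective azimuth
scale per participant rather than just adding response noise), left–right
asymmetries in localization, lapse rates that vary by participant,
serial dependence between trials, and vigilance failures correlated with
experimental-trial inattention.  Passing recovery tests therefore show
that the estimator chain is correct under its stated model, not that the
design is robust to every failure mode of real remote testing.

## Simulation scales and verification

The test suite verifies each stage against an independent oracle: the
joint fit against a dense parameter-grid search, the crossing solver
against a 1e−3° brute-force scan, the batched simplex against scipy's
scalar implementation, and the balanced-design mixed-model estimate
against the closed-form paired mean.  Calibration studies use 100
replicate datasets of 40 participants for effect recovery (mean signed
error of the gaze-effect estimate, LRT power) and 500 replicates of 20
participants for the null rejection rate; these sizes give Monte-Carlo
standard errors comfortably below the tolerances being asserted while
keeping the default suite runnable on one CPU.  The acceptance script
reruns the full pipeline at full study scale (125 and 76 analyzed
participants).

## Known limitations

* No uncertainty is attached to individual cone widths (no bootstrap or
  Bayesian alternative); widths enter the mixed model as point estimates.
* The residual-df convention for post-hoc t tests is one defensible
  choice among several (no Satterthwaite or Kenward–Roger approximation
  is provided).
* The lapse-free fitted model is mildly misspecified with respect to the
  generator by construction; at realistic lapse rates the induced bias is
  negligible relative to between-participant variation.
* Edge-accuracy QC requires the ±40° azimuths to be present; designs
  without them must disable or reconfigure the rule.
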