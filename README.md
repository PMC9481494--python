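# gazecone

Analysis pipeline for 3AFC (left / middle / right) sound-localization
experiments on the **ventriloquism effect**: the illusion in which the
perceived location of a sound is pulled toward a concurrent visual
stimulus, such as a face on a screen.  The package estimates each
participant's **cone width** — the range of sound azimuths reported as
central — and tests whether visual conditions (a face with direct eye
gaze, a face with eyes closed, or no face at all) change that width.

It is written for psychophysicists and perception researchers who have
trial-level response tables (participant, condition, azimuth, response)
and want a tested, reproducible path from raw trials to mixed-model
inference — plus a synthetic-observer module for power analysis,
parameter-recovery checks, and QC validation when no real data are at
hand.

## The statistic

For each participant × condition, the proportions of "left" and "right"
responses across azimuths x (−40°…+40° in 10° steps) are fitted jointly
with two logistic curves, the "middle" curve being their complement:

    L(x) = 1 / (1 + exp( β_L (x − μ_L)))
    R(x) = 1 / (1 + exp(−β_R (x − μ_R)))
    M(x) = 1 − L(x) − R(x)

All three curves are fitted at once by Nelder–Mead simplex minimization of
the summed squared residuals across curves.  The **cone width** is the
distance in degrees between the azimuth where L crosses M and the azimuth
where R crosses M.  Widths then enter a linear mixed model with a
participant random intercept; condition effects are tested with
likelihood-ratio tests (ML fits) and emmeans-style pairwise contrasts.
Participants are excluded when they fail more than 20% of vigilance
(catch) trials, score below 80% at the easiest azimuths (±40°), or cannot
be fitted.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a 24-participant two-condition experiment with the default
observer (a ~3° direct-gaze widening on top of ~20–24° cones) and run the
whole pipeline:

```
$ gazecone run --design exp1 --n 24 --seed 7 --out demo_run
Design: exp1  (n = 24 participants)
LRT drop condition:ethnicity: chi2(1) = 1.10, p = 0.2944
LRT drop condition: chi2(1) = 16.51, p = 4.85e-05
LRT drop ethnicity: chi2(1) = 0.29, p = 0.5895
direct_gaze - eyes_closed: +4.63 deg [2.70, 6.57], t(20) = 4.99, p = 7.108e-05
direct_gaze - eyes_closed | east_asian: +3.65 deg [0.91, 6.39], t(20) = 2.78, p = 0.01168
direct_gaze - eyes_closed | white: +5.62 deg [2.88, 8.36], t(20) = 4.28, p = 0.0003696
artifacts in demo_run
```

Reading the output: the likelihood-ratio test for the gaze condition is
clearly significant (χ²(1) = 16.51) while ethnicity and its interaction
are not; the marginal contrast says cones were on average 4.63° wider
under direct gaze than with eyes closed in this small simulated sample
(the generating truth is ≈3°; with 24 participants the estimate is noisy),
with the gaze effect present in both participant groups.  `demo_run/`
contains the trial CSV, ground truth, QC report, per-participant fitted
parameters and cone widths, the inference JSON, a log, and a manifest
(config + seed + versions) that makes the run exactly reproducible.

The same stages are available separately (`gazecone simulate`, `qc`,
`fit`, `infer`) and as library functions:

```python
import gazecone as gz

spec = gz.CohortSpec(n_participants={"white": 40, "east_asian": 40},
                     design="exp1", seed=1)
trials, truth = gz.simulate_cohort(spec, gz.ObserverParams())
result = gz.analyze_trials(trials, design="exp1")
print(result["inference"]["contrasts"][0])
```

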