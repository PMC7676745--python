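# aaarisk

Patient-specific, probabilistic rupture-risk assessment for abdominal
aortic aneurysms (AAAs).

An AAA ruptures where the von Mises wall stress exceeds the wall strength.
Neither the stress nor the strength of a living patient's wall can be
measured: wall thickness *t*, the stiffnesses *α*, *β* of the hyperelastic
strain energy Ψ(I₁) = α(I₁−3) + β(I₁−3)², and the strength σ<sub>γ</sub>
come from tensile tests on tissue harvested during open repair.  This
package predicts those four properties *jointly* — as a correlated
log-normal distribution conditioned on eight non-invasive clinical
features (aneurysm geometry and hemogram values) — and defines the risk
index as the probability of the failure event under that distribution:

> ℙ<sub>rupt</sub> = E<sub>p(log Θ)</sub>[ 1{ log σ<sub>vm</sub><sup>max</sup>(t, α, β) > log σ<sub>γ</sub> } ],  Θ = [t, α, β, σ<sub>γ</sub>]

estimated by seeded Monte Carlo with a cheap Kriging surrogate standing in
for the expensive stress solver.  It is aimed at researchers in vascular
biomechanics who want a reusable, testable implementation of this
pipeline with a pluggable stress model.

The pieces, in pipeline order:

| module | what it does |
| --- | --- |
| `cohort_data` | paired feature/property tables, missingness filters, median imputation, z-scoring, Spearman ranking, forward feature selection |
| `synthetic_cohort` | seeded generator of cohorts with the database's statistical structure |
| `mgp` | multi-output Gaussian process (coregionalized, Kronecker-structured) predicting p(log Θ); cohort log-normal and independent-GP baselines; leave-one-patient-out benchmarking |
| `forward_model` | pressure protocol (MAP raised 50%) and a hyperelastic membrane-balloon stress model implementing the `ForwardModel` plug-in contract |
| `kriging` | universal Kriging of log stress with an explicit trilinear trend (exact on trilinear functions) |
| `active_learning` | density- and stress-weighted acquisition to train the surrogate with ~10 forward evaluations |
| `risk` | Monte-Carlo ℙ<sub>rupt</sub>, stress-at-mean, RPI, PRRI, closed-form oracle |
| `study` | case-control evaluation: group summaries, relative differences, ROC/AUC |

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
import numpy as np
from aaarisk import (ActiveLearningConfig, CohortGeneratorConfig, MembraneBalloonModel,
                     compute_risk, generate_cohort, mgp_fit, preprocess,
                     train_surrogate_active)

# 1. a synthetic cohort with the database's statistical structure
cohort, norm_stats = preprocess(generate_cohort(CohortGeneratorConfig(n_patients=40, seed=7)))

# 2. joint predictive distribution of the wall properties for one patient
model = mgp_fit(cohort, restarts=3, seed=0)
predictive = model.predict(cohort.feature_matrix()[0])
print("mean log properties:", np.round(predictive.mu_log_theta, 3))
print("marginal log sd    :", np.round(predictive.marginal_sd, 3))

# 3. actively trained stress surrogate (membrane model, large aneurysm)
forward = MembraneBalloonModel(reference_radius=60.0)
surrogate, log = train_surrogate_active(forward, predictive, ActiveLearningConfig(seed=1))
print("forward evaluations:", log.n_forward_evaluations)

# 4. rupture-risk indices
result = compute_risk(surrogate, predictive, n_eval=10_000, seed=2)
print(f"P_rupt = {100 * result.p_rupt:.2f}% (MC standard error {100 * result.mc_standard_error:.3f}%)")
print(f"stress at mean = {result.sigma_at_mean:.1f} kPa, RPI = {result.rpi:.3f}, PRRI = {100 * result.prri:.2f}%")
```

prints

```
mean log properties: [0.478 4.461 7.579 6.679]
marginal log sd    : [0.098 0.972 0.705 0.159]
forward evaluations: 15
P_rupt = 0.50% (MC standard error 0.071%)
stress at mean = 483.2 kPa, RPI = 0.600, PRRI = 0.39%
```

Reading the output: the patient's predicted mean wall thickness is
exp(0.478) ≈ 1.6 mm and mean log strength 6.679 (≈ 800 kPa).  The
surrogate needed 15 stress-model evaluations (initial design of 8 plus 7
acquisitions).  The wall stress at the mean parameters is 483 kPa, a
rupture potential index (stress over mean strength) of 0.600; accounting
for the full joint uncertainty, the probability that stress exceeds
strength is 0.50%.  The PRRI comparator (independent thickness/strength
uncertainty only) gives 0.39% — indices are meaningful *relative to other
patients computed the same way*, not as absolute event probabilities.

The evaluation layer works directly off per-patient index tables; the
printed table for the 36-patient diameter-matched case-control study is
bundled:

```python
from aaarisk import load_printed_case_control, run_case_control
report = run_case_control(load_printed_case_control())
print(report.delta_median_pct["p_rupt"])   # 266.02  (% difference of group medians)
print(round(report.auc["p_rupt"], 3))      # discrimination of the probabilistic index
```

A thin CLI mirrors the library: `aaarisk simulate-cohort`, `fit-gp`,
`predict-wall`, `surrogate-train`, `risk`, `study` (see `--help`).

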