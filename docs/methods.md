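# Methods

`aaarisk` quantifies the rupture risk of an abdominal aortic aneurysm (AAA)
probabilistically.  Rupture is treated as material failure: the wall fails
where the von Mises stress exceeds the wall strength.  Because the wall
properties of a living patient cannot be measured, they are predicted as a
joint probability distribution from non-invasive clinical data, and the
risk index is the probability that stress exceeds strength under that
distribution.

## Notation and units

* Θ = [t, α, β, σ<sub>γ</sub>] — invasive wall properties: thickness (mm),
  the two stiffness parameters of the wall's hyperelastic strain energy
  Ψ(I₁) = α(I₁−3) + β(I₁−3)² (kPa), and wall strength (kPa).
* ξ — eight non-invasive features: maximum AAA diameter, maximum thrombus
  thickness, AAA length, subrenal diameter (mm); thrombocytes (1,000/µl),
  hemoglobin (g/dl), MCH (pg/cell), MCV (fl).
* σ<sub>vm</sub><sup>max</sup>(θ) — peak von Mises wall stress (kPa) at
  θ = (t, α, β) under the elevated pressure protocol.
* All logarithms are natural; entropies are in nats.

## Pipeline

### 1. Cohort data (`cohort_data`)

Paired delimited tables (features / properties, row-aligned by a leading
patient index; patients contribute multiple tissue samples).  Preprocessing
mirrors the usual database-preparation order: drop features missing in
more than 30% of records, drop records missing more than 30% of the
surviving features, impute the remaining gaps with per-feature medians,
then z-score each feature (population standard deviation).  The medians,
means and scales are frozen in `NormalizationStats` so a prospective
patient is transformed identically.  Imputation and normalization use the
full surviving dataset once, not per cross-validation fold — a small,
deliberate information leak that matches how such databases are prepared
in practice; the benchmark numbers inherit it.

Feature relevance is ranked by Spearman correlation against the four
properties (average ranks under ties; a constant column yields a missing
value, never a silent zero).  Sequential forward selection greedily adds
candidates, ordered by descending absolute correlation, while a
model-quality score improves; the empty model scores +∞ so the first
candidate is always accepted, and the first non-improvement stops the
search.  The default score is the leave-one-patient-out mean patient
standardized mean square error (PSMSE) of the multi-output GP; the score
is a plain callable parameter, so cheaper scores (e.g. grouped-CV linear
regression) can be substituted — the test suite does exactly that, since
repeated GP refits inside a greedy loop are expensive.

### 2. Synthetic cohorts (`synthetic_cohort`)

The generator emulates the database's structure for testing without any
download: per patient one Gaussian feature vector (cohort means/SDs of the
eight features), per sample log Θ = μ + Wᵀz + ε where z are the patient's
standardized features, W an 8×4 link matrix (zero by default) and ε
correlated Gaussian noise.  Default marginals are the cohort log-moments
(μ = [0.484, 4.543, 7.685, 6.704], σ = [0.105, 1.036, 0.758, 0.183]);
default cross-correlations are the strongest predictive correlations
reported for the demonstration patient (ρ<sub>t,σγ</sub> = −0.3214,
ρ<sub>β,σγ</sub> = 0.2274, ρ<sub>t,β</sub> = −0.1966, ρ<sub>α,β</sub> =
0.1413) because cohort-level pairwise correlations are not published; both
are fully configurable.  The samples-per-patient distribution defaults to
a mixture averaging ≈ 2.2, matching 251 samples from 113 patients.
Missingness injection is a separate, optional step (default rate 0).

What the generator does **not** emulate: non-Gaussian feature marginals,
feature-feature correlation structure, heavy-tailed stiffness
distributions, and any geometric/imaging information.  Tests passing on
synthetic cohorts therefore validate the statistical machinery, not
clinical performance on real data.

### 3. Multi-output GP (`mgp`)

The four log properties share one latent kernel over normalized features,

k(ξ, ξ′) = ζ₁ + ζ₂⟨ξ, ξ′⟩ + ζ₃ exp(−ζ₄‖ξ−ξ′‖²),

coupled by a coregionalization matrix Ω = LLᵀ (L lower triangular,
positive diagonal) with per-output noise variances S, so the stacked
targets are N(0, Ω⊗K + S⊗I).  The 18 hyperparameters (ζ₁..ζ₄, S₁₁..S₄₄,
10 entries of L) maximize the exact log marginal likelihood; positive
parameters are log-reparameterized, and multi-start L-BFGS-B (seeded,
default 10 restarts) guards against local optima.  All algebra runs
through the joint eigendecomposition of S^{−1/2}ΩS^{−1/2} and K, reducing
a likelihood evaluation from O((4n)³) to O(n³); dense 4n×4n oracles in the
test suite confirm agreement to 1e-8.  A relative jitter of 1e-8 on K's
diagonal (configurable) maintains conditioning; a covariance that is
singular despite it raises rather than being silently re-regularized.

Prediction for a new patient yields a 4-dimensional Gaussian for log Θ
(mean and full covariance, symmetrized after computation, noise
included).  Baselines: *Model 1* — independent log-normals with population
moments, identical for every patient; *Model 2* — off-diagonal entries of
L frozen at zero, which block-diagonalizes the model into four independent
GPs.  Leave-one-patient-out benchmarking reports PSMSE (per held-out
patient and variable, the variance-standardized squared error averaged
over the patient's samples, then over variables and patients — the hook is
pluggable since conventions differ) and the patient predictive entropy
½·log((2πe)⁴|Σ|).

A note on identifiability: Ω⊗K is invariant under Ω → cΩ, K → K/c, so
only the *correlations* of Ω (and products like Ω·k) are meaningful; the
parameter-recovery check in the acceptance suite compares correlations,
and does so in a kernel regime with weak between-record correlation — with
strongly overlapping kernels the effective sample for Ω shrinks and no
estimator could pin its correlations to ±0.15 at n = 200.

### 4. Forward model (`forward_model`)

The pressure protocol is MAP = systolic/3 + 2·diastolic/3 (defaults 121/87
mmHg → 98.33 mmHg), raised by 50% (elevation factor 1.5) and converted at
1 mmHg = 0.133322 kPa.

The packaged stress model is a spherical membrane of reference radius
R₀ = 25 mm under equibiaxial stretch λ with the wall's strain-energy
density: with I₁(λ) = 2λ² + λ⁻⁴ and ŵ′(λ) = (α + 2β(I₁−3))·(4λ − 4λ⁻⁵),
the equilibrium pressure is P(λ) = (t/R₀)·λ⁻²·ŵ′(λ); the smallest root
λ* ≥ 1 of P(λ*) = P_applied is found by bisection-bracketed root-finding
(tolerance 1e-10 in λ) and the returned stress is σ = (λ*/2)·ŵ′(λ*).  For
β > 0 the pressure-stretch curve is increasing over the solution bracket,
so the root is unique; for small β the classic membrane limit-point
instability can occur, and pressures beyond the first local maximum raise
`LimitPointError` naming the limit pressure.  The model is monotone
decreasing in t and non-increasing in α, β (property-tested).

This is a statically determinate stand-in with the correct constitutive
law and qualitative behavior; it does not reproduce patient-specific
finite-element stress fields, and no desk-scale model could.  Any external
solver can be plugged in through the `ForwardModel` contract (a callable
returning a positive peak stress in kPa; field-valued solvers apply their
own summary statistic, conventionally the 99th percentile of the stress
field).

### 5. Kriging surrogate (`kriging`)

Noise-free universal Kriging of log σ<sub>vm</sub><sup>max</sup> over
θ = (t, α, β): a squared-exponential kernel with signal variance ζ₁ and
per-dimension squared length scales diag(ζ₂, ζ₃, ζ₄), plus an explicit
trilinear trend h(θ) = [1, t, α, β, tα, tβ, αβ, tαβ] under a vague
coefficient prior (the closed-form generalized-least-squares limit; the
prior mean/covariance are never materialized).  Consequences: the mean
interpolates the training data (relative nugget 1e-10 for conditioning)
and reproduces *any* function in span(h) exactly, and the predictive
variance carries a positive-semidefinite trend-uncertainty term
rᵀ(HK⁻¹Hᵀ)⁻¹r on top of the zero-trend GP variance.

Inputs are standardized per dimension to the [0, 1] training box before
kernel and trend evaluation: t (~mm) and β (~thousands of kPa) differ by
three orders of magnitude, and a per-dimension affine map leaves span(h)
unchanged while improving conditioning enormously.  The surrogate
regresses on raw θ (the trend is written in t, α, β), not log θ.
Hyperparameters maximize the vague-prior marginal likelihood (including
the GLS quadratic and log|HK⁻¹Hᵀ| terms) from a seeded Latin-hypercube
multistart.  Degenerate designs (e.g. all points sharing a coordinate)
reduce the trend to the largest full-rank sub-basis with a warning.

### 6. Active learning (`active_learning`)

Forward-model evaluations are the expensive resource, so training points
are acquired sequentially at the maximizer of

ψ(Θ) = δ(θ) · p(log Θ) · μ(θ),

the predictive standard deviation of the surrogate, weighted by the
patient's predictive density and the predicted log stress (accuracy where
failures are both probable and severe).  The strength component of Θ
enters only through the density.  Negative predicted log stresses
(sub-kPa, outside the physiological regime) are clamped to zero in ψ with
a warning.

The candidate "grid" is a seeded Latin-hypercube sample of n_grid points
over the μ ± 3σ log-space box with the density evaluated exactly at each
point — a tensor grid is infeasible in 4-D at 10,000 points, and the grid
must not itself be density-distributed or the weighting would count p
twice.  The initial design is the predictive mean itself plus n_init − 1
Latin-hypercube points over the same box (θ components).  Iterations
monitor the grid average ψ̂; training stops when |ψ̂_iter − ψ̂_{iter−1}| ≤
tol, with ψ̂₀ = 0 so that at least one acquisition test occurs unless tol
is infinite.  Defaults: n_init = 8 (the trend rank, and the published
working value), n_grid = n_eval = 10,000, tol = 1e-4, plus a safety cap of
200 iterations.  Forward-model failures at proposed points are skipped
with the point penalized out of the grid; more than three consecutive
failures abort.  A full run is bit-for-bit reproducible from (seed,
config, forward model).  On the membrane model with the demonstration
patient's predictive moments the loop terminates after ≈ 15 total forward
evaluations, the same order as the published average of 11 with the
finite-element solver.

### 7. Risk indices (`risk`)

* **P_rupt** — Monte Carlo over the *joint* predictive: draw n_eval
  (default 10,000) correlated samples of log Θ via a factorization of the
  predictive covariance (Cholesky by default, eigendecomposition as a
  cross-check), compare the surrogate's mean log stress at the sampled
  (t, α, β) strictly against the sampled log strength; ties count as
  non-rupture.  Reported with the binomial standard error
  √(p̂(1−p̂)/n_eval).
* **σ at mean, RPI** — stress at exp(μ_log θ), and that stress divided by
  the predictive mean strength exp(μ + σ²/2) (the log-normal mean, which
  is what physical-space cohort means correspond to).
* **PRRI** — the independence comparator: log t and log σ<sub>γ</sub>
  sampled independently from their marginals, α and β held at their
  predictive means, stress evaluated at the sampled thickness.  The
  as-printed formulation of this index evaluates the stress at the *mean*
  thickness inside the indicator, which makes the thickness integral
  vacuous and collapses the index to a 0/1 step; that variant is
  implemented behind `literal=True` for comparison, and the sampled-t
  reading is the default.  With a diagonal predictive covariance and a
  stress ignoring α, β, PRRI and P_rupt coincide (tested within Monte-
  Carlo error), reflecting that the joint index generalizes it.
* A closed-form oracle Φ((μ₁−μ₂)/√(s₁²+s₂²)) for independent normal
  comparison validates the estimator.

### 8. Case-control evaluation (`study`)

Group summaries per index: mean, population standard deviation (the
sample convention is one `ddof` away for anyone who prefers it), and
quartiles by linear interpolation between order statistics — the
convention validated by reproducing the printed group median of the
rupture probability (1.28%) from the 18 printed per-patient values; the
25th/75th convention is not separately verifiable from the printed rows.
Relative group differences are Δq = 100·|q_s/r − q_a|/q_a.  ROC curves
sweep thresholds over the index values with the symptomatic/ruptured
group positive; the trapezoid AUC equals the Mann–Whitney U statistic
scaled by n₁n₂ (ties at half credit), which the tests assert to 1e-12
against `scipy.stats.mannwhitneyu`.  The curve/AUC computation is
delegated to scikit-learn.

The printed per-patient index table for the 36 diameter-matched AAAs
(18 asymptomatic / 18 symptomatic-ruptured, with the 11 known-ruptured
flagged) ships as a package fixture, so the whole evaluation layer is
testable without any stress solver.  `run_case_control_from_cohort` runs
the full prospective protocol — per patient: remove them from the
database, refit, predict, actively train a surrogate, compute all four
indices — collecting per-patient failures instead of aborting.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (NumPy `default_rng`,
seeded Latin hypercubes), and identical seeds reproduce results exactly.
The test suite exercises the expensive paths at reduced sizes chosen to
keep the statistical assertions sharp: GP fits on cohorts of 20–40
records with 1–3 optimizer restarts, one parameter-recovery and coverage
experiment at n = 200 records (the size at which coregionalization
correlations are estimable to roughly ±0.07), Monte-Carlo checks at the
default n_eval = 10,000, and active-learning runs at the default
n_grid = 10,000.  The full prospective pipeline test uses six patients
with a reduced acquisition grid, as a structural rather than statistical
check.

## Known limitations

* The membrane stress model shares only the constitutive law with a
  patient-specific finite-element model; absolute stresses and rupture
  probabilities are not comparable to published per-patient values, and
  none of the tests claim they are.
* The GP prior is zero-mean; the bias kernel term absorbs the overall
  level of log Θ.  For cohorts far from the training regime the
  predictions revert to zero, not to the cohort mean.
* PSMSE follows this package's definition (documented above) and is
  pluggable; published tables using other conventions are not directly
  comparable.
* Preprocessing imputes and normalizes once on the full dataset (shared
  with the original protocol), so cross-validation scores are slightly
  optimistic.
* The cohort generator's cross-correlation defaults come from a single
  patient's predictive distribution, the only correlations published.
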