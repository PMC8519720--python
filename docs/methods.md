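# Methods

This note documents the model, the numerical choices, and the synthetic
data behind `psoimpute`'s tests — including what passing tests do and do
not demonstrate about real clinical data.

## The imputation model

### Missingness mechanisms

The probability that a cell is missing may be independent of the data
(MCAR), depend only on observed values (MAR), or depend on the missing
value itself (MNAR). The pipeline decides the working mechanism in three
steps: Little's MCAR test on the continuous block; failing to reject at α
(default 0.05) ⇒ MCAR; rejecting with a user declaration ⇒ the declared
mechanism; otherwise MNAR — the conservative default for clinical data,
where unrecorded values are often unrecorded *because* of their magnitude.
"Nonignorable" missingness is treated as a synonym for MNAR; no fourth
operational category exists.

Little's test compares pattern-wise means against EM-estimated grand
means: with distinct missingness patterns *j* of size k_j over observed
subsets [j],

    d² = Σ_j k_j (ȳ_j − μ̂_[j])ᵀ Σ̂_[j]⁻¹ (ȳ_j − μ̂_[j]),   df = Σ_j p_j − p,

with μ̂, Σ̂ the maximum-likelihood (EM) estimates of a multivariate normal
on the continuous block and a chi-square upper tail for the p-value.
Discrete variables are excluded from the test (the normal model is
undefined for nominal data) but are still amputed and imputed. The EM uses
a 1e-6 relative log-likelihood tolerance, 500 iterations maximum and a
1e-8 ridge on the covariance diagonal; a single missingness pattern makes
the test vacuous and is reported as MCAR-consistent rather than an error.
Measured on 200 MCAR replicates (n=200, p=4, 20% missing per variable) the
test's type-I error sits inside [0.01, 0.10] at α = 0.05, and its power
against 20% upper-tail deletion exceeds 0.8 (both recomputed by
`scripts/acceptance.py` and the test suite).

### Amputation

Simulated missingness always hits the requested count exactly:
round(fraction × n) cells per variable (half-up rounding, so the counts of
the emulated case-study profiles reproduce their printed percentages).
MCAR deletes uniformly at random. MAR deletes by weighted sampling without
replacement, with weight logistic(z) on the driver covariate's z-score
(scale 1; only the narrative of driver-dependent missingness is fixed by
the method, so the weight form is this package's choice). MNAR deletes
the most extreme values of the variable itself — upper tail by default,
configurable to lower/both; the direction is a modelling choice, not a
derivable fact. The dependent variable is never amputed.

### The imputation chain

Incomplete independent variables are ordered by ascending missing
fraction (ties: schema position) — the best-observed variables are imputed
first and feed later predictors. Position *i* is predicted from the
already-completed variables x₁..x_{i−1}; position 1, which has no
predecessor, is predicted from the *next* chain variable (stated twice by
the method's definition, so honored literally), or from the least-missing
other independent variable when the chain has length one. Any still-
missing partner cell at query time is mean/mode-filled for the model input
only. Observed cells are never overwritten.

Restricting predictors to chain variables is a deliberate fidelity choice
with a real cost: fully observed covariates outside the chain never enter
the per-variable models (they do enter the downstream classifier). The
benchmark fixtures are designed with this in mind (below).

### The algorithm pools

18 discrete-target algorithms (SVM: linear, quadratic, cubic, RBF with
γ ∈ {5, 2, 1, 0.5, 0.2, 0.1}; k-NN with k ∈ {1,3,5,7,9}; entropy-criterion
decision tree; feed-forward net; logistic regression; Gaussian naive
Bayes) and 9 continuous-target algorithms (SVR; the same k-NN ladder;
CART; feed-forward net; multiple regression), all behind one
`fit_predict` contract on scikit-learn estimators. Interpretation choices
where the pool names a family only:

* "RBF = c" is read as the kernel width γ of exp(−γ‖u−v‖²) — the common
  single-parameter convention; config-overridable.
* SVM-polynomial is degree 3, quadratic degree 2.
* The network has one hidden layer of width ⌈(n_in + n_out)/2⌉, at most
  500 epochs, seeded initialization.
* The discrete tree is an entropy CART stand-in for C4.5 without rule
  post-pruning; the continuous tree uses variance reduction.
* Margin/distance learners (SVM, k-NN, nets, logistic, SVR, linear
  regression) see z-scored inputs; trees and naive Bayes see raw codes.
* Degenerate targets (one level, zero variance) fall back to a constant
  predictor; k-NN reduces k to n−1 on tiny training sets. Both are logged.

### The swarm

Particles in [0,1]ⁿ (n = chain length) decode per component through
`min(n_pool, ⌊x·n_pool⌋ + 1)` — surjective, monotone, an equal partition
of the unit interval, and pinned by the worked anchor 0.75 → row 14 (9-NN)
of the discrete pool. 100 particles by default, uniform initial positions,
zero initial velocities. The velocity update carries no inertia weight
beyond the unit carry-over term (a configurable inertia multiplier
defaults to 1.0 so the literal rule is the default); c₁ = c₂ = 2.0, the
classic PSO values, as none are fixed by the method. Velocities are
clamped symmetrically to ±v_max — the stated rule writes only the upper
branch, but an unbounded negative velocity would defeat the clamp's stated
purpose — with v_max = δ·(range), δ = 0.9^generation (the prose "90% less
per generation" conflicts with the formula 0.9^i; the formula wins, and
the decay factor is configurable). Positions are clamped to [0,1] after
the standard x ← x + v update.

The Pareto archive (capacity 100, crowding-distance pruning) holds
mutually nondominated (Δsensitivity, Δspecificity) pairs; each particle's
leader is drawn uniformly from the archive per update, and a particle's
personal best is replaced only when strictly dominated. Termination:
R_norm = R_max / diameter(S₀) < 0.01 (R_max the largest particle-to-leader
distance, leader = smallest-objective-sum archive member) or 50
generations.

### Fitness

For a candidate assignment, each of n_repeats (default 100; tests and the
acceptance script use 3–5) repeats: ampute the observational block under
the resolved profile, impute with the candidate's algorithms, and score a
classifier by stratified 5-fold cross-validation. The objectives are the
mean absolute differences in sensitivity and specificity against the
intact-data panel computed **under the same fold split as the repeat** —
the paired design makes each repeat's difference attributable to the
imputation alone, and guarantees that an ideal imputation (restoring the
true values exactly) scores exactly (0, 0). Both the amputation and the
folds are re-drawn per repeat from seeded streams, so fitness is a
deterministic function of (data, profile, assignment, seed). Because of
that determinism, fitness is memoized per decoded assignment: particles
decoding to the same pool rows share one evaluation, which is what makes
exhaustive 18×18 enumeration and desk-scale swarm runs affordable.

Absolute (not signed) differences are used — a signed mean could cancel
opposite-direction errors. The in-loop classifier defaults to logistic
regression (cheap, deterministic); it is configurable, and the benchmark
below deliberately uses a different one. The positive class defaults to
the lexicographically last observed label.

The final selection re-scores every archive member's accuracy on one
fresh amputation draw (a seed outside the fitness schedule, so the
re-score is not optimistically tied to the search draws); exact ties break
uniformly at random.

## Synthetic data

Real clinical tables of the motivating shape (an 80-record gastric
survival cohort, a 25-record ATLL laboratory cohort) are not publicly
deposited, so all tests run on seeded synthetic data with known structure:
an equicorrelated latent Gaussian; some dimensions exposed directly as
continuous variables; others quantile-thresholded into 2–4 ordinal levels;
a binary outcome through a logistic link on the latent scores; missingness
simulated by the amputation module. The `gastric` and `atll` presets
reproduce the two cohorts' shapes and per-variable missing fractions
exactly (80×15 with eight incomplete variables up to 88.75%, overall
29.5%; 25×35 with twelve incomplete variables up to 48%) — shapes and
missingness only, not clinical marginal distributions, units or ranges.

Two purpose-built fixtures drive the method-level experiments:

* **Linear-chain fixture** (selection recovery): x₂ = 2·x₁ + ε
  (σ_ε = 0.1), binary outcome loading on x₂, 35% *upper-tail MNAR*
  missingness on x₂ only. The MNAR tail is the point: under MCAR the
  collinear, fully observed x₁ lets a refit classifier compensate for any
  imputation of x₂, and the fitness cannot separate algorithms; with the
  deleted cells beyond the observed range, interpolation-only learners
  (k-NN, trees) must extrapolate and fail visibly while linear fits
  recover the tail almost exactly. The package recovers a
  regression-family algorithm for x₂ in ≳75% of seeded desk-scale runs
  (10 particles, 15 generations, 5 fitness repeats) against a 2/9
  random-choice rate.
* **MAR benchmark fixture** (directional comparison): n = 200, four
  informative continuous variables (equicorrelation 0.6) each 25% missing,
  driven by a fully observed covariate. With a refit *logistic* classifier
  downstream, the swarm-selected imputation and mean imputation are
  statistically indistinguishable — a refit linear model largely absorbs
  single-imputation distortion, and even a near-oracle fixed regression
  chain only ties mean imputation on this design. The benchmark therefore
  scores a Gaussian naive-Bayes classifier (pool row 18), which is
  genuinely sensitive to the point-mass distortion mean-filling creates in
  the feature distributions, and uses the same classifier inside the
  fitness — the method's premise is optimizing imputation *for the
  classifier it will serve*. Under these conditions the selected
  imputation matches or beats mean imputation in ≳90% of seeded runs.

What passing these tests shows: the search machinery finds assignments
that genuinely minimize the stated objectives, and the objectives rank
imputation quality correctly where imputation quality is identifiable.
What they do not show: effect sizes on real cohorts (the synthetic
margins are not clinical margins), behaviour under model misspecification
of the latent-Gaussian generator, or any advantage when the downstream
model is refit, linear, and the features are redundant — in that regime
imputation choice barely moves downstream accuracy, and the package makes
no contrary claim.

## Numerical and scale choices

* Rounding of amputation counts: half-up; deterministic.
* EM: tolerance 1e-6 (relative log-likelihood), ≤500 iterations, 1e-8
  ridge; non-convergence returns the last iterate with a warning.
* MICE: mean/mode initialization, 10 sweeps, linear draws with residual-SD
  noise for continuous targets, multinomial-logistic probability draws for
  discrete; the l2-penalized logistic doubles as the separation guard.
* missForest-style imputer: ascending-missingness variable order,
  stopping at the first increase of the difference criterion (normalized
  squared change for continuous cells + disagreement proportion for
  discrete), previous iterate returned; 100 trees by default.
* Observational-block bootstrap: records promoted fewest-missing-cells
  first, so the least invented information enters the block.
* Desk-scale problem sizes in the tests and acceptance script (60–200
  records, 3–5 fitness repeats, 6–20 particles, 3–15 generations) were
  chosen once as the smallest sizes at which each property is
  identifiable; defaults in the library remain at the full scale
  (100 particles, 100 repeats, 50 generations).
* All randomness flows through `numpy.random.default_rng` with seeds
  derived from a single user seed; runs are bit-reproducible.

## Known limitations

* Records are exchangeable rows: no longitudinal or time-series structure.
* The sensitivity/specificity objectives require a discrete (binary in
  practice) dependent variable; there is no continuous-outcome fitness.
* MNAR amputation assumes a tail direction; real nonignorable missingness
  need not be a tail, and no sensitivity analysis over MNAR assumptions is
  attempted.
* The chain's predictor restriction (previous chain variables only) can
  discard useful fully observed covariates; it is kept for fidelity to the
  chained-prediction definition.
* Little's test covers the continuous block only; data with fewer than two
  continuous variables skip the test and default to MCAR-consistent.
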