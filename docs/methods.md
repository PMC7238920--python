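# Methods

## Model

Each subject is represented by a profile s of age-residualized mean FA
over p named white-matter tract bundles. Controls are modelled as draws
from a multivariate normal with mean μ and covariance C over FA^r; a
subject's severity is the Mahalanobis distance
M = √((s−μ)ᵀC⁻¹(s−μ)), i.e. a probability distance: under the normal
model, M² of a new control follows a χ² distribution with p degrees of
freedom (this calibration is asserted by test). The univariate
comparator is the per-tract |Z| = |s_t − μ_t|/sd_t.

The assumptions that matter: (i) approximate multivariate normality of
control FA^r — M is still a sensible ranking under mild departures,
and all downstream evaluation (AUC, Spearman) is rank-based; (ii) the
age effect on FA is linear over the cohort's age range; (iii) patients
and controls share the control covariance structure apart from the
injury shifts.

### Age residualization

A per-tract OLS regression FA ~ 1 + age is fitted and its residuals
used everywhere downstream. Default fit population is **controls
only**, applied to all subjects: a normative model should not absorb
patient pathology into its age trend. Fitting on all subjects is
available (`fit_population="all_subjects"`) and the choice is recorded
in output metadata. Only a linear age term is used; no sex or education
covariates.

### Shrinkage covariance

With n ≈ p (25 controls per subsample, 22 tracts) the sample covariance
is near-singular and its correlations noisy. The estimator shrinks the
sample correlation matrix R toward the identity,
R* = (1−λ)R + λI, and rescales by the sample SDs, so off-diagonal
(potentially spurious) correlations are attenuated while each tract's
variance is preserved. The intensity is the Schäfer–Strimmer /
Ledoit–Wolf-type plug-in

    λ* = Σ_{i≠j} Var^(r_ij) / Σ_{i≠j} r_ij²,

clipped to [10⁻¹², 1]; the strictly positive floor makes R* (hence C)
positive definite by construction, for any p/n ratio. The realized
intensity is reported in the `ControlModel` and is data-dependent —
typically ≈0.2–0.3 at n=25, p=22, falling toward 0 as n grows. A plain
sample-covariance mode (`method="sample"`) exists for oracle testing
and large-n use. Quadratic forms are evaluated by Cholesky triangular
solves, never through an explicit inverse.

**Known limitation.** Shrinking toward zero correlation is the right
conservative prior when true correlations are weak or decaying (there
it improves the estimate over the sample covariance almost surely at
these sample sizes). When the true correlation field is uniformly
strong — e.g. a common factor giving all tract pairs r ≈ 0.4 — the
replicate-level comparison against the sample covariance becomes a
coin-flip-plus: whether shrinkage helps in a given replicate is then
dominated by whether that sample's *overall* correlation level happens
to overshoot or undershoot the truth, a common-mode fluctuation no
data-driven intensity can see. The scoring pipeline is unaffected (M is
rank-stable under the attenuation), but users estimating the covariance
itself in a strong-common-factor regime should prefer a structured
target.

### Permutation subsampling and leave-one-out

For each subject, `n_perm` subsets of `subset_size` controls are drawn
without replacement; (μ, sd, C) are refitted **on each subset** (the
whole reference distribution is subsample-derived, not just C), M and
|Z| are computed against it, and the subject's reported scores are the
medians across subsets. Defaults: subset_size = 25, n_perm = 1,000.
A control being scored is removed from the pool before any subset is
drawn. |Z| uses the subsample SD by default (consistent with the
subsampling logic); full-pool SD is available via `z_sd="pool"`.

Randomness: each subject's stream is seeded by
SeedSequence([master_seed, crc32(subject_id)]), so a subject's score
depends only on the master seed, its id and the control pool — never on
cohort ordering or which other subjects are scored. Subsets are drawn
by argsort of per-permutation random keys, which vectorizes; the
subset-level model fits run as one batched computation (batched
covariance, shrinkage intensity, and linear solves), making the full
65-subject × 1,000-permutation default take a few seconds. The batched
fit *is* the single fit (B=1), so there is no fast-path/slow-path
divergence to test for.

Numerical notes: M² is clipped at 0 before the square root (it can be
−ε for s ≈ μ); degenerate inputs (zero-variance tract, too-small pool
after hold-out) raise typed errors naming the offender; median of an
even permutation count averages the two central order statistics, which
is why only the p=1 case makes M and |Z| medians agree to rounding
rather than bitwise.

### Evaluation

AUC is the tie-corrected Mann–Whitney probability
P(score_patient > score_control) + ½P(equal), with the convention that
higher scores are more patient-like. Spearman ρ uses average ranks;
its two-sided p-value is an exact permutation tail below n = 10 and the
t-approximation otherwise (adequate at n = 34). The 22 univariate
correlations form one BH-FDR family; the single planned M correlation
is reported unadjusted, its q-value left missing. The display fit line
is Tukey-bisquare IRLS (c = 4.685, MAD scale, tol 1e-8, ≤100
iterations; non-convergence returns the last iterate with a warning and
flag).

### Cognitive composite

Tests whose |z-skewness| **or** |z-kurtosis| exceeds 1.96 (two-sided;
standard errors √(6n(n−1)/((n−2)(n+1)(n+3))) and
2·SE_skew·√((n²−1)/((n−3)(n+5)))) are shifted to positivity
(x → x − min + 1, shift recorded) and Box-Cox transformed, λ chosen by
profile likelihood on a [−5, 5] grid with bounded refinement. All tests
are then standardized and PCA is run on the correlation matrix; the
composite is the PC1 projection, sign-oriented to correlate positively
with the mean standardized score (inputs are expected oriented
higher = worse; the flip is recorded). Default fit population is
patients only — the composite is the patients' outcome variable —
configurable to all subjects. Box-Cox is strictly monotone for every λ,
so the transform cannot change any downstream rank correlation.

## Synthetic cohorts

The generator emulates the statistical structure of a small mild-TBI
tractometry study, with defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_controls / n_patients / n_tracts | 31 / 34 / 22 | study dimensions |
| control FA mean / SD | 0.50 / 0.03 | typical association-bundle FA |
| tract correlation | compound symmetry ρ = 0.4 | correlated-tract regime where the covariance-aware score has something to exploit |
| age range / slope | 20–60 y / −0.001 FA·y⁻¹ | adult FA decline |
| affected tracts per patient | uniform 5–12 | diffuse, heterogeneous axonal injury |
| effect size | uniform 0.5–1.5 control SD, negative | FA reduction |
| cognition | 4 tests, burden loading 0.35, noise SD 1, tests 1–2 exponentiated | links outcome to total injury load; the log-normal tests force the Box-Cox branch |

Injury direction defaults to FA reduction but signed effects are
supported. The ground truth (affected tracts, effect sizes, burden,
true covariance/slopes/loadings) is returned alongside the cohort and
serializable to JSON, enabling exact recovery tests (regenerating with
zero effects isolates the injury shift bit-for-bit).

What the generator does **not** emulate: non-Gaussian FA tails,
site/scanner effects, nonlinear age effects, tract-specific variances,
missing data, and any image-level structure. Passing tests therefore
demonstrate the statistical machinery under the stated generative
model, not performance on real scanner data.

A note on effect sizes in the brain–behavior arm: at these dimensions
the synthetic composite tracks true injury burden strongly (ρ ≈ 0.85)
but M tracks burden only weakly (ρ ≈ 0.16), because the burden-driven
noncentrality of M² competes with the subject's 22-dimensional baseline
variability and with subsample estimation noise. The M–composite
Spearman correlation in a single 34-patient cohort is therefore noisy
(mean ≈ 0.13, SD ≈ 0.13 across replicates): positive on average, but a
single cohort — synthetic or real — at this n cannot measure it
precisely.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run at deliberately moderate sizes chosen for
tight feedback: the replicate discrimination study uses 100 cohorts at
n_perm = 200 (the AUC of median scores is stable well below the
full 1,000 permutations); null calibration uses a 4,000-control fit and
2,000 held-out draws at p = 5; the acceptance script scores one cohort
at the full n_perm = 1,000 and 50 replicates at n_perm = 200. All
are reproducible from a single master seed.
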