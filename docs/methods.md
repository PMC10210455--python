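# Methods

## Effect sizes and the data model

The unit of analysis is a Pearson correlation *r* between parasite load and
ornament quality measured on *n* host individuals. Its large-sample sampling
variance is v = (1 − r²)²/(n − 1); the Fisher-z scale (z = arctanh r,
variance 1/(n − 3)) is available as an alternative analysis scale. A minimal
conversion set maps reported t, one-df F, one-df chi-square and Cohen's d
statistics to r; anything richer (digitised figures, precedence rules among
several reported statistics) is out of scope.

Records flagged *directionless* — nonsignificant results published without a
sign — are retained with r = 0 and v = 1/(n − 1) (the r-scale variance
formula at r = 0; the alternative 1/(n − 3) differs by under 10% for n ≥ 23
and changes nothing qualitatively). Dropping such records would keep only
significant effects and bias the pooled mean away from zero; `censor_report`
demonstrates the size and direction of that bias on generated data using
Fisher-z weighted means (weights n − 3). r-scale inverse-variance weights
1/v were rejected for that summary because they diverge as |r| → 1, letting
single extreme records dominate.

Named subsets mirror the three analysis datasets (all records; directional
only; male morphological traits measured synchronously with parasites) plus
`drop_small_categories`, which removes moderator levels with ten or fewer
records before meta-regression. Records missing a moderator are kept for the
overall model and dropped listwise from that moderator's meta-regression.
Category labels are matched case-insensitively after trimming.

## Phylogeny

Host supertrees assembled from taxonomy carry no meaningful branch lengths,
so all branches are set to one and the tree is made ultrametric with Grafen's
method: each internal node is placed at height ((t − 1)/(T − 1))^ρ for t
descendant tips of T total, tips at height 0, root depth 1. ρ defaults to 1,
the canonical choice; the transform is idempotent. Polytomies are retained
as-is (no random resolution), keeping results deterministic. Under Brownian
trait evolution on an ultrametric tree of depth d, the between-species
correlation is the shared root-to-MRCA path length divided by d; the matrix
is symmetric, unit-diagonal and PSD by construction, with species ordered
lexicographically and all model code mapping by label, never position.
Pruning preserves tip-to-tip path lengths, and the Brownian matrix of a
pruned tree equals the corresponding submatrix (tested to 1e−12).

## REML engine

The marginal covariance is V = M + Σᵤ σ²ᵤ ZᵤAᵤZᵤᵀ. M is diag(v), plus
ρ·√(vᵢvⱼ) between effects sharing an experiment (same host individuals) when
the shared-host variant is requested; ρ defaults to 0.5 there. The restricted
log-likelihood is

    −½ [(k − p) log 2π + log|V| + log|XᵀV⁻¹X| + (y − Xβ̂)ᵀV⁻¹(y − Xβ̂)]

computed via Cholesky factorizations only (a single 1e−10 diagonal jitter is
retried once if V is numerically singular). Note some reference
implementations add the constant ½log|XᵀX|, which cancels in estimation.

Optimization is L-BFGS-B on log σ² from three starts ({1e−4, 1e−2, 1e−1} ×
Var(y)), with the analytic REML gradient ∂ℓ/∂σ²ᵤ = −½[tr(P Gᵤ) − (Py)ᵀGᵤ(Py)]
(checked against central finite differences in the tests). Components that
run to the parameter floor are compared, with the others re-profiled, against
an exact-zero fit, so boundary estimates are reported as exactly 0. Fixed
effects use GLS at the optimum; intervals are Wald z (a Student-t switch
exists but is off by default, matching standard practice at these k). The
omnibus moderator test is Q_M = β̂ₘᵀ[cov β̂ₘ]⁻¹β̂ₘ against chi-square; for
interaction models only the interaction coefficients are tested. The engine
agrees with `metafor::rma.mv` on β, SE and σ̂² to ≤1e−4 on a fixture, and
with exhaustive grid search of the criterion on toy data.

Fixed designs supported: intercept-only; one categorical moderator with
treatment coding (or with the intercept dropped, giving per-level pooled
means — a pure reparameterization with identical restricted likelihood); two
moderators plus interaction; one continuous covariate (mean-centered by
default). Designs are checked for full rank after category drops.

## Heterogeneity

Typical sampling variance uses s̄² = (k − 1)Σw / ((Σw)² − Σw²), w = 1/v,
which collapses to v when all variances are equal; a plain mean-v alternative
can be substituted for sensitivity. Only the diagonal v enter s̄² even when a
within-experiment covariance was used in fitting (noted in the report).
Multilevel I² is 100·σ̂²ᵤ/(Σσ̂² + s̄²) per component; components sum to the
total by construction, and the report distinguishes an exact boundary
estimate (σ̂² = 0) from a small rounded share. Marginal R² is
σ²f/(σ²f + Σσ̂²) with σ²f the population variance of the fitted linear
predictor; it is 0 for intercept-only fits.

## Pipeline

`run_overall` fits the four overall models (three data subsets plus the
shared-host covariance variant) and attaches the I² partition of the full
fit. `run_moderator` fits each categorical moderator twice (with intercept
for Q_M and marginal R²; intercept-dropped for per-level means) after the
small-category drop. `run_sensitivity_subsample` removes m effects uniformly
without replacement B times, refits the base four-component model, and
reports the fraction of replicate intercept p-values above .05, the mean of
replicate intercepts and their 2.5–97.5 percentile interval (the simplest
reading of a bootstrapped CI for that mean); replicate p-values are the
intercept's Wald z p. `run_bias_tests` runs two univariate meta-regressions
under the full random structure: mean-centered publication year, and a
precision predictor — the standard error √v by default (classic Egger), √n
as the alternative, with the choice printed in the result. No
multiple-testing adjustment is applied across moderators; p-values are
reported raw. Reports (JSON, CSV tables, text summary) contain no timestamps
and are byte-identical across reruns with the same seed and config.

## Synthetic data generator

The generator draws exactly the structure the model assumes, on the Fisher-z
scale: a Yule species tree (Grafen depth 1); species effects jointly normal
with covariance σ²_phylo·A plus independent N(0, σ²_species) effects;
study and observation effects i.i.d. normal; twelve categorical moderators
sampled per effect with optional true level effects (dynamism_binary is
derived from dynamism_score, category 2 ↔ dynamic); per-effect host sample
sizes lognormal(3.3, 0.6) clipped to [10, 1000] (median ≈ 27 hosts); sampling
error with variance 1/(n − 3), compound-symmetrically correlated (ρ = 0.5)
within experiments, which group effects sharing host individuals inside a
study; observed r = tanh(z). With censoring enabled, a nonsignificant effect
(|r|·√(n − 1) < 1.96) becomes directionless with probability `censor_prob`.

Defaults are fixed once to echo the scale of a large cross-species synthesis:
83 species, Poisson(1.7, min 1) studies per species, Poisson(2.9, min 1)
effects per study (k ≈ 460), σ² = {phylogeny 0.005, species 0.010, study
0.012, observation 0.017} (z² units), grand mean −0.084 (z units). Censoring
is off by default — the default configuration is the well-specified model the
estimator assumes — and `study_like_params()` switches on censoring
(censor_prob 0.25, giving roughly 14–20% directionless records) plus modest
dynamism and transmission-risk effects. Generation on the z scale with
analysis optionally on raw r is a deliberate mild mismatch mirroring real
meta-analyses; recovery experiments fit on the z scale so variance units
match the truth. The generator does not emulate literature screening,
realistic taxon labels, or year-dependent reporting; passing tests therefore
validate the estimator under its own assumptions, not robustness to
violations beyond the censoring mechanism above.

## Numerical and testing choices

Simulation-based checks run at deliberately chosen sizes: parameter recovery
uses 200 generator-default datasets (k ≈ 460) fitted with the matching
within-experiment sampling covariance; QM null calibration uses 200 smaller
datasets (25 species, k ≈ 110), where a fit takes a fraction of a second.
Recovery of the four variance components is unbiased to better than 0.005
(z² units) at defaults.

## Known limitations

- **Wald intervals under weak phylogenetic identifiability.** On Grafen-
  ultrametrized Yule trees the Brownian matrix averages ≈ 0.33 off the
  diagonal, so the phylogeny component contributes roughly a third of its σ²
  directly to Var(β̂₀) while being identified from only a few effectively
  independent deep clades. REML then estimates σ̂²_phylo at the zero boundary
  in a fifth or more of replicates, and Wald z intervals — which ignore
  σ̂² uncertainty — undercover the grand mean noticeably (empirically ≈ 0.8
  rather than 0.95 at the default generator setting with σ²_phylo = 0.005).
  With the true variance components fixed, coverage is ≈ 0.94, and the same
  behaviour is expected of any engine using Wald-z inference here. Interval
  methods that propagate variance-component uncertainty (profile likelihood,
  parametric bootstrap) are out of scope.
- Likelihood-ratio tests, random slopes, robust/clustered variance, trim-and-
  fill and selection models are not implemented.
- The phylogeny/species split (A vs identity over the same labels) is
  data-dependent and can be weakly identified; boundary estimates are
  reported explicitly rather than smoothed.
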