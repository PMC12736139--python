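# Methods

This note documents the statistical procedures, the synthetic-cohort
generator that underwrites the tests, the numerical choices, and the known
limitations of the package.

## Latent correlation inference (`metsnet.cclasso`)

Relative abundances carry only ratio information: closure to a constant
sum makes the observed parts negatively coupled regardless of any real
ecology.  The package adopts the latent-variable view: unobserved log
"basis" abundances have covariance Σ, and the observed log-composition
covariance S differs from Σ only within the span of the all-ones vector.
The projector P = I − (1/p)·11ᵀ annihilates that direction, giving the
estimator

  minimize over symmetric PSD Σ:  ½‖P(Σ − S)P‖²_F + λ Σ_{i<j}|σ_ij|.

The problem is the intersection of a smooth quadratic, the PSD cone, and a
separable L1 penalty, and is solved by three-block consensus ADMM, each
block having a closed-form proximal map:

1. quadratic step — the map Σ ↦ PΣP is an orthogonal projector in the
   Frobenius inner product, so the prox splits into a weighted average on
   the range of the projector and a pass-through on its complement;
2. PSD projection — eigendecomposition with negative eigenvalues clipped
   to zero;
3. soft-thresholding of off-diagonal entries at λ/ρ (diagonal untouched).

The consensus iterate stops when successive iterates differ by < `tol`
(default 1e-6, max-norm) or at `max_iter` (default 2000; the pipeline
default is 5000).  Non-convergence is flagged on the result and logged,
never silently dropped.  At convergence the iterate is polished by one
soft-threshold (to certify the sparsity pattern) followed by one PSD
projection (to certify feasibility), then rescaled to a correlation matrix
(D^{-1/2} Σ D^{-1/2}, entries clipped to [−1, 1]).  Because the final PSD
projection perturbs exact zeros at the order of the tolerance, "nonzero"
off-diagonals are defined as |ρ| > 1e-5 wherever sparsity is counted.

Zeros are replaced before the log transform by 0.5 × the smallest nonzero
value of the table, followed by re-closure — the simplest multiplicative
replacement; an all-zero sample is an error.  The penalty is either fixed
or selected by k-fold cross-validation minimizing the held-out loss
½‖P(Σ̂_train − S_test)P‖²_F with seed-deterministic folds; the
cross-validation is run per network, since nothing in the procedure ties
the six strata to a common penalty.

## Edge pooling and differential calling

Within a group, each unordered taxon pair has one latent-correlation
estimate per region.  These are pooled on the Fisher-Z scale by
DerSimonian–Laird random-effects meta-analysis (method-of-moments τ², no
Hartung–Knapp adjustment, se_i = 1/√(n_i − 3)); the implementation agrees
with R `metafor`'s `rma(..., method="DL")` to ~1e-12 (tested).  BH FDR is
computed over all p(p−1)/2 pairs of a group; the "significant network" is
the edge set with FDR < 0.05, summarized by edge count, positive-edge
fraction and per-taxon degree.

Between groups, each edge's two pooled effects are compared by a
fixed-effect Cochran's Q with df = 1 and I² = max(0, (Q−1)/Q); a
differential edge needs I² > 0.75 **and** p < 0.05.  With df = 1 these two
thresholds are almost redundant (I² > 0.75 ⟺ Q > 4 ⟹ p < 0.046), so the
I² cut is the binding one — the conjunction is kept because it is the
pre-specified rule.  The edge set eligible for differential testing is the
union of edges significant in either group (configurable to intersection
or all pairs); heterogeneity p-values are not multiplicity-adjusted, per
the pre-specified rule.  A direction-change flag marks edges whose pooled
effects differ in sign.

Calibration: with (TE, seTE) pairs at their nominal sampling distribution
— the inputs the test is defined on — the null heterogeneity p-value is
exactly uniform (KS ≈ 0.014 over 2000 null edges in the reproduction
script).  When the DL pooling stage is included, truncating τ² at zero
makes seTE slightly conservative, and the null rejection rate at 0.05
drops to ≈ 0.04 (also reported by the script).  The test therefore errs on
the safe side end-to-end.

## Covariate adjustment (`metsnet.partial_corr`)

The Pearson correlation matrix over [involved genera + all eleven
covariates] is inverted; pcor_ij = −Ω_ij/√(Ω_ii Ω_jj) gives the partial
correlation of each pair given *everything else* — all covariates and all
co-included genera simultaneously, which is what full-matrix inversion
means and is documented here because prose descriptions of "adjusting the
matrix" are ambiguous.  Ordinal covariates enter as integer scores, binary
as 0/1.  The before/after comparison is a df = 1 Cochran's Q on the
Fisher-Z scale with the same se for both coefficients (same samples);
p > 0.05 marks the edge robust.  Analysis script 05 additionally reports
covariates-only conditioning (the pair plus covariates), which isolates
confounder control from the compositional coupling among co-included
genera; on synthetic cohorts with covariates unassociated with taxa the
covariates-only adjustment leaves essentially all edges unchanged, while
full conditioning can shift edges through the co-genera — a genuine
property of compositional log-abundance correlations, not a covariate
effect.

## EPI keystone screening (`metsnet.epi_keystone`)

Candidates are taxa with prevalence in the closed window [0.25, 0.75].
For each candidate, samples are split by its presence (> 0 on the
unfiltered table), the remaining taxa are renormalized (the candidate's
own mass is excluded, so indicators measure impact on *others*), and three
indicators are computed:

- **D1** — Bray–Curtis distance between the two partitions' mean
  renormalized profiles;
- **D2** — mean over remaining taxa of the two-sample Kolmogorov–Smirnov
  statistic (vectorized across taxa; equal to `scipy.stats.ks_2samp`
  column by column, tested);
- **Q** — Newman modularity of the presence bipartition on a symmetrized
  k-nearest-neighbour sample graph (k = 10 by default) weighted by
  Bray–Curtis similarity (equal to `networkx.community.modularity`,
  tested).

The null is a permutation of the presence labels (prevalence preserved
exactly, B ≥ 100, seed-deterministic); a taxon is flagged by an indicator
when the observed value exceeds the null's 95th percentile.  The
renormalized profiles and the kNN graph are label-independent and built
once per candidate, so permutations are cheap.

Two compositional artifacts surfaced while validating this stage and shape
how the generator is used for it:

1. **Shared-lattice artifact.**  With a single fixed sequencing depth for
   all samples, candidate-excluded renormalization puts the
   candidate-absent group on the exact lattice m/depth while
   candidate-present samples sit on m/(depth − k); the KS statistic then
   detects the lattice itself.  Real cohorts have variable per-sample
   depth, and so does the generator (lognormal depths, default CV 0.3),
   which dissolves the artifact.
2. **Community-load coupling.**  A taxon near the detection limit is
   absent more often in samples where the community total (or the
   sequencing depth) is high on other taxa — so the presence pattern of a
   window taxon genuinely tracks community state whenever per-taxon latent
   fluctuations are large.  Under such coupling the permutation null is
   *correctly* exceeded: the taxon is associated with the rest of the
   community, just not causally.  Null-calibration experiments therefore
   use a weak-coupling regime (latent SD 0.2, depth CV 0.08) in which a
   window taxon's presence is sampling-driven and exchangeable; in that
   regime the false-flag rate is at the nominal level (tested ≤ 10%,
   observed ≈ 0–7%).  This is a real property of cross-sectional
   presence/absence screening on compositional counts, and a caveat for
   interpreting EPI flags on real data.

The concrete D1/D2/Q operationalization above is this package's own; the
indicator interface isolates it so alternative definitions can be slotted
in, and no claim is made that it matches any other implementation
numerically.

## Abundance and function tests (`metsnet.abundance_diff`)

Each feature is inverse-rank transformed to normal scores with the Blom
offset (Φ⁻¹((rank − 0.375)/(n + 0.25)), average ranks for ties; the offset
is configurable), residualized on [intercept + all covariates] by OLS, and
the residuals compared between groups with the two-sided Wilcoxon rank-sum
test (exact enumeration when n_a + n_b ≤ 12 without ties, normal
approximation with tie and continuity correction otherwise — via
`scipy.stats.mannwhitneyu`, reported as the rank-sum W).  Combining the
regression adjustment with the rank test by residualizing first is this
package's reconciliation of the two; the transform-residualize-test
pipeline has uniform null p-values (KS < 0.05 over 2000 null features,
tested).  BH families are kept separate per feature kind (genus, EC, KO,
pathway).

## Variance decomposition (`metsnet.variance_decomposition`)

For a functional feature Y and genus pair (χ₁, χ₂), all inverse-rank
transformed, OLS fits of the additive and interaction models give
var_ind = R²_add, var_int = R²_int, extra_var = their difference, the
additive model's overall F-test p (df 2, n−3) as `p_ind`, and the nested
F-test of the interaction (df 1, n−4) as `p_interaction`.  Both p-values
are emitted (with separate BH columns) because a single printed FDR column
can ambiguously track either.  R² and both F-tests agree with
`statsmodels` OLS to 1e-10 (tested).  Degenerate inputs are rejected:
identical regressors, n ≤ 10, constant vectors.

## The synthetic cohort generator (`metsnet.synthetic_data`)

The generator emulates the study conditions end to end: 603 participants
(221 MetS / 382 non-MetS) in three regions, genus-level compositions, the
eleven covariates with realistic frequencies (smoking/alcohol/activity
category frequencies and dietary gamma means follow the cohort's
descriptive table), and functional features generated from two genera plus
an optional interaction term on standardized latent log-abundances.

The latent model is logistic-normal — multivariate normal latent
log-abundances per (group, region) with a specified correlation matrix,
exponentiated and closed — matching the generative assumption under which
the latent-correlation estimator is derived.  Counts are multinomial at a
lognormal per-sample depth (mean 10,000, CV 0.3 by default); zeros arise
only through this sampling mechanism, which is what makes prevalence
filtering meaningful.  Taxon base log-means are normal with SD 3.0 by
default, giving a long-tailed rank-abundance curve in which most taxa pass
the 10% prevalence filter and a sizable minority sits in the 25–75% EPI
window, as in the target cohort.  Differential edges are planted as
group-specific latent correlations (shared across regions within a group);
background edges are drawn under a per-taxon absolute-correlation budget
of 0.9, which keeps every row diagonally dominant and hence the matrix
positive definite by construction (a diagonal-jitter fallback exists but
is unreachable under the budget); user-supplied matrices that are not PSD
are rejected with the offending eigenvalue named.  Keystones are planted
by shifting target taxa's latent means in samples where the candidate is
present, with the candidate's observed column held fixed so the presence
split under study is exactly preserved.

What the generator does **not** emulate: taxonomic assignment error,
primer/copy-number bias, overdispersion beyond multinomial sampling,
phylogenetic correlation of effects, and covariate distributions beyond
the marginals.  Passing recovery tests on these cohorts demonstrates that
the estimators recover the structures they target under their own
generative assumptions — not that those assumptions hold in any real
cohort.

## Problem sizes and defaults

Recovery and calibration experiments run at the sizes stated with each
result: support recovery at p = 20, n = 500 with 10 planted edges (AUC
median over 10 seeds); end-to-end differential recovery at p = 15,
n = 200 per group and region with 5 planted pairs (Fisher-Z gap ≈ 0.49);
null calibration with 2000 null edges, a 30-taxon EPI cohort and 240 null
interaction tests.  The analysis scripts use a 30-genus cohort at the full
603-participant scale.  Thresholds follow the pre-specified rules
throughout: prevalence ≥ 10% (inclusive), FDR < 0.05, I² > 0.75 with
Q-test p < 0.05, EPI window [0.25, 0.75] (closed).

## Known limitations

- The latent-correlation objective identifies Σ only up to the
  compositional null space; the L1 penalty and PSD constraint select a
  particular representative.  Estimates shrink toward zero with λ, so
  pooled effects are attenuated relative to the latent truth — the
  differential test inherits the safety margin noted above.
- Per-edge inference before pooling is deliberately absent: the region
  estimates carry only (r, n), and all inference enters at the
  meta-analysis stage.
- The EPI permutation null tests exchangeability, not causality; see the
  coupling discussion above.
- Nested-model p-values assume independent homoscedastic errors on the
  rank-normal scale; with compositional regressors they are approximate.
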