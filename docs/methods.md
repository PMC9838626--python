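# Methods

## Scope and data model

`spellclust` analyzes wide tables of binary current-wheeze indicators
recorded at T ordered epochs per subject (default T = 5: infancy 0.5–1 yr,
early childhood 2–3 yr, preschool 4–5 yr, middle childhood 8–10 yr,
adolescence 14–18 yr). Inputs are assumed pre-harmonized to a shared epoch
grid; harmonization of heterogeneous follow-up schedules is out of scope.
Age-valued quantities can be encoded either as ordinal epoch indices 1..T
(default — the epochs pool wide age ranges and only their order is certain)
or as midpoint ages in years (0.75, 2.5, 4.5, 9, 16 for the default grid),
offered for sensitivity analysis.

## Spell variables

A spell is a maximal run of consecutive wheeze records. Each complete
sequence maps deterministically to six variables: first/last encoded age of
wheeze, total records, longest spell, number of spells, and the categorical
spell type (0 never / 1 single spell / 2 intermittent, i.e. at least two
non-consecutive spells). Never-wheezers have no onset or offset age; these
are recorded as missing, not as a sentinel value, and are handled natively
by the distance's pairwise-deletion weighting — a sentinel age would inject
an arbitrary quantitative difference. Feature derivation requires complete
sequences; in the multiple-imputation pipeline it runs after imputation.

Because the map from sequence to features is a pure function, any
deterministic assigner built on it (e.g. nearest medoid) sends identical
sequences to identical clusters; `sequence_audit` verifies this over all
2^T sequences and exposes the contrast with per-subject stochastic
allocation.

## Mixed-data dissimilarity

The dissimilarity is a normalized Gower-type form: squared standardized
differences for quantitative variables, simple mismatch for the categorical
spell type, averaged over the variables observed for both subjects
(weights wₖ = 1 by default; no variable weighting is assumed). Scales are
sample standard deviations (ddof = 1) fitted on the analysis table;
standardization by range and an ordinal treatment of spell type are exposed
as configuration. A zero-variance variable contributes 0 with a warning. A
pair sharing no observed variable is an error rather than a silent 0.
Pairwise deletion means the triangle inequality is not guaranteed; nothing
downstream requires it. Since at most 2^T distinct feature profiles exist,
distances are computed on unique profiles and expanded, which makes the
matrix exact (duplicates are bitwise-identical) and fast at cohort scale.

## PAM clustering and cluster-count selection

PAM uses BUILD (first medoid = total-distance minimizer, then greedy gain
maximization) followed by steepest-descent SWAP evaluated from nearest and
second-nearest medoid distances (one sweep costs O(n²)). All ties break
toward the lowest index, so a fit is a deterministic function of the
distance matrix; the accepted-configuration cost trace is recorded and is
non-increasing by construction. SWAP is a local search: on unstructured
random instances it can terminate a few percent above the exhaustive
optimum (R's `cluster::pam` lands in the same local optima), while on
clusterable data it reaches the optimum in essentially all tested cases.

The cluster count is chosen by maximizing a silhouette criterion over a
candidate range, smallest k on ties. Two criteria are available:

- `subject` — the ordinary average silhouette width over all subjects.
- `profile` (default) — the average silhouette over *distinct zero-distance
  profiles*, ignoring profiles carried by fewer than 0.5% of subjects.

The default departs from the usual subject-level silhouette deliberately.
Spell features collapse a cohort onto at most 2^T profiles, most of them
massively duplicated. Under that duplication the subject-level average
silhouette is monotone increasing in k: splitting any cluster that contains
two common profiles sends the members of each to silhouette ≈ 1 regardless
of how close the two profiles are, so no finite k is ever optimal (the same
holds for the Calinski–Harabasz index). Evaluating the silhouette once per
distinct profile restores the compactness/separation trade-off at the level
where the geometry actually lives; the rare-profile cut keeps one-off
sequences from dominating an unweighted average. On duplicate-free data the
profile criterion reduces exactly to the ordinary average silhouette. The
per-k diagnostics table reports cost and both silhouettes so other
criteria can be applied externally.

## Latent class comparison arm

The binary comparison model is a k-class mixture of independent Bernoulli
indicators fitted by EM on the distinct-pattern representation (weights =
pattern counts), best of `n_starts = 20` random initializations, item
probabilities clipped to [1e-6, 1−1e-6], convergence at relative
log-likelihood change below `tol = 1e-8` (`max_iter = 1000`). Subjects are
assigned by maximum posterior probability. BIC = −2ℓ + p·ln n with
p = (k−1) + kT.

A caution that the tests document explicitly: with T = 5 items and k = 5
classes the mixture has 29 free parameters against 31 free pattern
frequencies. The model is near-saturated and its parameters are only weakly
identified — EM started *at* the generating values and run to convergence
at n = 200,000 still drifts by ≈ 0.06 in item probabilities while gaining
likelihood. Class *assignments* are stable (tightly converged refits from
different seeds agree with ARI = 1), but parameter recovery to tight
tolerances is not achievable in this configuration, and the corresponding
acceptance test fails for that structural reason.

## Multiple-imputation consensus

Chained-equations imputation: missing cells are initialized from the
observed epoch margins, then each epoch with missingness is redrawn for
`cycles = 10` sweeps from a ridge-penalized logistic regression (λ = 1e-3)
on the other epochs, using a posterior draw of the coefficients
(N(β̂, (XᵀWX+λI)⁻¹)) so the M completions are proper imputations. M = 10
by default. Observed cells are never altered; a subject must have ≥ 1
observed epoch (the intended analysis set is subjects with ≥ 2
observations, enforced upstream via `filter_by_observed`).

Each completed dataset runs the full spell pipeline with per-imputation
cluster-count selection; the pooled k* is the modal selection (ties to the
smaller k), each imputation is refit at k*, labels are aligned to
imputation 1 by optimal assignment on the overlap matrix, and membership
probabilities are per-cluster assignment fractions. With complete data the
ensemble collapses to M identical runs and memberships are exactly 0/1;
with M = 1 it reduces to a single pipeline run.

## Association stage

Membership-weighted multinomial logistic regression maximizes
Σᵢ Σ_c p_ic log P(c | xᵢ) by full Newton iterations with step-halving
(monotone in the weighted log-likelihood); hard memberships reproduce the
ordinary multinomial fit exactly. Effects are reported as relative risk
ratios with Wald 95% CIs (z = 1.96) against a reference phenotype;
coefficients beyond ±15 flag likely separation. Covariates must be numeric
(categoricals pre-expanded; genotypes coded additively 0/1/2). Per-cohort
log effects are pooled by the DerSimonian–Laird moment estimator
(τ² = max(0, (Q−(m−1))/(Σw − Σw²/Σw))); a single study passes through with
τ² = 0.

## Synthetic cohort generator

The generator draws each subject's phenotype from fixed prevalences, then
per-epoch indicators independently given the phenotype, then missingness
(MCAR per cell, or MAR where the rate doubles after an epoch with wheeze;
epoch 1 is never missing under MAR since it has no predecessor). A single
seeded generator is consumed in a fixed order, so identical configurations
reproduce exactly. Prevalences are 0.541/0.237/0.069/0.083/0.069
(renormalized from their rounded sum of 0.999).

The per-epoch wheeze probabilities were calibrated once so that the
generated cohorts exhibit the structure the pipeline is designed to detect:
each class keeps several common sequence patterns of its own type (this
within-class profile diversity is what makes five clusters the optimum of
the profile silhouette), while cross-type noise — sporadic records among
never-wheezers, late stray records in early-transient wheeze, interior
gaps in persistent wheeze — is kept low enough that complete-case PAM
recovers the generating labels with ARI > 0.9 at n = 2,000. The defaults
are NWZ (.005×5), ETW (.90,.85,.35,.01,.01), LOW (.01,.01,.01,.60,.82),
PEW (.93,.97,.97,.97,.93), INT (.85,.15,.80,.15,.80).

What the generator does *not* emulate: real cohorts' informative
missingness and attrition, between-cohort heterogeneity in instruments and
follow-up schedules, within-class dependence of epochs beyond the class
label (the mixture assumes conditional independence), and covariates or
genotypes linked to phenotype. Passing tests therefore demonstrate that the
pipeline recovers a five-phenotype latent structure under clean mixture
sampling with MCAR-style missingness — not that five phenotypes exist in
any particular cohort. Exact confinement of intermittent patterns to a
single cluster, observed on real data, holds for many but not all synthetic
draws (the generator's cross-type noise creates borderline two-spell
sequences); the tests assert concentration and dominance instead.

## Problem sizes and numerical choices

Tested scales: n = 2,000 for complete-case recovery, n = 3,000 with 30% of
subjects missing 1–2 epochs for the imputation-robustness analysis,
n = 20,000 for latent-class fits, n = 50,000 for generator law-of-large-
numbers checks. Tolerances: distance-matrix symmetry 1e-12; membership and
posterior row sums 1e-10; oracle comparisons 1e-10 or the documented
statistical margins. Degenerate inputs are handled explicitly: singleton
silhouette = 0, zero-denominator silhouette (duplicate split across
clusters) = 0, zero-variance distance variables contribute 0 with a
warning, k = 1 PAM skips SWAP, empty tables and all-missing subjects raise
validation errors.

## Known limitations

- SWAP is a local search; global optimality is not guaranteed (ties and
  unstructured geometries can end a few percent above the optimum).
- The latent class arm requires complete data by design; imputed LCA is out
  of scope.
- `changed_fraction` requires equal cluster counts; comparisons across
  different k should use the adjusted Rand index or the transition table.
- Rendering (alluvial plots, heatmaps) is out of scope: the package emits
  the underlying tables only.
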