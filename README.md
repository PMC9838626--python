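# spellclust

Spell-based phenotyping of longitudinal binary wheeze data.

Childhood wheeze is commonly recorded as a yes/no answer at a handful of
follow-up epochs from infancy to adolescence, and data-driven "wheeze
phenotypes" (never, early-transient, late-onset, persistent, ...) are then
derived by clustering those binary sequences — typically with latent class
analysis (LCA). Binary point-prevalence input, however, ignores *how*
wheeze unfolds over time: two children with the sequences `11000` and
`10100` look similar to an LCA yet one had a single early spell and the
other a relapsing pattern. `spellclust` implements the alternative
*spells* approach for epidemiologists working with harmonized birth-cohort
data: each complete sequence is transformed into six variables describing
the timing, duration and recurrence of wheezing spells, and subjects are
clustered on those variables with partition-around-medoids (PAM) under a
mixed-data dissimilarity. The package also provides the binary LCA
comparison arm, a multiple-imputation consensus pipeline for subjects with
incomplete follow-up, and the downstream association stage (membership-
weighted multinomial regression, DerSimonian–Laird meta-analysis).

## The model

A *spell* is a maximal run of consecutive epochs with reported wheeze. For
a complete sequence x ∈ {0,1}^T the six derived variables are

1. `first_age` — encoded age of the first wheeze record (missing if never),
2. `last_age` — encoded age of the last wheeze record,
3. `n_records` — total number of wheeze records,
4. `longest_spell` — length of the longest run of consecutive records,
5. `n_spells` — number of separate spells,
6. `spell_type` — categorical: 0 = never, 1 = single spell, 2 = intermittent
   (≥ 2 non-consecutive spells of any length).

Pairwise dissimilarity between subjects i, j mixes quantitative and
categorical variables with pairwise-deletion weighting for missing values:

    d(i,j)² = Σₖ δᵢⱼₖ wₖ gₖ(i,j) / Σₖ δᵢⱼₖ wₖ

with gₖ = ((xᵢₖ−xⱼₖ)/sₖ)² for quantitative variables (sₖ the sample SD) and
gₖ = 1[xᵢₖ ≠ xⱼₖ] for categorical ones; δᵢⱼₖ = 1 iff variable k is observed
for both subjects. PAM (BUILD + steepest-descent SWAP, fully deterministic)
minimizes the total distance to cluster medoids; the cluster count is chosen
by silhouette over distinct feature profiles. Subjects with incomplete
follow-up enter through chained-equations multiple imputation: M completed
copies are clustered independently, labels are aligned by optimal matching,
and each subject's phenotype membership probability is the fraction of
imputations assigning it to each cluster. Those probabilities weight the
multinomial logistic regression of the association stage, whose relative
risk ratios can be pooled across cohorts with the DerSimonian–Laird
random-effects estimator.

Because the cohort data behind these analyses are not publicly deposited,
the package ships a synthetic-cohort generator with a latent five-phenotype
structure (never 54.1%, early-transient 23.7%, late-onset 6.9%, persistent
8.3%, intermittent 6.9%) and ground-truth labels, so the full pipeline is
testable end to end.

## Worked example

```python
import numpy as np
import spellclust as sc

# simulate a five-phenotype cohort and derive spell features
table, truth = sc.simulate_cohort(sc.GeneratorConfig(n=2000, seed=7))
features = sc.derive_feature_table(table)
D = sc.pairwise_distance(features)

# choose the cluster count, fit, and compare with the generating labels
k_star, diagnostics = sc.select_k(D, range(2, 9))
fit = sc.pam_fit(D, k_star)
print(f"selected k = {k_star}")
print(diagnostics.round(3).to_string(index=False))
sizes = np.bincount(fit.assignment) / table.n_subjects
print("cluster shares:", np.round(sizes, 3))
print("ARI vs truth:", round(sc.adjusted_rand(fit.assignment, np.array(truth)), 3))
```

prints

```
selected k = 5
 k  total_cost  avg_silhouette  profile_silhouette
 2     675.200           0.699               0.238
 3     469.853           0.708               0.282
 4     343.545           0.781               0.237
 5     241.621           0.831               0.296
 6     180.058           0.836               0.221
 7     143.128           0.864               0.217
 8     113.105           0.885               0.214
cluster shares: [0.241 0.076 0.548 0.075 0.06 ]
ARI vs truth: 0.911
```

The profile silhouette (computed once per distinct feature profile) peaks
at five clusters, the scale of the generating structure, while the plain
subject-level silhouette keeps growing as duplicated profiles are split.
The five cluster shares track the generating prevalences — the 0.548
cluster is the never-wheezers — and the adjusted Rand index of 0.911 says
phenotype recovery is nearly exact up to the noise subjects whose sequences
genuinely resemble another phenotype.

The same pipeline is available from the shell:

```bash
spellclust simulate --n 2000 --seed 7 --out cohort.csv --truth-out truth.csv
spellclust features cohort.csv --out features.csv
spellclust distance features.csv --out dist.bin
spellclust cluster dist.bin --select-k 2:8
spellclust impute-cluster cohort.csv --m 10 --seed 11 --out membership.csv
```

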