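# proteosubtype

Proteogenomic subtype discovery and ex vivo drug-response modeling for
acute myeloid leukemia (AML) multiomics cohorts.

AML is usually stratified by mutations, but mutations predict therapy
response inconsistently. This package implements the complementary
proteogenomic route as a tested, reusable pipeline for analysts working
with TMT proteomics + transcriptomics cohorts paired with ex vivo drug
screens:

1. **Quantification preprocessing** — TMT reporter ratios
   (log2 sample/reference, zero-centered per gene), missingness and
   plex-completeness filters, Tukey median polish, feature-space KNN
   imputation, and empirical-Bayes removal of loading-mass and plex
   batch effects.
2. **Subtype discovery** — per-feature z-scoring, signed splitting into a
   nonnegative matrix (twice the rows), multiplicative-update NMF
   (X ≈ WH, generalized KL divergence) restarted ~50× per rank, a
   consensus co-clustering matrix A, and rank selection by the
   cophenetic correlation of A's dendrogram.
3. **Subtype classifier** — a multinomial elastic-net model
   (penalty λ[(1−α)/2‖β‖₂² + α‖β‖₁]) on protein/phosphosite features,
   α chosen by stratified repeated 5-fold CV to maximize recall of the
   hardest subtype, so samples lacking mRNA (or external cell lines) can
   be subtyped from proteomics alone.
4. **Enrichment** — per-subtype ranked lists (mean-centered subtype
   averages), preranked GSEA (weighted KS enrichment score, permutation
   p, BH), and KSEA kinase z-scores z = (m̄_s − m̄_p)·√m/δ.
5. **Drug stratification** — drugs filtered to ≥100 assayed samples and
   ≥10 sensitive (AUC < 100, on the [1, 300] scale where lower = more
   sensitive); Welch t-tests of AUC by mutation, subtype (one-vs-rest),
   and subtype × mutation interaction under joint BH control; Fisher
   exact cluster enrichment; Kaplan-Meier + log-rank survival.
6. **Drug-response models** — per-drug elastic-net and gradient-boosted
   tree (LightGBM) AUC regressions with 5×5 repeated CV (25 held-out
   correlations per drug), final feature signatures, fold-ensemble
   prediction of external samples (e.g. drug-resistance cell-line
   trajectories), and UMAP signature landscapes.

A first-class synthetic-cohort generator (`proteosubtype.synthetic`)
plants subtypes, batch structure, intensity-dependent missingness,
subtype-enriched mutations, drug responses, and survival, so the entire
pipeline is testable without the controlled-access patient data.
`docs/methods.md` documents the models and design choices in detail.

## Worked example

```python
from proteosubtype import classifier, nmf, preprocess
from proteosubtype.synthetic import SyntheticConfig, generate_cohort
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(SyntheticConfig(seed=1))   # 160 samples, 4 subtypes

corrected = {}
for mod, m in cohort.omics.items():
    m = preprocess.filter_missingness(m, 0.5)
    m = preprocess.knn_impute(m, k=10)
    corrected[mod] = preprocess.eb_covariate_correction(
        m, cohort.annotation, ["loading_mass", "plex"]
    )

split = nmf.standardize_and_split(list(corrected.values()))
sel = nmf.select_k(split, range(2, 9), n_runs=30, seed=1,
                   max_iter=150, tol=1e-4)
labels = sel.results[sel.k_best].labels
print("selected k =", sel.k_best)
print("cophenetic curve:", sel.curve.round(3).to_dict())
print("ARI vs planted subtypes:",
      round(adjusted_rand_score(cohort.truth_labels, labels), 3))

model = classifier.fit_multinomial_elasticnet(
    corrected["protein"], labels, alpha=0.9, seed=1
)
probs, calls = classifier.predict_proba(model, corrected["protein"])
print("training agreement:", round((calls == labels).mean(), 3))
```

Output:

```
selected k = 4
cophenetic curve: {2: 0.988, 3: 0.994, 4: 1.0, 5: 0.999, 6: 0.998, 7: 0.997, 8: 0.995}
ARI vs planted subtypes: 1.0
training agreement: 1.0
```

The cophenetic correlation peaks at the planted rank (consensus
clustering is perfectly reproducible there and degrades on either side),
the consensus labels recover the planted subtypes exactly, and the
proteome-only classifier reproduces those labels.

Command-line equivalents: `proteosubtype simulate | preprocess |
subtype | classify | apply | enrich | stratify | model-drugs | run`
(see `proteosubtype --help`; `run` drives the full pipeline from a YAML
config and writes a reproducibility manifest).

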