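# mcf — metabolic classifier and feature generator

Cancer rewires cellular metabolism through routes that the canonical,
hand-curated metabolic pathways of healthy tissue do not describe well:
aggregating gene expression by canonical pathway labels tends *not* to beat
classifiers built on individual metabolic genes. `mcf` implements a
data-driven alternative. It overlays ranked gene expression on a
genome-scale metabolic network (e.g. Recon1) to discover **composite
pathways** — heaviest simple paths from *reporter metabolites* in
patient-specific weighted metabolite graphs — and uses them both to
classify cancerous vs. noncancerous samples and to score patients for
survival prediction. It is aimed at computational biologists working with
tumor/normal expression cohorts and genome-scale metabolic reconstructions.

## The method

Given an expression matrix (genes × samples), a binary cancer/normal
labelling, and a metabolic model with gene-protein-reaction (GPR) rules and
reaction stoichiometry:

1. **Rank transform.** Each sample's expression values are replaced by
   within-sample ascending midranks (over the model-gene universe), so the
   most expressed gene gets rank *G*.
2. **Reaction expression.** Each reaction's Boolean GPR is evaluated with
   AND → min (an enzyme complex is limited by its scarcest subunit) and
   OR → max (isozymes). This yields patient-specific weighted metabolite
   digraphs: one directed edge per (substrate, product, reaction) triple,
   weighted by that reaction's rank in that sample; reversible reactions
   contribute both directions.
3. **Reporter seeds.** A reaction is differentially expressed if its ranks
   differ between groups (two-sided Wilcoxon rank-sum, α = 0.05,
   Bonferroni-corrected). A metabolite that is a substrate of at least
   *k* = 5 such reactions becomes a seed.
4. **Composite pathways.** For each seed *s*, the heaviest simple-path
   weight (largest sum of edge weights, first reaction required to be
   differential, path length bounded) from *s* to every other metabolite is
   computed per sample; the *L* = 10 targets T_s whose distance vectors
   best separate the groups (smallest rank-sum p) define s's composite
   pathways, and the distances are that seed's feature vector.
5. **Ensemble classification.** One SVM per seed (linear kernel, C = 1,
   standardized features) is trained on its L distance features. A test
   sample is classified by majority vote over the N per-seed SVMs; the
   continuous score is MCFscore(x) = Σᵢ fᵢ(x), the sum of the members'
   decision values. Evaluation uses balanced repeated cross-validation:
   100 × (down-sample the majority class, stratified 5-fold CV with all
   feature selection refit inside each training fold).
6. **Survival scoring.** Trained (seed, target) pairs transfer to an
   unseen cohort: weightᵢ(p) is the heaviest distance realized on patient
   i's graph (for canonical pathways, the sum of member reaction ranks).
   Pathways split into P_c (mean weight higher in cancer) and P_n (higher
   in normal), and each patient is scored by

   score(patientᵢ) = Σ_{p∈P_c} weightᵢ(p) / Σ_{p∈P_n} weightᵢ(p).

   Evaluation: Kaplan–Meier curves of the top/bottom score deciles with a
   log-rank test and the normalized area between the curves (delta-AUC),
   Harrell's concordance index, per-pathway log-rank with
   Benjamini–Hochberg FDR, and hypergeometric enrichment of
   composite-pathway reactions in canonical pathways.

Finding the most separating simple path is NP-hard (longest-path
reduction), so the search is restricted: first hop differential, simple
paths only, depth ≤ 6 by default. Within that budget `exact_bounded` is an
exhaustive (exact) search; a beam-search alternative is available.

## Worked example

Everything runs on generated data with a planted ground truth — a seed
metabolite feeding ten node-disjoint reaction chains whose genes are
shifted in the cancer group:

```python
from mcf import synthetic_data as syn
from mcf.api import MCFModel
from mcf.classification import EvalProtocol

spec = syn.SimulationSpec(seed=0)           # 60 metabolites, 120 reactions,
network = syn.make_toy_model(spec)          # 50+50 samples, 3-sigma shift
expr, labels = syn.simulate_expression(network, spec)

res = MCFModel(expr, labels, network).fit()
print(res.summary())
```

```
MCF ensemble fit
==================================================
samples: 100 (50 cancer / 50 normal)
network: 60 metabolites, 120 reactions, 108 genes
parameters: k=5, L=10, alpha=0.05 (bonferroni), search=exact_bounded depth 6
seeds (N=1): seed_c
composite pathways: 10

seed                 targets  min p        max p
--------------------------------------------------
seed_c                    10  7.02e-18    8.41e-18
```

The planted seed (`seed_c`) is recovered as the single reporter metabolite,
with ten composite pathways whose selection p-values (~1e-17) reflect the
planted 3-sigma separation. Cross-validating the full pipeline (feature
selection refit per fold):

```python
cv = MCFModel(expr, labels, network).cross_validate(
    EvalProtocol(n_repetitions=3, seed=17))
print(f"CV mean AUC: {cv.mean_auc:.3f}, mean accuracy: {cv.mean_accuracy:.3f}")
# CV mean AUC: 1.000, mean accuracy: 1.000
```

An AUC of 1.0 says the planted classes are perfectly separable by the
learned composite-pathway features; under permuted labels the same
pipeline scores ~0.5 (see the tests). The same objects drive survival
scoring on a second cohort via `res.survival_scores(new_expression)`.

The `mcf` command line wraps the same pipeline:
`mcf simulate | train | evaluate | survival | enrich` (see `mcf --help`).

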