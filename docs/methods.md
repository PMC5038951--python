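# Methods notes

This note records the modelling choices behind `mcf`, the knobs that
matter, and what the synthetic validation does and does not establish.

## Model and assumptions

The central object is the patient-specific weighted metabolite digraph.
Its construction assumes that (i) within-sample expression *ranks* are the
comparable unit across samples and platforms — absolute intensities are
never used downstream of the rank transform, which also makes the whole
pipeline invariant to any strictly monotone per-sample normalization; and
(ii) a reaction's activity is summarized by its GPR rule evaluated over
gene ranks with AND → min and OR → max. GPR leaves missing from the data
are dropped at the node where they occur (an OR falls back to its measured
isozymes); a reaction with no measured leaf, or no GPR at all, is *absent*
and contributes no edges. This drop-at-the-node policy is not equivalent
to dropping missing genes from flattened AND-combinations, and the test
suite's independent oracle (DNF expansion) deliberately shares only the
pruning step.

Composite pathways are heaviest simple paths. Exact optimization is
NP-hard, so the search space is restricted to simple paths whose first
reaction is differentially expressed and whose length is at most
`max_depth` edges. Within this budget `exact_bounded` enumerates
exhaustively (depth-bounded DFS over simple paths, parallel edges
collapsed to the heavier — lossless for path search) and is therefore
exact; `beam` keeps the `beam_width` heaviest partial paths per depth and
is a cheaper lower bound, validated in tests to match the exact optimum on
≥ 90% of targets at width 50 on 30-node graphs. Self-loops are never
traversed. Which restriction the method's original heuristic used is not
determinable; both strategies are exposed so the choice is explicit.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 5 | minimum number of significant reactions a seed metabolite must feed (substrate side; for reversible reactions both sides count) |
| `L` | 10 | targets per seed; each seed's SVM sees an L-dimensional distance feature |
| `alpha` | 0.05 | Wilcoxon significance level; Bonferroni-corrected for seed detection, configurable elsewhere |
| `max_depth` | 6 | path-length bound (reactions per composite pathway); keeps pathways interpretable and the exhaustive search tractable on genome-scale graphs |
| `beam_width` | 50 | only for `strategy="beam"` |
| `coverage` | 0.8 | a target must be reachable in ≥ 80% of training samples to be eligible; avoids features dominated by missingness |
| SVM | linear, C = 1 | kernel/regularization are unstated in the method's description; a standardized linear SVM is the robust default for ~10 features (RBF available) |
| CV protocol | 100 × 5-fold | balanced by down-sampling the majority class; feature selection refit inside every training fold |

Units: path weights are sums of within-sample reaction ranks, so they are
dimensionless and bounded by `max_depth × G` (G = number of ranked genes).
Survival times are in whatever unit the input table uses; only their order
and censoring pattern matter to the statistics computed here.

## Statistical details

* **Wilcoxon rank-sum**: exact null when both groups have ≤ 6 samples and
  the pooled values are tie-free; tie-corrected normal approximation
  otherwise. The switch point exists because the exact method does not
  condition on ties; it reproduces the closed-form small-sample examples
  (p = 2/252 for {1..5} vs {6..10}) deterministically.
* **Target selection** operates on the 0-filled feature vectors
  (unreachable target → weight 0, with a retained missing mask), so
  selection and classification see identical numbers. Ties on p break
  lexicographically by metabolite id; the per-target direction flag
  compares group means (group medians available).
* **Vote ties** (even ensemble size) fall back to the sign of the summed
  decision values; a rule is required even though ties are not expected in
  practice.
* **Multiplicity**: Benjamini–Hochberg for the per-pathway log-rank
  family; Bonferroni for canonical enrichment and for differential
  reactions.
* **Delta-AUC** between Kaplan–Meier curves is defined here as the
  absolute difference of the areas under the two step functions, carried
  forward to the common follow-up horizon (the largest observed time in
  the two extreme groups) and divided by that horizon — a number in
  [0, 1], hand-computable on toy inputs (the all-die-at-1 vs
  all-censored-at-10 example gives exactly 0.9). Other definitions exist;
  this one is chosen for transparency and testability.
* **Concordance index** follows the risk-score convention (higher score →
  earlier failure counts as concordant; score ties count 0.5), computed
  via lifelines with the sign flipped accordingly.
* **Degenerate comparisons**: a paired t-test over fold metrics with a
  zero-variance difference vector is reported as p = 0.5 (zero mean) or
  the smallest positive float (uniform improvement), with a flag.
* Patients with a zero P_n weight sum have undefined ratio scores; they
  are excluded from survival statistics and counted in the run log.
* `build_features` skips a seed whose target selection finds no eligible
  target (warning) rather than aborting the run; the per-seed
  `select_targets` contract still raises, so the failure mode is visible
  where it happens.

## Survival transfer

On an unseen cohort there are no labels, hence no differential-reaction
set. Each trained feature set therefore freezes the training cohort's
significant-reaction set and reuses it as the first-hop restriction when
its heaviest distances are evaluated on new patients; seeds and targets
are never re-selected. Canonical pathway weights on any cohort equal the
summed member-reaction ranks, identical to the `sum`-aggregated pathway
expression.

## The synthetic generator

`synthetic_data` plants one seed metabolite feeding `n_planted_chains`
(default 10 — enough for both k = 5 and L = 10) node-disjoint chains of 3
reactions, each reaction carrying one dedicated gene; background
metabolites are connected by a random skeleton that keeps the digraph
weakly connected, with random AND/OR GPRs over a shared gene pool.
Expression values are Gaussian log-intensities (per-gene baseline mean
U(5, 9), noise sd σ₀ = 1); planted genes gain +δ (default 3 = 3σ₀) in the
50 cancer samples. The log scale is the one on which both the planted
shift and the Gaussian robustness noise N(0, σ), σ ∈ {1, 2, 3}, are
defined ("N(0, 2)" is read as standard deviation 2; a flag switches to the
variance reading). Ranking is invariant to exponentiation, so the pipeline
is identical either way. Survival times are exponential with hazard
λ₀·exp(β·z) over the standardized score (λ₀ = 0.05, β = 1 by default),
censored by an independent uniform time whose upper bound is calibrated by
bisection to hit the requested censoring fraction (20%).

One emergent property worth knowing: because ranks are compositional,
shifting the planted genes *up* pushes every background gene's rank
*down*, so background reactions also become significantly differential
(downward) at these sample sizes. That is faithful to how rank statistics
behave on real data; seed recovery and classification are unaffected, but
"differential" sets on the toy data are larger than the planted set alone.

The generator does **not** emulate platform artifacts, batch effects,
probe-level noise structure, or tumor heterogeneity. Passing tests
establish correctness of the algorithms and recoverability of a planted
signal under the stated conditions — not performance on real cohorts.

## Validation problem sizes

The packaged validation (test suite and `scripts/acceptance.py`) uses: 200
random ≤ 12-node graphs against exhaustive path enumeration (depth 11);
1,000 random GPR trees against the DNF oracle; 100 expression replicates
for seed recovery at δ = 3σ₀, 50+50 samples; 3 × 5-fold CV for the planted
end-to-end AUC and 20 × 5-fold under permuted labels; 200 label
permutations for the seed-selection null (a scaled-down default, with the
permutation count configurable); survival recovery at n = 500 (β = 1, 20%
censoring) and n = 1000 (β = 0). These sizes are the package's choices for
a reproducible desk-scale validation.

## Known limitations

* True (unbounded) heaviest-path optimization is out of scope; results are
  conditional on the depth budget.
* The SBML reader takes the canonical pathway label from the reaction
  `subsystem`/notes field (key configurable); models annotating pathways
  elsewhere need a custom loader.
* Cross-cohort merging concatenates rank-transformed matrices on the gene
  intersection; no further batch correction is attempted.
* Cox models with clinical covariates, stoichiometric consistency checks
  and flux-based analyses are deliberately out of scope.
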