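# Methods

## The model

`asvrf` classifies rows of a continuous feature table into `a ≥ 2` classes
with an ensemble whose distinguishing idea is *weighted* feature
subsampling. A plain random forest draws each tree's feature subset
uniformly; when most columns are noisy — the typical situation for sparse,
heavily missing e-health tables — many trees end up built on irrelevant
features. Here every feature first receives a chi-squared weight

    χ²_f = Σ_i Σ_j (O_ij − e_ij)² / e_ij,    e_ij = (row_i · col_j) / N,

computed from the contingency table of the feature's discretized levels
against the class label. Features are ranked, the top `n' = max(1,
round(β·n))` are retained, and each of the `k` trees draws `t = ⌊log₂ n'⌋ + 1`
(capped at `n'`) distinct features from that pool, sequentially, with
probability proportional to weight. Trees are C4.5-style: binary midpoint
thresholds, gain-ratio criterion (information gain divided by the entropy
of the partition sizes) with the guard that raw information gain must be
strictly positive, Laplace-smoothed leaf probabilities `(c_i + 1)/(c + a)`,
no pruning. The ensemble averages leaf probabilities and takes the argmax.

Upstream, min–max normalization maps every feature into [0, 1] using
training-set extremes (missing entries are first replaced by the
training-set median), and an optional LDA stage projects the data onto the
top generalized eigenvectors of between-class vs within-class scatter.
Downstream, a PSO with linearly decaying inertia can tune `(β, k)` against
stratified cross-validated error.

## Assumptions

- Features are numeric; categorical inputs must be encoded upstream.
- Rows are treated as exchangeable during training. Repeated readings per
  patient violate this; the synthetic generator can emulate that violation
  (see below) but the estimator does not model it.
- Missingness is assumed ignorable (imputation by the training median);
  informative missingness is not modelled.
- The chi-squared weighting sees discretized features, so associations
  invisible at the bin resolution (default 5 equal-frequency bins) get
  weight near zero.

## Parameters that matter

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `weighting.beta` | 0.5 | fraction of ranked features retained; 1.0 disables selection |
| `weighting.bins` | 5 | equal-frequency bins for the contingency tables; robust to skew, fit on training data only |
| `forest.k` | 50 | ensemble size; conventional desk-scale choice, tunable by PSO |
| `forest.t` | `⌊log₂ n'⌋+1` | per-tree feature-subset size; the classic logarithmic subspace rule applied to the post-selection space |
| `tree.min_samples_leaf` | 1 | unpruned low-bias trees for ensembling |
| `tree.max_depth` | unlimited | growth stops on purity or lack of admissible splits |
| `lda.L` | `min(a−1, n)` | maximal discriminant capacity; binary problems give L = 1 |
| `lda.ridge` | `1e-6·tr(S_V)/n` | Tikhonov term keeping the generalized eigenproblem well-posed |
| `pso c1, c2, w_max, w_min` | 2.0, 2.0, 0.9, 0.4 | canonical swarm settings; velocity clamped at 50% of each range, reflection at bounds |

## Design choices where the design was open

- **Feature sampling without replacement.** Sampling `t` features "with
  replacement" would produce duplicate features, which are vacuous for
  tree induction; sequential weighted sampling without replacement is used,
  with a 1e-12 weight floor so zero-weight features stay reachable.
- **Per-tree vs per-node subsets.** The subset is drawn once per tree (the
  procedure's stated form); a `per_node_sampling` flag provides the
  Breiman-style per-node variant for ablation.
- **`t` computed from `n'`**, the post-selection feature count, because
  selection precedes the tree loop.
- **Recall = sensitivity = TP/(TP+FN)** throughout; both fields are emitted
  for report compatibility and are always equal.
- **Cohen's kappa** uses marginal-product expected agreement; MAE/RMSE are
  computed between the positive-class probability and the 0/1 label, the
  only probability the pipeline produces.
- **Zero-denominator metrics return 0 with a warning flag** instead of
  raising, so degenerate cross-validation folds never abort a PSO run.
- **Constant features** map to `new_min` under normalization (the min–max
  formula is 0/0 there); out-of-range test values are clipped into the
  target interval to keep downstream binning calibrated.
- **Eigenvector sign** is fixed by making each basis column's
  largest-magnitude component positive, so serialized models reproduce.
- **PSO objective.** The forest exposes exactly two free scalars, `β` and
  `k`; the tuner minimizes their stratified CV misclassification with the
  fold assignment drawn once per run, keeping the objective deterministic
  per position. `k` lives in continuous space and is rounded only at
  evaluation, so the velocity/position updates stay exact.
- **LDA before weighting.** When LDA is enabled the chi-squared weights are
  computed on the projected space (the pipeline feeds extraction into
  classification); disabling LDA (`lda.enabled: false`) weights the raw
  normalized features. For a binary problem LDA reduces the feature space
  to one dimension, which makes feature weighting trivial — benchmarks of
  the weighting mechanism therefore run with LDA off.

## The synthetic cohort generator

`CohortSpec` defaults emulate a continuous-glucose-monitoring cohort: 62
patients × 203 readings (≈ 12.6k rows), 5 informative features, 15 noise
features, class separation 1.5 SD per informative feature, equicorrelation
0.3 within the informative block, balanced binary labels ("normal" vs
"alarming" readings), and 20% MCAR missingness. A per-patient random
intercept (`patient_effect`, default 0) can add repeated-measures
structure. Because the generative model is two homoscedastic Gaussians,
the Bayes-optimal error is available in closed form:
`Δ = s·√(f/(1−ρ+ρf))` and, for balanced classes, `error = Φ(−Δ/2)`
(the unbalanced case shifts the threshold by the log prior odds). At the
defaults Δ ≈ 2.26, so no classifier should exceed ≈ 87% + noise on held-out
data — a guard that catches leakage bugs.

What the generator does **not** emulate: physiological glucose dynamics,
temporal autocorrelation, informative missingness, label noise, and
non-Gaussian tails. Passing tests on this generator therefore demonstrate
correctness of the algorithms and the expected ordering between methods
under clean planted structure, not clinical performance.

## Benchmark sizes

The multi-seed benchmarks (forest vs single tree, feature recovery, Bayes
ceiling) run on cohorts of 62 patients × 40 readings (≈ 2.5k rows, 20-25
seeds in the test suite, 10 in the acceptance script). This is the
package's benchmark size choice: the compared quantities — mean accuracy
orderings and recovery rates — are properties of the generative model that
stabilize well below the full default cohort size, and the smaller cohorts
keep a full run on one CPU in minutes. The generator's own defaults are
unchanged.

## Numerical notes and edge cases

- Split search: thresholds are midpoints between consecutive distinct
  sorted values; a point exactly at a threshold routes left (`≤`). Ties in
  gain ratio break toward the lower feature index, then the lower
  threshold.
- Contingency cells with zero expectation contribute 0 to χ² (they occur
  when a bootstrap misses a level or class).
- Equal-frequency bin edges with duplicated quantiles are merged, so a
  constant feature yields a single level and weight 0.
- PSO records non-finite objective values as +∞; the particle keeps
  moving. `pbest`/`gbest` update only on strict improvement, making tie
  behaviour deterministic; the gbest sequence is non-increasing by
  construction.
- Serialization is versioned JSON (trees as nested objects); loading a
  bundle reproduces predictions bit-identically, which the test suite
  asserts.

## Known limitations

- Training is single-threaded; at the full default cohort size (~12.6k
  rows) an unpruned 50-tree forest takes tens of seconds.
- No missing-value handling inside trees (no fractional-instance routing);
  imputation happens once, upstream.
- Multiclass evaluation is one-vs-rest macro-averaging; the forest itself
  is natively multiclass but the headline metrics assume a declared
  positive class.
- The PSO tuner retrains a forest per (position, fold) evaluation; use
  small swarms/iteration counts on large tables.
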