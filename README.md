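# asvrf

A classification stack for tabular e-health data — glucose-monitoring-style
cohorts with a modest number of continuous characteristics, many repeated
readings per patient, and lots of missing values. It targets the setting
where a plain random forest suffers because uniformly random feature
subsampling keeps picking noisy or irrelevant columns.

The pipeline is:

1. **Preprocessing** — per-feature train-median imputation, then min–max
   normalization `D_nor = (D − D_min)/(D_max − D_min) · (new_max − new_min) + new_min`
   with defaults mapping into [0, 1]; statistics are fit on the training
   split only.
2. **Feature extraction (optional)** — linear discriminant analysis: solve
   the generalized eigenproblem `S_C w = ψ (S_V + rI) w` for the between-
   and within-class scatter matrices and project rows onto the top-L
   eigenvectors (`L ≤ min(n, a−1)`).
3. **Classification** — a weighted-subspace random forest of C4.5 trees:
   every feature is scored by the chi-squared statistic
   `χ² = Σ_ij (O_ij − e_ij)²/e_ij` of its (binned) contingency table
   against the label; the top `n' = round(β·n)` features are retained; each
   of `k` trees is grown on a bootstrap sample using `t = ⌊log₂ n'⌋ + 1`
   features drawn without replacement with probability proportional to
   their weights. Trees split by C4.5's gain ratio on midpoint thresholds
   and store Laplace-smoothed leaf probabilities; the ensemble predicts by
   probability averaging, `P(c_i|x) = (1/k) Σ_j P(c_i|x, h_j)`.
4. **Hyperparameter tuning (optional)** — particle swarm optimization with
   a linearly decaying inertia weight `w = w_max − (w_max − w_min)·iter/iter_max`
   minimizes stratified cross-validated misclassification over `(β, k)`.
5. **Evaluation** — confusion-matrix metrics (accuracy, precision,
   sensitivity = recall, specificity, F1, Cohen's kappa, TP/FP rates) plus
   MAE/RMSE of the positive-class probabilities.

A seeded synthetic cohort generator with planted informative features and a
closed-form Bayes-error oracle makes every stage testable without any
clinical data.

## Worked example

```python
import numpy as np
from asvrf import (CohortSpec, PipelineConfig, generate_cohort,
                   run_evaluate, run_train, split_dataset)

ds, truth = generate_cohort(CohortSpec(readings_per_patient=40, seed=1))
sp = split_dataset(ds, test_fraction=0.25, seed=1)
bundle = run_train(PipelineConfig(seed=1, lda={"enabled": False}), sp.train, log=print)
report = run_evaluate(bundle, sp.test, positive_class="alarming")
print(f"accuracy {report.accuracy:.3f}  kappa {report.kappa:.3f}  "
      f"bayes ceiling {1 - truth['bayes_error']:.3f}")
```

prints

```
preprocess: fitting min-max normalizer (1860 rows, 20 features; impute=median)
forest: trained k=50 trees, beta=0.5, seed=329826294, oob_accuracy=0.8397849462365592
training completed in 4.625 s
accuracy 0.855  kappa 0.710  bayes ceiling 0.871
```

The cohort has 5 informative and 15 noise features with 20% of entries
missing; the forest's held-out accuracy (0.855) approaches but does not
exceed the generative model's Bayes-optimal accuracy (0.871), and kappa
0.710 is the same agreement corrected for chance. The chi-squared ranking
places the 5 planted features at the top, which is why the weighted forest
beats a single unpruned C4.5 tree (≈ 0.75 on the same split).

The same flow is available from the shell:

```bash
asvrf simulate --seed 1 --out cohort.csv --truth truth.json
asvrf train cohort.csv --seed 1 --out model.json
asvrf evaluate model.json cohort.csv --positive-class alarming
asvrf tune cohort.csv --seed 1          # PSO search over (beta, k)
asvrf predict model.json cohort.csv
```

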