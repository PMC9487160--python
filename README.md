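# elas — ensemble learning with active sampling

A meta-classifier for imbalanced binary clinical prediction. Training
builds a sequence of base classifiers (RBF-SVM, L2 logistic regression, or
CART) along an active-sampling curriculum: start from a class-balanced
seed, then repeatedly query the most informative pool samples by ranked
batch-mode scoring (uncertainty traded off against similarity to already
selected points) and retrain. The classifiers scoring best on held-out
internal-validation folds — across `n_folds` folds and `t_seed` independent
seed initializations — are averaged into a probability ensemble
(`n_folds × t_seed × k` members).

The package also ships:

- **cohort I/O + preprocessing** (`elas.cohort`): CSV/TSV cohorts with a
  YAML/JSON column-role schema; missing-row exclusion, one-hot encoding,
  quantile binning of continuous features, post-encoding low-variance
  filtering, optional standardization; horizon label derivation from
  disease-free/overall-survival follow-up (event within the closed horizon
  → positive, followed through → negative, lost to follow-up → excluded).
- **a synthetic imbalanced-cohort generator** (`elas.synthetic`) with a
  closed-form Bayes-optimal score for oracle checks, exact-prevalence mode,
  follow-up generation, and named prevalence presets (4.6%–51.9%).
- **an evaluation harness** (`elas.evaluation`): repeated stratified 80/20
  holdout, AUROC/AUPRC/sensitivity/specificity with mean ± SD, paired
  two-sided t-tests, and baselines (tuned single learners, AdaBoost,
  Bagging, SMOTE- and Tomek-links-resampled learners).

## CLI

All commands take a YAML run config (unknown keys are rejected) and write
their resolved config next to their outputs for reproducibility.

```sh
# generate a synthetic cohort (CSV + schema + ground truth)
elas simulate --config run.yaml --preset table1-1y-death --seed 1 -o out/

# train the ensemble and serialize the model
elas fit --config run.yaml --seed 1 -o out/

# score a cohort with a saved model
elas predict --model out/model.joblib --input cohort.csv \
    --schema schema.yaml -o predictions.csv

# repeated-holdout comparison against baselines
elas evaluate --config run.yaml --seed 1 -o out/
```

Example config:

```yaml
seed: 1
output_dir: out
cohort:
  path: cohort.csv
  schema: schema.yaml
  horizon: 1          # optional: derive labels from follow-up
  outcome: death
elas:
  learner: svm_rbf    # or {family: cart, grid: [{max_depth: 5, min_samples_leaf: 3}]}
  n_seed: 50          # balanced seed size (n_seed/2 per class)
  n_batch: 10         # samples queried per iteration
  t_seed: 3           # seed initializations per fold
  k: 20               # top classifiers kept per run
  n_folds: 5          # internal-validation folds
evaluate:
  methods: [elas, base_svm, adaboost, bagging, smote+svm_rbf, tomeklinks+svm_rbf]
  n_repeats: 10
```

## Python API

```python
from elas import ELASConfig, LearnerSpec, fit_elas
model = fit_elas(X, y, ELASConfig(learner=LearnerSpec("cart")))
proba = model.predict_proba(X_test)   # mean of member probabilities
```

`ELASClassifier` wraps the same procedure behind a scikit-learn-style
`fit/predict_proba/predict` contract.

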