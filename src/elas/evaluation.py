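"""Evaluation protocol: metrics, repeated holdout, paired tests, baselines.

Repeated stratified 80/20 holdout fits every method on the same train split
per repeat and scores the same test split; AUROC/AUPRC (and sensitivity/
specificity at a threshold) are aggregated as mean +/- SD, and paired
two-sided t-tests compare methods repeat-by-repeat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from elas import resampling
from elas.learners import LearnerSpec, fit_base, make_estimator, tune

logger = logging.getLogger(__name__)

METRICS = ("auroc", "auprc", "sensitivity", "specificity")


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney, tie-corrected)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, non-interpolated)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def sens_spec(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """(sensitivity, specificity) of thresholded scores."""
    labels = _check_two_classes(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    pos = labels == 1
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[~pos]).mean())
    return sensitivity, specificity


def paired_t_test(values_a, values_b) -> float:
    """Two-sided paired t-test p-value over per-repeat metric values.

    Zero-variance differences are degenerate: p = 1.0 (with a warning) when
    the sequences are identical, p = 0.0 when one is a constant nonzero
    shift of the other.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            warnings.warn("identical paired values; p-value degenerate (1.0)")
            return 1.0
        warnings.warn(
            "constant nonzero paired differences; p-value degenerate (0.0)"
        )
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class EvaluationReport:
    """Per-repeat metric values with mean/SD summaries and pairwise p-values."""

    per_repeat: pd.DataFrame  # columns: repeat, seed, method, metric, value
    summary: pd.DataFrame  # columns: method, metric, mean, sd, n_repeats
    t_tests: pd.DataFrame  # columns: metric, method_a, method_b, p_value, significant
    repeat_seeds: list[int] = field(default_factory=list)

    def to_csv(self, prefix: str) -> None:
        self.per_repeat.to_csv(f"{prefix}_per_repeat.csv", index=False)
        self.summary.to_csv(f"{prefix}_summary.csv", index=False)
        self.t_tests.to_csv(f"{prefix}_t_tests.csv", index=False)

    def format_summary(self) -> str:
        lines = ["method".ljust(24) + "".join(m.rjust(22) for m in METRICS)]
        for method in self.summary["method"].unique():
            row = [method.ljust(24)]
            sub = self.summary[self.summary["method"] == method]
            for metric in METRICS:
                cell = sub[sub["metric"] == metric]
                if len(cell):
                    mean, sd = cell["mean"].iloc[0], cell["sd"].iloc[0]
                    row.append(f"{mean:.3f} +/- {sd:.3f}".rjust(22))
                else:
                    row.append("-".rjust(22))
            lines.append("".join(row))
        return "\n".join(lines)


class TunedBaseLearner:
    """Grid-search-tuned single base classifier (estimator contract)."""

    def __init__(self, spec: LearnerSpec, seed: int = 0, tune_folds: int = 5,
                 tune_metric: str = "auroc"):
        self.spec = spec
        self.seed = seed
        self.tune_folds = tune_folds
        self.tune_metric = tune_metric
        self.chosen_params_: dict | None = None

    def fit(self, X, y):
        self.chosen_params_ = tune(self.spec, X, y, n_folds=self.tune_folds,
                                   metric=self.tune_metric, seed=self.seed)
        self.model_ = fit_base(self.spec, self.chosen_params_, X, y, self.seed)
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ResampledLearner:
    """Resample the training set (SMOTE or Tomek links), then fit a learner."""

    def __init__(self, sampler: str, spec: LearnerSpec, seed: int = 0):
        if sampler not in ("smote", "tomeklinks"):
            raise ValueError(f"unknown sampler {sampler!r}")
        self.sampler = sampler
        self.inner = TunedBaseLearner(spec, seed=seed)
        self.seed = seed

    def fit(self, X, y):
        if self.sampler == "smote":
            Xr, yr = resampling.smote(X, y, seed=self.seed)
        else:
            Xr, yr = resampling.tomek_links(X, y)
        self.resampled_shape_ = (len(yr), int(np.bincount(yr, minlength=2)[1]))
        self.inner.fit(Xr, yr)
        return self

    def predict_proba(self, X):
        return self.inner.predict_proba(X)

    def predict(self, X):
        return self.inner.predict(X)


def _baseline_factory(name: str, spec: LearnerSpec, seed: int):
    base_map = {"base_svm": "svm_rbf", "base_logreg": "logreg_l2",
                "base_cart": "cart"}
    if name in base_map:
        return TunedBaseLearner(LearnerSpec(base_map[name]), seed=seed)
    if name == "adaboost":
        return AdaBoostClassifier(
            estimator=make_estimator(spec.family, spec.grid[0], seed),
            n_estimators=50, random_state=seed,
        )
    if name == "bagging":
        return BaggingClassifier(
            estimator=make_estimator(spec.family, spec.grid[0], seed),
            n_estimators=50, random_state=seed,
        )
    if "+" in name:
        sampler, family = name.split("+", 1)
        if sampler in ("smote", "tomeklinks") and family in (
            "svm_rbf", "logreg_l2", "cart",
        ):
            return ResampledLearner(sampler, LearnerSpec(family), seed=seed)
    raise ValueError(f"unknown baseline roster name {name!r}")


def run_baselines(
    X: np.ndarray,
    y: np.ndarray,
    roster: list[str],
    seed: int = 0,
    spec: LearnerSpec | None = None,
) -> dict[str, object]:
    """Fit each named baseline on (X, y); returns name -> fitted model.

    Roster names: ``base_svm``, ``base_logreg``, ``base_cart``,
    ``adaboost``, ``bagging``, ``smote+<family>``, ``tomeklinks+<family>``.
    The ensemble baselines wrap the given learner spec's first grid point.
    """
    spec = spec if spec is not None else LearnerSpec("cart")
    out = {}
    for name in roster:
        model = _baseline_factory(name, spec, seed)
        model.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        out[name] = model
    return out


def repeated_holdout(
    X: np.ndarray,
    y: np.ndarray,
    methods: dict[str, callable],
    n_repeats: int = 10,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Repeated stratified holdout evaluation.

    ``methods`` maps a name to a factory ``(seed) -> estimator`` (objects
    with fit/predict_proba).  Every method sees the same split per repeat.
    A failing method is excluded from that repeat with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    seeds = [int(s) for s in
             np.random.SeedSequence(master_seed).generate_state(n_repeats)]
    rows = []
    for r, seed in enumerate(seeds):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y,
            random_state=seed % (2**32),
        )
        for name, factory in methods.items():
            try:
                model = factory(seed)
                model.fit(X_tr, y_tr)
                p = model.predict_proba(X_te)[:, 1]
            except Exception as exc:
                warnings.warn(f"method {name!r} failed on repeat {r}: {exc}")
                logger.warning("method %r failed on repeat %d: %s", name, r, exc)
                continue
            sens, spec_ = sens_spec(p, y_te, threshold)
            for metric, value in (
                ("auroc", auroc(p, y_te)),
                ("auprc", auprc(p, y_te)),
                ("sensitivity", sens),
                ("specificity", spec_),
            ):
                rows.append({"repeat": r, "seed": seed, "method": name,
                             "metric": metric, "value": value})
    per_repeat = pd.DataFrame(rows)

    summary_rows = []
    for (method, metric), grp in per_repeat.groupby(["method", "metric"],
                                                    sort=False):
        vals = grp["value"].to_numpy()
        summary_rows.append({
            "method": method, "metric": metric,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_repeats": len(vals),
        })
    summary = pd.DataFrame(summary_rows)

    t_rows = []
    names = list(methods)
    for metric in ("auroc", "auprc"):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                va = per_repeat.query("method == @a and metric == @metric")
                vb = per_repeat.query("method == @b and metric == @metric")
                merged = va.merge(vb, on="repeat", suffixes=("_a", "_b"))
                if len(merged) < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = paired_t_test(merged["value_a"], merged["value_b"])
                t_rows.append({"metric": metric, "method_a": a, "method_b": b,
                               "p_value": p, "significant": p < 0.05})
    t_tests = pd.DataFrame(
        t_rows, columns=["metric", "method_a", "method_b", "p_value",
                         "significant"],
    )
    return EvaluationReport(per_repeat=per_repeat, summary=summary,
                            t_tests=t_tests, repeat_seeds=seeds)
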