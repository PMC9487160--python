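"""Synthetic imbalanced clinical-like cohorts with known ground truth.

The signal model is class-conditional: informative continuous features are
Gaussian with a class-dependent mean shift, informative categorical
features have exponentially tilted level frequencies in the positive class.
This gives a closed-form Bayes-optimal score (a log-likelihood ratio,
linear in the continuous features) used by oracle checks.  Follow-up
records are generated so horizon label derivation reproduces configurable
per-horizon event fractions, with optional early censoring to exercise the
exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from elas.cohort import Cohort, Schema

#: prevalences of the six prognostic tasks shipped as named presets
PRESETS: dict[str, float] = {
    "table1-1y-recurrence": 0.076,
    "table1-1y-death": 0.046,
    "table1-3y-recurrence": 0.291,
    "table1-3y-death": 0.218,
    "table1-5y-recurrence": 0.519,
    "table1-5y-death": 0.437,
}


@dataclass
class SimSpec:
    """Parameters of the synthetic cohort generator."""

    n: int = 1000
    prevalence: float = 0.1
    n_continuous: int = 5
    n_categorical: int = 3
    n_levels: int = 3
    n_informative: int = 4
    effect_size: float = 1.0
    noise_sd: float = 1.0
    exact: bool = True
    censor_frac: float = 0.0
    horizon_rates: dict[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_informative > self.n_continuous + self.n_categorical:
            raise ValueError("n_informative exceeds the total feature count")
        if not 0.0 <= self.censor_frac <= 1.0:
            raise ValueError("censor_frac must lie in [0, 1]")
        if self.n_levels < 2:
            raise ValueError("categorical features need >= 2 levels")
        if self.horizon_rates is not None:
            items = sorted(self.horizon_rates.items())
            rates = [r for _, r in items]
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError("horizon rates must lie in [0, 1]")
            if any(b < a for a, b in zip(rates, rates[1:])):
                raise ValueError(
                    "horizon_rates must be non-decreasing in the horizon "
                    "(cumulative event fractions)"
                )


def _categorical_level_probs(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """(negative-class, positive-class) level probabilities."""
    L = spec.n_levels
    p_neg = np.full(L, 1.0 / L)
    tilt = np.exp(spec.effect_size * np.arange(L) / (L - 1))
    p_pos = tilt / tilt.sum()
    return p_neg, p_pos


def generate_cohort(spec: SimSpec) -> tuple[Cohort, dict]:
    """Generate a cohort and the ground truth that produced it.

    The first ``min(n_informative, n_continuous)`` continuous features get
    a positive-class mean shift of ``effect_size``; remaining informative
    slots go to categorical features with tilted positive-class level
    frequencies.  In exact mode the positive count is forced to
    ``round(n * prevalence)``.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.exact:
        n_pos = int(round(spec.n * spec.prevalence))
        if n_pos < 1:
            raise ValueError(
                f"exact mode infeasible: round(n * prevalence) = {n_pos} < 1"
            )
        if n_pos >= spec.n:
            raise ValueError("exact mode infeasible: no negatives left")
        y = np.zeros(spec.n, dtype=int)
        y[rng.choice(spec.n, size=n_pos, replace=False)] = 1
    else:
        y = (rng.random(spec.n) < spec.prevalence).astype(int)

    n_cont_inf = min(spec.n_informative, spec.n_continuous)
    n_cat_inf = spec.n_informative - n_cont_inf

    cols: dict[str, np.ndarray] = {}
    cont_shifts = np.zeros(spec.n_continuous)
    cont_shifts[:n_cont_inf] = spec.effect_size
    for j in range(spec.n_continuous):
        cols[f"cont_{j}"] = rng.normal(y * cont_shifts[j], spec.noise_sd)

    p_neg, p_pos = _categorical_level_probs(spec)
    levels = np.array([f"L{i}" for i in range(spec.n_levels)])
    cat_informative = np.zeros(spec.n_categorical, dtype=bool)
    cat_informative[:n_cat_inf] = True
    for j in range(spec.n_categorical):
        if cat_informative[j]:
            draws = np.where(
                y == 1,
                rng.choice(spec.n_levels, size=spec.n, p=p_pos),
                rng.choice(spec.n_levels, size=spec.n, p=p_neg),
            )
        else:
            draws = rng.integers(0, spec.n_levels, size=spec.n)
        cols[f"cat_{j}"] = levels[draws]

    feature_order = [f"cat_{j}" for j in range(spec.n_categorical)] + [
        f"cont_{j}" for j in range(spec.n_continuous)
    ]
    features = pd.DataFrame(cols)[feature_order]
    schema = Schema(
        id="patient_id",
        categorical=[f"cat_{j}" for j in range(spec.n_categorical)],
        continuous=[f"cont_{j}" for j in range(spec.n_continuous)],
        label="event",
    )
    cohort = Cohort(
        features=features,
        schema=schema,
        ids=pd.Series([f"P{i:06d}" for i in range(spec.n)], name="patient_id"),
        labels=y,
    )
    ground_truth = {
        "continuous_shifts": cont_shifts.tolist(),
        "noise_sd": spec.noise_sd,
        "categorical_informative": cat_informative.tolist(),
        "level_probs_negative": p_neg.tolist(),
        "level_probs_positive": p_pos.tolist(),
        "prevalence": spec.prevalence,
        # LLR coefficients of the continuous block (equal-variance Gaussians)
        "bayes_coefficients": (cont_shifts / spec.noise_sd**2).tolist(),
    }
    return cohort, ground_truth


def bayes_scores(cohort: Cohort, ground_truth: dict) -> np.ndarray:
    """Log-likelihood-ratio score of each row under the true generative model."""
    shifts = np.asarray(ground_truth["continuous_shifts"])
    sd = ground_truth["noise_sd"]
    coef = shifts / sd**2
    schema = cohort.schema
    Xc = cohort.features[schema.continuous].to_numpy(dtype=float)
    # Gaussian LLR: sum_j coef_j * (x_j - shift_j / 2)
    score = (Xc - shifts / 2.0) @ coef

    p_neg = np.asarray(ground_truth["level_probs_negative"])
    p_pos = np.asarray(ground_truth["level_probs_positive"])
    log_ratio = np.log(p_pos) - np.log(p_neg)
    for j, informative in enumerate(ground_truth["categorical_informative"]):
        if not informative:
            continue
        vals = cohort.features[schema.categorical[j]].astype(str)
        level_idx = vals.str.removeprefix("L").astype(int).to_numpy()
        score = score + log_ratio[level_idx]
    return score


def generate_followup(cohort: Cohort, spec: SimSpec) -> pd.DataFrame:
    """Generate follow-up records consistent with per-horizon event rates.

    ``spec.horizon_rates`` maps horizons (years) to cumulative event
    fractions; when absent, the cohort's own labels define a single 1-year
    horizon.  A ``censor_frac`` share of event-free patients get a last
    contact uniformly before the longest horizon (they are excluded by
    label derivation at later horizons).  Identical DFS and OS processes
    are drawn independently.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = cohort.n
    if spec.horizon_rates is not None:
        horizons = sorted(spec.horizon_rates)
        rates = [spec.horizon_rates[h] for h in horizons]
    elif cohort.labels is not None:
        horizons = [1.0]
        rates = [float(np.mean(cohort.labels))]
    else:
        raise ValueError("need horizon_rates or cohort labels")
    max_months = 12.0 * horizons[-1]

    def one_process(labels_first_band: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        times = np.empty(n)
        events = np.zeros(n, dtype=int)
        u = rng.random(n)
        prev_rate, prev_months = 0.0, 0.0
        assigned = np.zeros(n, dtype=bool)
        if labels_first_band is not None:
            # honor the cohort's own labels for the first horizon band
            band = labels_first_band == 1
            times[band] = rng.uniform(0.0, 12.0 * horizons[0], size=band.sum())
            events[band] = 1
            assigned |= band
            prev_rate, prev_months = rates[0], 12.0 * horizons[0]
            bands = zip(horizons[1:], rates[1:])
        else:
            bands = zip(horizons, rates)
        for h, r in bands:
            months = 12.0 * h
            band = (~assigned) & (u >= prev_rate) & (u < r)
            times[band] = rng.uniform(prev_months, months, size=band.sum())
            events[band] = 1
            assigned |= band
            prev_rate, prev_months = r, months
        # event-free: followed beyond the longest horizon ...
        free = ~assigned & ~(events == 1)
        times[free] = max_months + rng.uniform(1.0, 24.0, size=free.sum())
        # ... except a censored share with early last contact
        if spec.censor_frac > 0:
            free_idx = np.flatnonzero(free)
            n_censor = int(round(spec.censor_frac * len(free_idx)))
            censored = rng.choice(free_idx, size=n_censor, replace=False)
            times[censored] = rng.uniform(0.0, max_months, size=n_censor)
        return times, events

    labels = cohort.labels if spec.horizon_rates is None else None
    dfs_time, dfs_event = one_process(labels)
    os_time, os_event = one_process(labels)
    return pd.DataFrame({
        "dfs_time": dfs_time,
        "dfs_event": dfs_event,
        "os_time": os_time,
        "os_event": os_event,
    })
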