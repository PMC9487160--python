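"""Tabular cohort I/O, clinical preprocessing, and horizon label derivation.

Cohorts are delimited text tables (one row per patient) with a schema that
declares column roles.  Preprocessing follows clinical-tabular conventions:
rows with missing feature values are excluded, categorical features are
one-hot encoded, continuous features are binned into intervals, and
post-encoding columns with variance below a threshold are dropped.
Horizon labels are derived from follow-up data: an event at or before the
horizon is positive, event-free follow-up through the horizon is negative,
and event-free patients lost to follow-up within the horizon are excluded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PREPROCESS_FORMAT_VERSION = 1

#: canonical follow-up column names (times in months, flags in {0,1})
FOLLOWUP_COLUMNS = ("dfs_time", "dfs_event", "os_time", "os_event")

OUTCOME_COLUMNS = {
    "recurrence": ("dfs_time", "dfs_event"),
    "death": ("os_time", "os_event"),
}


class SchemaError(ValueError):
    """Schema is malformed or does not match the data file."""


@dataclass
class Schema:
    """Column-role declaration for a cohort file.

    Parameters
    ----------
    id : str
        Name of the row-identifier column.
    categorical, continuous : list of str
        Feature columns by type.
    label : str, optional
        Pre-computed binary label column.
    dfs_time, dfs_event, os_time, os_event : str, optional
        Follow-up columns (times in months, event flags in {0, 1}).
    """

    id: str
    categorical: list[str] = field(default_factory=list)
    continuous: list[str] = field(default_factory=list)
    label: str | None = None
    dfs_time: str | None = None
    dfs_event: str | None = None
    os_time: str | None = None
    os_event: str | None = None

    def __post_init__(self) -> None:
        overlap = set(self.categorical) & set(self.continuous)
        if overlap:
            raise SchemaError(
                f"columns declared both categorical and continuous: {sorted(overlap)}"
            )

    @property
    def feature_columns(self) -> list[str]:
        return list(self.categorical) + list(self.continuous)

    @property
    def followup_columns(self) -> dict[str, str]:
        """Mapping canonical follow-up name -> declared column name."""
        out = {}
        for name in FOLLOWUP_COLUMNS:
            col = getattr(self, name)
            if col is not None:
                out[name] = col
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        known = {
            "id", "categorical", "continuous", "label",
            "dfs_time", "dfs_event", "os_time", "os_event",
        }
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        if "id" not in d:
            raise SchemaError("schema must declare an 'id' column")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in {".yaml", ".yml"}:
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        if not isinstance(d, dict):
            raise SchemaError(f"schema file {path} does not contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = {"id": self.id, "categorical": list(self.categorical),
             "continuous": list(self.continuous)}
        for name in ("label",) + FOLLOWUP_COLUMNS:
            val = getattr(self, name)
            if val is not None:
                d[name] = val
        return d

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in {".yaml", ".yml"}:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)


@dataclass
class Cohort:
    """A patient cohort: features, optional labels, optional follow-up.

    ``features`` holds the raw (pre-encoding) feature table in file order;
    ``followup``, when present, uses the canonical columns ``dfs_time``,
    ``dfs_event``, ``os_time``, ``os_event`` (times in months).
    """

    features: pd.DataFrame
    schema: Schema
    ids: pd.Series
    labels: np.ndarray | None = None
    followup: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ids.duplicated().any():
            dupes = self.ids[self.ids.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate ids in cohort: {dupes}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            bad = ~np.isin(self.labels[~pd.isna(self.labels)], [0, 1])
            if bad.any():
                raise ValueError("labels must be binary (0/1)")
        if self.followup is not None:
            for col in self.followup.columns:
                if col.endswith("_time"):
                    times = self.followup[col].dropna()
                    if (times < 0).any():
                        raise ValueError(f"negative follow-up time in {col}")
                if col.endswith("_event"):
                    flags = self.followup[col].dropna()
                    if not np.isin(flags, [0, 1]).all():
                        raise ValueError(f"non-binary event flag in {col}")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def p(self) -> int:
        return self.features.shape[1]


def read_cohort(path: str | Path, schema: Schema | str | Path) -> Cohort:
    """Read a delimited cohort file (CSV or TSV, header required).

    Columns not declared in the schema are ignored.  Raises on a missing
    declared column or a non-numeric value in a continuous column.
    """
    if not isinstance(schema, Schema):
        schema = Schema.from_file(schema)
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise ValueError(f"could not parse {path}: {exc}") from exc

    declared = (
        [schema.id]
        + schema.feature_columns
        + ([schema.label] if schema.label else [])
        + list(schema.followup_columns.values())
    )
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"declared columns absent from {path.name}: {missing}")

    for col in schema.continuous:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in continuous column {col!r}: "
                f"{df.loc[bad, col].iloc[0]!r}"
            )
        df[col] = coerced

    features = df[schema.feature_columns].copy()
    features[schema.categorical] = features[schema.categorical].astype("object")
    labels = df[schema.label].to_numpy() if schema.label else None
    followup = None
    fu_cols = schema.followup_columns
    if fu_cols:
        followup = df[list(fu_cols.values())].copy()
        followup.columns = list(fu_cols.keys())
    return Cohort(features=features, schema=schema, ids=df[schema.id],
                  labels=labels, followup=followup)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.DataFrame({cohort.schema.id: cohort.ids})
    df = pd.concat([df, cohort.features.reset_index(drop=True)], axis=1)
    if cohort.labels is not None and cohort.schema.label:
        df[cohort.schema.label] = cohort.labels
    if cohort.followup is not None:
        for canon, col in cohort.schema.followup_columns.items():
            df[col] = cohort.followup[canon].to_numpy()
    df.to_csv(path, sep=sep, index=False)


def derive_labels(
    followup: pd.DataFrame,
    horizon: float,
    outcome: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive binary labels at a prognostic horizon from follow-up records.

    Parameters
    ----------
    followup : DataFrame
        Canonical follow-up columns; times in months.
    horizon : float
        Horizon in years (typically 1, 3, or 5).
    outcome : {"recurrence", "death"}

    Returns
    -------
    labels : int array of length N
        1 if the event occurred at or before the horizon (closed interval),
        0 otherwise.  Entries where ``included`` is False are 0 and
        meaningless.
    included : bool array of length N
        False for event-free patients whose last contact precedes the
        horizon (lost to follow-up within the period).
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {sorted(OUTCOME_COLUMNS)}"
        )
    time_col, event_col = OUTCOME_COLUMNS[outcome]
    for col in (time_col, event_col):
        if col not in followup.columns:
            raise ValueError(f"follow-up table lacks column {col!r}")
    times = followup[time_col].to_numpy(dtype=float)
    events = followup[event_col].to_numpy(dtype=float)
    if np.isnan(times).any() or np.isnan(events).any():
        raise ValueError("missing follow-up values; exclude such rows first")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    horizon_months = 12.0 * float(horizon)

    # event at or before the horizon counts as within the period
    positive = (events == 1) & (times <= horizon_months)
    followed_through = times >= horizon_months
    included = positive | followed_through
    labels = positive.astype(int)
    return labels, included


@dataclass
class PreprocessState:
    """Frozen preprocessing state; applying it is deterministic.

    ``columns`` is the ordered list of retained post-encoding columns.
    One-hot columns are named ``"<feature>=<level>"``; continuous features
    keep their name and carry an ordinal bin index.  ``center``/``scale``
    allow optional standardization of the encoded matrix (used before SVM
    training and Euclidean similarity, where scaling matters).
    """

    variance_threshold: float
    n_bins: int
    categorical_level_maps: dict[str, list]
    bin_edges: dict[str, list[float]]
    columns: list[str]
    dropped_feature_names: list[str]
    center: list[float]
    scale: list[float]
    format_version: int = PREPROCESS_FORMAT_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "format_version": self.format_version,
                "variance_threshold": self.variance_threshold,
                "n_bins": self.n_bins,
                "categorical_level_maps": {
                    k: [str(v) for v in vals]
                    for k, vals in self.categorical_level_maps.items()
                },
                "bin_edges": self.bin_edges,
                "columns": self.columns,
                "dropped_feature_names": self.dropped_feature_names,
                "center": self.center,
                "scale": self.scale,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "PreprocessState":
        if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc
                                     and Path(doc).exists()):
            doc = Path(doc).read_text()
        d = json.loads(doc)
        version = d.pop("format_version", None)
        if version != PREPROCESS_FORMAT_VERSION:
            raise ValueError(f"unsupported preprocess state version: {version}")
        return cls(format_version=PREPROCESS_FORMAT_VERSION, **d)


def drop_missing_rows(cohort: Cohort) -> Cohort:
    """Return the cohort restricted to rows with no missing feature value."""
    mask = cohort.features.notna().all(axis=1).to_numpy()
    if mask.all():
        return cohort
    return Cohort(
        features=cohort.features.loc[mask].reset_index(drop=True),
        schema=cohort.schema,
        ids=cohort.ids.loc[mask].reset_index(drop=True),
        labels=None if cohort.labels is None else cohort.labels[mask],
        followup=None if cohort.followup is None
        else cohort.followup.loc[mask].reset_index(drop=True),
    )


def _encode(
    features: pd.DataFrame,
    schema: Schema,
    level_maps: dict[str, list],
    bin_edges: dict[str, list[float]],
    *,
    warn_unseen: bool,
) -> pd.DataFrame:
    blocks: list[pd.DataFrame] = []
    for col in schema.categorical:
        levels = level_maps[col]
        vals = features[col].astype(str)
        onehot = pd.DataFrame(
            {f"{col}={lvl}": (vals == str(lvl)).astype(float) for lvl in levels}
        )
        if warn_unseen:
            unseen = ~vals.isin([str(lvl) for lvl in levels])
            if unseen.any():
                examples = sorted(set(vals[unseen]))[:3]
                warnings.warn(
                    f"unseen level(s) {examples} in categorical feature "
                    f"{col!r}; encoded as all-zero",
                    stacklevel=3,
                )
                logger.warning(
                    "unseen categorical level(s) %s in %r mapped to zero block",
                    examples, col,
                )
        blocks.append(onehot)
    for col in schema.continuous:
        edges = np.asarray(bin_edges[col], dtype=float)
        vals = features[col].to_numpy(dtype=float)
        # interior edges only; values outside fitted range clip to end bins
        idx = np.searchsorted(edges, vals, side="right").astype(float)
        blocks.append(pd.DataFrame({col: idx}))
    if not blocks:
        return pd.DataFrame(index=features.index)
    return pd.concat([b.set_index(features.index) for b in blocks], axis=1)


def fit_preprocess(
    cohort: Cohort,
    variance_threshold: float = 0.01,
    n_bins: int = 4,
) -> PreprocessState:
    """Fit preprocessing state on a cohort.

    Rows with any missing feature value are excluded from fitting.
    Continuous features get equal-frequency (quantile) bin edges; the
    variance filter runs on the post-encoding columns.
    """
    if cohort.n < 2:
        raise ValueError("need at least 2 rows to fit preprocessing")
    fit_cohort = drop_missing_rows(cohort)
    if fit_cohort.n == 0:
        raise ValueError("all rows contain missing values; nothing to fit on")
    schema = cohort.schema

    level_maps: dict[str, list] = {}
    for col in schema.categorical:
        level_maps[col] = sorted(fit_cohort.features[col].astype(str).unique())

    bin_edges: dict[str, list[float]] = {}
    for col in schema.continuous:
        vals = fit_cohort.features[col].to_numpy(dtype=float)
        qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1)[1:-1])
        bin_edges[col] = np.unique(qs).tolist()

    encoded = _encode(fit_cohort.features, schema, level_maps, bin_edges,
                      warn_unseen=False)
    variances = encoded.var(axis=0, ddof=1)
    keep = variances >= variance_threshold
    columns = [c for c in encoded.columns if keep[c]]
    dropped = [c for c in encoded.columns if not keep[c]]
    if not columns:
        raise ValueError("variance filter removed every column")

    retained = encoded[columns]
    center = retained.mean(axis=0).to_numpy()
    scale = retained.std(axis=0, ddof=1).to_numpy()
    scale[scale == 0] = 1.0

    return PreprocessState(
        variance_threshold=variance_threshold,
        n_bins=n_bins,
        categorical_level_maps=level_maps,
        bin_edges=bin_edges,
        columns=columns,
        dropped_feature_names=dropped,
        center=center.tolist(),
        scale=scale.tolist(),
    )


def apply_preprocess(
    cohort: Cohort,
    state: PreprocessState,
    *,
    standardize: bool = False,
) -> np.ndarray:
    """Encode a cohort with a fitted state into a fully numeric matrix.

    Row count is preserved; rows must be complete (no missing feature
    values).  Unseen categorical levels map to an all-zero one-hot block
    with a warning.  With ``standardize=True`` the stored per-column
    center/scale is applied (required before SVM training and Euclidean
    similarity computation).
    """
    if cohort.features.isna().any().any():
        raise ValueError(
            "cohort contains missing feature values; drop such rows before "
            "applying preprocessing"
        )
    encoded = _encode(cohort.features, cohort.schema,
                      state.categorical_level_maps, state.bin_edges,
                      warn_unseen=True)
    missing_cols = [c for c in state.columns if c not in encoded.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks fitted columns: {missing_cols}")
    X = encoded[state.columns].to_numpy(dtype=float)
    if standardize:
        X = (X - np.asarray(state.center)) / np.asarray(state.scale)
    return X
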