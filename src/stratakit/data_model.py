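"""Ingestion of clinical tables: feature typing, one-hot encoding, scenarios.

A study starts from a rectangular patient x feature table holding a mix of
binary, categorical and numeric columns, possibly with missing values.
This module classifies columns, expands categoricals into indicator
columns, tracks the missingness mask, and decides which of three analysis
scenarios applies:

* ``complete``         -- no missing values;
* ``impute_internal``  -- missing values imputed here with chained
  equations (m completed copies);
* ``impute_external``  -- the caller supplies m pre-imputed complete
  copies of the table.

The held-out label column, when present, is removed from every matrix the
downstream analysis sees and kept only for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("binary", "categorical", "numeric")

__all__ = [
    "FeatureSpec",
    "StudyMatrix",
    "ImputationStack",
    "classify_features",
    "one_hot_encode",
    "create_study",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Type assignment for one input column.

    ``levels`` records the ordered category labels for categorical
    features; for binary features it records the two observed values (the
    first maps to 0, the second to 1 at encoding time).
    """

    name: str
    kind: str  # one of KINDS
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError(f"binary feature {self.name!r} needs exactly 2 levels")
        if self.kind == "categorical" and len(self.levels) < 3:
            raise ValueError(f"categorical feature {self.name!r} needs >=3 levels")


@dataclass
class StudyMatrix:
    """Canonical analysis container: raw table, encoded matrix, metadata."""

    samples: list
    raw: pd.DataFrame
    encoded: pd.DataFrame  # patients x encoded columns; NaN where raw missing
    mask: pd.DataFrame  # aligned to raw; True = missing
    specs: list
    labels: pd.Series | None = None
    scenario: str = "complete"  # complete | impute_internal | impute_external

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_names(self) -> list:
        return [s.name for s in self.specs]


@dataclass
class ImputationStack:
    """m complete encoded copies of the study matrix.

    Invariant: every dataset is complete, and observed cells equal the
    original values in all m copies.
    """

    m: int
    datasets: list = field(default_factory=list)  # list of encoded DataFrames
    provenance: str = "internal"  # internal | external


def _sorted_levels(values) -> tuple:
    # stable ordering of observed levels; mixed types fall back to str order
    uniq = pd.unique(values)
    try:
        return tuple(sorted(uniq))
    except TypeError:
        return tuple(sorted(uniq, key=str))


def classify_features(raw: pd.DataFrame, overrides: dict | None = None) -> list:
    """Assign each column a kind: binary, categorical, or numeric.

    Inference ignores missing cells: <=2 distinct observed values means
    binary; non-numeric columns are categorical; everything else numeric.
    An explicit ``overrides`` entry {column: kind} always wins, e.g. to
    force an integer-coded column with few distinct values into
    ``categorical``.
    """
    overrides = overrides or {}
    if raw.shape[1] < 2:
        raise ValueError("at least 2 feature columns are required")
    if raw.shape[0] < 3:
        raise ValueError("at least 3 rows are required")
    specs = []
    for col in raw.columns:
        observed = raw[col].dropna()
        nuniq = observed.nunique()
        if nuniq < 2:
            raise ValueError(f"constant feature: {col!r} has a single observed value")
        kind = overrides.get(col)
        if kind is None:
            if nuniq == 2:
                kind = "binary"
            elif pd.api.types.is_numeric_dtype(observed):
                kind = "numeric"
            else:
                kind = "categorical"
        if kind not in KINDS:
            raise ValueError(f"invalid kind override {kind!r} for column {col!r}")
        if kind == "numeric":
            vals = pd.to_numeric(observed, errors="coerce")
            if vals.isna().any() or not np.isfinite(vals.to_numpy()).all():
                raise ValueError(f"column {col!r} declared numeric but has non-finite values")
            specs.append(FeatureSpec(col, "numeric"))
        else:
            specs.append(FeatureSpec(col, kind, _sorted_levels(observed)))
    return specs


def one_hot_encode(raw: pd.DataFrame, specs: list) -> pd.DataFrame:
    """Expand the raw table into an all-numeric matrix.

    Numeric columns pass through; a binary column becomes one 0/1 column;
    a categorical column with L levels becomes L indicator columns named
    ``col=level``. A missing raw cell propagates NaN to every column it
    produces. Values unseen at classification time are rejected.
    """
    cols: dict[str, pd.Series] = {}
    for spec in specs:
        s = raw[spec.name]
        missing = s.isna()
        if spec.kind == "numeric":
            cols[spec.name] = pd.to_numeric(s, errors="raise").astype(float)
        elif spec.kind == "binary":
            observed = s[~missing]
            unseen = set(pd.unique(observed)) - set(spec.levels)
            if unseen:
                raise ValueError(f"unseen level(s) {unseen!r} in binary column {spec.name!r}")
            enc = s.map({spec.levels[0]: 0.0, spec.levels[1]: 1.0})
            enc[missing] = np.nan
            cols[spec.name] = enc.astype(float)
        else:
            observed = s[~missing]
            unseen = set(pd.unique(observed)) - set(spec.levels)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {unseen!r} in categorical column {spec.name!r}"
                )
            for level in spec.levels:
                ind = (s == level).astype(float)
                ind[missing] = np.nan
                cols[f"{spec.name}={level}"] = ind
    return pd.DataFrame(cols, index=raw.index)


def indicator_columns(specs: list) -> list:
    """Names of encoded columns constrained to [0, 1] (binary + indicators)."""
    out = []
    for spec in specs:
        if spec.kind == "binary":
            out.append(spec.name)
        elif spec.kind == "categorical":
            out.extend(f"{spec.name}={lv}" for lv in spec.levels)
    return out


def _impute_internal(encoded: pd.DataFrame, specs: list, m: int, seed: int) -> ImputationStack:
    """Chained-equations imputation producing m complete encoded copies."""
    # IterativeImputer is sklearn's MICE-style imputer; sample_posterior
    # draws distinct imputations per copy.
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    from ._seeds import STAGE_IMPUTE, as_int_seed, stream

    X = encoded.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    clip_cols = [encoded.columns.get_loc(c) for c in indicator_columns(specs)]
    datasets = []
    for i in range(m):
        imp = IterativeImputer(
            sample_posterior=True,
            random_state=as_int_seed(stream(seed, STAGE_IMPUTE, i)),
            max_iter=10,
        )
        Xi = imp.fit_transform(X)
        if Xi.shape != X.shape:  # a fully-missing column would be dropped
            raise ValueError("imputer dropped columns; check for fully-missing features")
        Xi[observed] = X[observed]  # exact observed-cell preservation
        if clip_cols:
            Xi[:, clip_cols] = np.clip(Xi[:, clip_cols], 0.0, 1.0)
        datasets.append(pd.DataFrame(Xi, index=encoded.index, columns=encoded.columns))
    return ImputationStack(m=m, datasets=datasets, provenance="internal")


def create_study(
    raw: pd.DataFrame,
    labels=None,
    *,
    label_column: str | None = None,
    overrides: dict | None = None,
    m: int | None = None,
    external_stack=None,
    seed: int = 0,
):
    """Build the :class:`StudyMatrix` (and :class:`ImputationStack` if needed).

    Parameters
    ----------
    raw : DataFrame
        Patients x features. Missing values as NaN.
    labels : Series, optional
        Held-out ground-truth labels, or use ``label_column`` to pull them
        out of ``raw`` (they never enter the encoded matrix).
    m : int, optional
        Number of internal chained-equations imputations when the table has
        missing values (the command-line runner defaults this to 5). If
        missingness is present and neither ``m`` nor ``external_stack`` is
        given, the table is rejected.
    external_stack : list of DataFrame, optional
        m complete copies of ``raw`` (same columns) imputed elsewhere.

    Returns
    -------
    (StudyMatrix, ImputationStack | None)
    """
    raw = raw.copy()
    if label_column is not None:
        if label_column not in raw.columns:
            raise ValueError(f"label column {label_column!r} not in table")
        labels = raw[label_column].copy()
        raw = raw.drop(columns=[label_column])
    if labels is not None:
        labels = pd.Series(labels, index=raw.index)

    specs = classify_features(raw, overrides)
    encoded = one_hot_encode(raw, specs)
    mask = raw.isna()
    has_missing = bool(mask.to_numpy().any())

    stack = None
    if external_stack is not None:
        datasets = []
        for i, ds in enumerate(external_stack):
            if ds.shape[0] != raw.shape[0]:
                raise ValueError(
                    f"external imputation {i} has {ds.shape[0]} rows, expected {raw.shape[0]}"
                )
            if list(ds.columns) != list(raw.columns):
                raise ValueError(f"external imputation {i} columns do not match the input table")
            if ds.isna().to_numpy().any():
                raise ValueError(f"external imputation {i} still contains missing values")
            ds = ds.copy()
            ds.index = raw.index
            enc = one_hot_encode(ds, specs)
            # observed cells must agree with the original
            obs = ~encoded.isna()
            if not np.allclose(
                enc.to_numpy()[obs.to_numpy()], encoded.to_numpy()[obs.to_numpy()]
            ):
                raise ValueError(f"external imputation {i} alters observed cells")
            datasets.append(enc)
        stack = ImputationStack(m=len(datasets), datasets=datasets, provenance="external")
        scenario = "impute_external"
    elif has_missing:
        if m is None:
            raise ValueError(
                "table has missing values: request internal imputation (m>=1) "
                "or supply an external imputation stack"
            )
        stack = _impute_internal(encoded, specs, m=int(m), seed=seed)
        scenario = "impute_internal"
    else:
        scenario = "complete"

    study = StudyMatrix(
        samples=list(raw.index),
        raw=raw,
        encoded=encoded,
        mask=mask,
        specs=specs,
        labels=labels,
        scenario=scenario,
    )
    return study, stack
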