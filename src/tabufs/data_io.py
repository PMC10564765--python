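"""Loading, cleaning, normalizing and partitioning tabular diagnosis datasets.

A dataset is an ``n x m`` numeric feature matrix with a binary label per case
(``1`` = positive / disease present, ``0`` = negative).  Files are delimited
text with a header row; a :class:`DatasetSchema` names the label column, the
raw value mapped to the positive class, the delimiter and the tokens treated
as missing.  Cleaning (dropping heavily-missing columns, then incomplete
rows) and normalization are explicit, separate steps so that fold-wise
pipelines can order them correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class DatasetSchema:
    """How to read a delimited file into a labelled dataset.

    Parameters
    ----------
    label_column
        Name (or integer position) of the column holding the class mark.
    positive_label
        Raw value in the label column mapped to the positive class.  It is
        never inferred from lexical order; it must be stated.
    delimiter
        Field separator, default comma.
    missing_markers
        Raw tokens treated as missing values (e.g. ``["NA", "?"]``).
    """

    label_column: str | int
    positive_label: object
    delimiter: str = ","
    missing_markers: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, path: str | Path) -> "DatasetSchema":
        """Read a schema from a YAML (or JSON) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            label_column=raw["label_column"],
            positive_label=raw["positive_label"],
            delimiter=raw.get("delimiter", ","),
            missing_markers=tuple(raw.get("missing_markers", ())),
        )


@dataclass
class Dataset:
    """An ``n x m`` feature matrix plus binary labels and feature names.

    ``features`` may contain NaN before :func:`clean_missing`; after
    preprocessing it must not.  Labels are ``{0, 1}`` with 1 = positive.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, m = self.features.shape
        if n < 2 or m < 1:
            raise ValueError(f"dataset too small: n={n}, m={m}")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of cases")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match m")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names must be unique")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def m(self) -> int:
        return self.features.shape[1]

    def take(self, indices: Sequence[int] | np.ndarray) -> "Dataset":
        """Row-subset view (copy) of the dataset, e.g. one CV fold."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(self.features[idx], self.labels[idx], list(self.feature_names))


@dataclass(frozen=True)
class FoldPlan:
    """A k-fold partition of case indices, reproducible from its seed."""

    k: int
    seed: int
    assignments: np.ndarray  # length-n fold id in 0..k-1

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        present = set(np.unique(a))
        if present != set(range(self.k)):
            raise ValueError("every fold id 0..k-1 must occur")
        sizes = np.bincount(a, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes may differ by at most 1")

    def splits(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_indices, test_indices) for each fold in order."""
        all_idx = np.arange(len(self.assignments))
        for fold in range(self.k):
            test = all_idx[self.assignments == fold]
            yield all_idx[self.assignments != fold], test

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"case_id": np.arange(len(self.assignments)), "fold": self.assignments}
        ).to_csv(path, index=False)


def load_dataset(path: str | Path, schema: DatasetSchema) -> Dataset:
    """Parse a delimited file into a :class:`Dataset` under ``schema``.

    Rows with missing feature values are retained (cleaning is a separate
    step); cells matching ``schema.missing_markers`` become NaN.  The label
    column must contain exactly two distinct values, one of them
    ``schema.positive_label``.
    """
    df = pd.read_csv(
        path,
        sep=schema.delimiter,
        na_values=list(schema.missing_markers),
        keep_default_na=False,
    )
    if isinstance(schema.label_column, int):
        if not 0 <= schema.label_column < df.shape[1]:
            raise ValueError(f"label column index {schema.label_column} out of range")
        label_name = df.columns[schema.label_column]
    else:
        if schema.label_column not in df.columns:
            raise ValueError(f"label column {schema.label_column!r} not in file")
        label_name = schema.label_column

    raw_labels = df[label_name]
    classes = raw_labels.dropna().unique()
    if len(classes) < 2:
        raise ValueError("single-class dataset: label column has fewer than two classes")
    if len(classes) > 2:
        raise ValueError(f"label column has {len(classes)} classes; expected two")
    pos = schema.positive_label
    if not (raw_labels == pos).any():
        # tolerate string/number type drift between config and file
        if (raw_labels.astype(str) == str(pos)).any():
            raw_labels = raw_labels.astype(str)
            pos = str(pos)
        else:
            raise ValueError(f"positive label {pos!r} absent from label column")

    labels = (raw_labels == pos).astype(int).to_numpy()
    feat = df.drop(columns=[label_name]).apply(pd.to_numeric, errors="raise")
    return Dataset(feat.to_numpy(dtype=float), labels, list(feat.columns))


def clean_missing(ds: Dataset, drop_worst_vars: int = 0) -> Dataset:
    """Drop the ``drop_worst_vars`` most-missing features, then incomplete cases.

    Ties in per-column missing counts are broken toward the lower column
    index.  After this step the dataset holds no missing cell.
    """
    if drop_worst_vars < 0:
        raise ValueError("drop_worst_vars must be >= 0")
    X = ds.features
    keep_cols = np.arange(ds.m)
    if drop_worst_vars > 0:
        counts = np.isnan(X).sum(axis=0)
        # stable sort on descending count -> lower index wins ties
        order = np.argsort(-counts, kind="stable")
        dropped = set(order[:drop_worst_vars].tolist())
        keep_cols = np.array([j for j in range(ds.m) if j not in dropped], dtype=int)
        if keep_cols.size == 0:
            raise ValueError("clean_missing removed every feature")
        X = X[:, keep_cols]
    keep_rows = ~np.isnan(X).any(axis=1)
    if keep_rows.sum() < 2:
        raise ValueError("clean_missing removed (almost) every case")
    names = [ds.feature_names[j] for j in keep_cols]
    return Dataset(X[keep_rows], ds.labels[keep_rows], names)


def normalize(
    train: Dataset,
    others: Sequence[Dataset] = (),
    method: str = "zscore",
) -> tuple[Dataset, list[Dataset]]:
    """Standardize features using statistics fit on ``train`` only.

    ``zscore`` (default) maps each feature to zero mean / unit variance as
    measured on the training cases; ``minmax`` rescales to [0, 1] over the
    training range.  The identical affine transform is applied to every
    dataset in ``others`` (e.g. the held-out fold), so no test information
    leaks into the fit.  A feature constant on the training set carries no
    signal under either transform and is mapped to all-zeros everywhere.
    """
    for o in others:
        if o.feature_names != train.feature_names:
            raise ValueError("datasets must share feature_names with train")
    X = train.features
    if method == "zscore":
        center = X.mean(axis=0)
        scale = X.std(axis=0)  # population sd
    elif method == "minmax":
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)

    def apply(ds: Dataset) -> Dataset:
        Z = (ds.features - center) / scale
        Z[:, constant] = 0.0
        return Dataset(Z, ds.labels, list(ds.feature_names))

    return apply(train), [apply(o) for o in others]


def stratified_kfold(ds: Dataset, k: int, seed: int) -> FoldPlan:
    """Seeded, class-stratified k-fold assignment of the dataset's cases.

    Falls back to unstratified folds (with a warning) when some class has
    fewer than ``k`` members, in which case stratification is impossible.
    """
    if not 2 <= k <= ds.n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={ds.n}")
    class_counts = np.bincount(ds.labels, minlength=2)
    assignments = np.empty(ds.n, dtype=int)
    if class_counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(ds.n), ds.labels)
    else:
        warnings.warn(
            f"a class has fewer than k={k} members; using unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(ds.n))
    for fold, (_, test_idx) in enumerate(splits):
        assignments[test_idx] = fold
    return FoldPlan(k=k, seed=seed, assignments=assignments)
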