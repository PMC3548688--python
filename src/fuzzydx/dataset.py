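"""Tabular dataset container, CSV I/O and stratified k-fold partitioning.

Datasets are plain tables with a header row of attribute names, one
designated categorical class attribute, and a mix of numeric and
categorical features.  Every numeric feature carries a closed *universe of
discourse* ``[lo, hi]`` (by default the observed min/max), which later
stages use to place and bound membership functions.

Missing values are rejected, never imputed: the downstream rule machinery
assumes every item is fully observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "Dataset",
    "FoldPartition",
    "DatasetError",
    "read_csv",
    "write_csv",
    "stratified_kfold",
]


class DatasetError(ValueError):
    """Raised for malformed datasets or dataset files."""


@dataclass(frozen=True)
class FeatureSpec:
    """Description of one attribute: its kind and admissible values.

    Parameters
    ----------
    name
        Attribute name, unique within a dataset.
    kind
        ``"numeric"`` or ``"categorical"``.
    universe
        Closed interval ``(lo, hi)`` with ``lo < hi``; numeric features only.
    categories
        Ordered tuple of admissible values; categorical features only.  The
        order is meaningful: output-class singleton positions follow it.
    """

    name: str
    kind: Literal["numeric", "categorical"]
    universe: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "numeric":
            if self.universe is None:
                raise DatasetError(f"numeric feature {self.name!r} needs a universe")
            lo, hi = self.universe
            if not lo < hi:
                raise DatasetError(
                    f"feature {self.name!r}: universe must satisfy lo < hi, got [{lo}, {hi}]"
                )
            if self.categories is not None:
                raise DatasetError(f"numeric feature {self.name!r} cannot have categories")
        elif self.kind == "categorical":
            if not self.categories:
                raise DatasetError(f"categorical feature {self.name!r} needs categories")
            if self.universe is not None:
                raise DatasetError(f"categorical feature {self.name!r} cannot have a universe")
        else:
            raise DatasetError(f"unknown feature kind {self.kind!r}")


@dataclass
class Dataset:
    """A fully observed table with one categorical class attribute.

    ``items`` holds one column per feature plus the class column; numeric
    columns are float64, categorical columns are plain strings.
    """

    features: list[FeatureSpec]
    class_attribute: FeatureSpec
    items: pd.DataFrame

    def __post_init__(self) -> None:
        if self.class_attribute.kind != "categorical":
            raise DatasetError("class attribute must be categorical")
        names = [f.name for f in self.features] + [self.class_attribute.name]
        if len(set(names)) != len(names):
            raise DatasetError("duplicate attribute names")
        missing = set(names) - set(self.items.columns)
        if missing:
            raise DatasetError(f"items lack columns: {sorted(missing)}")
        if self.items.isna().any().any():
            raise DatasetError("dataset contains missing values")
        for f in self.features:
            col = self.items[f.name]
            if f.kind == "numeric":
                lo, hi = f.universe  # type: ignore[misc]
                vals = col.to_numpy(dtype=float)
                if vals.size and (vals.min() < lo or vals.max() > hi):
                    raise DatasetError(f"feature {f.name!r}: values outside universe [{lo}, {hi}]")
            else:
                bad = set(col.astype(str)) - set(f.categories or ())
                if bad:
                    raise DatasetError(f"feature {f.name!r}: unknown categories {sorted(bad)}")
        bad = set(self.items[self.class_attribute.name].astype(str)) - set(
            self.class_attribute.categories or ()
        )
        if bad:
            raise DatasetError(f"unknown class values {sorted(bad)}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def classes(self) -> tuple[str, ...]:
        """Class values in declaration order."""
        return tuple(self.class_attribute.categories or ())

    @property
    def labels(self) -> np.ndarray:
        return self.items[self.class_attribute.name].astype(str).to_numpy()

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Dataset":
        """A new dataset with the selected rows (positions, 0-based)."""
        sub = self.items.iloc[np.asarray(indices)].reset_index(drop=True)
        return Dataset(list(self.features), self.class_attribute, sub)

    def iter_items(self) -> Iterator[dict]:
        for rec in self.items.to_dict(orient="records"):
            yield rec


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _infer_kind(values: pd.Series) -> bool:
    """True if every value parses as a number."""
    try:
        pd.to_numeric(values)
        return True
    except (ValueError, TypeError):
        return False


def read_csv(
    path: str | Path,
    class_attribute: str,
    universes: dict[str, tuple[float, float]] | None = None,
) -> Dataset:
    """Load a comma-separated table: header row of attribute names, then rows.

    Feature kinds are inferred per column (numeric if every value parses as
    a number, categorical otherwise); numeric universes default to the
    observed ``[min, max]`` and may be overridden via ``universes``.

    Raises
    ------
    DatasetError
        On a missing file, absent class column, ragged rows, or any missing
        value (reported with its 1-based data-row index).
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows
        raise DatasetError(f"{path}: header/row arity mismatch ({exc})") from exc
    if class_attribute not in df.columns:
        raise DatasetError(f"class attribute {class_attribute!r} not in header {list(df.columns)}")

    blank = (df == "").any(axis=1)
    if blank.any():
        row = int(np.flatnonzero(blank.to_numpy())[0]) + 1  # 1-based data row
        raise DatasetError(f"{path}: missing value in data row {row}")

    universes = universes or {}
    features: list[FeatureSpec] = []
    for name in df.columns:
        if name == class_attribute:
            continue
        col = df[name].str.strip()
        if _infer_kind(col):
            vals = pd.to_numeric(col).astype(float)
            df[name] = vals
            lo, hi = universes.get(name, (float(vals.min()), float(vals.max())))
            if lo == hi:  # constant column: widen so the universe is an interval
                lo, hi = lo - 0.5, hi + 0.5
            features.append(FeatureSpec(name, "numeric", universe=(lo, hi)))
        else:
            df[name] = col
            cats = tuple(dict.fromkeys(col))  # order of first appearance
            features.append(FeatureSpec(name, "categorical", categories=cats))

    cls_col = df[class_attribute].str.strip()
    df[class_attribute] = cls_col
    class_values = tuple(dict.fromkeys(cls_col))
    if len(class_values) < 2:
        warnings.warn(f"class column {class_attribute!r} is constant", stacklevel=2)
    cls_spec = FeatureSpec(class_attribute, "categorical", categories=class_values)
    return Dataset(features, cls_spec, df)


def write_csv(ds: Dataset, path: str | Path) -> None:
    """Write the dataset back in the same dialect (header row, commas)."""
    cols = ds.feature_names + [ds.class_attribute.name]
    ds.items[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPartition:
    """Stratified assignment of each item to one of ``k`` folds (1-based)."""

    k: int
    assignments: np.ndarray = field(repr=False)  # shape (n_items,), values 1..k
    seed: int = 0

    def test_indices(self, fold: int) -> np.ndarray:
        if not 1 <= fold <= self.k:
            raise ValueError(f"fold must be in 1..{self.k}")
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        if not 1 <= fold <= self.k:
            raise ValueError(f"fold must be in 1..{self.k}")
        return np.flatnonzero(self.assignments != fold)

    def split(self, ds: Dataset, fold: int) -> tuple[Dataset, Dataset]:
        """(train, test) datasets for the given fold."""
        return ds.subset(self.train_indices(fold)), ds.subset(self.test_indices(fold))


def stratified_kfold(ds: Dataset, k: int, seed: int = 0) -> FoldPartition:
    """Assign items to ``k`` folds, balanced within each class stratum.

    Within every class the items are shuffled (seeded) and dealt round-robin,
    so per-class fold counts differ by at most one and the same
    ``(ds, k, seed)`` always yields the same partition.
    """
    if k < 2:
        raise DatasetError("k must be at least 2")
    if k > ds.n_items:
        raise DatasetError(f"k={k} exceeds the number of items ({ds.n_items})")
    rng = np.random.default_rng(seed)
    labels = ds.labels
    assignments = np.zeros(ds.n_items, dtype=int)
    # iterate classes in declaration order so the assignment is reproducible
    for cls in ds.classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        if idx.size < k:
            warnings.warn(
                f"class {cls!r} has only {idx.size} items for k={k}; "
                "some folds will lack this class",
                stacklevel=2,
            )
        rng.shuffle(idx)
        assignments[idx] = (np.arange(idx.size) % k) + 1
    return FoldPartition(k=k, assignments=assignments, seed=seed)
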