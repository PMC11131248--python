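"""Feature schema and in-memory cohort container.

A cohort is one row per patient: a numeric feature matrix with an explicit
missingness mask, a binary 30-day all-cause-mortality label, and a hospital
identifier per row.  Several clinical indicators appear twice — once as a
continuous measurement (e.g. age, body temperature) and once as a paired
binary discretization (e.g. "age > 80", "temperature < 36 °C"); the schema
records those pairings so downstream code can select discrete-only,
continuous-only, or combined feature groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Descriptor",
    "Pairing",
    "FeatureSchema",
    "Cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

_RESERVED_COLUMNS = ("hospital_id", "label")
_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass(frozen=True)
class Descriptor:
    """One feature column: its name, kind, and marginal missingness rate."""

    name: str
    kind: str  # "continuous" | "binary"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(
                f"missing_rate for {self.name!r} must lie in [0, 1], "
                f"got {self.missing_rate}"
            )


@dataclass(frozen=True)
class Pairing:
    """Link between a continuous column and its derived binary indicator.

    The binary column equals ``comparator(continuous, threshold)``, e.g.
    ``Pairing("age", "age_gt_80", 80.0, ">")`` encodes "age > 80 years".
    """

    continuous_name: str
    binary_name: str
    threshold: float
    comparator: str = ">"

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def indicator(self, values: np.ndarray) -> np.ndarray:
        return _COMPARATORS[self.comparator](values, self.threshold).astype(float)


@dataclass(frozen=True)
class FeatureSchema:
    descriptors: tuple[Descriptor, ...]
    pairings: tuple[Pairing, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        object.__setattr__(self, "pairings", tuple(self.pairings))
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("descriptor names must be unique")
        for col in _RESERVED_COLUMNS:
            if col in names:
                raise ValueError(f"{col!r} is a reserved column name")
        by_name = {d.name: d for d in self.descriptors}
        for p in self.pairings:
            if p.continuous_name not in by_name:
                raise ValueError(
                    f"pairing references unknown continuous column {p.continuous_name!r}"
                )
            if by_name[p.continuous_name].kind != "continuous":
                raise ValueError(
                    f"pairing source {p.continuous_name!r} is not continuous"
                )
            if p.binary_name not in by_name:
                raise ValueError(
                    f"pairing references unknown binary column {p.binary_name!r}"
                )
            if by_name[p.binary_name].kind != "binary":
                raise ValueError(f"pairing target {p.binary_name!r} is not binary")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def descriptor(self, name: str) -> Descriptor:
        return self.descriptors[self.index_of(name)]

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors if d.kind == "continuous")

    def binary_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors if d.kind == "binary")

    def paired_continuous(self) -> tuple[str, ...]:
        return tuple(p.continuous_name for p in self.pairings)

    def paired_binaries(self) -> tuple[str, ...]:
        return tuple(p.binary_name for p in self.pairings)

    def subset(self, keep: Iterable[str]) -> "FeatureSchema":
        """Schema restricted to ``keep`` (original column order), dropping
        pairings whose members are no longer both present."""
        keep = set(keep)
        unknown = keep - set(self.names)
        if unknown:
            raise KeyError(f"unknown features {sorted(unknown)}")
        descriptors = tuple(d for d in self.descriptors if d.name in keep)
        pairings = tuple(
            p
            for p in self.pairings
            if p.continuous_name in keep and p.binary_name in keep
        )
        return FeatureSchema(descriptors, pairings)


@dataclass
class Cohort:
    """Patient-level data: features with a missingness mask, labels, hospitals.

    ``features[i, j]`` is ``NaN`` exactly where ``mask[i, j]`` is True, so a
    masked cell read before imputation propagates as NaN rather than being
    silently treated as a number.  ``labels`` is 1 for death within the
    30-day follow-up, 0 otherwise.
    """

    features: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    hospital_ids: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        self.hospital_ids = np.asarray(self.hospital_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n, p = self.features.shape
        if p != self.schema.n_features:
            raise ValueError(
                f"feature matrix has {p} columns but schema defines "
                f"{self.schema.n_features}"
            )
        if self.mask.shape != (n, p):
            raise ValueError("mask shape does not match feature matrix")
        if self.labels.shape != (n,) or self.hospital_ids.shape != (n,):
            raise ValueError("labels/hospital_ids length does not match features")
        labels = np.unique(self.labels)
        if not np.isin(labels, [0, 1]).all():
            raise ValueError(f"labels must be 0/1, found {labels}")
        self.labels = self.labels.astype(int)
        # NaN placement and the mask must agree exactly.
        if not np.array_equal(np.isnan(self.features), self.mask):
            raise ValueError("NaN cells and missingness mask disagree")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.mask.any())

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.schema.index_of(name)]

    def take_rows(self, idx: np.ndarray | Sequence[int]) -> "Cohort":
        idx = np.asarray(idx, dtype=int)
        return Cohort(
            self.features[idx],
            self.mask[idx],
            self.labels[idx],
            self.hospital_ids[idx],
            self.schema,
        )

    def select_columns(self, names: Iterable[str]) -> "Cohort":
        names = list(names)
        schema = self.schema.subset(names)
        cols = [self.schema.index_of(n) for n in schema.names]
        return Cohort(
            self.features[:, cols],
            self.mask[:, cols],
            self.labels,
            self.hospital_ids,
            schema,
        )

    def copy(self) -> "Cohort":
        return Cohort(
            self.features.copy(),
            self.mask.copy(),
            self.labels.copy(),
            self.hospital_ids.copy(),
            self.schema,
        )

    def hospital_sizes(self) -> dict[str, int]:
        ids, counts = np.unique(self.hospital_ids.astype(str), return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.schema.names))
        df["hospital_id"] = self.hospital_ids.astype(str)
        df["label"] = self.labels
        return df


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Serialize a cohort to CSV; masked cells become empty fields."""
    df = cohort.to_frame()
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path, schema: FeatureSchema) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Columns must be exactly the schema's features plus ``hospital_id`` and
    ``label``.  Empty fields are masked (missing) entries, never zeros.
    Raises on unknown columns, labels outside {0, 1}, and malformed numeric
    cells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(schema.names) | set(_RESERVED_COLUMNS)
    got = set(df.columns)
    if got - expected:
        raise ValueError(f"unknown columns in cohort file: {sorted(got - expected)}")
    if expected - got:
        raise ValueError(f"missing columns in cohort file: {sorted(expected - got)}")

    n = len(df)
    features = np.full((n, schema.n_features), np.nan)
    for j, name in enumerate(schema.names):
        raw = df[name].to_numpy()
        observed = raw != ""
        try:
            features[observed, j] = raw[observed].astype(float)
        except ValueError as exc:
            raise ValueError(f"malformed numeric cell in column {name!r}: {exc}")
    mask = np.isnan(features)

    raw_labels = df["label"].to_numpy()
    if (raw_labels == "").any():
        raise ValueError("label column contains empty fields")
    try:
        labels = raw_labels.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed label cell: {exc}")
    if not np.isin(labels, [0.0, 1.0]).all():
        bad = sorted(set(labels.tolist()) - {0.0, 1.0})
        raise ValueError(f"labels must be 0/1, found {bad}")

    return Cohort(features, mask, labels.astype(int), df["hospital_id"].to_numpy(), schema)
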