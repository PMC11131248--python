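"""Mean imputation, z-standardization, and feature-group selection.

Missing cells are filled with the per-column mean of the observed values.
Standardization uses the population form: mu = (1/n) sum x_i and
sigma = sqrt((1/n) sum (x_i - mu)^2), then x' = (x - mu) / sigma, with
constant columns (sigma = 0) mapped to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "StandardizationParams",
    "impute_mean",
    "fit_standardizer",
    "apply_standardizer",
    "inverse_standardizer",
    "select_feature_group",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location (mu) and scale (sigma), population form."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if self.mu.shape != self.sigma.shape or self.mu.shape != (
            len(self.feature_names),
        ):
            raise ValueError("mu/sigma/feature_names lengths disagree")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be nonnegative")

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StandardizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.array(payload["mu"]),
            np.array(payload["sigma"]),
            tuple(payload["feature_names"]),
        )


def impute_mean(cohort: Cohort) -> tuple[Cohort, dict[str, float]]:
    """Fill every masked cell with its column's observed mean.

    Returns the imputed cohort (mask all-false) and the per-feature fill
    values.  A column with no observed value at all is an error — silently
    zero-filling it would invent data.
    """
    features = cohort.features.copy()
    fills: dict[str, float] = {}
    for j, name in enumerate(cohort.schema.names):
        col = features[:, j]
        observed = ~cohort.mask[:, j]
        if not observed.any():
            raise ValueError(f"column {name!r} is entirely missing; cannot impute")
        fill = float(col[observed].mean())
        fills[name] = fill
        col[~observed] = fill
    imputed = Cohort(
        features,
        np.zeros_like(cohort.mask),
        cohort.labels.copy(),
        cohort.hospital_ids.copy(),
        cohort.schema,
    )
    return imputed, fills


def fit_standardizer(
    cohort: Cohort, standardize_binaries: bool = True
) -> StandardizationParams:
    """Estimate per-feature mu and sigma (population 1/n form).

    Requires a fully observed cohort (run :func:`impute_mean` first).  With
    ``standardize_binaries=False`` binary columns get the identity transform
    (mu 0, sigma 1); the default standardizes every column alike.
    """
    if cohort.n == 0:
        raise ValueError("cannot standardize an empty cohort")
    if cohort.has_missing:
        raise ValueError("cohort has missing cells; impute before standardizing")
    mu = cohort.features.mean(axis=0)
    sigma = cohort.features.std(axis=0)  # ddof=0: population form
    if not standardize_binaries:
        for j, d in enumerate(cohort.schema.descriptors):
            if d.kind == "binary":
                mu[j], sigma[j] = 0.0, 1.0
    return StandardizationParams(mu, sigma, cohort.schema.names)


def apply_standardizer(cohort: Cohort, params: StandardizationParams) -> Cohort:
    """x' = (x - mu) / sigma; constant columns (sigma = 0) map to 0."""
    if params.feature_names != cohort.schema.names:
        raise ValueError("standardizer was fitted on a different feature set")
    if cohort.has_missing:
        raise ValueError("cohort has missing cells; impute before standardizing")
    sigma = np.where(params.sigma == 0.0, 1.0, params.sigma)
    features = (cohort.features - params.mu) / sigma
    features[:, params.sigma == 0.0] = 0.0
    return Cohort(
        features,
        np.zeros_like(cohort.mask),
        cohort.labels.copy(),
        cohort.hospital_ids.copy(),
        cohort.schema,
    )


def inverse_standardizer(cohort: Cohort, params: StandardizationParams) -> Cohort:
    """Undo :func:`apply_standardizer` (x = x'·sigma + mu).

    Columns with sigma = 0 were collapsed to zero and invert to mu.
    """
    if params.feature_names != cohort.schema.names:
        raise ValueError("standardizer was fitted on a different feature set")
    features = cohort.features * params.sigma + params.mu
    return Cohort(
        features,
        np.zeros_like(cohort.mask),
        cohort.labels.copy(),
        cohort.hospital_ids.copy(),
        cohort.schema,
    )


def select_feature_group(cohort: Cohort, group: str) -> Cohort:
    """Restrict the indicators that exist in both forms to one form.

    Group "A" keeps only the discrete (binary) version of each paired
    indicator, "B" keeps only the continuous version, and "C" keeps both.
    Features without a paired counterpart are kept in every group.
    """
    group = group.upper()
    if group not in ("A", "B", "C"):
        raise ValueError(f"unknown feature group {group!r}; expected A, B or C")
    if group == "C":
        drop: set[str] = set()
    elif group == "A":
        drop = set(cohort.schema.paired_continuous())
    else:
        drop = set(cohort.schema.paired_binaries())
    keep = [name for name in cohort.schema.names if name not in drop]
    return cohort.select_columns(keep)
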