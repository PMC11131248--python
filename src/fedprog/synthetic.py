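"""Seeded synthetic multi-hospital cohort generator.

The real 12-hospital pulmonary-thromboembolism cohort behind this pipeline
is private, so experiments run on synthetic cohorts that reproduce its
*marginal* printed structure: 19 clinical indicators (7 continuous vitals /
labs, their 7 paired binary discretizations, and 5 standalone binary
comorbidity or status flags), per-feature missingness at the published
rates, hospital-to-hospital heterogeneity in size, feature means and flag
prevalences, and a binary 30-day mortality outcome with an exactly
calibrated event count (176 deaths among 3997 patients, 4.40%).

Outcome labels follow a logistic model: each patient's linear predictor
``eta = x·beta + intercept`` receives standard-logistic noise, and the
``n_events`` patients with the largest noisy risk are labelled positive.
This is a logistic regression data-generating process conditioned on the
total event count, so the calibration is exact for every seed while slope
coefficients remain recoverable by a logistic fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .cohort import Cohort, Descriptor, FeatureSchema, Pairing

__all__ = [
    "HospitalSpec",
    "GeneratorSpec",
    "default_schema",
    "default_generator_spec",
    "generate_cohort",
    "spec_from_yaml",
    "spec_to_yaml",
]


@dataclass(frozen=True)
class HospitalSpec:
    """One simulated hospital: its share of patients and its local shifts.

    ``mean_shift`` offsets continuous feature means in raw units;
    ``prevalence_shift`` offsets standalone binary flags on the log-odds
    scale.  Both default to no shift.
    """

    id: str
    sample_fraction: float
    mean_shift: dict[str, float] = field(default_factory=dict)
    prevalence_shift: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorSpec:
    """Full parameterization of one synthetic cohort draw."""

    schema: FeatureSchema
    n_patients: int
    n_events: int
    hospitals: tuple[HospitalSpec, ...]
    continuous_params: dict[str, tuple[float, float]]  # name -> (mean, sd)
    binary_prevalence: dict[str, float]  # standalone binaries only
    beta: dict[str, float]  # outcome log-odds per feature; absent -> 0
    intercept: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.hospitals = tuple(self.hospitals)
        self.validate()

    def validate(self) -> None:
        if self.n_events > self.n_patients:
            raise ValueError(
                f"n_events ({self.n_events}) exceeds n_patients ({self.n_patients})"
            )
        if self.n_events < 0 or self.n_patients < 1:
            raise ValueError("need n_patients >= 1 and n_events >= 0")
        total = sum(h.sample_fraction for h in self.hospitals)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"hospital sample fractions sum to {total}, not 1")
        ids = [h.id for h in self.hospitals]
        if len(set(ids)) != len(ids):
            raise ValueError("hospital ids must be unique")
        names = set(self.schema.names)
        for name in self.beta:
            if name not in names:
                raise KeyError(f"beta references unknown feature {name!r}")
        derived = set(self.schema.paired_binaries())
        for d in self.schema.descriptors:
            if d.kind == "continuous" and d.name not in self.continuous_params:
                raise KeyError(f"no (mean, sd) given for continuous {d.name!r}")
            if (
                d.kind == "binary"
                and d.name not in derived
                and d.name not in self.binary_prevalence
            ):
                raise KeyError(f"no prevalence given for standalone binary {d.name!r}")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact quotas then hands remaining units to the largest
    fractional parts; ties broken by position (lowest index first).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = quota - np.floor(quota)
        # stable sort => ties go to the earlier hospital
        order = np.argsort(-frac, kind="stable")
        counts[order[:remainder]] += 1
    return counts


def generate_cohort(spec: GeneratorSpec) -> Cohort:
    """Draw one cohort from ``spec``; identical spec (incl. seed) gives an
    identical cohort.

    Per hospital, continuous features are independent Gaussians with the
    hospital's mean shift applied; standalone binaries are Bernoulli with
    the hospital's log-odds shift; each paired binary is the exact indicator
    of its continuous partner against the schema threshold (before any
    masking).  Exactly ``spec.n_events`` rows are labelled positive.
    Missingness is applied last, completely at random per descriptor.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    names = schema.names
    n = spec.n_patients
    counts = _largest_remainder(
        np.array([h.sample_fraction for h in spec.hospitals]), n
    )

    pairing_by_binary = {p.binary_name: p for p in schema.pairings}
    features = np.empty((n, schema.n_features))
    hospital_ids = np.empty(n, dtype=object)

    start = 0
    for hosp, n_h in zip(spec.hospitals, counts):
        rows = slice(start, start + n_h)
        hospital_ids[rows] = hosp.id
        # continuous first (their paired indicators depend on them)
        for j, name in enumerate(names):
            d = schema.descriptors[j]
            if d.kind != "continuous":
                continue
            mean, sd = spec.continuous_params[name]
            mean += hosp.mean_shift.get(name, 0.0)
            features[rows, j] = rng.normal(mean, sd, size=n_h)
        for j, name in enumerate(names):
            d = schema.descriptors[j]
            if d.kind != "binary":
                continue
            if name in pairing_by_binary:
                p = pairing_by_binary[name]
                cont = features[rows, schema.index_of(p.continuous_name)]
                features[rows, j] = p.indicator(cont)
            else:
                base = spec.binary_prevalence[name]
                logit = math.log(base / (1.0 - base)) + hosp.prevalence_shift.get(
                    name, 0.0
                )
                prob = 1.0 / (1.0 + math.exp(-logit))
                features[rows, j] = (rng.random(n_h) < prob).astype(float)
        start += n_h

    # Outcome: logistic latent risk, thresholded at the quantile that yields
    # the exact requested number of events.
    beta = np.array([spec.beta.get(name, 0.0) for name in names])
    eta = features @ beta + spec.intercept
    latent = eta + rng.logistic(size=n)
    labels = np.zeros(n, dtype=int)
    if spec.n_events > 0:
        top = np.argsort(latent, kind="stable")[-spec.n_events :]
        labels[top] = 1

    # MCAR missingness per descriptor at its schema rate.
    mask = np.zeros_like(features, dtype=bool)
    for j, d in enumerate(schema.descriptors):
        if d.missing_rate > 0.0:
            mask[:, j] = rng.random(n) < d.missing_rate
    values = features.copy()
    values[mask] = np.nan

    return Cohort(values, mask, labels, hospital_ids, schema)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# (mean, sd) for the continuous indicators, in clinical units.  Means follow
# the published cohort's central values; sds are set so each paired binary's
# Gaussian tail probability lands near its published prevalence (e.g. age
# 68 ± 12 years gives P(age > 80) ≈ 15.9% against a printed 15.01%).
_CONTINUOUS_PARAMS: dict[str, tuple[float, float]] = {
    "age": (68.0, 12.0),
    "systolic_bp": (121.0, 18.0),
    "pulse_rate": (82.0, 23.0),
    "temperature": (36.5, 0.23),
    "respiratory_rate": (19.0, 5.5),
    "serum_calcium": (2.2, 0.15),
    "sao2": (95.0, 4.6),
}

# Published prevalences for the standalone binary flags.
_BINARY_PREVALENCE: dict[str, float] = {
    "male_sex": 0.4991,
    "altered_mental_status": 0.1331,
    "chronic_heart_failure": 0.135,
    "chronic_pulmonary_disease": 0.1419,
    "cancer": 0.1544,
}

# Published per-column missing-value ratios; all other columns are complete.
_MISSING_RATES: dict[str, float] = {
    "systolic_bp": 0.007,
    "pulse_rate": 0.005,
    "temperature": 0.010,
    "respiratory_rate": 0.0145,
    "serum_calcium": 0.015,
    "sao2": 0.1611,
    "chronic_heart_failure": 0.1233,
}

_PAIRINGS: tuple[tuple[str, str, float, str], ...] = (
    ("age", "age_gt_80", 80.0, ">"),
    ("systolic_bp", "sbp_lt_100", 100.0, "<"),
    ("pulse_rate", "pulse_ge_110", 110.0, ">="),
    ("temperature", "temp_lt_36", 36.0, "<"),
    ("respiratory_rate", "resp_gt_30", 30.0, ">"),
    ("serum_calcium", "calcium_le_2_13", 2.13, "<="),
    ("sao2", "sao2_lt_90", 90.0, "<"),
)

# Outcome log-odds: 0.35 x the PUMCH point weights on the corresponding
# binary indicators, so the synthetic risk signal is clinically shaped
# (cancer OR ≈ 5.8, low systolic BP OR ≈ 2.9, ...).  A default, not a claim
# about the private cohort's true coefficients.
_BETA_SCALE = 0.35
_DEFAULT_BETA: dict[str, float] = {
    "age_gt_80": 2 * _BETA_SCALE,
    "male_sex": 1 * _BETA_SCALE,
    "cancer": 5 * _BETA_SCALE,
    "chronic_heart_failure": 2 * _BETA_SCALE,
    "chronic_pulmonary_disease": 3 * _BETA_SCALE,
    "pulse_ge_110": 3 * _BETA_SCALE,
    "sbp_lt_100": 3 * _BETA_SCALE,
    "altered_mental_status": 2 * _BETA_SCALE,
    "sao2_lt_90": 1 * _BETA_SCALE,
    "calcium_le_2_13": 1 * _BETA_SCALE,
}
_DEFAULT_INTERCEPT = -4.6

# Heterogeneous hospital sizes (12 hospitals summing to 1); the two smallest
# default to the held-out test role downstream.
_HOSPITAL_FRACTIONS = (
    0.17, 0.14, 0.12, 0.11, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.035, 0.025,
)

# Fixed entropy for drawing the default per-hospital shifts; part of the
# default study conditions, independent of the cohort seed.
_SHIFT_ENTROPY = 20240527


def default_schema(missing: bool = True) -> FeatureSchema:
    """The 19-indicator schema (7 continuous + 7 paired binaries + 5 flags)."""
    rates = _MISSING_RATES if missing else {}
    descriptors = []
    for name in _CONTINUOUS_PARAMS:
        descriptors.append(Descriptor(name, "continuous", rates.get(name, 0.0)))
    for _, bname, _, _ in _PAIRINGS:
        descriptors.append(Descriptor(bname, "binary", rates.get(bname, 0.0)))
    for name in _BINARY_PREVALENCE:
        descriptors.append(Descriptor(name, "binary", rates.get(name, 0.0)))
    pairings = tuple(Pairing(c, b, t, op) for c, b, t, op in _PAIRINGS)
    return FeatureSchema(tuple(descriptors), pairings)


def _default_hospitals(
    n_hospitals: int, shift_scale: float, schema: FeatureSchema
) -> tuple[HospitalSpec, ...]:
    if n_hospitals == len(_HOSPITAL_FRACTIONS):
        fractions = np.array(_HOSPITAL_FRACTIONS)
    else:
        # geometric size decay, renormalized
        fractions = 0.8 ** np.arange(n_hospitals)
        fractions /= fractions.sum()
    rng = np.random.default_rng(_SHIFT_ENTROPY)
    standalone = [
        n for n in schema.binary_names() if n not in schema.paired_binaries()
    ]
    hospitals = []
    for h in range(n_hospitals):
        mean_shift = {
            name: float(rng.normal(0.0, shift_scale * sd))
            for name, (_, sd) in _CONTINUOUS_PARAMS.items()
            if name in schema.names
        }
        prev_shift = {name: float(rng.normal(0.0, 2.0 * shift_scale)) for name in standalone}
        hospitals.append(
            HospitalSpec(
                id=f"H{h + 1:02d}",
                sample_fraction=float(fractions[h]),
                mean_shift=mean_shift if shift_scale > 0 else {},
                prevalence_shift=prev_shift if shift_scale > 0 else {},
            )
        )
    return tuple(hospitals)


def default_generator_spec(
    seed: int = 0,
    n_patients: int = 3997,
    n_events: int = 176,
    n_hospitals: int = 12,
    shift_scale: float = 0.15,
    missing: bool = True,
) -> GeneratorSpec:
    """Default study conditions: 3997 patients, 176 events (4.40%), 12
    hospitals of heterogeneous size with moderate distribution shifts, and
    the published per-column missingness rates.

    ``shift_scale`` controls hospital heterogeneity: continuous means shift
    by N(0, (shift_scale·sd)²) and standalone flag log-odds by
    N(0, (2·shift_scale)²); 0 disables all shifts.
    """
    schema = default_schema(missing=missing)
    return GeneratorSpec(
        schema=schema,
        n_patients=n_patients,
        n_events=n_events,
        hospitals=_default_hospitals(n_hospitals, shift_scale, schema),
        continuous_params=dict(_CONTINUOUS_PARAMS),
        binary_prevalence=dict(_BINARY_PREVALENCE),
        beta=dict(_DEFAULT_BETA),
        intercept=_DEFAULT_INTERCEPT,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def spec_from_yaml(source) -> GeneratorSpec:
    """Build a GeneratorSpec from a YAML mapping (path or file object).

    A config with ``schema: default`` uses the packaged 19-indicator schema
    and its default distribution parameters; top-level keys (``n_patients``,
    ``n_events``, ``n_hospitals``, ``seed``, ``shift_scale``) override the
    defaults.
    """
    if hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("generator config must be a YAML mapping")
    if cfg.get("schema", "default") != "default":
        raise ValueError("only the packaged default schema is configurable via YAML")
    kwargs = {}
    for key in ("seed", "n_patients", "n_events", "n_hospitals", "shift_scale"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "missing" in cfg:
        kwargs["missing"] = bool(cfg["missing"])
    return default_generator_spec(**kwargs)


def spec_to_yaml(spec_kwargs: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"schema": "default", **spec_kwargs}, fh, sort_keys=True)


def packaged_default_config():
    """Open the packaged default generator configuration."""
    return resources.files("fedprog").joinpath("data/default_generator.yaml").open("r")
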