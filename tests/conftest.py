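import numpy as np
import pytest

from fedprog.cohort import Cohort, Descriptor, FeatureSchema, Pairing
from fedprog.synthetic import GeneratorSpec, HospitalSpec


@pytest.fixture
def tiny_schema() -> FeatureSchema:
    """Two continuous columns, one derived indicator, one standalone flag."""
    return FeatureSchema(
        descriptors=(
            Descriptor("age", "continuous"),
            Descriptor("sao2", "continuous", missing_rate=0.2),
            Descriptor("age_gt_80", "binary"),
            Descriptor("cancer", "binary"),
        ),
        pairings=(Pairing("age", "age_gt_80", 80.0, ">"),),
    )


def make_cohort(features, labels, hospital_ids=None, schema=None, mask=None) -> Cohort:
    features = np.asarray(features, dtype=float)
    n, p = features.shape
    if schema is None:
        schema = FeatureSchema(
            tuple(Descriptor(f"x{j}", "continuous") for j in range(p))
        )
    if mask is None:
        mask = np.isnan(features)
    if hospital_ids is None:
        hospital_ids = np.array(["H1"] * n, dtype=object)
    return Cohort(features, mask, np.asarray(labels), np.asarray(hospital_ids, dtype=object), schema)


@pytest.fixture
def unpaired_spec_factory():
    """GeneratorSpec over independent features (no derived indicators), for
    clean logistic parameter-recovery checks."""

    schema = FeatureSchema(
        (
            Descriptor("x1", "continuous"),
            Descriptor("x2", "continuous"),
            Descriptor("x3", "continuous"),
            Descriptor("f1", "binary"),
            Descriptor("f2", "binary"),
            Descriptor("f3", "binary"),
        )
    )
    beta = {"x1": 0.8, "x2": -0.5, "x3": 0.0, "f1": 1.2, "f2": -0.7, "f3": 0.3}

    def factory(n_patients, n_events, seed=42, n_hospitals=1):
        if n_hospitals == 1:
            hospitals = (HospitalSpec("H1", 1.0),)
        else:
            frac = 1.0 / n_hospitals
            hospitals = tuple(
                HospitalSpec(f"H{i+1}", frac) for i in range(n_hospitals)
            )
        return GeneratorSpec(
            schema=schema,
            n_patients=n_patients,
            n_events=n_events,
            hospitals=hospitals,
            continuous_params={
                "x1": (0.0, 1.0),
                "x2": (1.0, 2.0),
                "x3": (-0.5, 1.0),
            },
            binary_prevalence={"f1": 0.3, "f2": 0.5, "f3": 0.15},
            beta=beta,
            intercept=-2.0,
            seed=seed,
        )

    factory.schema = schema
    factory.beta = beta
    factory.intercept = -2.0
    return factory
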