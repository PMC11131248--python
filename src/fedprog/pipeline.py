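"""Config-driven experiment runner.

One experiment = ``replicates`` independent repetitions of the full chain
generate (or load) -> impute -> feature group -> standardize -> split ->
client partition -> train (FedAvg + requested baselines) -> evaluate on
train/validation/test at a fixed classification threshold.  Replicate r
uses seed ``base_seed + r``; that seed is split into fixed per-stage
streams (cohort generation, validation sampling, client assignment, model
initialization and minibatch shuffles) so every run is reproducible
bit-for-bit and replicates are mutually independent.

Baselines: the centralized ("NonFed") model trained on the pooled training
set with the same optimizer, per-client locally trained models, and the
PESI/sPESI/PUMCH clinical scores ranked directly by their point totals.
Significance: a two-tailed t-test on test-set AUC across replicates
(federated vs centralized) and per-replicate DeLong tests (federated vs
each clinical score).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, read_cohort_csv
from .federated import (
    FedConfig,
    LinearModelParams,
    predict_proba,
    run_fedavg,
    train_centralized,
    train_local_only,
)
from .metrics import (
    MetricsReport,
    delong_test,
    summarize_replicates,
    threshold_metrics,
    two_tailed_t_test,
)
from .partition import (
    ClientAssignment,
    assign_clients_iid,
    assign_clients_noniid,
    assign_clients_realworld,
    balanced_hospital_mapping,
    split_indices,
)
from .preprocess import (
    apply_standardizer,
    fit_standardizer,
    impute_mean,
    select_feature_group,
)
from .scores import records_from_cohort, pesi_score, pumch_score, spesi_score
from .synthetic import GeneratorSpec, default_generator_spec, generate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "scoring_comparison"]

SPLITS = ("train", "validation", "test")
SCORE_RULES = ("pesi", "spesi", "pumch")

# Decision thresholds when the integer clinical scores are used as
# classifiers (their AUC/AUPRC use the raw totals as ranking statistics):
# the conventional not-low-risk cutoffs.
SCORE_THRESHOLDS = {"pesi": 86.0, "spesi": 1.0, "pumch": 2.0}

_SCORE_FN = {"pesi": pesi_score, "spesi": spesi_score, "pumch": pumch_score}


@dataclass
class ExperimentConfig:
    """Everything one experiment depends on.

    ``distribution`` selects how training rows reach the K clients: "iid"
    (label-balanced dealing), "noniid" (Dirichlet or explicit label-skew
    proportions) or "realworld" (by hospital source).  ``baselines`` is a
    subset of {"centralized", "local_only", "pesi", "spesi", "pumch"}.
    """

    generator: GeneratorSpec | None = None
    cohort_csv: str | None = None
    feature_group: str = "C"
    standardize_binaries: bool = True
    fit_on_train_only: bool = False
    n_test_hospitals: int = 2
    val_fraction: float = 0.10
    distribution: str = "iid"
    dirichlet_alpha: float = 0.5
    noniid_proportions: list | None = None
    hospital_to_client: dict | None = None
    fed: FedConfig = field(default_factory=FedConfig)
    baselines: tuple[str, ...] = ("centralized",)
    replicates: int = 10
    base_seed: int = 0
    threshold: float = 0.3
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("iid", "noniid", "realworld"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        allowed = {"centralized", "local_only", *SCORE_RULES}
        unknown = set(self.baselines) - allowed
        if unknown:
            raise ValueError(f"unknown baselines {sorted(unknown)}")
        if self.generator is None and self.cohort_csv is None:
            self.generator = default_generator_spec()


# fixed stage indices of the per-replicate seed split
_STAGE_GENERATE, _STAGE_SPLIT, _STAGE_PARTITION, _STAGE_MODEL = range(4)


def stage_seed(replicate_seed: int, stage: int) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    ss = np.random.SeedSequence([int(replicate_seed), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _model_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    return cohort.features, cohort.labels


def _evaluate(
    params: LinearModelParams, splits: dict[str, Cohort], threshold: float
) -> dict[str, MetricsReport]:
    out = {}
    for name, cohort in splits.items():
        scores = predict_proba(params, cohort.features)
        out[name] = threshold_metrics(scores, cohort.labels, threshold)
    return out


def _score_totals(cohort: Cohort, rule: str) -> np.ndarray:
    fn = _SCORE_FN[rule]
    return np.array([fn(rec).total for rec in records_from_cohort(cohort)])


def _assign(config: ExperimentConfig, train: Cohort, seed: int) -> ClientAssignment:
    K = config.fed.K
    if config.distribution == "iid":
        return assign_clients_iid(train.labels, K, seed)
    if config.distribution == "noniid":
        return assign_clients_noniid(
            train.labels,
            K,
            proportions=config.noniid_proportions,
            dirichlet_alpha=config.dirichlet_alpha,
            seed=seed,
        )
    mapping = config.hospital_to_client or balanced_hospital_mapping(
        train.hospital_ids, K
    )
    return assign_clients_realworld(train.hospital_ids, mapping, K)


def run_replicate(config: ExperimentConfig, replicate: int) -> dict:
    """Run one seeded replicate and return its machine-readable record."""
    seed_r = config.base_seed + replicate
    s_gen = stage_seed(seed_r, _STAGE_GENERATE)
    s_split = stage_seed(seed_r, _STAGE_SPLIT)
    s_part = stage_seed(seed_r, _STAGE_PARTITION)
    s_model = stage_seed(seed_r, _STAGE_MODEL)

    if config.cohort_csv is not None:
        spec = config.generator or default_generator_spec()
        cohort = read_cohort_csv(config.cohort_csv, spec.schema)
    else:
        spec = dataclasses.replace(config.generator, seed=s_gen)
        cohort = generate_cohort(spec)

    imputed_raw, fills = impute_mean(cohort)
    grouped = select_feature_group(imputed_raw, config.feature_group)

    train_idx, val_idx, test_idx, test_hospitals = split_indices(
        cohort.hospital_ids, config.n_test_hospitals, config.val_fraction, s_split
    )
    fit_cohort = grouped.take_rows(train_idx) if config.fit_on_train_only else grouped
    std = fit_standardizer(fit_cohort, config.standardize_binaries)
    standardized = apply_standardizer(grouped, std)

    splits = {
        "train": standardized.take_rows(train_idx),
        "validation": standardized.take_rows(val_idx),
        "test": standardized.take_rows(test_idx),
    }
    raw_splits = {
        "train": imputed_raw.take_rows(train_idx),
        "validation": imputed_raw.take_rows(val_idx),
        "test": imputed_raw.take_rows(test_idx),
    }

    assignment = _assign(config, splits["train"], s_part)
    Xtr, ytr = _model_arrays(splits["train"])
    clients = [
        (Xtr[assignment.client_rows(k)], ytr[assignment.client_rows(k)])
        for k in range(assignment.K)
    ]

    fed_cfg = dataclasses.replace(config.fed, seed=s_model)
    val_pair = _model_arrays(splits["validation"])
    fed_params, fed_trace = run_fedavg(clients, fed_cfg, validation=val_pair)

    models: dict[str, dict[str, MetricsReport]] = {
        "fed": _evaluate(fed_params, splits, config.threshold)
    }
    model_scores: dict[str, dict[str, np.ndarray]] = {
        "fed": {
            name: predict_proba(fed_params, c.features) for name, c in splits.items()
        }
    }
    params_out: dict[str, LinearModelParams] = {"fed": fed_params}

    if "centralized" in config.baselines:
        cent_params, _ = train_centralized(Xtr, ytr, fed_cfg, validation=val_pair)
        models["centralized"] = _evaluate(cent_params, splits, config.threshold)
        params_out["centralized"] = cent_params
    if "local_only" in config.baselines:
        for k in range(assignment.K):
            Xk, yk = clients[k]
            local_params = train_local_only(Xk, yk, fed_cfg)
            models[f"client_{k + 1}"] = _evaluate(
                local_params, splits, config.threshold
            )
            params_out[f"client_{k + 1}"] = local_params

    delong_vs_fed: dict[str, dict[str, dict]] = {}
    for rule in SCORE_RULES:
        if rule not in config.baselines:
            continue
        models[rule] = {}
        delong_vs_fed[rule] = {}
        for split_name in SPLITS:
            totals = _score_totals(raw_splits[split_name], rule)
            labels = raw_splits[split_name].labels
            models[rule][split_name] = threshold_metrics(
                totals, labels, SCORE_THRESHOLDS[rule]
            )
            if labels.sum() and (1 - labels).sum():
                res = delong_test(model_scores["fed"][split_name], totals, labels)
                delong_vs_fed[rule][split_name] = {
                    "auc_fed": res.auc_a,
                    "auc_rule": res.auc_b,
                    "delta": res.delta,
                    "z": res.z,
                    "p_two_sided": res.p_two_sided,
                }

    return {
        "replicate": replicate,
        "seed": seed_r,
        "test_hospitals": list(test_hospitals),
        "n_rows": {name: splits[name].n for name in SPLITS},
        "client_sizes": assignment.sizes().tolist(),
        "executed_rounds": fed_trace.executed_rounds,
        "imputation_fills": fills,
        "metrics": {
            model: {s: rep.to_dict() for s, rep in by_split.items()}
            for model, by_split in models.items()
        },
        "delong_vs_fed": delong_vs_fed,
        "_params": params_out,  # stripped before JSON serialization
        "_reports": models,
    }


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all replicates, aggregate, test significance, optionally persist.

    Returns the report bundle: per-replicate records, per-model/per-split
    replicate summaries ("mean ± sd" over replicates), the federated-vs-
    centralized t-test on test AUC, and any per-replicate failures (a
    failing replicate is recorded, not fatal).
    """
    replicate_records: list[dict] = []
    failures: list[dict] = []
    for r in range(1, config.replicates + 1):
        try:
            replicate_records.append(run_replicate(config, r))
        except Exception as exc:  # noqa: BLE001 - failure is part of the report
            failures.append(
                {"replicate": r, "error_type": type(exc).__name__, "error": str(exc)}
            )

    model_names: list[str] = []
    for rec in replicate_records:
        for name in rec["_reports"]:
            if name not in model_names:
                model_names.append(name)

    summaries: dict[str, dict[str, dict]] = {}
    for model in model_names:
        summaries[model] = {}
        for split_name in SPLITS:
            reports = [
                rec["_reports"][model][split_name]
                for rec in replicate_records
                if model in rec["_reports"]
            ]
            if reports:
                summaries[model][split_name] = summarize_replicates(reports).to_dict()

    significance: dict[str, dict] = {}
    if (
        "centralized" in model_names
        and len(replicate_records) >= 2
    ):
        for split_name in SPLITS:
            fed_auc = [r["_reports"]["fed"][split_name].auc for r in replicate_records]
            cen_auc = [
                r["_reports"]["centralized"][split_name].auc
                for r in replicate_records
            ]
            significance[split_name] = {
                "test": "two_tailed_t_test_welch",
                "fed_mean_auc": float(np.mean(fed_auc)),
                "centralized_mean_auc": float(np.mean(cen_auc)),
                "p_value": two_tailed_t_test(fed_auc, cen_auc),
            }

    bundle = {
        "config": _config_payload(config),
        "replicates": [
            {k: v for k, v in rec.items() if not k.startswith("_")}
            for rec in replicate_records
        ],
        "summaries": summaries,
        "fed_vs_centralized_ttest": significance,
        "failures": failures,
        "partial": bool(failures),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        for rec in replicate_records:
            rep_dir = out / f"replicate_{rec['replicate']:03d}"
            _write_json(
                rep_dir / "metrics.json",
                {k: v for k, v in rec.items() if not k.startswith("_")},
            )
            for model, params in rec["_params"].items():
                rep_dir.mkdir(parents=True, exist_ok=True)
                params.to_json(rep_dir / f"params_{model}.json")
        _write_json(
            out / "summary.json", {k: v for k, v in bundle.items() if k != "replicates"}
        )
    return bundle


def scoring_comparison(config: ExperimentConfig) -> dict:
    """The federated model against PESI/sPESI/PUMCH on identical splits.

    Forces the three clinical-score baselines on, runs the experiment, and
    returns the bundle (whose ``delong_vs_fed`` blocks hold the per-split
    DeLong p-values against the federated model).
    """
    baselines = tuple(dict.fromkeys([*config.baselines, *SCORE_RULES]))
    config = dataclasses.replace(config, baselines=baselines)
    return run_experiment(config)


def _config_payload(config: ExperimentConfig) -> dict:
    payload = dataclasses.asdict(config)
    gen = payload.get("generator")
    if gen is not None:
        # the schema dataclass is deeply nested; record its column names only
        payload["generator"] = {
            "n_patients": gen["n_patients"],
            "n_events": gen["n_events"],
            "n_hospitals": len(gen["hospitals"]),
            "seed": gen["seed"],
            "features": list(config.generator.schema.names),
        }
    return payload
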