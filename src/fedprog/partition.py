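"""Train/validation/test splitting and federated client assignment.

The held-out test set is formed from whole hospitals (the smallest ones by
row count), the validation set is a seeded 10%-per-hospital sample of the
remainder, and the training rows are distributed to K simulated clients
under one of three regimes:

* IID — positive and negative rows dealt to clients in equal proportions;
* Non-IID — label/size skew, with per-class client proportions either given
  explicitly or drawn from a symmetric Dirichlet;
* Real-world — each client holds the rows of its mapped hospitals.

Clients are indexed 0..K-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "DatasetSplit",
    "ClientAssignment",
    "split_indices",
    "make_splits",
    "assign_clients_iid",
    "assign_clients_noniid",
    "assign_clients_realworld",
    "balanced_hospital_mapping",
]


@dataclass
class DatasetSplit:
    train: Cohort
    validation: Cohort
    test: Cohort
    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray
    test_hospitals: tuple[str, ...]


@dataclass
class ClientAssignment:
    """Training-row -> client map; ``client_of[i]`` in 0..K-1."""

    client_of: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.client_of = np.asarray(self.client_of, dtype=int)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.client_of.size and (
            self.client_of.min() < 0 or self.client_of.max() >= self.K
        ):
            raise ValueError("client ids out of range")
        sizes = np.bincount(self.client_of, minlength=self.K)
        if (sizes == 0).any():
            raise ValueError(f"empty client(s): {np.flatnonzero(sizes == 0).tolist()}")

    def client_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.client_of == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.client_of, minlength=self.K)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"row_index": np.arange(self.client_of.size), "client_id": self.client_of}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, K: int | None = None) -> "ClientAssignment":
        df = pd.read_csv(path)
        client_of = df.sort_values("row_index")["client_id"].to_numpy()
        return cls(client_of, K if K is not None else int(client_of.max()) + 1)


def _round_half_away(x: float) -> int:
    """round() with halves away from zero (0.5 -> 1), for the 10% draw."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_indices(
    hospital_ids: np.ndarray,
    n_test_hospitals: int = 2,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Row indices of (train, validation, test) plus the test hospitals.

    Depends only on hospital membership and the seed, so the same split can
    be applied to differently preprocessed copies of one cohort.
    """
    hospital_ids = np.asarray(hospital_ids).astype(str)
    ids, counts = np.unique(hospital_ids, return_counts=True)
    if n_test_hospitals < 0 or n_test_hospitals >= len(ids):
        raise ValueError(
            f"need 0 <= n_test_hospitals < number of hospitals ({len(ids)})"
        )
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")

    # smallest hospitals become the test set; ties broken by id order
    order = sorted(range(len(ids)), key=lambda i: (counts[i], ids[i]))
    test_hospitals = tuple(ids[i] for i in order[:n_test_hospitals])
    test_idx = np.flatnonzero(np.isin(hospital_ids, test_hospitals))

    rng = np.random.default_rng(seed)
    val_parts: list[np.ndarray] = []
    train_parts: list[np.ndarray] = []
    for i in order[n_test_hospitals:]:
        hosp = ids[i]
        rows = np.flatnonzero(hospital_ids == hosp)
        n_h = rows.size
        n_val = _round_half_away(val_fraction * n_h)
        if n_h < 2 or n_val >= n_h:
            raise ValueError(
                f"hospital {hosp!r} ({n_h} rows) cannot contribute to both "
                "train and validation"
            )
        chosen = rng.choice(rows, size=n_val, replace=False)
        val_parts.append(np.sort(chosen))
        train_parts.append(np.setdiff1d(rows, chosen))
    val_idx = (
        np.sort(np.concatenate(val_parts)) if val_parts else np.array([], dtype=int)
    )
    train_idx = (
        np.sort(np.concatenate(train_parts)) if train_parts else np.array([], dtype=int)
    )
    return train_idx, val_idx, test_idx, test_hospitals


def make_splits(
    cohort: Cohort,
    n_test_hospitals: int = 2,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> DatasetSplit:
    """Hospital-held-out test set, 10%-per-hospital validation, rest train."""
    train_idx, val_idx, test_idx, test_hospitals = split_indices(
        cohort.hospital_ids, n_test_hospitals, val_fraction, seed
    )
    return DatasetSplit(
        train=cohort.take_rows(train_idx),
        validation=cohort.take_rows(val_idx),
        test=cohort.take_rows(test_idx),
        train_idx=train_idx,
        validation_idx=val_idx,
        test_idx=test_idx,
        test_hospitals=test_hospitals,
    )


def _deal_round_robin(
    rows: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle ``rows`` and deal them to clients as evenly as possible.

    The dealing order over clients is itself a seeded permutation, so which
    clients receive the remainder is randomized rather than always 0..r-1.
    Returns the client id of each row (aligned with ``rows``).
    """
    shuffled = rng.permutation(rows.size)
    client_order = rng.permutation(K)
    out = np.empty(rows.size, dtype=int)
    out[shuffled] = client_order[np.arange(rows.size) % K]
    return out


def assign_clients_iid(labels: np.ndarray, K: int, seed: int = 0) -> ClientAssignment:
    """Deal positives and negatives separately, as evenly as possible.

    Every client's positive fraction then deviates from the global one by at
    most one sample's worth.
    """
    labels = np.asarray(labels, dtype=int)
    if K < 1:
        raise ValueError("K must be >= 1")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos < K or n_neg < K:
        raise ValueError(
            f"need at least K={K} rows of each class (got {n_pos} pos, {n_neg} neg)"
        )
    rng = np.random.default_rng(seed)
    client_of = np.empty(labels.size, dtype=int)
    for cls in (1, 0):  # positives first: fixed draw order for determinism
        rows = np.flatnonzero(labels == cls)
        client_of[rows] = _deal_round_robin(rows, K, rng)
    return ClientAssignment(client_of, K)


def assign_clients_noniid(
    labels: np.ndarray,
    K: int,
    proportions: np.ndarray | Sequence[Sequence[float]] | None = None,
    dirichlet_alpha: float = 0.5,
    seed: int = 0,
) -> ClientAssignment:
    """Label-skewed assignment: per class, client shares are either the rows
    of ``proportions`` (shape n_classes x K, rows summing to 1; class order
    0 then 1) or draws from Dirichlet(alpha).  Counts use largest-remainder
    rounding; a client left empty is repaired by taking one row from the
    currently largest client.
    """
    labels = np.asarray(labels, dtype=int)
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if proportions is not None:
        proportions = np.asarray(proportions, dtype=float)
        if proportions.shape != (classes.size, K):
            raise ValueError(
                f"proportions must have shape ({classes.size}, {K}), "
                f"got {proportions.shape}"
            )
        if (proportions < 0).any() or (proportions.sum(axis=1) == 0).any():
            raise ValueError("each class's proportions must be nonnegative, not all zero")
        proportions = proportions / proportions.sum(axis=1, keepdims=True)
    else:
        if dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")
        proportions = rng.dirichlet(np.full(K, dirichlet_alpha), size=classes.size)

    client_of = np.empty(labels.size, dtype=int)
    from .synthetic import _largest_remainder  # same rounding rule as the generator

    for c, cls in enumerate(classes):
        rows = rng.permutation(np.flatnonzero(labels == cls))
        counts = _largest_remainder(proportions[c], rows.size)
        boundaries = np.cumsum(counts)[:-1]
        for k, chunk in enumerate(np.split(rows, boundaries)):
            client_of[chunk] = k

    # repair empty clients by moving one row from the largest client
    sizes = np.bincount(client_of, minlength=K)
    while (sizes == 0).any():
        empty = int(np.flatnonzero(sizes == 0)[0])
        donor = int(sizes.argmax())
        if sizes[donor] < 2:
            raise ValueError("not enough rows to populate every client")
        mover = np.flatnonzero(client_of == donor)[0]
        client_of[mover] = empty
        sizes = np.bincount(client_of, minlength=K)
    return ClientAssignment(client_of, K)


def assign_clients_realworld(
    hospital_ids: np.ndarray, hospital_to_client: Mapping[str, int], K: int | None = None
) -> ClientAssignment:
    """Deterministic assignment by hospital source: every training hospital
    must be mapped to exactly one client."""
    hospital_ids = np.asarray(hospital_ids).astype(str)
    present = set(np.unique(hospital_ids).tolist())
    unmapped = present - set(map(str, hospital_to_client))
    if unmapped:
        raise KeyError(f"unmapped hospitals: {sorted(unmapped)}")
    mapping = {str(h): int(k) for h, k in hospital_to_client.items()}
    client_of = np.array([mapping[h] for h in hospital_ids], dtype=int)
    if K is None:
        K = max(mapping[h] for h in present) + 1
    return ClientAssignment(client_of, K)


def balanced_hospital_mapping(
    hospital_ids: np.ndarray, K: int = 5
) -> dict[str, int]:
    """Greedy size-balanced hospital -> client grouping.

    Hospitals are taken largest-first (ties by id) and each is placed on the
    client with the currently smallest total row count (ties by client id).
    """
    hospital_ids = np.asarray(hospital_ids).astype(str)
    ids, counts = np.unique(hospital_ids, return_counts=True)
    if len(ids) < K:
        raise ValueError(f"cannot spread {len(ids)} hospitals over {K} clients")
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    totals = np.zeros(K, dtype=int)
    mapping: dict[str, int] = {}
    for i in order:
        k = int(totals.argmin())
        mapping[str(ids[i])] = k
        totals[k] += counts[i]
    return mapping
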