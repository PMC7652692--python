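"""Client sharding: the four non-IID data-distribution scenarios.

A federation experiment assigns each named client a disjoint subset of the
training records ("without duplication", matching the multi-hospital
framing). Four scenarios are provided:

- ``basic`` — every client gets the same number of uniformly sampled records;
- ``imbalanced_random`` — per-client sizes drawn uniformly from a range
  (quantity skew, e.g. 1-600 records per client);
- ``imbalanced_fraction`` — explicit fractions of the training set
  (e.g. 50/30/20) with largest-remainder rounding;
- ``skewed`` — one client per class, each holding records of only that class
  (extreme label skew: one digit per client);
- ``imbalanced_skewed`` — single-class shards with random sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import LabeledDataset, _largest_remainder_counts
from ._seeds import derive_seed

__all__ = [
    "ClientShard",
    "PartitionPlan",
    "SizingError",
    "partition_basic",
    "partition_imbalanced_random",
    "partition_imbalanced_fraction",
    "partition_skewed",
    "partition_imbalanced_skewed",
    "save_plan",
    "load_plan",
]

SCENARIOS = (
    "basic",
    "imbalanced_random",
    "imbalanced_fraction",
    "skewed",
    "imbalanced_skewed",
)


class SizingError(ValueError):
    """Requested shard sizes cannot be carved from the dataset."""


@dataclass
class ClientShard:
    client_id: str
    record_indices: list[int]

    def __post_init__(self) -> None:
        if len(set(self.record_indices)) != len(self.record_indices):
            raise ValueError(f"duplicate indices in shard {self.client_id}")
        if not self.record_indices:
            raise ValueError(f"shard {self.client_id} is empty")

    @property
    def n_k(self) -> int:
        """Sample count of this client; the FedAVG aggregation weight."""
        return len(self.record_indices)


@dataclass
class PartitionPlan:
    scenario: str
    shards: list[ClientShard]
    source_fingerprint: str
    seed: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for shard in self.shards:
            overlap = seen.intersection(shard.record_indices)
            if overlap:
                raise ValueError(f"shards overlap on indices {sorted(overlap)[:5]}")
            seen.update(shard.record_indices)

    @property
    def client_ids(self) -> list[str]:
        return [s.client_id for s in self.shards]

    def sizes(self) -> dict[str, int]:
        return {s.client_id: s.n_k for s in self.shards}


def dataset_fingerprint(ds: LabeledDataset) -> str:
    """Stable hash of the dataset identity (ids + labels), for plan/DS pairing."""
    h = hashlib.sha256()
    h.update(ds.archetype.encode())
    h.update(ds.split.encode())
    for rid, lab in zip(ds.record_ids, ds.labels):
        h.update(rid.encode())
        h.update(bytes([int(lab) % 256]))
    return h.hexdigest()[:16]


def _client_names(n: int) -> list[str]:
    return [f"client_{i}" for i in range(n)]


def _carve(
    ds: LabeledDataset, sizes: Sequence[int], scenario: str, seed: int
) -> PartitionPlan:
    """Disjoint uniform sampling: permute the train set once, cut consecutively."""
    total = sum(sizes)
    if total > len(ds):
        raise SizingError(f"requested {total} records from a {len(ds)}-record dataset")
    rng = np.random.default_rng(derive_seed(seed, scenario, "carve"))
    perm = rng.permutation(len(ds))
    shards, start = [], 0
    for cid, size in zip(_client_names(len(sizes)), sizes):
        shards.append(ClientShard(cid, [int(i) for i in perm[start : start + size]]))
        start += size
    return PartitionPlan(scenario, shards, dataset_fingerprint(ds), seed)


def partition_basic(
    ds: LabeledDataset, n_clients: int, per_client: int, seed: int = 0
) -> PartitionPlan:
    """Equal-size shards sampled uniformly without replacement across clients."""
    if n_clients < 1 or per_client < 1:
        raise SizingError("n_clients and per_client must be >= 1")
    return _carve(ds, [per_client] * n_clients, "basic", seed)


def partition_imbalanced_random(
    ds: LabeledDataset,
    n_clients: int,
    size_min: int = 1,
    size_max: int = 600,
    seed: int = 0,
    max_retries: int = 100,
) -> PartitionPlan:
    """Shard sizes drawn uniformly from [size_min, size_max] per client.

    If a draw oversubscribes the dataset the sizes are redrawn up to
    ``max_retries`` times before raising :class:`SizingError`.
    """
    if not (1 <= size_min <= size_max):
        raise SizingError("need 1 <= size_min <= size_max")
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            derive_seed(seed, "imbalanced_random", "sizes", attempt)
        )
        sizes = rng.integers(size_min, size_max + 1, size=n_clients)
        if sizes.sum() <= len(ds):
            plan = _carve(ds, [int(s) for s in sizes], "imbalanced_random", seed)
            return plan
    raise SizingError(
        f"could not fit {n_clients} shards of size in [{size_min},{size_max}] "
        f"into {len(ds)} records after {max_retries} draws"
    )


def partition_imbalanced_fraction(
    ds: LabeledDataset, fractions: Sequence[float], seed: int = 0
) -> PartitionPlan:
    """Fractional split (e.g. 0.5/0.3/0.2) with largest-remainder rounding."""
    fr = [float(f) for f in fractions]
    if not fr or min(fr) <= 0:
        raise SizingError("fractions must be positive")
    if sum(fr) > 1.0 + 1e-9:
        raise SizingError("fractions must sum to at most 1")
    if abs(sum(fr) - 1.0) <= 1e-9:
        sizes = _largest_remainder_counts(len(ds), fr)
    else:
        sizes = np.array([int(np.floor(f * len(ds))) for f in fr])
    if sizes.min() < 1:
        raise SizingError("a fraction rounds to an empty shard")
    return _carve(ds, [int(s) for s in sizes], "imbalanced_fraction", seed)


def _per_class_indices(ds: LabeledDataset) -> list[np.ndarray]:
    return [np.flatnonzero(ds.labels == c) for c in range(ds.n_classes)]


def _skewed_plan(
    ds: LabeledDataset, sizes: Sequence[int | None], scenario: str, seed: int
) -> PartitionPlan:
    shards = []
    for c, (pool, size) in enumerate(zip(_per_class_indices(ds), sizes)):
        take = len(pool) if size is None else size
        if take > len(pool):
            raise SizingError(
                f"class {c} has only {len(pool)} records, {take} requested"
            )
        rng = np.random.default_rng(derive_seed(seed, scenario, "class", c))
        chosen = rng.choice(pool, size=take, replace=False)
        shards.append(ClientShard(f"client_{c}", [int(i) for i in chosen]))
    return PartitionPlan(scenario, shards, dataset_fingerprint(ds), seed)


def partition_skewed(
    ds: LabeledDataset, per_client: int | None = None, seed: int = 0
) -> PartitionPlan:
    """One client per class; each shard holds only that class's records."""
    return _skewed_plan(ds, [per_client] * ds.n_classes, "skewed", seed)


def partition_imbalanced_skewed(
    ds: LabeledDataset, size_min: int = 1, size_max: int = 600, seed: int = 0
) -> PartitionPlan:
    """Single-class shards with sizes drawn uniformly from [size_min, size_max]."""
    if not (1 <= size_min <= size_max):
        raise SizingError("need 1 <= size_min <= size_max")
    rng = np.random.default_rng(derive_seed(seed, "imbalanced_skewed", "sizes"))
    sizes = [int(s) for s in rng.integers(size_min, size_max + 1, size=ds.n_classes)]
    return _skewed_plan(ds, sizes, "imbalanced_skewed", seed)


def save_plan(plan: PartitionPlan, path: str | Path) -> None:
    doc = {
        "scenario": plan.scenario,
        "seed": plan.seed,
        "source_fingerprint": plan.source_fingerprint,
        "shards": [
            {"client_id": s.client_id, "record_indices": s.record_indices}
            for s in plan.shards
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_plan(path: str | Path) -> PartitionPlan:
    doc = json.loads(Path(path).read_text())
    return PartitionPlan(
        scenario=doc["scenario"],
        shards=[
            ClientShard(s["client_id"], [int(i) for i in s["record_indices"]])
            for s in doc["shards"]
        ],
        source_fingerprint=doc["source_fingerprint"],
        seed=doc["seed"],
    )
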