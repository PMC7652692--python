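"""Synthetic stand-ins for the three benchmark datasets.

Every downstream module (partitioning, federation, protocol, evaluation) is
exercised on data produced here, so nothing in the package needs a download.
Three archetypes are generated, each reproducing only the statistical
structure the benchmark experiments rely on:

``image10``
    Fixed-shape 28x28 "images", 10 classes drawn as class prototypes plus
    Gaussian pixel noise. Selected class pairs (by default {3,5} and {4,9},
    the visually similar digit pairs) share correlated prototypes so a
    classifier confuses them more often than unrelated pairs.
``icu_mortality``
    Variable-length multivariate vital-sign-like series (default 17
    channels, emulating the first 48 h of an ICU stay) with a binary
    in-hospital-mortality label tied to a latent severity score through a
    logistic link. The positive (death) class is the minority.
``ecg4``
    Variable-length single-channel 1-D signals in four rhythm classes:
    regular quasi-periodic (normal sinus), irregular inter-beat intervals
    (AF-like), altered beat morphology (other rhythm), and broadband noise
    (the rare "noisy" class, ~3% of records by default).

All generators are deterministic functions of their :class:`GeneratorConfig`
(including its seed); identical configs give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ._seeds import derive_seed

__all__ = [
    "ARCHETYPES",
    "LabeledDataset",
    "GeneratorConfig",
    "generate",
    "generate_image10",
    "generate_icu",
    "generate_ecg4",
    "generate_split_pair",
    "save_dataset_container",
    "load_dataset_container",
]

ARCHETYPES = ("image10", "icu_mortality", "ecg4")

#: Default class mixes. The ECG mix makes the broadband-noise class ~3% of
#: records, matching the rarity that degrades its per-class precision/recall.
_DEFAULT_PROPORTIONS = {
    "image10": tuple([0.1] * 10),
    "icu_mortality": (0.87, 0.13),
    "ecg4": (0.60, 0.09, 0.28, 0.03),
}
_N_CLASSES = {"image10": 10, "icu_mortality": 2, "ecg4": 4}
_DEFAULT_LENGTH_RANGE = {
    "image10": None,
    "icu_mortality": (16, 48),  # hourly samples, up to 48 h
    "ecg4": (300, 900),
}


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass
class LabeledDataset:
    """Records plus integer labels for one archetype and one split."""

    records: list[np.ndarray]
    labels: np.ndarray
    n_classes: int
    archetype: str
    split: str
    record_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels length mismatch")
        if len(set(self.record_ids)) != len(self.record_ids):
            raise ValueError("record_ids must be unique")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError("labels outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: Sequence[int], split: str | None = None) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            labels=self.labels[idx],
            n_classes=self.n_classes,
            archetype=self.archetype,
            split=split or self.split,
            record_ids=[self.record_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic-dataset draw.

    ``noise_scale`` multiplies the archetype's nominal observation noise;
    ``confusability`` (image10 only) is a symmetric class-similarity matrix
    with unit diagonal; ``severity_coef`` (ICU only) scales how strongly the
    latent severity drives the mortality label (0 gives a label with no
    signal); ``label_mode`` is ``stratified`` (exact class counts by largest
    remainder — small fixtures are exact) or ``iid`` (each label drawn
    independently from the class proportions).
    """

    archetype: str
    n_train: int = 1000
    n_test: int = 200
    class_proportions: tuple[float, ...] | None = None
    noise_scale: float = 1.0
    confusability: np.ndarray | None = None
    length_range: tuple[int, int] | None = None
    label_mode: str = "stratified"
    n_channels: int = 17
    severity_coef: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if self.n_train < 0 or self.n_test < 0:
            raise ConfigurationError("n_train/n_test must be nonnegative")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be nonnegative")
        if self.label_mode not in ("stratified", "iid"):
            raise ConfigurationError(f"unknown label_mode {self.label_mode!r}")
        props = self.proportions
        if len(props) != self.n_classes:
            raise ConfigurationError(
                f"class_proportions needs {self.n_classes} entries, got {len(props)}"
            )
        if min(props) < 0 or abs(sum(props) - 1.0) > 1e-6:
            raise ConfigurationError("class_proportions must be >=0 and sum to 1")
        lr = self.lengths
        if lr is not None and (lr[0] < 1 or lr[0] > lr[1]):
            raise ConfigurationError("length_range needs 1 <= min <= max")

    @property
    def n_classes(self) -> int:
        return _N_CLASSES[self.archetype]

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.class_proportions is not None:
            return tuple(float(p) for p in self.class_proportions)
        return _DEFAULT_PROPORTIONS[self.archetype]

    @property
    def lengths(self) -> tuple[int, int] | None:
        return self.length_range or _DEFAULT_LENGTH_RANGE[self.archetype]


def _largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer class counts summing to n, proportional by largest remainder."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _draw_labels(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    props = np.asarray(cfg.proportions)
    if cfg.label_mode == "iid":
        return rng.choice(cfg.n_classes, size=n, p=props / props.sum())
    counts = _largest_remainder_counts(n, props)
    labels = np.repeat(np.arange(cfg.n_classes), counts)
    rng.shuffle(labels)
    return labels


def _default_confusability() -> np.ndarray:
    c = np.eye(10)
    for a, b in ((3, 5), (4, 9)):
        c[a, b] = c[b, a] = 0.85
    return c


def _image_prototypes(cfg: GeneratorConfig) -> np.ndarray:
    """Class prototypes with pairwise correlations set by the confusability
    matrix: rows of L @ B have covariance C across the class dimension."""
    conf = cfg.confusability
    if conf is None:
        conf = _default_confusability()
    conf = np.asarray(conf, dtype=float)
    if conf.shape != (10, 10) or not np.allclose(conf, conf.T):
        raise ConfigurationError("confusability must be a symmetric 10x10 matrix")
    rng = np.random.default_rng(derive_seed(cfg.seed, "image10", "prototypes"))
    base = rng.standard_normal((10, 28 * 28))
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    try:
        chol = np.linalg.cholesky(conf + 1e-9 * np.eye(10))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("confusability matrix is not positive definite") from exc
    protos = chol @ base
    return protos / np.linalg.norm(protos, axis=1, keepdims=True)


def generate_image10(cfg: GeneratorConfig, split: str = "train") -> LabeledDataset:
    """Fixed-shape 28x28 records: unit-norm class prototype + pixel noise."""
    if cfg.archetype != "image10":
        raise ConfigurationError("config archetype must be image10")
    n = cfg.n_train if split == "train" else cfg.n_test
    rng = np.random.default_rng(derive_seed(cfg.seed, "image10", split))
    labels = _draw_labels(cfg, n, rng)
    protos = _image_prototypes(cfg)
    # prototype pixels are O(1/sqrt(784)); per-pixel noise is scaled so that
    # confusable prototype pairs (correlation 0.85) sit ~1 noise-sd apart
    # while unrelated pairs sit ~3 sd apart — a linear classifier then errs
    # mostly between the flagged pairs, as on the real digits
    sigma = cfg.noise_scale * 0.25
    records = []
    for lab in labels:
        img = protos[lab].reshape(28, 28) + sigma * rng.standard_normal((28, 28))
        records.append(img.astype(np.float32))
    ids = [f"image10-{cfg.seed}-{split}-{i}" for i in range(n)]
    return LabeledDataset(records, labels, 10, "image10", split, ids)


def _icu_threshold(coef: float, target_pos: float) -> float:
    """Threshold c with E_z[sigmoid(coef*z - c)] == target positive rate."""
    if target_pos <= 0.0:
        return np.inf
    if target_pos >= 1.0:
        return -np.inf
    grid = np.linspace(-8, 8, 4001)
    weights = np.exp(-0.5 * grid**2)
    weights /= weights.sum()

    def marginal(c: float) -> float:
        return float(weights @ expit(coef * grid - c)) - target_pos

    return brentq(marginal, -50.0, 50.0)


def generate_icu(cfg: GeneratorConfig, split: str = "train") -> LabeledDataset:
    """Variable-length multichannel series with a severity-linked label.

    A latent severity ``z ~ N(0,1)`` shifts every channel through a fixed
    loading vector; the mortality label is 1 when ``severity_coef*z`` plus
    logistic noise exceeds a threshold, i.e. P(death|z) follows a logistic
    link. In stratified mode the threshold is the empirical utility quantile
    (exact class counts); in iid mode it is solved so the marginal positive
    rate matches the configured proportion.
    """
    if cfg.archetype != "icu_mortality":
        raise ConfigurationError("config archetype must be icu_mortality")
    n = cfg.n_train if split == "train" else cfg.n_test
    rng = np.random.default_rng(derive_seed(cfg.seed, "icu", split))
    lo, hi = cfg.lengths
    p_pos = cfg.proportions[1]

    z = rng.standard_normal(n)
    noise = rng.logistic(size=n)
    utility = cfg.severity_coef * z + noise
    if cfg.label_mode == "stratified":
        n_pos = _largest_remainder_counts(n, cfg.proportions)[1]
        labels = np.zeros(n, dtype=np.int64)
        if n_pos:
            labels[np.argsort(-utility, kind="stable")[:n_pos]] = 1
    else:
        labels = (utility > _icu_threshold(cfg.severity_coef, p_pos)).astype(np.int64)

    # channel geometry fixed per config seed, shared by train and test
    geo = np.random.default_rng(derive_seed(cfg.seed, "icu", "channels"))
    baseline = geo.standard_normal(cfg.n_channels)
    loading = geo.normal(0.0, 0.5, cfg.n_channels)

    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        eps = rng.standard_normal((length, cfg.n_channels)) * cfg.noise_scale
        ar = np.empty_like(eps)
        ar[0] = eps[0]
        for t in range(1, length):  # AR(1) temporal correlation
            ar[t] = 0.8 * ar[t - 1] + np.sqrt(1 - 0.8**2) * eps[t]
        series = baseline + z[i] * loading + ar
        records.append(series.astype(np.float32))
    ids = [f"icu-{cfg.seed}-{split}-{i}" for i in range(n)]
    return LabeledDataset(records, labels, 2, "icu_mortality", split, ids)


def _gauss_beat(width: float, half: int) -> np.ndarray:
    t = np.arange(-half, half + 1, dtype=float)
    return np.exp(-0.5 * (t / width) ** 2)


def _ecg_signal(label: int, length: int, noise: float, rng: np.random.Generator) -> np.ndarray:
    sig = np.zeros(length)
    if label == 3:  # broadband noise: flat spectrum by construction
        return (0.5 * rng.standard_normal(length)).astype(np.float32)
    if label == 2:  # altered morphology: wide biphasic beats, regular rhythm
        half = 12
        t = np.arange(-half, half + 1, dtype=float)
        beat = -t / 8.0 * np.exp(-0.5 * (t / 8.0) ** 2) * np.e**0.5
    else:  # narrow monophasic beat for normal and AF-like rhythms
        half = 6
        beat = _gauss_beat(3.0, half)
    interval = rng.integers(55, 76)
    pos = int(rng.integers(0, interval))
    while pos < length:
        a, b = max(pos - half, 0), min(pos + half + 1, length)
        sig[a:b] += beat[a - (pos - half) : b - (pos - half)]
        if label == 1:  # AF-like: each inter-beat gap drawn independently
            pos += int(rng.integers(35, 96))
        else:
            pos += int(interval + rng.integers(-1, 2))
    drift = 0.05 * np.sin(2 * np.pi * np.arange(length) / length * rng.uniform(1, 3))
    sig += drift + noise * 0.05 * rng.standard_normal(length)
    return sig.astype(np.float32)


def generate_ecg4(cfg: GeneratorConfig, split: str = "train") -> LabeledDataset:
    """Four-class 1-D rhythm signals with a rare broadband-noise class."""
    if cfg.archetype != "ecg4":
        raise ConfigurationError("config archetype must be ecg4")
    n = cfg.n_train if split == "train" else cfg.n_test
    rng = np.random.default_rng(derive_seed(cfg.seed, "ecg4", split))
    labels = _draw_labels(cfg, n, rng)
    lo, hi = cfg.lengths
    records = [
        _ecg_signal(int(lab), int(rng.integers(lo, hi + 1)), cfg.noise_scale, rng)
        for lab in labels
    ]
    ids = [f"ecg4-{cfg.seed}-{split}-{i}" for i in range(n)]
    return LabeledDataset(records, labels, 4, "ecg4", split, ids)


_GENERATORS = {
    "image10": generate_image10,
    "icu_mortality": generate_icu,
    "ecg4": generate_ecg4,
}


def generate(cfg: GeneratorConfig, split: str = "train") -> LabeledDataset:
    """Generate one split of the archetype named in the config."""
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    return _GENERATORS[cfg.archetype](cfg, split)


def generate_split_pair(cfg: GeneratorConfig) -> tuple[LabeledDataset, LabeledDataset]:
    """Train and test splits from one config; record ids are disjoint."""
    return generate(cfg, "train"), generate(cfg, "test")


# ---------------------------------------------------------------------------
# portable container: metadata.json + per-split ragged arrays + label CSVs


def save_dataset_container(
    directory: str | Path, splits: dict[str, LabeledDataset], seed: int | None = None
) -> None:
    """Write datasets as one metadata JSON plus per-split ragged arrays.

    Records are stored flattened back-to-back with an offsets vector and an
    explicit per-record shape table, so variable-length archetypes round-trip
    exactly. Labels are additionally exported as CSV for eyeballing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict = {"splits": {}, "seed": seed}
    for name, ds in splits.items():
        meta["archetype"] = ds.archetype
        meta["n_classes"] = ds.n_classes
        meta["splits"][name] = len(ds)
        flat = (
            np.concatenate([r.ravel() for r in ds.records])
            if ds.records
            else np.empty(0, dtype=np.float32)
        )
        sizes = np.array([r.size for r in ds.records], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        shapes = np.array([r.shape for r in ds.records], dtype=np.int64).reshape(
            len(ds), -1
        )
        np.savez(
            directory / f"{name}_records.npz",
            values=flat.astype(np.float32),
            offsets=offsets,
            shapes=shapes,
            labels=ds.labels,
        )
        with open(directory / f"{name}_labels.csv", "w") as fh:
            fh.write("record_id,label\n")
            for rid, lab in zip(ds.record_ids, ds.labels):
                fh.write(f"{rid},{int(lab)}\n")
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_dataset_container(directory: str | Path) -> dict[str, LabeledDataset]:
    directory = Path(directory)
    with open(directory / "metadata.json") as fh:
        meta = json.load(fh)
    out: dict[str, LabeledDataset] = {}
    for name in meta["splits"]:
        with np.load(directory / f"{name}_records.npz") as npz:
            values, offsets = npz["values"], npz["offsets"]
            shapes, labels = npz["shapes"], npz["labels"]
        records = [
            values[offsets[i] : offsets[i + 1]].reshape(tuple(shapes[i]))
            for i in range(len(labels))
        ]
        ids = []
        with open(directory / f"{name}_labels.csv") as fh:
            next(fh)
            ids = [line.split(",")[0] for line in fh if line.strip()]
        out[name] = LabeledDataset(
            records, labels, meta["n_classes"], meta["archetype"], name, ids
        )
    return out
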