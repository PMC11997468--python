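"""Synthetic two-class image datasets and stratified splitting.

The generator emulates the statistical structure a cold-start
active-learning study needs from its data without modeling radiograph
appearance: strong class imbalance, within-class sub-cluster structure
(so diversity sampling has something to find), a spectrum of per-sample
difficulty (so uncertainty sampling has something to rank), and a
low-dimensional latent coordinate from which both the image and an
"oracle" embedding can be derived.

Each sample is drawn from one of ``clusters_per_class`` Gaussian clusters
in latent space; the image is a fixed smooth basis expansion of the
latent vector, plus a class-specific spatial template whose amplitude is
per-sample log-normal (graded difficulty), plus pixel noise, squashed to
[0, 1] with a logistic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticDatasetSpec",
    "ImageDataset",
    "DataSplit",
    "generate_dataset",
    "preset",
    "stratified_split",
    "save_image_dir",
    "load_image_dir",
    "save_bundle",
    "load_bundle",
]

#: preset (n_samples, n_positive) pairs: a large imbalanced pediatric
#: pneumonia-like cohort and a small imbalanced COVID-19-like cohort
_PRESETS = {
    "guangzhou_like": (5856, 4273),
    "pakistan_like": (450, 390),
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the synthetic generator.

    ``cluster_separation`` is the distance between latent cluster centers
    in units of the within-cluster latent SD (``latent_sd``);
    ``difficulty_spread`` is the log-normal sigma of the per-sample
    class-signal amplitude (0 = every sample equally hard).
    """

    n_samples: int
    n_positive: int
    image_width: int = 32
    image_height: int = 32
    clusters_per_class: int = 2
    cluster_separation: float = 4.0
    difficulty_spread: float = 1.0
    noise_sd: float = 0.3
    latent_dim: int = 8
    latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if not 0 < self.n_positive < self.n_samples:
            raise ValueError(
                f"n_positive must satisfy 0 < n_positive < n_samples, got {self.n_positive}"
            )
        for name in ("image_width", "image_height", "clusters_per_class", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in ("cluster_separation", "difficulty_spread", "noise_sd", "latent_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")


@dataclass
class ImageDataset:
    """Images with binary labels and unique string ids.

    ``latents`` holds the ground-truth generative coordinates; they are
    retained for oracle encoders and tests and must never be shown to
    query strategies or classifiers.
    """

    images: np.ndarray  # (n, H, W) float in [0, 1]
    labels: np.ndarray  # (n,) in {0, 1}
    ids: list[str]
    latents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.ids)
        if not (self.images.shape[0] == self.labels.shape[0] == n):
            raise ValueError("images, labels and ids must have equal lengths")
        if len(set(self.ids)) != n:
            raise ValueError("ids must be unique")
        if n and (self.images.min() < 0.0 or self.images.max() > 1.0):
            raise ValueError("pixel values must lie in [0, 1]")
        if self.latents is not None and self.latents.shape[0] != n:
            raise ValueError("latents must have one row per sample")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, indices: np.ndarray | list[int]) -> "ImageDataset":
        indices = np.asarray(indices, dtype=int)
        return ImageDataset(
            images=self.images[indices],
            labels=self.labels[indices],
            ids=[self.ids[i] for i in indices],
            latents=None if self.latents is None else self.latents[indices],
        )

    def subset_by_ids(self, wanted: list[str]) -> "ImageDataset":
        pos = {s: i for i, s in enumerate(self.ids)}
        return self.subset([pos[s] for s in wanted])


@dataclass
class DataSplit:
    train: ImageDataset
    test: ImageDataset

    def __post_init__(self) -> None:
        if set(self.train.ids) & set(self.test.ids):
            raise ValueError("train and test ids must be disjoint")


def _smooth_basis(latent_dim: int, height: int, width: int) -> np.ndarray:
    """Fixed low-frequency cosine basis images, unit RMS each."""
    ys = (np.arange(height) + 0.5) / height
    xs = (np.arange(width) + 0.5) / width
    freqs = [(fy, fx) for fy in range(4) for fx in range(4) if (fy, fx) != (0, 0)]
    basis = np.empty((latent_dim, height, width))
    for d in range(latent_dim):
        fy, fx = freqs[d % len(freqs)]
        img = np.cos(np.pi * fy * ys)[:, None] * np.cos(np.pi * fx * xs)[None, :]
        basis[d] = img / np.sqrt(np.mean(img**2))
    return basis


def _class_templates(height: int, width: int) -> np.ndarray:
    """One distinct Gaussian-blob pattern per class, unit RMS each."""
    yy, xx = np.meshgrid(
        (np.arange(height) + 0.5) / height, (np.arange(width) + 0.5) / width, indexing="ij"
    )

    def blob(cy: float, cx: float, s: float) -> np.ndarray:
        return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)))

    t0 = blob(0.70, 0.30, 0.14)
    t1 = blob(0.30, 0.70, 0.14) + 0.6 * blob(0.65, 0.75, 0.10)
    out = np.stack([t0, t1])
    return out / np.sqrt(np.mean(out**2, axis=(1, 2), keepdims=True))


#: fixed gains of the two structured image components; per-pixel noise is
#: scaled by the spec's noise_sd. The class-signal gain is calibrated so a
#: pixel classifier's learning curve over 10-50 labels stays clearly below
#: the all-samples upper bound instead of saturating immediately.
_LATENT_GAIN = 0.5
_SIGNAL_GAIN = 0.2


def generate_dataset(spec: SyntheticDatasetSpec) -> ImageDataset:
    """Draw a fully reproducible synthetic dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.latent_dim
    h, w = spec.image_height, spec.image_width

    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: spec.n_positive]] = 1

    # latent cluster centers per class, placed on a sphere whose radius makes
    # typical center-to-center distances ~= cluster_separation * latent_sd
    centers = rng.standard_normal((2, spec.clusters_per_class, d))
    norms = np.linalg.norm(centers, axis=2, keepdims=True)
    norms[norms == 0] = 1.0
    radius = spec.cluster_separation * spec.latent_sd / math.sqrt(2.0)
    centers = centers / norms * radius

    cluster_of = rng.integers(0, spec.clusters_per_class, size=n)
    latents = centers[labels, cluster_of] + spec.latent_sd * rng.standard_normal((n, d))

    basis = _smooth_basis(d, h, w)
    templates = _class_templates(h, w)

    # per-sample log-normal amplitude with median 1 controls difficulty
    amplitude = np.exp(spec.difficulty_spread * rng.standard_normal(n))

    raw = _LATENT_GAIN / math.sqrt(d) * np.tensordot(latents, basis, axes=(1, 0))
    raw += _SIGNAL_GAIN * amplitude[:, None, None] * templates[labels]
    raw += spec.noise_sd * rng.standard_normal((n, h, w))
    images = 1.0 / (1.0 + np.exp(-raw))

    ids = [f"s{i:05d}" for i in range(n)]
    dataset = ImageDataset(images=images, labels=labels, ids=ids, latents=latents)
    # diagnostic metadata for generator sanity checks; not part of the contract
    dataset.planted_clusters = labels * spec.clusters_per_class + cluster_of
    return dataset


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def preset(name: str, scale: float = 1.0, **overrides) -> SyntheticDatasetSpec:
    """Spec for one of the study-sized cohorts, optionally scaled down.

    At ``scale=1`` the sample counts match the cohorts the benchmark
    mirrors (5856/4273 and 450/390); at smaller scales both counts are
    multiplied and rounded half-up, preserving 0 < n_positive < n_samples.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    n_samples, n_positive = _PRESETS[name]
    n_samples = max(_round_half_up(n_samples * scale), 2)
    n_positive = min(max(_round_half_up(n_positive * scale), 1), n_samples - 1)
    return SyntheticDatasetSpec(n_samples=n_samples, n_positive=n_positive, **overrides)


def _train_count(class_count: int, train_fraction: float) -> int:
    """Per-class training-set size: ceiling of count x fraction.

    Isolated here so the rounding rule can be swapped in one place.
    """
    return math.ceil(class_count * train_fraction)


def stratified_split(dataset: ImageDataset, train_fraction: float, seed: int) -> DataSplit:
    """Class-stratified random split with per-class ceiling rounding."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    classes = np.unique(dataset.labels)
    if classes.size < 2:
        raise ValueError("stratified_split requires both classes present")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(dataset.labels == c)
        members = members[rng.permutation(members.size)]
        k = _train_count(members.size, train_fraction)
        train_idx.extend(members[:k].tolist())
        test_idx.extend(members[k:].tolist())
    return DataSplit(train=dataset.subset(sorted(train_idx)), test=dataset.subset(sorted(test_idx)))


# ---------------------------------------------------------------------------
# persistence: PNG directory + CSV manifest, and a fast binary bundle


def save_image_dir(dataset: ImageDataset, directory: str | Path) -> Path:
    """Write images as 8-bit grayscale PNGs plus a ``manifest.csv``.

    Pixels are quantized to uint8; latents are not stored in this format.
    """
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "filename", "label"])
        for i, sid in enumerate(dataset.ids):
            fname = f"{sid}.png"
            arr = np.clip(np.round(dataset.images[i] * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(directory / fname)
            writer.writerow([sid, fname, int(dataset.labels[i])])
    return manifest


def load_image_dir(directory: str | Path) -> ImageDataset:
    from PIL import Image

    directory = Path(directory)
    ids: list[str] = []
    labels: list[int] = []
    images: list[np.ndarray] = []
    with open(directory / "manifest.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["id"])
            labels.append(int(row["label"]))
            arr = np.asarray(Image.open(directory / row["filename"]).convert("L"), dtype=float)
            images.append(arr / 255.0)
    return ImageDataset(images=np.stack(images), labels=np.array(labels), ids=ids)


def save_bundle(dataset: ImageDataset, path: str | Path) -> None:
    """Round-trip the full dataset (including latents) through one NPZ file."""
    payload = {
        "images": dataset.images,
        "labels": dataset.labels,
        "ids": np.array(dataset.ids),
    }
    if dataset.latents is not None:
        payload["latents"] = dataset.latents
    np.savez_compressed(path, **payload)


def load_bundle(path: str | Path) -> ImageDataset:
    with np.load(path, allow_pickle=False) as data:
        return ImageDataset(
            images=data["images"],
            labels=data["labels"],
            ids=[str(s) for s in data["ids"]],
            latents=data["latents"] if "latents" in data else None,
        )
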