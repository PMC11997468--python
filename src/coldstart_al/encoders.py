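"""Frozen representation providers mapping images to embeddings.

Real pretrained backbones (domain-specific or general) plug in behind the
same two-call surface — ``make_encoder`` and ``encode`` — but the package
ships synthetic stand-ins only, keeping the benchmark download-free:

``oracle_informative``
    A noisy linear map of the generator's ground-truth latents. Its
    ``informativeness`` knob mixes signal against per-sample hash noise,
    spanning the spectrum from a perfect domain-specific encoder (1.0)
    to one carrying no task information (0.0).
``generic_frozen``
    A fixed random convolutional filter bank over the pixels with global
    average pooling — the classic "random features" stand-in for a
    general-domain frozen backbone.
``degraded``
    ``generic_frozen`` with the same hash-noise mixing applied, for
    ablations between the two.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datasets import ImageDataset

__all__ = [
    "EncoderModel",
    "EmbeddingMatrix",
    "make_encoder",
    "encode",
    "standardize_embeddings",
    "save_embeddings_csv",
    "load_embeddings_csv",
]

_KINDS = ("oracle_informative", "generic_frozen", "degraded")
_FILTER_SIZE = 5


@dataclass(frozen=True)
class EncoderModel:
    name: str
    kind: str
    embedding_dim: int
    informativeness: float
    seed: int

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError(f"embedding_dim must be >= 2, got {self.embedding_dim}")
        if not 0.0 <= self.informativeness <= 1.0:
            raise ValueError(f"informativeness must be in [0, 1], got {self.informativeness}")


@dataclass
class EmbeddingMatrix:
    ids: list[str]
    vectors: np.ndarray  # (n, embedding_dim)
    encoder_name: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be a 2-D array with one row per id")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def embedding_dim(self) -> int:
        return self.vectors.shape[1]

    def subset_by_ids(self, wanted: list[str]) -> "EmbeddingMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in wanted]
        return EmbeddingMatrix(ids=list(wanted), vectors=self.vectors[idx], encoder_name=self.encoder_name)


def make_encoder(
    kind: str,
    embedding_dim: int = 32,
    informativeness: float = 1.0,
    seed: int = 0,
    name: str | None = None,
) -> EncoderModel:
    if kind not in _KINDS:
        raise ValueError(f"unknown encoder kind {kind!r}; choose from {_KINDS}")
    return EncoderModel(
        name=name or f"{kind}_d{embedding_dim}_i{informativeness:g}",
        kind=kind,
        embedding_dim=embedding_dim,
        informativeness=informativeness,
        seed=seed,
    )


def _sample_hash_noise(image: np.ndarray, dim: int, salt: int) -> np.ndarray:
    """Deterministic pseudo-noise derived from the image content alone.

    Hashing the pixel bytes keeps encoding row-wise pure (the embedding of
    sample i depends only on image i) while destroying any usable class
    structure, which is exactly what an uninformative feature should do.
    """
    digest = hashlib.blake2b(image.tobytes(), digest_size=8, salt=salt.to_bytes(8, "little", signed=True)).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


def _mix(signal: np.ndarray, images: np.ndarray, informativeness: float, salt: int) -> np.ndarray:
    if informativeness >= 1.0:
        return signal
    noise = np.stack([_sample_hash_noise(img, signal.shape[1], salt) for img in images])
    return informativeness * signal + (1.0 - informativeness) * noise


def _filter_bank_features(images: np.ndarray, embedding_dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    k = _FILTER_SIZE
    filters = rng.standard_normal((embedding_dim, k, k)) / k
    biases = 0.1 * rng.standard_normal(embedding_dim)
    windows = sliding_window_view(images, (k, k), axis=(1, 2))  # (n, H-k+1, W-k+1, k, k)
    responses = np.einsum("nhwij,oij->nohw", windows, filters, optimize=True)
    return np.maximum(responses + biases[None, :, None, None], 0.0).mean(axis=(2, 3))


def encode(encoder: EncoderModel, dataset: ImageDataset) -> EmbeddingMatrix:
    """One embedding row per sample, in dataset order."""
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    if encoder.kind == "oracle_informative":
        if dataset.latents is None:
            raise ValueError("oracle_informative encoder requires a dataset with latents")
        d_latent = dataset.latents.shape[1]
        rng = np.random.default_rng(encoder.seed)
        mixing = rng.standard_normal((d_latent, encoder.embedding_dim)) / np.sqrt(d_latent)
        signal = dataset.latents @ mixing
        vectors = _mix(signal, dataset.images, encoder.informativeness, encoder.seed)
    elif encoder.kind == "generic_frozen":
        vectors = _filter_bank_features(dataset.images, encoder.embedding_dim, encoder.seed)
    else:  # degraded
        feats = _filter_bank_features(dataset.images, encoder.embedding_dim, encoder.seed)
        # standardize before mixing so the noise floor is on a comparable scale
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
        vectors = _mix(feats, dataset.images, encoder.informativeness, encoder.seed)
    return EmbeddingMatrix(ids=list(dataset.ids), vectors=vectors, encoder_name=encoder.name)


def standardize_embeddings(embeddings: EmbeddingMatrix) -> EmbeddingMatrix:
    """Per-dimension zero mean / unit variance; constant dimensions map to 0."""
    mu = embeddings.vectors.mean(axis=0)
    sd = embeddings.vectors.std(axis=0)
    constant = sd <= 1e-9 * (np.abs(mu) + 1.0)  # numerically constant dimension
    sd[constant] = np.inf
    return EmbeddingMatrix(
        ids=list(embeddings.ids),
        vectors=(embeddings.vectors - mu) / sd,
        encoder_name=embeddings.encoder_name,
    )


def save_embeddings_csv(embeddings: EmbeddingMatrix, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"v{j}" for j in range(embeddings.embedding_dim)])
        for sid, row in zip(embeddings.ids, embeddings.vectors):
            writer.writerow([sid] + [repr(float(v)) for v in row])


def load_embeddings_csv(path: str | Path, encoder_name: str = "loaded") -> EmbeddingMatrix:
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            ids.append(row[0])
            rows.append([float(v) for v in row[1:]])
    del header
    return EmbeddingMatrix(ids=ids, vectors=np.array(rows), encoder_name=encoder_name)
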