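"""Text-to-vector providers and cosine similarity.

The harmonization models never look at raw text: every description is first
mapped to a fixed-dimension real vector by an *embedding provider*. In
production that provider is a frozen biomedical transformer (768-dim output);
for tests and simulation two self-contained providers are supplied:

``FixtureProvider``
    A deterministic seeded hash-to-vector map. Any dimension, no downloads,
    bit-reproducible across processes. Carries no semantics — identical texts
    get identical vectors, different texts get (almost surely) near-orthogonal
    ones — which is exactly what contract/plumbing tests need.

``LookupProvider``
    Returns precomputed vectors from a text-keyed table. The synthetic-data
    generator uses it to connect generated description texts to their latent
    concept geometry, so model tests exercise realistic similarity structure
    without a language model.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmbeddingBackendUnavailable, ValidationError


def _text_hash(text: str) -> str:
    return hashlib.blake2b(text.encode("utf-8"), digest_size=16).hexdigest()


class EmbeddingProvider(ABC):
    """Contract: map a batch of nonempty texts to an (n, dimension) array."""

    name: str
    dimension: int
    deterministic: bool = True

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Embed ``texts``, order preserved; one row per text."""
        if len(texts) == 0:
            raise ValidationError("embed() requires at least one text")
        for i, t in enumerate(texts):
            if not t or not t.strip():
                raise ValidationError(f"empty text at position {i}")
        out = self._embed(list(texts))
        out = np.asarray(out, dtype=np.float64)
        if out.shape != (len(texts), self.dimension):
            raise ValidationError(
                f"provider {self.name!r} returned shape {out.shape}, "
                f"expected {(len(texts), self.dimension)}"
            )
        return out

    def embed_one(self, text: str) -> np.ndarray:
        return self.embed([text])[0]

    @abstractmethod
    def _embed(self, texts: list[str]) -> np.ndarray: ...


class FixtureProvider(EmbeddingProvider):
    """Deterministic hash-seeded Gaussian vectors, unit-normalized."""

    def __init__(self, dimension: int = 64, seed: int = 0):
        if dimension < 1:
            raise ValidationError("dimension must be positive")
        self.name = f"fixture(d={dimension},seed={seed})"
        self.dimension = dimension
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(
            f"{self.seed}\x00{text}".encode("utf-8"), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(self.dimension)
        v /= np.linalg.norm(v)
        self._cache[text] = v
        return v

    def _embed(self, texts: list[str]) -> np.ndarray:
        return np.stack([self._vector(t) for t in texts])


class LookupProvider(EmbeddingProvider):
    """Precomputed text → vector table (keyed internally by a text hash)."""

    def __init__(self, mapping: Mapping[str, np.ndarray], name: str = "lookup"):
        if not mapping:
            raise ValidationError("lookup table is empty")
        vectors = {_text_hash(t): np.asarray(v, dtype=np.float64) for t, v in mapping.items()}
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValidationError(f"inconsistent vector shapes in lookup table: {dims}")
        self.name = name
        self.dimension = next(iter(vectors.values())).shape[0]
        self._vectors = vectors

    def _embed(self, texts: list[str]) -> np.ndarray:
        rows = []
        for t in texts:
            h = _text_hash(t)
            if h not in self._vectors:
                raise ValidationError(f"text not present in lookup table: {t!r}")
            rows.append(self._vectors[h])
        return np.stack(rows)

    def save(self, path: str | Path) -> None:
        """Write as TSV: text_hash followed by the vector components."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for h in sorted(self._vectors):
                vals = "\t".join(repr(float(x)) for x in self._vectors[h])
                fh.write(f"{h}\t{vals}\n")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "LookupProvider":
        path = Path(path)
        vectors: dict[str, np.ndarray] = {}
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        obj = cls.__new__(cls)
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValidationError(f"inconsistent vector shapes in {path}")
        obj.name = name or f"lookup({path.name})"
        obj.dimension = next(iter(vectors.values())).shape[0]
        obj._vectors = vectors
        return obj


class TransformerProvider(EmbeddingProvider):
    """Frozen biomedical transformer backend (768-dim), mean-pooled.

    Requires the optional ``torch`` and ``transformers`` extras. Pooling is the
    mean over final-layer token states (attention-masked), truncated at
    ``max_tokens``; CLS pooling is available via ``pooling="cls"``.
    """

    def __init__(
        self,
        model_name: str = "dmis-lab/biobert-base-cased-v1.1",
        pooling: str = "mean",
        max_tokens: int = 128,
    ):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise EmbeddingBackendUnavailable(
                "transformer embedding backend requires the optional 'torch' and "
                "'transformers' packages; install them or use the 'fixture' or "
                "'lookup' provider instead"
            ) from exc
        if pooling not in ("mean", "cls"):
            raise ValidationError(f"unknown pooling {pooling!r}")
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.name = f"transformer({model_name},{pooling})"
        self.dimension = int(self._model.config.hidden_size)
        self.pooling = pooling
        self.max_tokens = max_tokens

    def _embed(self, texts: list[str]) -> np.ndarray:
        torch = self._torch
        enc = self._tokenizer(
            texts, padding=True, truncation=True, max_length=self.max_tokens,
            return_tensors="pt",
        )
        with torch.no_grad():
            out = self._model(**enc).last_hidden_state
        if self.pooling == "cls":
            pooled = out[:, 0]
        else:
            mask = enc["attention_mask"].unsqueeze(-1)
            pooled = (out * mask).sum(1) / mask.sum(1).clamp(min=1)
        return pooled.numpy().astype(np.float64)


def get_provider(spec: str, dimension: int = 64, seed: int = 0) -> EmbeddingProvider:
    """Resolve a provider from a short spec: ``fixture``, a lookup file path,
    or ``transformer[:model_name]``."""
    if spec == "fixture":
        return FixtureProvider(dimension=dimension, seed=seed)
    if spec.startswith("transformer"):
        _, _, model = spec.partition(":")
        kwargs = {"model_name": model} if model else {}
        return TransformerProvider(**kwargs)
    return LookupProvider.from_file(spec)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a·b / (‖a‖‖b‖); symmetric, in [-1, 1].

    Raises on dimension mismatch or an all-zero argument — a zero vector has
    no direction, so its similarity is undefined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine similarity undefined for an all-zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def cosine_rows(A: np.ndarray, B: np.ndarray, zero_as: float | None = None) -> np.ndarray:
    """Row-wise cosine between two (n, d) arrays.

    ``zero_as=None`` raises on zero rows; a float substitutes that value
    (the pair-scorer head uses 0, since ReLU can zero a projection).
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch: {A.shape} vs {B.shape}")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    bad = (na == 0) | (nb == 0)
    if bad.any():
        if zero_as is None:
            raise ValidationError("zero vector in cosine_rows")
        na = np.where(na == 0, 1.0, na)
        nb = np.where(nb == 0, 1.0, nb)
    out = np.einsum("ij,ij->i", A, B) / (na * nb)
    if bad.any():
        out[bad] = zero_as
    return np.clip(out, -1.0, 1.0)
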