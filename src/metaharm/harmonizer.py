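"""Concept assignment: rank all known concepts for an unlabeled description.

At inference a query description is scored against every labeled reference
description; each concept's score is an aggregate (default: max) of the pair
scores against that concept's references, and concepts are returned sorted by
score, ties broken lexicographically by concept id. Top-1 gives the assigned
concept; top-K underlies the ranking accuracy metrics.
"""

from __future__ import annotations

import warnings
import weakref
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingProvider
from .errors import ValidationError
from .metadata_io import Corpus, VariableRecord
from .models import BaselineLR, SiameseFCN, TrainedScorer


class ReferenceIndex:
    """Labeled reference descriptions with cached embeddings, grouped by concept."""

    def __init__(
        self,
        concept_ids: list[str],
        records: list[VariableRecord],
        embeddings: np.ndarray,
        record_concepts: np.ndarray,
        concept_names: dict[str, str],
        provider: EmbeddingProvider,
        aggregation: Literal["max", "mean"] = "max",
    ):
        if aggregation not in ("max", "mean"):
            raise ValidationError(f"unknown aggregation {aggregation!r}")
        self.concept_ids = concept_ids  # sorted
        self.records = records
        self.embeddings = embeddings  # (n_refs, d)
        self.record_concepts = record_concepts  # (n_refs,) indices into concept_ids
        self.concept_names = concept_names
        self.provider = provider
        self.aggregation = aggregation
        self._proj_cache: "weakref.WeakKeyDictionary" = weakref.WeakKeyDictionary()

    def __len__(self) -> int:
        return len(self.concept_ids)

    @property
    def n_references(self) -> int:
        return len(self.records)

    def projected(self, scorer: TrainedScorer) -> np.ndarray:
        """Reference projections for an FCN scorer, cached per scorer."""
        cached = self._proj_cache.get(scorer)
        if cached is None:
            cached = scorer.model.project(self.embeddings)  # type: ignore[union-attr]
            self._proj_cache[scorer] = cached
        return cached


def build_reference_index(
    corpus: Corpus,
    provider: EmbeddingProvider,
    aggregation: Literal["max", "mean"] = "max",
) -> ReferenceIndex:
    """Index every concept that has at least one labeled description.

    Dictionary concepts with no description in the corpus are excluded with a
    warning — there is nothing to compare a query against.
    """
    records = corpus.labeled
    if not records:
        raise ValidationError("reference index requires a labeled corpus")
    present = sorted({r.concept_id for r in records})  # type: ignore[arg-type]
    absent = [c for c in corpus.concepts.ids if c not in set(present)]
    if absent:
        warnings.warn(
            f"{len(absent)} dictionary concept(s) have no labeled description "
            f"and are excluded from the index: {absent[:5]}..."
        )
    pos = {c: i for i, c in enumerate(present)}
    embeddings = provider.embed([r.description for r in records])
    record_concepts = np.array([pos[r.concept_id] for r in records])
    names = {c: corpus.concepts[c].name if c in corpus.concepts else c for c in present}
    return ReferenceIndex(
        concept_ids=present,
        records=list(records),
        embeddings=embeddings,
        record_concepts=record_concepts,
        concept_names=names,
        provider=provider,
        aggregation=aggregation,
    )


@dataclass
class RankingResult:
    """Full concept ranking for one query, best first."""

    query: VariableRecord
    ranked: list[tuple[str, float]]  # (concept_id, score), score non-increasing

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.ranked[: max(k, 0)]

    def top_concepts(self, k: int) -> list[str]:
        return [c for c, _ in self.top(k)]

    def rank_of(self, concept_id: str) -> int:
        """1-based rank of a concept; raises if absent."""
        for i, (c, _) in enumerate(self.ranked):
            if c == concept_id:
                return i + 1
        raise ValidationError(f"concept {concept_id!r} not present in ranking")


def _aggregate(scores: np.ndarray, concept_idx: np.ndarray, n_concepts: int, how: str) -> np.ndarray:
    agg = np.full(n_concepts, -np.inf)
    if how == "max":
        np.maximum.at(agg, concept_idx, scores)
    else:
        sums = np.zeros(n_concepts)
        counts = np.zeros(n_concepts)
        np.add.at(sums, concept_idx, scores)
        np.add.at(counts, concept_idx, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            agg = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    return agg


def rank_concepts(
    scorer: TrainedScorer,
    index: ReferenceIndex,
    query: VariableRecord,
    exclude_key: Optional[tuple[str, str]] = None,
    query_embedding: Optional[np.ndarray] = None,
) -> RankingResult:
    """Score the query against every reference and rank concepts.

    ``exclude_key`` drops one reference record (leave-query-out evaluation).
    Concepts left with no reference after exclusion are omitted from the
    ranking. Ties are broken lexicographically by concept id.
    """
    if len(index) == 0:
        raise ValidationError("empty reference index")
    if scorer.dimension != index.provider.dimension:
        raise ValidationError(
            f"model dimension {scorer.dimension} does not match index provider "
            f"dimension {index.provider.dimension}"
        )
    q = (
        np.asarray(query_embedding, dtype=np.float64)
        if query_embedding is not None
        else index.provider.embed_one(query.description)
    )

    keep = np.ones(index.n_references, dtype=bool)
    if exclude_key is not None:
        for i, r in enumerate(index.records):
            if r.key == exclude_key:
                keep[i] = False
    model = scorer.model
    if isinstance(model, SiameseFCN):
        scores_all = model.scores_one_vs_many(q, index.projected(scorer))
    else:
        scores_all = model.scores_one_vs_many(q, index.embeddings)
    scores = scores_all[keep]
    concept_idx = index.record_concepts[keep]

    agg = _aggregate(scores, concept_idx, len(index), index.aggregation)
    ranked = [
        (index.concept_ids[i], float(agg[i]))
        for i in range(len(index))
        if np.isfinite(agg[i])
    ]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return RankingResult(query=query, ranked=ranked)


def harmonize_batch(
    scorer: TrainedScorer,
    index: ReferenceIndex,
    queries: Sequence[VariableRecord],
    k: int = 5,
) -> pd.DataFrame:
    """Top-k concept assignments for each query, one output row per rank."""
    if k < 1:
        raise ValidationError("k must be at least 1")
    if k > len(index):
        warnings.warn(f"k={k} exceeds the {len(index)} indexed concepts; truncating")
        k = len(index)
    rows = []
    for query in queries:
        result = rank_concepts(scorer, index, query)
        for rank, (cid, score) in enumerate(result.top(k), start=1):
            rows.append(
                (
                    query.cohort_id,
                    query.variable_name,
                    rank,
                    cid,
                    index.concept_names.get(cid, cid),
                    score,
                )
            )
    return pd.DataFrame(
        rows, columns=["cohort", "variable", "rank", "concept_id", "concept_name", "score"]
    )
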