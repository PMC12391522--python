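"""Sentence-pair dataset construction and train/validation/test splitting.

Harmonization is framed as binary classification over pairs of variable
descriptions: a pair is *matched* (label 1) when both members carry the same
harmonized concept. Matched pairs are enumerated exhaustively within each
concept; nonmatched pairs are sampled across concepts at a configurable
nonmatched:matched ratio (default 3) to control class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .metadata_io import Corpus, VariableRecord


@dataclass(frozen=True)
class SentencePair:
    """Two distinct variable records plus the same-concept label."""

    x1: VariableRecord
    x2: VariableRecord
    label: int

    def __post_init__(self) -> None:
        if self.x1.key == self.x2.key:
            raise ValidationError(f"self-pair for {self.x1.key}")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0/1, got {self.label}")

    @property
    def unordered_key(self) -> frozenset:
        return frozenset((self.x1.key, self.x2.key))


@dataclass
class PairDataset:
    pairs: list[SentencePair]
    ratio: float = 3.0
    seed: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_matched(self) -> int:
        return sum(p.label for p in self.pairs)

    @property
    def n_nonmatched(self) -> int:
        return len(self.pairs) - self.n_matched

    def record_keys(self) -> set:
        return {p.x1.key for p in self.pairs} | {p.x2.key for p in self.pairs}


@dataclass
class SplitPlan:
    """How to carve the pair dataset into train/validation/test.

    ``combined`` pools all cohorts and splits at random with ``fractions``
    (default 4:1:1). ``leave_one_cohort_out`` sends every pair touching
    ``held_out_cohort`` to the test split and divides the remainder between
    train and validation, probing cross-cohort generalization.

    ``unit`` controls the random split's granularity: ``"pair"`` partitions
    pairs exactly (a description may then appear on both sides of the split
    boundary); ``"description"`` assigns whole descriptions to splits so no
    description leaks across splits, at the cost of dropping pairs whose two
    members land in different splits.
    """

    strategy: Literal["combined", "leave_one_cohort_out"] = "combined"
    fractions: tuple[float, float, float] = (4 / 6, 1 / 6, 1 / 6)
    unit: Literal["pair", "description"] = "pair"
    held_out_cohort: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("combined", "leave_one_cohort_out"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.unit not in ("pair", "description"):
            raise ValidationError(f"unknown split unit {self.unit!r}")
        if any(f < 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions must be nonnegative and sum to 1, got {self.fractions}"
            )
        if (self.strategy == "leave_one_cohort_out") != (self.held_out_cohort is not None):
            raise ValidationError(
                "held_out_cohort must be given exactly when strategy is leave_one_cohort_out"
            )


def build_matched_pairs(corpus: Corpus) -> list[SentencePair]:
    """All within-concept description pairs: C(n_c, 2) per concept, label 1."""
    by_concept: dict[str, list[VariableRecord]] = {}
    for r in corpus.labeled:
        by_concept.setdefault(r.concept_id, []).append(r)  # type: ignore[arg-type]
    pairs = [
        SentencePair(a, b, 1)
        for members in by_concept.values()
        for a, b in combinations(members, 2)
    ]
    if not pairs:
        raise ValidationError(
            "no concept has two or more labeled descriptions; cannot build matched pairs"
        )
    return pairs


def _all_cross_pairs(records: Sequence[VariableRecord]) -> list[SentencePair]:
    return [
        SentencePair(a, b, 0)
        for a, b in combinations(records, 2)
        if a.concept_id != b.concept_id
    ]


def sample_nonmatched_pairs(
    corpus: Corpus, n_matched: int, ratio: float = 3.0, seed: int = 0
) -> list[SentencePair]:
    """Sample cross-concept pairs, label 0, unique as unordered pairs.

    Targets ``round(ratio * n_matched)`` pairs, drawn without replacement and
    stratified so each labeled description contributes negatives at roughly
    equal rates (round-robin over descriptions, random cross-concept partner
    each turn). If fewer distinct cross-concept pairs exist than requested,
    all of them are returned once, with a warning.
    """
    if ratio < 0:
        raise ValidationError("ratio must be nonnegative")
    records = corpus.labeled
    concept_ids = {r.concept_id for r in records}
    if len(concept_ids) < 2:
        raise ValidationError("need at least two distinct concepts to sample nonmatches")
    target = int(round(ratio * n_matched))
    if target == 0:
        return []
    counts = pd.Series([r.concept_id for r in records]).value_counts()
    n = len(records)
    available = n * (n - 1) // 2 - int((counts * (counts - 1) // 2).sum())
    if target >= available:
        if target > available:
            warnings.warn(
                f"requested {target} nonmatched pairs but only {available} distinct "
                "cross-concept pairs exist; returning all of them"
            )
        return _all_cross_pairs(records)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    by_other: list[np.ndarray] = []
    concept_arr = np.array([r.concept_id for r in records])
    for r in records:
        by_other.append(np.flatnonzero(concept_arr != r.concept_id))
    seen: set[frozenset] = set()
    out: list[SentencePair] = []
    misses = 0
    cursor = 0
    while len(out) < target:
        i = int(order[cursor % len(order)])
        cursor += 1
        others = by_other[i]
        j = int(others[rng.integers(len(others))])
        key = frozenset((records[i].key, records[j].key))
        if key in seen:
            misses += 1
            # rejection sampling stalls only when nearly all pairs are taken,
            # which the availability check above rules out; fall back anyway
            if misses > 50 * target:
                remaining = [p for p in _all_cross_pairs(records) if p.unordered_key not in seen]
                rng.shuffle(remaining)  # type: ignore[arg-type]
                out.extend(remaining[: target - len(out)])
                break
            continue
        seen.add(key)
        out.append(SentencePair(records[i], records[j], 0))
    return out


def build_pair_dataset(
    corpus: Corpus, ratio: float = 3.0, seed: int = 0
) -> PairDataset:
    """Matched pairs plus sampled nonmatched pairs at the given ratio."""
    matched = build_matched_pairs(corpus)
    nonmatched = sample_nonmatched_pairs(corpus, len(matched), ratio=ratio, seed=seed)
    return PairDataset(pairs=matched + nonmatched, ratio=ratio, seed=seed)


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(x) for x in raw]
    short = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def _split_random_pairs(
    pairs: list[SentencePair], fractions: Sequence[float], rng: np.random.Generator
) -> tuple[list[SentencePair], ...]:
    idx = rng.permutation(len(pairs))
    sizes = _largest_remainder_sizes(len(pairs), fractions)
    out = []
    start = 0
    for s in sizes:
        out.append([pairs[i] for i in idx[start : start + s]])
        start += s
    return tuple(out)


def _split_by_description(
    pairs: list[SentencePair], fractions: Sequence[float], rng: np.random.Generator
) -> tuple[list[SentencePair], ...]:
    keys = sorted({k for p in pairs for k in (p.x1.key, p.x2.key)})
    idx = rng.permutation(len(keys))
    sizes = _largest_remainder_sizes(len(keys), fractions)
    assign: dict = {}
    start = 0
    for part, s in enumerate(sizes):
        for i in idx[start : start + s]:
            assign[keys[i]] = part
        start += s
    out: tuple[list[SentencePair], ...] = ([], [], [])
    for p in pairs:
        a, b = assign[p.x1.key], assign[p.x2.key]
        if a == b:
            out[a].append(p)
        # pairs spanning two description-splits are dropped (leakage control)
    return out


def split_pairs(
    dataset: PairDataset, plan: SplitPlan
) -> tuple[PairDataset, PairDataset, PairDataset]:
    """Split into (train, val, test) per the plan; deterministic given seed."""
    if not dataset.pairs:
        raise ValidationError("cannot split an empty pair dataset")
    rng = np.random.default_rng(plan.seed)

    if plan.strategy == "leave_one_cohort_out":
        cohorts = {k[0] for k in dataset.record_keys()}
        if plan.held_out_cohort not in cohorts:
            raise ValidationError(
                f"held-out cohort {plan.held_out_cohort!r} absent from dataset "
                f"(present: {sorted(cohorts)})"
            )
        test = [
            p
            for p in dataset.pairs
            if plan.held_out_cohort in (p.x1.cohort_id, p.x2.cohort_id)
        ]
        rest = [
            p
            for p in dataset.pairs
            if plan.held_out_cohort not in (p.x1.cohort_id, p.x2.cohort_id)
        ]
        f_train, f_val, _ = plan.fractions
        denom = f_train + f_val
        inner = (f_train / denom, f_val / denom) if denom > 0 else (0.5, 0.5)
        if plan.unit == "pair":
            train, val = _split_random_pairs(rest, inner, rng)
        else:
            train, val, _extra = _split_by_description(rest, (*inner, 0.0), rng)
    else:
        if plan.unit == "pair":
            train, val, test = _split_random_pairs(dataset.pairs, plan.fractions, rng)
        else:
            train, val, test = _split_by_description(dataset.pairs, plan.fractions, rng)

    mk = lambda ps: PairDataset(pairs=list(ps), ratio=dataset.ratio, seed=plan.seed)
    return mk(train), mk(val), mk(test)


PAIR_COLUMNS = ("cohort1", "variable1", "cohort2", "variable2", "label")


def save_pairs(dataset: PairDataset, path: str | Path) -> None:
    rows = [
        (p.x1.cohort_id, p.x1.variable_name, p.x2.cohort_id, p.x2.variable_name, p.label)
        for p in dataset.pairs
    ]
    pd.DataFrame(rows, columns=list(PAIR_COLUMNS)).to_csv(Path(path), index=False)


def load_pairs(path: str | Path, corpus: Corpus, ratio: float = 3.0, seed: int = 0) -> PairDataset:
    """Resolve a saved pair table against a corpus (keys must all be present)."""
    df = pd.read_csv(Path(path), dtype={"label": int}, keep_default_na=False)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    by_key = {r.key: r for r in corpus.records}
    pairs = []
    for row in df.itertuples(index=False):
        k1 = (str(row.cohort1), str(row.variable1))
        k2 = (str(row.cohort2), str(row.variable2))
        if k1 not in by_key or k2 not in by_key:
            raise ValidationError(f"{path}: pair references unknown record {k1} or {k2}")
        pairs.append(SentencePair(by_key[k1], by_key[k2], int(row.label)))
    return PairDataset(pairs=pairs, ratio=ratio, seed=seed)
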