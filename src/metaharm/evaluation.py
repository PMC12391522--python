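"""Evaluation suite: pairwise ROC/AUC, top-K ranking accuracy, bootstrap
confidence intervals, per-concept confusion rates and score-distribution
summaries.

Two complementary views of performance are computed. The *pairwise* view asks
how well a model separates matched from nonmatched description pairs (ROC
AUC, the primary measure). The *ranking* view asks how often the correct
concept lands in the top-K of the full concept ranking for a held-out query
description (top-1/top-5 accuracy), which is what a harmonization user
actually experiences. Confidence intervals come from a percentile bootstrap —
resampling pairs for the AUC and query descriptions for the top-K rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .embeddings import EmbeddingProvider
from .errors import ValidationError
from .harmonizer import RankingResult, build_reference_index, rank_concepts
from .metadata_io import Corpus
from .models import (
    EmbeddedPairs,
    TrainConfig,
    TrainedScorer,
    fit_baseline,
    fit_contrastive,
    fit_fcn,
)
from .pairing import PairDataset, SplitPlan, build_pair_dataset, split_pairs


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC (Mann–Whitney: P(random positive outscores random negative), ties
    counted half) and the ROC curve as (fpr, tpr) points."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("roc_auc requires both positive and negative labels")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def top_k_accuracy(rankings: Sequence[RankingResult], k: int) -> float:
    """Percentage of queries whose true concept is among the k best-ranked.

    Each query record must carry its true ``concept_id``, and that concept
    must be present in the ranking.
    """
    if not rankings:
        raise ValidationError("no rankings supplied")
    missing = [
        r.query.key
        for r in rankings
        if r.query.concept_id is None
        or r.query.concept_id not in {c for c, _ in r.ranked}
    ]
    if missing:
        raise ValidationError(
            f"true concept absent from ranking for queries: {missing[:10]}"
        )
    hits = sum(1 for r in rankings if r.query.concept_id in r.top_concepts(k))
    return 100.0 * hits / len(rankings)


def bootstrap_ci(
    metric: Callable,
    data: Union[np.ndarray, tuple[np.ndarray, ...]],
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric`` evaluated on resamples.

    ``data`` is an array or a tuple of equal-length arrays; each resample
    draws rows with replacement and calls ``metric`` on the resampled data
    (positionally, one argument per array). A resample on which the metric
    raises ``ValidationError`` (e.g. a single-class AUC resample) is redrawn,
    at most 10 times, before the error propagates.
    """
    if reps < 100:
        raise ValidationError("bootstrap requires at least 100 replicates")
    arrays = data if isinstance(data, tuple) else (np.asarray(data),)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValidationError("bootstrap data arrays must have equal length")
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    for r in range(reps):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                stats[r] = metric(*(a[idx] for a in arrays))
                break
            except ValidationError:
                if attempt == 9:
                    raise
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def per_concept_confusion(
    rankings: Sequence[RankingResult],
) -> dict[str, dict[str, Optional[float]]]:
    """One-vs-rest confusion rates of top-1 assignments, per concept.

    For concept c, a query is "positive" when its top-1 prediction is c.
    Ratios with zero denominator (e.g. PPV of a never-predicted concept) are
    reported as None rather than imputed.
    """
    if not rankings:
        raise ValidationError("no rankings supplied")
    truths = [r.query.concept_id for r in rankings]
    preds = [r.ranked[0][0] for r in rankings]
    concepts = sorted(set(truths))
    n = len(rankings)
    out: dict[str, dict[str, Optional[float]]] = {}
    for c in concepts:
        tp = sum(1 for t, p in zip(truths, preds) if t == c and p == c)
        fp = sum(1 for t, p in zip(truths, preds) if t != c and p == c)
        fn = sum(1 for t, p in zip(truths, preds) if t == c and p != c)
        tn = n - tp - fp - fn
        ratio = lambda num, den: (num / den) if den > 0 else None
        out[c] = {
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
            "tpr": ratio(tp, tp + fn),
            "fpr": ratio(fp, fp + tn),
        }
    return out


def mean_confusion_rates(
    per_concept: dict[str, dict[str, Optional[float]]]
) -> dict[str, tuple[float, float]]:
    """Mean and SD of each rate over concepts where the rate is defined."""
    out = {}
    for key in ("ppv", "npv", "tpr", "fpr"):
        vals = [v[key] for v in per_concept.values() if v[key] is not None]
        if vals:
            out[key] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def _quartiles(x: np.ndarray) -> list[float]:
    return [float(q) for q in np.quantile(x, [0.25, 0.5, 0.75])]


def score_summary_by_group(
    scores: np.ndarray,
    labels: np.ndarray,
    groups1: Sequence[str],
    groups2: Sequence[str],
) -> dict[str, dict[str, Optional[list[float]]]]:
    """Quartiles of predicted scores for matches and nonmatches, per concept
    group. A pair contributes to the group(s) of both its members."""
    by_group: dict[str, dict[str, list[float]]] = {}
    for s, y, g1, g2 in zip(scores, labels, groups1, groups2):
        for g in {g1, g2}:
            slot = by_group.setdefault(g, {"match": [], "nonmatch": []})
            slot["match" if y == 1 else "nonmatch"].append(float(s))
    return {
        g: {
            kind: (_quartiles(np.array(vals)) if vals else None)
            for kind, vals in slots.items()
        }
        for g, slots in sorted(by_group.items())
    }


@dataclass
class EvalReport:
    """All metrics from one evaluation run, JSON-serializable."""

    model_kind: str
    strategy: str
    auc: float
    auc_ci: tuple[float, float]
    top_k: dict[int, dict[str, object]]  # k -> {"accuracy": pct, "ci": (lo, hi)}
    per_concept: dict[str, dict[str, Optional[float]]]
    per_group_score_summary: dict[str, dict[str, Optional[list[float]]]]
    roc_points: list[tuple[float, float]]
    n_pairs_test: int
    n_queries: int
    query_cohorts: list[str]
    n_queries_skipped: int
    bootstrap_reps: int
    seed: int
    best_epoch: int
    n_epochs: int

    def to_dict(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "strategy": self.strategy,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "top_k": {
                str(k): {"accuracy": v["accuracy"], "ci": list(v["ci"])}
                for k, v in self.top_k.items()
            },
            "per_concept": self.per_concept,
            "per_group_score_summary": self.per_group_score_summary,
            "roc_points": [list(p) for p in self.roc_points],
            "n_pairs_test": self.n_pairs_test,
            "n_queries": self.n_queries,
            "query_cohorts": self.query_cohorts,
            "n_queries_skipped": self.n_queries_skipped,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "n_epochs": self.n_epochs,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_evaluation(
    corpus: Corpus,
    provider: EmbeddingProvider,
    plan: SplitPlan,
    model: Union[str, TrainedScorer] = "fcn",
    train_config: Optional[TrainConfig] = None,
    ratio: float = 3.0,
    ks: Sequence[int] = (1, 5),
    bootstrap_reps: int = 1000,
    seed: int = 0,
    aggregation: Literal["max", "mean"] = "max",
) -> tuple[EvalReport, TrainedScorer]:
    """Full pipeline: pair building, splitting, training, and all metrics.

    ``model`` is "baseline" | "fcn" | "contrastive" to train from scratch, or
    an already-trained scorer to evaluate as-is. Ranking metrics use a
    leave-query-out reference index over the corpus's labeled descriptions:
    the query itself never serves as its own reference. Queries are the
    descriptions appearing in test pairs (for leave-one-cohort-out, the
    held-out cohort's descriptions); queries whose concept has no other
    reference are skipped and counted.

    Every stage derives its seed from ``seed``, so reruns are bit-identical.
    """
    pair_seed, split_seed, train_seed, boot_auc_seed, *boot_k_seeds = _spawn_seeds(
        seed, 4 + len(ks)
    )
    dataset = build_pair_dataset(corpus, ratio=ratio, seed=pair_seed)
    plan_used = SplitPlan(
        strategy=plan.strategy,
        fractions=plan.fractions,
        unit=plan.unit,
        held_out_cohort=plan.held_out_cohort,
        seed=split_seed,
    )
    train, val, test = split_pairs(dataset, plan_used)
    if not test.pairs:
        raise ValidationError("test split is empty")

    if isinstance(model, TrainedScorer):
        scorer = model
    else:
        cfg = train_config if train_config is not None else TrainConfig(seed=train_seed)
        tr = EmbeddedPairs.from_pairs(train, provider)
        va = EmbeddedPairs.from_pairs(val, provider)
        if model == "baseline":
            scorer = fit_baseline(tr, va, cfg, provider_name=provider.name)
        elif model == "fcn":
            scorer = fit_fcn(tr, va, cfg, provider_name=provider.name)
        elif model == "contrastive":
            cfg = TrainConfig(**{**cfg.__dict__, "loss": "nce"})
            scorer = fit_contrastive(tr, va, cfg, provider_name=provider.name)
        else:
            raise ValidationError(f"unknown model kind {model!r}")

    # --- pairwise metrics on test pairs
    te = EmbeddedPairs.from_pairs(test, provider)
    scores = scorer.score_batch(te.X1, te.X2)
    auc, curve = roc_auc(scores, te.y)

    def auc_metric(s, y):
        if len(np.unique(y)) < 2:
            raise ValidationError("single-class resample")
        return roc_auc_score(y, s)

    auc_ci = bootstrap_ci(
        auc_metric, (scores, te.y), reps=bootstrap_reps, seed=boot_auc_seed
    )

    groups1 = [corpus.concepts.group_of(p.x1.concept_id) for p in test.pairs]
    groups2 = [corpus.concepts.group_of(p.x2.concept_id) for p in test.pairs]
    group_summary = score_summary_by_group(scores, te.y, groups1, groups2)

    # --- ranking metrics on test descriptions, leave-query-out
    index = build_reference_index(corpus, provider, aggregation=aggregation)
    concept_sizes: dict[str, int] = {}
    for r in corpus.labeled:
        concept_sizes[r.concept_id] = concept_sizes.get(r.concept_id, 0) + 1

    if plan.strategy == "leave_one_cohort_out":
        query_keys = {
            r.key
            for p in test.pairs
            for r in (p.x1, p.x2)
            if r.cohort_id == plan.held_out_cohort
        }
    else:
        query_keys = test.record_keys()
    queries = [r for r in corpus.labeled if r.key in query_keys]
    skipped = [q for q in queries if concept_sizes.get(q.concept_id, 0) < 2]
    queries = [q for q in queries if concept_sizes.get(q.concept_id, 0) >= 2]
    if not queries:
        raise ValidationError("no test queries with a concept represented elsewhere")

    rankings = [
        rank_concepts(scorer, index, q, exclude_key=q.key) for q in queries
    ]
    top_k: dict[int, dict[str, object]] = {}
    for k, bseed in zip(ks, boot_k_seeds):
        hits = np.array(
            [1.0 if r.query.concept_id in r.top_concepts(k) else 0.0 for r in rankings]
        )
        acc = 100.0 * float(hits.mean())
        ci = bootstrap_ci(
            lambda h: 100.0 * float(np.mean(h)), hits, reps=bootstrap_reps, seed=bseed
        )
        top_k[k] = {"accuracy": acc, "ci": ci}

    per_concept = per_concept_confusion(rankings)

    history = scorer.history if isinstance(scorer.history, dict) else {}
    n_epochs = len(history.get("train_loss", []))
    report = EvalReport(
        model_kind=scorer.kind,
        strategy=plan.strategy,
        auc=auc,
        auc_ci=auc_ci,
        top_k=top_k,
        per_concept=per_concept,
        per_group_score_summary=group_summary,
        roc_points=curve,
        n_pairs_test=len(test),
        n_queries=len(queries),
        query_cohorts=sorted({q.cohort_id for q in queries}),
        n_queries_skipped=len(skipped),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
        best_epoch=scorer.best_epoch,
        n_epochs=n_epochs,
    )
    return report, scorer
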