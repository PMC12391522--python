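"""Synthetic multi-cohort variable-metadata worlds with matched embeddings.

The generator produces everything the pipeline needs — a labeled corpus, a
concept dictionary and a lookup embedding provider — with the statistical
structure the harmonization method assumes:

* concepts live in concept groups; centroids of concepts in the same group
  are correlated (medical concepts within, say, "medications" resemble each
  other more than they resemble "diet" concepts), so cross-concept similarity
  is not uniformly near zero;
* per-concept description counts follow a long-tailed (geometric) law, so a
  few concepts have many phrasings and many have few;
* each cohort writes descriptions in its own house style: a cohort-specific
  latent direction is mixed into every description vector (and a style token
  appended to the text), inflating same-cohort similarity and creating a
  genuine distribution shift for leave-one-cohort-out evaluation;
* each description's latent vector is its concept centroid plus isotropic
  Gaussian noise, renormalized; ``noise_sigma`` is the single difficulty
  knob, from perfectly separable (0) to noise-dominated (≫1).

Description texts are templated ("<concept phrase>, <qualifier> [<style>]"),
and the returned ``LookupProvider`` maps each text to exactly its latent
vector, so the full text pipeline runs without any language model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np

from .embeddings import LookupProvider
from .errors import ValidationError
from .metadata_io import ConceptDictionary, ConceptEntry, Corpus, VariableRecord

# Expected noise norm is NOISE_AMPLIFICATION * noise_sigma relative to the
# unit centroid; calibrated so noise_sigma spans clearly-separable (~0.3)
# through substantially-overlapping (~2.0) similarity structure in the
# default 64-dimensional latent space.
NOISE_AMPLIFICATION = np.sqrt(3.0)

DEFAULT_GROUPS = (
    "sociodemographics",
    "vitals",
    "comorbidities",
    "laboratories",
    "medications",
    "diet",
    "other",
)

_PHRASE_A = (
    "history of", "status of", "measured", "self reported", "adjudicated",
    "derived", "baseline", "follow-up", "screening", "prevalent",
)
_PHRASE_B = (
    "condition", "measurement", "medication use", "intake", "level",
    "indicator", "score", "category", "event", "assessment",
)
_QUALIFIERS = (
    "exam 1", "exam 2", "visit 1", "visit 2", "visit 3", "baseline visit",
    "annual follow-up", "phone interview", "clinic visit", "cycle 4",
)


@dataclass
class WorldConfig:
    """Shape and difficulty of a synthetic harmonization world.

    Defaults emulate a three-cohort cardiovascular metadata inventory:
    64 concepts in 7 groups with a long-tailed ~14 descriptions/concept
    (≈900 descriptions overall), moderate latent noise and a pronounced
    cohort house style.
    """

    n_cohorts: int = 3
    n_groups: int = 7
    n_concepts: int = 64
    mean_descriptions_per_concept: float = 14.0
    min_descriptions: int = 1
    noise_sigma: float = 0.3
    cohort_style_strength: float = 0.7
    group_correlation: float = 0.7
    embedding_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("need at least two concepts")
        if self.n_groups < 1 or self.n_groups > self.n_concepts:
            raise ValidationError("n_groups must be in [1, n_concepts]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be nonnegative")
        if not 0.0 <= self.cohort_style_strength <= 1.0:
            raise ValidationError("cohort_style_strength must lie in [0, 1]")
        if not 0.0 <= self.group_correlation < 1.0:
            raise ValidationError("group_correlation must lie in [0, 1)")
        if self.mean_descriptions_per_concept < 1:
            raise ValidationError("mean_descriptions_per_concept must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "WorldConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(eq=False)
class SyntheticWorld:
    corpus: Corpus
    latent_centroids: dict[str, np.ndarray]  # concept_id -> unit vector
    latent_embeddings: dict[tuple[str, str], np.ndarray]  # record key -> unit vector
    provider: LookupProvider
    config: WorldConfig


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a synthetic world; fully reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d = config.embedding_dim

    if config.n_groups <= len(DEFAULT_GROUPS):
        group_names = list(DEFAULT_GROUPS[: config.n_groups])
    else:
        group_names = list(DEFAULT_GROUPS) + [
            f"group{i:02d}" for i in range(len(DEFAULT_GROUPS), config.n_groups)
        ]
    cohort_names = [f"cohort_{chr(ord('a') + i)}" for i in range(config.n_cohorts)]

    group_dirs = _unit(rng.standard_normal((config.n_groups, d)))
    # round-robin so every group gets at least one concept
    concept_groups = np.array(
        [i % config.n_groups for i in range(config.n_concepts)]
    )
    rho = config.group_correlation
    own = _unit(rng.standard_normal((config.n_concepts, d)))
    centroids = _unit(rho * group_dirs[concept_groups] + np.sqrt(1 - rho**2) * own)
    style_dirs = _unit(rng.standard_normal((config.n_cohorts, d)))

    entries = []
    for ci in range(config.n_concepts):
        g = group_names[concept_groups[ci]]
        pa = _PHRASE_A[rng.integers(len(_PHRASE_A))]
        pb = _PHRASE_B[rng.integers(len(_PHRASE_B))]
        entries.append(
            ConceptEntry(f"c{ci:03d}", f"{pa} {g} {pb} {ci:03d}", g)
        )
    concepts = ConceptDictionary(entries)

    p = 1.0 / config.mean_descriptions_per_concept
    records: list[VariableRecord] = []
    latents: dict[tuple[str, str], np.ndarray] = {}
    centroid_map: dict[str, np.ndarray] = {}
    noise_scale = config.noise_sigma * float(NOISE_AMPLIFICATION) / np.sqrt(d)
    per_cohort_counter = {c: 0 for c in cohort_names}

    for ci, entry in enumerate(concepts):
        centroid_map[entry.concept_id] = centroids[ci]
        n_desc = max(config.min_descriptions, int(rng.geometric(p)))
        for j in range(n_desc):
            k = int(rng.integers(config.n_cohorts))
            cohort = cohort_names[k]
            per_cohort_counter[cohort] += 1
            var = f"{cohort[-1]}_{entry.concept_id}_{j:02d}"
            qual = _QUALIFIERS[rng.integers(len(_QUALIFIERS))]
            desc = f"{entry.name}, {qual} #{j:02d}"
            if config.cohort_style_strength > 0:
                desc += f" [{cohort} codebook]"
            vec = (
                centroids[ci]
                + noise_scale * rng.standard_normal(d)
                + config.cohort_style_strength * style_dirs[k]
            )
            vec = vec / np.linalg.norm(vec)
            records.append(
                VariableRecord(
                    cohort_id=cohort,
                    variable_name=var,
                    description=desc,
                    concept_id=entry.concept_id,
                )
            )
            latents[(cohort, var)] = vec

    corpus = Corpus(records=records, concepts=concepts)
    provider = LookupProvider(
        {r.description: latents[r.key] for r in records},
        name=f"synthetic(seed={config.seed})",
    )
    return SyntheticWorld(
        corpus=corpus,
        latent_centroids=centroid_map,
        latent_embeddings=latents,
        provider=provider,
        config=config,
    )


@dataclass
class SeparabilityEstimate:
    within_mean: float
    within_se: float
    cross_mean: float
    cross_se: float


def expected_separability(
    config: WorldConfig, n_pairs: int = 10_000, seed: Optional[int] = None
) -> SeparabilityEstimate:
    """Monte-Carlo estimate of mean within- vs cross-concept cosine similarity.

    Used to understand (and document) how hard a configuration is before
    running the full pipeline on it.
    """
    world = generate_world(config)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    by_concept: dict[str, list[np.ndarray]] = {}
    for r in world.corpus.records:
        by_concept.setdefault(r.concept_id, []).append(world.latent_embeddings[r.key])
    multi = [c for c, vs in by_concept.items() if len(vs) >= 2]
    if not multi:
        raise ValidationError("no concept has two descriptions; within-cosine undefined")
    concepts = list(by_concept)

    within = np.empty(n_pairs)
    cross = np.empty(n_pairs)
    for i in range(n_pairs):
        c = multi[rng.integers(len(multi))]
        vs = by_concept[c]
        a, b = rng.choice(len(vs), size=2, replace=False)
        within[i] = float(vs[a] @ vs[b])
        c1, c2 = rng.choice(len(concepts), size=2, replace=False)
        v1 = by_concept[concepts[c1]]
        v2 = by_concept[concepts[c2]]
        cross[i] = float(
            v1[rng.integers(len(v1))] @ v2[rng.integers(len(v2))]
        )
    return SeparabilityEstimate(
        within_mean=float(within.mean()),
        within_se=float(within.std(ddof=1) / np.sqrt(n_pairs)),
        cross_mean=float(cross.mean()),
        cross_se=float(cross.std(ddof=1) / np.sqrt(n_pairs)),
    )
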