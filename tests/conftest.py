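import numpy as np
import pytest

from metaharm import (
    ConceptDictionary,
    ConceptEntry,
    Corpus,
    FixtureProvider,
    VariableRecord,
)
from metaharm.synthetic import WorldConfig, generate_world


@pytest.fixture
def tiny_concepts():
    return ConceptDictionary(
        [
            ConceptEntry("diabetes", "diabetes mellitus", "comorbidities"),
            ConceptEntry("htn", "hypertension", "comorbidities"),
            ConceptEntry("sbp", "systolic blood pressure", "vitals"),
        ]
    )


@pytest.fixture
def tiny_corpus(tiny_concepts):
    records = [
        VariableRecord("aric", "dm_01", "diabetes with fasting glucose cutpoint<126", "diabetes"),
        VariableRecord("aric", "dm_02", "diabetes using lower cutpoint 126 mg/dL", "diabetes"),
        VariableRecord("fhs", "dm_ex1", "diabetes mellitus status, exam 1", "diabetes"),
        VariableRecord("fhs", "htn_ex1", "hypertension status, exam 1", "htn"),
        VariableRecord("mesa", "htn_v2", "high blood pressure at visit 2", "htn"),
        VariableRecord("mesa", "sbp_v1", "seated systolic blood pressure visit 1", "sbp"),
        VariableRecord("mesa", "unlab_1", "pending variable awaiting mapping"),
    ]
    return Corpus(records=records, concepts=tiny_concepts)


@pytest.fixture
def provider16():
    return FixtureProvider(dimension=16, seed=0)


@pytest.fixture(scope="session")
def small_world():
    """A quick multi-cohort world: 10 concepts, ~60 descriptions, dim 32."""
    return generate_world(
        WorldConfig(
            n_concepts=10, n_groups=4, mean_descriptions_per_concept=6,
            embedding_dim=32, seed=7,
        )
    )


@pytest.fixture(scope="session")
def separable_world():
    """Low-noise world used for trained-model performance floors."""
    return generate_world(
        WorldConfig(
            n_concepts=20, n_groups=5, mean_descriptions_per_concept=10,
            noise_sigma=0.1, embedding_dim=64, seed=13,
        )
    )


def random_labeled_corpus(rng: np.random.Generator, n_concepts=None, mean_desc=4):
    """Small random corpus for pairing/count oracles."""
    n_concepts = n_concepts or int(rng.integers(2, 9))
    entries = [
        ConceptEntry(f"c{i}", f"concept {i}", f"g{i % 3}") for i in range(n_concepts)
    ]
    records = []
    for i in range(n_concepts):
        n = int(rng.geometric(1 / mean_desc))
        for j in range(n):
            cohort = f"coh{rng.integers(3)}"
            records.append(
                VariableRecord(cohort, f"v_{i}_{j}", f"description {i} {j}", f"c{i}")
            )
    return Corpus(records=records, concepts=ConceptDictionary(entries))
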