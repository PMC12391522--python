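"""Train the siamese FCN and rank concepts for one held-out description.

The scorer maps a pair of description embeddings to a same-concept
probability; at inference a query is scored against every reference
description and each concept keeps its best-scoring reference. The query's
own entry is excluded from the index, so the printed ranking reflects what an
unseen description would get.
"""

from metaharm import (
    EmbeddedPairs, SplitPlan, TrainConfig, build_pair_dataset,
    build_reference_index, fit_fcn, rank_concepts, split_pairs,
)
from metaharm.synthetic import WorldConfig, generate_world

world = generate_world(WorldConfig(n_concepts=12, n_groups=4,
                                   mean_descriptions_per_concept=8, seed=42))
dataset = build_pair_dataset(world.corpus, ratio=3.0, seed=0)
train, val, _ = split_pairs(dataset, SplitPlan(seed=0))
config = TrainConfig(seed=1, max_epochs=40, patience=6, hidden_dim=64)
scorer = fit_fcn(
    EmbeddedPairs.from_pairs(train, world.provider),
    EmbeddedPairs.from_pairs(val, world.provider),
    config, provider_name=world.provider.name,
)
print(f"trained {scorer.kind}: {len(scorer.history['train_loss'])} epochs, "
      f"best validation epoch {scorer.best_epoch}")

index = build_reference_index(world.corpus, world.provider)
query = world.corpus.labeled[0]
result = rank_concepts(scorer, index, query, exclude_key=query.key)
print(f"\nquery: {query.description!r}  (true concept {query.concept_id})")
print("top-5 concepts (same-concept probability of best reference):")
for rank, (cid, score) in enumerate(result.top(5), 1):
    marker = " <- correct" if cid == query.concept_id else ""
    print(f"  {rank}. {cid}  {score:.4f}{marker}")
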