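# Methods

## Task and data model

A *corpus* is a list of variable records — (cohort, variable name, free-text
description, optional concept label) — plus a concept dictionary mapping
each concept id to a name and exactly one concept group. Harmonization
assigns a concept to each unlabeled description. The package treats this as
paired-sentence classification: learn P(same concept | description pair),
then rank all concepts for a query by its pair scores against labeled
reference descriptions.

Descriptions are embedded once by a pluggable provider (the text→vector
contract is the method's only dependency on language modeling). Three
providers ship: a deterministic hash-to-vector `fixture` (testing), a
text-keyed `lookup` table (precomputed embeddings; also how the synthetic
generator injects latent geometry), and an optional frozen biomedical
`transformer` backend (768-dim, mean pooling over final-layer token states
truncated at 128 tokens; CLS pooling available — the pooling choice is
configuration, not science). Only the description text is embedded by
default; concatenating the variable name is left to the caller because
names are frequently uninformative codes (`q4xa12`).

## Pair construction

Matched pairs enumerate all C(n_c, 2) within-concept combinations. Negative
pairs are drawn without replacement over unordered cross-concept pairs,
round-robin over descriptions so each contributes negatives at a similar
rate, until round(ratio × n_matched) pairs exist (default ratio 3,
controlling class imbalance). When fewer distinct cross-concept pairs exist
than requested, all are returned once, with a warning.

Splits are 4:1:1 train/validation/test by default. Two granularities:

* `unit="pair"` (default): pairs are partitioned exactly. A description can
  then occur on both sides of a split boundary — test pairs are unseen but
  their member descriptions usually are not. This matches the convention of
  reporting performance on pairs absent from training.
* `unit="description"`: whole descriptions are assigned to splits, and
  pairs spanning two splits are dropped. No description leakage, at the
  cost of discarding pairs. Use this to measure generalization to genuinely
  unseen phrasings; the difference between the two units on the same world
  quantifies the memorization component.

Leave-one-cohort-out sends every pair touching the held-out cohort to the
test split and divides the remainder between train and validation.

## Models

**Baseline.** p = σ(a·cos(e₁,e₂) + b), an unpenalized one-feature logistic
regression (scikit-learn, lbfgs). Any monotone transform of the raw cosine
gives the same AUC, so the baseline's AUC *is* the raw embedding cosine's
discriminative power.

**Siamese FCN.** u = ReLU(W e₁ + c), v = ReLU(W e₂ + c),
p = σ(w·cos(u, v) + b), with W (h×d), c (h), scalar w, b. The published
description of "two hidden layers, the second a cosine similarity rescaled
by a weight and bias into a sigmoid" is read as: one trainable ReLU
projection applied to *both* inputs (sharing is the only reading that makes
a cosine layer over a pair coherent, and it enforces the symmetry the task
semantics require), followed by the two-parameter cosine head. A ReLU
output can be identically zero; its cosine is defined as 0 at the head —
symmetric, finite, and logged when it occurs. Training: binary
cross-entropy, Adam (β₁ 0.9, β₂ 0.999), mini-batches shuffled by the run
seed, early stopping when validation loss has not improved for `patience`
epochs, weights restored from the best validation epoch. Gradients are
closed-form numpy (the network is two matmuls and a cosine); they are
verified against central finite differences in the test suite.

**Contrastive FCN.** Two stages. Stage 1 trains the projection with an
InfoNCE loss: batches of positive pairs (aᵢ, bᵢ), loss
−log[e^{cos(uᵢ,vᵢ)/τ} / Σⱼ e^{cos(uᵢ,vⱼ)/τ}] averaged over the batch, with
the other in-batch partners serving as negatives and temperature τ = 0.07.
The positive pool is the matched training pairs plus one augmented view per
anchor: a random `permute_fraction` (default 0.1) of coordinate positions
shuffled within the vector — "permuting embeddings" is ambiguous in the
source tradition; within-vector coordinate permutation is adopted because
it preserves the norm and most of the direction while breaking exact
identity, and it needs no second description. Stage 2 freezes the
projection and calibrates (w, b) by logistic regression on projected
cosines of all labeled training pairs, so inference is identical across the
three models and evaluation is uniform. Both the InfoNCE formulation and
the augmentation are documented interpretations, configurable.

Unstated hyperparameters are package defaults, not inherited values: hidden
width 256, learning rate 10⁻³, batch 64, max 200 epochs, patience 10. No
class weighting — the 3:1 negative ratio is the imbalance control.

## Inference and ranking

A reference index holds every labeled description with cached embeddings
(and, for FCN models, cached projections). A query's concept score is the
max of its pair scores against that concept's references — a concept
matches if *any* of its known phrasings matches; mean aggregation is
available for smoother behaviour with noisy references. Ties break
lexicographically by concept id for reproducibility. In evaluation the
query is removed from the index (leave-query-out), otherwise self-matching
makes top-1 trivially perfect; queries whose concept has no second
reference are skipped and counted.

## Metrics

* **AUC** on test pairs, Mann–Whitney convention (ties count ½), via
  scikit-learn; an O(n²) enumeration oracle pins the implementation in
  tests. ROC curves from sorted unique thresholds, trapezoidal.
* **Top-K accuracy**: percentage of queries whose true concept is among the
  K best-ranked.
* **Bootstrap CIs**: percentile method, 1000 replicates by default,
  resampling at the metric's own sampling unit — pairs for AUC, query
  descriptions for top-K. Degenerate (single-class) resamples are redrawn,
  at most 10 times. Calibration is verified empirically: coverage of the
  95% interval for a Bernoulli(0.7) mean at n = 200 lands in 93–97% over
  500 simulated datasets.
* **Per-concept confusion** (PPV/NPV/TPR/FPR) from one-vs-rest top-1
  assignments; zero-denominator ratios are reported as absent, never
  imputed as 0, and means over concepts use defined values only.
* **Score summaries**: quartiles of predicted scores for matches and
  nonmatches per concept group (a pair contributes to both members'
  groups).

Every stage seed is derived from one run seed via `SeedSequence`, making
full evaluation reports byte-identical across reruns.

## Synthetic worlds

The generator emulates the structure the method assumes, with one
difficulty knob:

* **Geometry.** Group directions are uniform unit vectors; concept
  centroids mix their group direction with an own direction at correlation
  ρ = 0.7, so same-group concepts overlap (within-group centroid cosine
  ≈ 0.5) the way related medical concepts do. A description's latent vector
  is its centroid plus isotropic Gaussian noise, renormalized. Noise is
  drawn N(0, 3σ²/d · I) — expected norm √3·σ relative to the unit centroid.
  The √3 amplification was calibrated once, by simulating raw-cosine
  separability across σ, so that the single knob spans the intended regimes
  in the default 64-dim space: σ = 0.3 clearly separable (raw-cosine AUC
  ≈ 0.99), σ = 1.0 degraded, σ = 2.0 heavily overlapping (≈ 0.66).
* **Cohort style.** Each cohort has a unit style direction added at
  strength 0.7 (and a style token appended to the text). Style inflates
  similarity between same-cohort descriptions of *different* concepts,
  which (a) handicaps the raw-cosine baseline — the learned projection can
  suppress the three style directions, the cosine cannot — and (b) gives
  leave-one-cohort-out evaluation a genuine unseen-style shift. 0.7 was
  chosen so the handicap is visible (style-removed oracle AUC 1.0 vs 0.987
  with style at σ = 0.3) while the default world stays solvable.
* **Counts.** Per-concept description counts are geometric with mean 14
  (min 1) over 64 concepts in 7 groups and 3 cohorts — a long-tailed
  ≈ 900-description inventory shaped like a real multi-cohort codebook
  collection.
* **Texts.** Templated ("<concept phrase>, <qualifier> [<cohort>
  codebook]") and wired to the latents through a lookup provider, so the
  whole text pipeline runs with zero downloads.

`expected_separability` reports Monte-Carlo within- and cross-concept
cosine means with standard errors for any configuration.

**What passing on synthetic worlds shows — and does not.** It shows the
machinery is correct end to end: pairing combinatorics, optimization,
ranking, metrics, seeds. It reproduces the *qualitative* phenomena —
learned projections beat raw cosine, held-out cohorts score lower, noise
degrades everything. It does not certify performance on real codebooks:
real description similarity is not isotropic-Gaussian around clean
centroids, real embedding models have their own biases, and real annotation
noise has structure. Published headline numbers obtained on real cohort
metadata with transformer embeddings are therefore not comparison targets
for the synthetic benchmark.

## Problem sizes

The default benchmark (64 concepts, ~900 descriptions, ~31k pairs of which
~7.6k test pairs under the combined split) trains the FCN in ≈ 2 minutes on
one CPU and the whole three-model benchmark plus leave-one-cohort-out in
≈ 3 minutes; unit tests use 10–20-concept worlds that run in seconds. These
sizes were chosen to match the scale of a real three-cohort inventory while
keeping a full reproduction convenient on a laptop.

## Known limitations

* No abstention: the argmax concept is always assigned; downstream users
  should threshold on the reported score if "no concept" must be possible.
* Laboratory-unit harmonization is out of scope — the method sees only
  metadata text, not value distributions.
* The contrastive stage treats same-concept in-batch partners as negatives
  when a concept appears twice in a batch (standard InfoNCE behaviour);
  with 64 concepts and batch 64 this mislabeling is rare but nonzero.
* Pair-unit splits leak descriptions across splits by construction; use
  description-unit splits when measuring generalization to unseen phrasings.
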