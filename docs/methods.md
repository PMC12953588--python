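# Methods

This note documents the models, procedures and design choices behind
`trialgraph`: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Registry ingestion and canonicalization

A registry export is a CSV with seven required columns (NCT Number, Study
Title, Conditions, Interventions, Sponsor, Collaborators, Locations) and
`|` as the intra-cell delimiter; an optional registration-date column
supplies the year needed by the temporal split.  The sponsor and the
collaborators are merged into one ordered, duplicate-free affiliation
list — the collaboration graph is undirected, so funding vs participating
roles are not distinguished downstream.  Countries are the final
comma-separated token of each location entry.  Intervention cells of the
form `CATEGORY: name` are parsed into (category, name) pairs; the category
vocabulary is open (any letter-token prefix is accepted, uppercased) and
bare values default to `OTHER`, since registries list categories
non-exhaustively.

Affiliation names are noisy in real exports (the same institution under
several spellings, hospitals under their parent university).  Cleaning is
strictly deterministic: NFKC unicode normalization and whitespace
collapse, followed by lookup in a user-supplied alias map raw → canonical.
Canonical targets must be fixed points (a canonical name that is itself
remapped is rejected), which makes `canonicalize` idempotent and
order-independent; the resolved target is re-cleaned so maps with
un-normalized canonical spellings cannot break idempotence.  No fuzzy or
learned entity resolution is attempted — that is a data-curation task,
not something to hide inside a deterministic pipeline.

## Graph construction

Each trial contributes a clique over its affiliations: +1 trial count per
node, +1 collaboration count per unordered pair; single-affiliation
trials yield isolated nodes and duplicate affiliations within one trial
count once and never create self-loops.  Two conservation laws pin the
construction down exactly and are enforced by tests: the node trial
counts sum to the total affiliation slots over trials, and the edge
collaboration counts sum to Σ C(n_t, 2) over trials with n_t affiliations.

Each edge also records how many of its co-trials listed at least one
intervention; these raw counts are min-max scaled across edges into
[0, 1].  When all raws coincide (including single-edge graphs) the
attribute is set to 1.0 rather than 0, so a uniform attribute does not
erase edge information.  Matrix row order is lexicographic in canonical
node name, making every derived matrix reproducible regardless of record
order.

## Feature fusion

Per node the fused input vector concatenates four blocks: log(1 + trial
count) (counts span orders of magnitude, so the raw value would dominate),
a text embedding of the dominant country, the intervention-category
histogram normalized to sum to one (fixed category order; all-zero when
the node has no recorded interventions), and a text embedding of the
dominant category.  "Dominant" is the mode with lexicographic
tie-breaking; the histograms keep the full distribution so the tie-break
loses nothing.  If the concatenation width differs from the model input
width (default 128) a seeded Gaussian random projection (scaled by
1/√width_in) maps it there.

Text goes through a pluggable embedding provider.  The default is a
feature-hashing encoder: tokens are hashed (keyed by the seed) into ±1
buckets and the vector is L2-normalized; if all tokens cancel pairwise a
whole-text bucket keeps the embedding non-zero, so every non-empty text
has a unit-norm, deterministic embedding.  This encoder carries no
semantics — distinct values get near-orthogonal codes — which is exactly
what the offline experiments need: the signal tested is "same attribute
value", not semantic similarity.  An external semantic embedding service
can be wrapped in the same provider contract (with an on-disk cache keyed
by text hash); the default build performs no network calls.

The structure-only ablation replaces the attribute blocks with a seeded
random projection of the one-hot node identity plus the log trial count:
what a purely structural encoder starts from.

## Encoders and training

Both encoders are bias-free two-layer stacks (ReLU between layers, linear
output), dense numpy throughout — the graphs here are hundreds to a few
thousand nodes, where dense matrices are faster and simpler than sparse
frameworks, and explicit forward/backward passes keep every run
bit-reproducible per seed.

* **GCN**: H⁽ˡ⁺¹⁾ = act(D̂^(−1/2)(A+I)D̂^(−1/2) · H⁽ˡ⁾ · W⁽ˡ⁾), the
  standard symmetric-normalized propagation with self-loops.
* **GraphSAGE-mean**: per layer act(H·W_self + D⁻¹A·H·W_nbr), the mean
  aggregator; isolated nodes aggregate a zero neighbor mean.

Edge weights (collaboration counts) enter only through the weighted
adjacency; with `use_edge_weights` off the adjacency is binarized first.
The per-edge intervention attribute optionally scales the message weight
by (1 + intervention_norm) — intervention-heavy ties propagate up to
twice as strongly — a floor chosen so that the minimum-attribute edge is
never silently deleted from message passing (a plain product would zero
it).  Analytic gradients are verified against central finite differences
in the test suite.

The link predictor is the dot product s_uv = h_u·h_v, trained with
binary cross-entropy on sigmoid(s): observed training edges are labelled
1, sampled non-edges 0, at a 1:1 ratio.  The loss choice is the standard
one for dot-product link prediction and treats s as an unnormalized log
odds of collaboration.  Optimization uses full-batch Adam, learning rate
0.001, L2 regularization 1e-5 added to the gradients, at most 100 epochs.
Early stopping monitors the loss on a validation set carved per seed from
10% of the training positives (with matched negatives), with patience 10;
the best-epoch weights are returned.  Glorot-uniform initialization,
seeded.

## Splits, negative sampling and leakage control

**Temporal split** (default): a pair is a training positive if any
supporting co-trial is registered in or before the cutoff year (default
2021), and a test positive if it first appears in cutoff+1; pairs first
appearing later are ignored, and test pairs with an endpoint absent from
the training graph are dropped (they cannot be scored).  The graph,
attribute tallies and features are built exclusively from train-period
records, so test-year trials contribute nothing to counts, features or
message passing.

**Random split**: edges are shuffled by seed and moved to the test set up
to the requested fraction, but only if both endpoints keep at least one
other training edge — no node is ever isolated from the training graph.
Consequently edges incident to degree-1 nodes always train, and on very
constrained graphs the realized test fraction can fall below the request
(a star with two leaves yields zero eligible test edges).

**Negatives** are drawn uniformly without replacement from the unordered
non-adjacent pairs, excluding all positives and previously sampled
negatives, separately per role (train/validation/test) — so the six edge
sets are pairwise disjoint and each negative set matches its positive set
1:1.  The sampler enumerates the non-edge pool explicitly, which is exact
and fast at desk scale; it reports the deficit when the pool is too small.

## Metrics

* **AUC** is the rank statistic: the probability that a random positive
  outranks a random negative, ties counted ½ — the standard ROC integral
  ∫TPR d(FPR) in rank form.  It is tested against a brute-force all-pairs
  oracle and scikit-learn's implementation.
* **F1** = 2PR/(P+R) with predictions sigmoid(score) ≥ 0.5 (threshold
  exposed), 0 when P+R = 0.
* **Accuracy@K** comes in two modes.  Literal: the mean raw hit count
  |Rel_i ∩ Rec_i(k)| over users.  Normalized: each user's hits divided by
  min(k, |Rel_i|).  Note the normalized form is **not** monotone in k
  (a user with 2 relevant items and a hit at rank 1 scores 1.0 at k=1 but
  0.5 at k=2); the literal count is monotone because top-k lists are
  nested.  Both modes are therefore reported per repeat, and monotonicity
  is only an invariant of the literal values.  Users with no relevant
  items are skipped with a warning.

Per-user rankings for Accuracy@K are computed over the user's test
positives plus a seeded sample of non-partners (candidate pool size 50 by
default, configurable) — the pool size materially affects the percentage
and is recorded with the run configuration.

The repeated experiment re-draws splits (random strategy), negatives,
initialization and candidate pools from seeds derived deterministically
from one master seed (10 repeats by default) and reports per-repeat
metrics with mean and standard deviation; the JSON report is
byte-identical across reruns with the same master seed.

## Synthetic registry generator

The generator emulates a disease-specific registry export with planted
structure so the whole pipeline is testable offline.  Affiliations are
assigned round-robin to blocks (a planted-partition model).  Each trial
draws a lead uniformly, a collaborator count 1 + Poisson(mean_team_size −
2) (so every trial has at least two affiliations and the mean team size
hits the configured value, default 3 — a sponsor plus two collaborators),
and teammates from the lead's block with probability `p_within` (default
0.85), else uniformly outside it.  Each block has a signature country and
intervention category; every node follows its block's signature with
probability `attribute_coupling` (default 0.9), else draws uniformly.
Registration years are uniform over 2011–2022 by default, matching the
temporal-split window (train through 2021, test 2022); an optional
`test_year_fraction` reweights the final year.  Everything is
deterministic per seed, and the emitted CSV round-trips through the
reader without loss.

Structural homophily (`p_within`) and attribute homophily
(`attribute_coupling`) are independent dials, so the benefit of attribute
fusion can be isolated from pure structure.

**What the generator does not emulate** — and hence what passing tests do
not show about real registries: heavy-tailed affiliation activity (leads
are uniform, so there are no hub institutions), semantic relatedness
between attribute values, growth and churn of institutions over time,
noisy or aliased names (records are emitted pre-canonicalized), and
registry-scale sparsity patterns.  Results on synthetic data demonstrate
correctness and direction-of-effect, not real-world accuracy levels.

### The recovery experiment and its ceiling

The headline synthetic experiment (120 affiliations, 600 trials, 2
blocks, p_within 0.85, coupling 0.9, temporal split, 5 repeats) shows the
attribute-fused GCN beating the structure-only ablation by a double-digit
AUC margin (percentage points) — the qualitative fusion effect.  The
absolute AUC level, however, is capped by the generative model itself:
teammates are drawn *uniformly* within a block, so a within-block pair
that first collaborates in the test year is statistically exchangeable
with a within-block pair that never collaborates, and with two equal
blocks roughly 40–45% of sampled negatives are within-block.  Block
membership — the only signal attributes carry — therefore bounds the
achievable test AUC near 0.7, with noticeable registry-to-registry
variance (≈0.65–0.84 across generator seeds).  An oracle scoring pairs by
the true block assignment plus common-neighbor counts lands at ≈0.68 mean
under the same protocol, which the trained fused model matches or exceeds.

## Numerical and degenerate-input conventions

Tie-breaks are lexicographic everywhere (dominant attributes, ranking
order, matrix row order).  Min-max normalization of a constant vector
yields 1.0.  Empty graphs produce empty (0×d) feature matrices; edgeless
graphs make the intervention normalization a warned no-op and
`planted_quality` return 0.  The AUC rejects empty score sets, F1 returns
0 when no positives are predicted, and Accuracy@K skips users with no
relevant items.  BCE is computed in the numerically stable
softplus form; non-finite training loss aborts with the epoch index.
Model state round-trips through a single npz archive bit-exactly.

## Known limitations

* Dense numpy encoders scale to a few thousand nodes; registry-scale
  graphs (tens of thousands of affiliations) would need sparse
  propagation and minibatched negatives.
* The default embedding provider is non-semantic by design; recommending
  by semantic suitability of interventions requires plugging in a real
  text-embedding service.
* Affiliation canonicalization is only as good as the supplied alias map.
* The literal Accuracy@K is unbounded (it counts hits); compare runs only
  at a fixed candidate-pool size and k.
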