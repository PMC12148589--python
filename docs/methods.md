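# Methods

## The problem and the approach

Assigning Enzyme Commission (EC) numbers to protein sequences is posed
here as a retrieval problem.  A query is not classified by a softmax over
a fixed label space; instead its embedding is searched against a
pre-embedded, labelled *lookup set*, and the labels of its k nearest
neighbours are transferred with a confidence score.  Retrieval has two
practical advantages over per-class classifiers: the label space extends
by simply adding entries to the lookup set (no retraining), and classes
with very few representatives still participate on equal terms.

The embedding space is learned contrastively.  Each protein's EC numbers
are expanded into a **hierarchical label set**: the set of dot-joined
prefixes at depths 1–4 of every EC number the protein carries, e.g.

    2.3.2.27  ->  {"2", "2.3", "2.3.2", "2.3.2.27"}

For a multi-EC protein the label set is the union of the per-EC prefix
sets.  The similarity between two proteins' label sets is the **overlap
coefficient**

    y(A, B) = |A ∩ B| / min(|A|, |B|),

which for two single complete EC numbers equals (shared leading
levels)/4 — e.g. 0.75 for the transferase siblings 2.3.2.27 and 2.3.2.31.
The union convention for multi-EC proteins is the only reading under
which each protein owns a single label set, and it makes the coefficient
saturate at 1 when one protein's label set is contained in the other's.

## The projection network f_θ

Input: a per-residue embedding matrix of shape (L × D), D = 1280 by
default (the per-residue output of a 650M-parameter protein language
model; this package consumes such embeddings, it never computes them).
Architecture:

1. one transformer encoder layer: multi-head self-attention (20 heads at
   D = 1280) and a position-wise feed-forward block of width 5120, each
   wrapped in a residual connection with a following layer
   normalisation (post-norm);
2. masked mean pooling over residues;
3. a two-layer perceptron 1280 → 1024 → 512 with GELU activation and
   layer normalisation at the penultimate layer;
4. explicit scaling of the output to unit Euclidean norm, so that index
   dot products are exact cosine similarities.

Design choices where the architecture was genuinely open:

* **Pooling position.**  Residues are mean-pooled after the transformer
  layer, before the MLP; the MLP input width (D) matches a pooled vector
  and mean pooling is the convention for language-model baselines of
  this kind.
* **No positional encoding.**  The input residue embeddings already
  encode position.  A consequence we verify numerically: the map is
  permutation-equivariant in the residue axis, so the pooled output is
  invariant to residue order.
* **Post-norm, no dropout.**  A single encoder layer trained on tens of
  thousands of items does not need dropout; the normalisation placement
  follows the "layer normalisation following the transformer layer"
  convention.
* **Masking.**  Padded positions are excluded from attention keys and
  from pooling, so a sequence's vector is identical (to 1e-5) whether it
  is projected alone or inside any padded batch.

All dimensions are configuration-driven; tests and the synthetic
benchmark run at D = 64 with 4 heads.

The model is implemented in NumPy on top of a small reverse-mode
automatic-differentiation engine written for this package
(`ecknn/_autodiff.py`); the full backward pass is validated against
central finite differences to 1e-4 absolute in the unit tests.

## Contrastive loss and optimisation

For a mini-batch B, with x_ij the pairwise cosine similarity of the
projected vectors and y_ij the pairwise overlap coefficient,

    L = Σ_{i<j} (x_ij − y_ij)²,

summed over strict upper-triangle pairs (the loss is a plain pair sum,
not a per-pair average; the learning-rate defaults below assume this
reduction).  Optimisation: AdamW (β = 0.9/0.999, ε = 1e-8, weight decay
0.01) with batch size 16, learning rate 1e-3 decayed per epoch by cosine
annealing to 5e-5.  Epoch presets of 150 ("full") and 50 ("clustered")
are exposed, but any count is accepted.  Batches are uniform random
shuffles each epoch (no class balancing); a trailing batch of size 1 is
dropped because a pairwise loss needs a pair.  "Until convergence on a
hold-out validation set" is operationalised as best-validation-loss
checkpointing with a patience of 10 epochs; validation loss is the mean
per-batch pair loss over fixed, unshuffled validation batches.  Training
is bitwise reproducible given the model and training seeds.

## Retrieval, probabilities, refusal

The lookup index is **flat and exact**: cosine distance
d = 1 − cos-similarity is computed against every entry (unit vectors, so
a matrix–vector product), and the k smallest are returned with ties
broken by insertion order.  Approximate search (LSH, HNSW, IVF-PQ) is
out of scope by design.  The index is extensible: appending entries
requires no retraining and no re-embedding of existing entries.

The probability that query t carries depth-4 label l is a
distance-weighted softmax over its neighbourhood N(t):

    p(t, l) = Σ_{x ∈ N(t), l ∈ labels(x)} exp(−d(t,x)/T)
              ─────────────────────────────────────────────
              Σ_{x ∈ N(t)}              exp(−d(t,x)/T)

with temperature T = 1e-3 throughout.  Neighbours that do not carry l
contribute nothing to the numerator — the unique reading under which
p ∈ (0, 1] and a single neighbour trivially receives p = 1.0.
Numerics: distances are shifted by the minimum before exponentiation and
the exponentials are taken in extended precision (`numpy.longdouble`),
so for any distances in [0, 2] at T = 1e-3 every probability is finite,
strictly positive and at most 1; naive exponentiation underflows to 0/0
in this regime.  Defaults k = 20 and probability threshold 0.5; only
depth-4 labels are emitted as predictions (shallower prefixes shape the
training similarity but are not annotation outputs).

**Refusal.**  A query whose nearest lookup neighbour is farther than a
distance cutoff receives no annotation.  The cutoff is calibrated as the
75th percentile (linear interpolation between order statistics) of the
nearest-hit distances of a calibration set that is deliberately
*distant* from the lookup set — at full scale, a low-identity validation
split, where this procedure yields a cutoff of 0.38.  Calibrating on
queries drawn from the same distribution that is later annotated would
by construction refuse ~25% of them; the cutoff is meaningful precisely
because the calibration set sits in the far tail of legitimate queries.
In the synthetic benchmark the calibration set is the held-out-class
split: classes the model never trained on, whose members embed near
their trained siblings but measurably farther than in-distribution
queries.  The cutoff is data-dependent and therefore never hard-coded;
0.38 is documented as the full-scale calibrated value only.

## Evaluation protocol

Metrics are one-hot at the fourth EC level: predicting 2.7.7.7 for truth
2.7.7.6 is simply wrong.  Per record, TP = |pred ∩ truth|,
FP = |pred \ truth|, FN = |truth \ pred|; precision, recall and F1 use
the convention 0 when a denominator is 0, so a refusal counts as a
missed recall for every truth label.  Two aggregations: the *sample*
average (per-record metrics averaged over records) and the *weighted*
average (per-class metrics weighted by truth support).  For
hold-out-class studies, codes can be truncated to a shallower level
(duplicates merged) before scoring, and per-vector maximum cosine
similarities within a group versus to a reference set quantify whether
held-out sequences cluster with each other.  Support bucketing tabulates
sample-average F1 against the training-set count of each record's
rarest truth label.

## Dataset construction

Split construction consumes cluster tables from an external sequence
clustering tool (this package never runs one): whole clusters of at
least 5 members are sampled out of training, their representatives
becoming test queries — the minimum size screens out fragment-only
clusters.  A label-consistency filter then drops any test/validation
sequence with a depth-4 EC that has no training carrier (a class no
retrieval method could annotate); for multi-EC sequences the strict
reading is used (drop if *any* EC is unrepresented), with the relaxed
any-EC-represented reading behind a flag.  Time-based splits cut a
dated label table at an ISO-8601 cutoff date and apply the same filter.
A consensus filter keeps only (sequence, EC) pairs on which two
annotation methods agree, the curation rule for lookup-set
supplementation.  All split operations are pure functions of inputs and
seed, and all writers sort their keys, so re-running reproduces
byte-identical files.

## The synthetic benchmark

Real embeddings are emulated by a planted hierarchy.  A tree of depth-4
codes (default 4 top classes branching 3/3/3 = 108 classes) gets one
unit centroid per class: the top-level centroid is a random unit vector
and each deeper node adds a perturbation of scale 0.6/0.4/0.25/0.15
(levels 1–4) to its parent and renormalises, so between-class cosine
similarity increases with shared-prefix depth — the same monotone
structure the overlap coefficient encodes, which is exactly what the
contrastive loss is meant to sharpen.  Sequences are (L × D) matrices,
L uniform in 20–60, rows = centroid + noise of typical norm 0.5
(relative to the unit centroid); 10% of sequences carry a second EC from
a different top class whose geometry they do *not* reflect (label
noise); 4 classes are held out of training as the calibration/hold-out
split.  Defaults: 30 training and 5 test sequences per class at D = 64,
sized so that the full train→index→annotate→score loop runs in minutes
on one CPU; the benchmark profile trains for 30 epochs.

What passing on this fixture shows: the loss, optimiser, retrieval and
scoring machinery recover a planted hierarchical geometry end to end.
What it does not show: performance on real protein embeddings, with
their class imbalance, annotation errors, length effects and much weaker
raw geometry.

## Numerical conventions and degenerate inputs

* Percentiles: linear interpolation between closest order statistics.
* k-NN ties: stable insertion order; equal-probability labels:
  lexicographic EC order.
* Self-exclusion matches ids, not vectors: duplicate sequences under
  different ids are legitimate neighbours.
* k larger than the candidate pool returns all candidates and flags
  truncation.
* Partial EC codes ("3.4.-.-") truncate the hierarchical set at the last
  resolved level; preliminary serials ("n1") are literal tokens matching
  only on exact equality.  Whether partially annotated sequences enter
  training is left to the caller.
* Unit-norm is enforced at 1e-6 on every vector entering an index.

## Known limitations

* Single-process CPU training only; at Swiss-Prot scale (hundreds of
  thousands of sequences, D = 1280) this implementation is not
  practical — the defaults reproduce the recipe, not the wall-time.
* Only EC numbers are implemented, though the loss generalises to any
  hierarchical (or set-valued) annotation scheme.
* The flat index is O(N·d) per query by design; very large lookup sets
  need the approximate-search methods deliberately left out of scope.
* EC codes are validated syntactically, not against a nomenclature
  database.
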