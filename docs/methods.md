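# Methods

## Problem setting

`ginplans` targets multi-target bioactivity prediction from chemical
structure (QSAR) under three data pathologies that are typical of
pharmacological panels: few fully labeled molecules, many molecules with
*partial* label vectors (some targets never assayed), and a large pool of
unlabeled structures, all under severe class imbalance dominated by the
all-negative profile. It implements two cooperating methods:

1. **GINFP** — a self-supervised molecular embedding. A Graph Isomorphism
   Network (GIN) is pretrained to reconstruct a molecule's binary
   extended-connectivity fingerprint (ECFP) from its heavy-atom graph;
   the 300-dimension graph-level hidden embedding is then used as a dense,
   continuous substitute for the sparse 2048-bit ECFP.
2. **PLANS** — partially-labeled noisy-student self-training. A small
   teacher MLP trained on the fully labeled data pseudo-labels the partial
   and unlabeled pools; progressively larger *noisy* students (dropout and
   optional mixup) are trained on the union and promoted to teachers.

## Label model

With `n` binary targets, a complete activity profile is one of `2**n`
*combination classes*, indexed MSB-first (the first target is the most
significant bit): `[0,1,1,0,1] -> 13`, the all-negative profile is
class 0. A partial profile with `m` missing entries is consistent with
exactly `2**m` candidate classes. Pseudo-labeling a partial row restricts
the teacher's softmax distribution to the candidate set and renormalises
it to sum to one; an observed row therefore collapses to a hard one-hot
regardless of the teacher. If the teacher puts zero mass on every
candidate, completion falls back to a uniform distribution over the
candidates (logged). One-hot combination mode refuses `n > 16` (class
explosion); a per-target sigmoid *multi-label* mode is provided for
problems framed as independent binary tasks, completing each missing
target with the teacher's per-target probability.

## GIN encoder

Node features are fixed-length one-hot blocks (atom type, degree, formal
charge, hybridization, aromaticity, chirality tag; overflow buckets keep
the length constant at 35). Bonds are unweighted undirected edges; edge
types are not used in message passing. Layer `k` aggregates

    a_v = (1 - eps_k) * h_v^(k-1) + sum_{u in N(v)} h_u^(k-1)

with a trainable scalar `eps_k` per layer, then applies that layer's node
MLP (default hidden widths 1024 and 512, output = embedding width).
Neighbour embeddings are **summed**, never averaged, so the network can
separate nodes by neighbour multiset. The `(1 - eps)` coefficient is the
default; `epsilon_sign=+1` switches to the `(1 + eps)` convention of the
original GIN formulation — the two differ only by the sign of a trainable
scalar initialised at zero, so the choice is exposed rather than decided.
The graph embedding sums each node's embeddings across all `K` layers
(default `K = 5`) and mean-pools over nodes; its length is `embed_dim`
(default 300). Pretraining attaches a two-layer MLP head producing
`out_dim` logits (default 2048) and minimises mean per-bit binary
cross-entropy against the molecule's ECFP (radius 4, 2048 bits, chirality
flags off by default), with Adam (lr 1e-3), minibatches of 64, a 10%
validation split, and early stopping (patience 5, best weights restored).
The initial node embedding is a learned linear projection of the raw
feature vector; the head is discarded at embedding time.

All networks (GIN and MLPs) are implemented directly on NumPy in float32
— dense layers with manual backpropagation, ReLU hidden activations,
inverted dropout, and Adam — with gradients verified against central
finite differences in the test suite. Forward passes over graph batches
pack node matrices and use a block-sparse adjacency, so permutation
invariance holds exactly up to float32 summation order (the tests allow
1e-5 relative).

## PLANS loop

The fully labeled pool is split 7:3 into train and test; 10% of the
training part is held out as a fixed validation slice for early stopping.
The test split is never touched during training, and partial/unlabeled
rows are used for training only. The staged sequence is:

1. Train the **Small** teacher on the fully labeled training rows with the
   combination-class cross-entropy `-sum_i y_i log p_i` (soft targets
   supported). Teachers are trained and run *without* noise.
2. For each student tier (**Medium**, then **Large**, optionally repeated
   Large rounds until the validation micro-F1 stops improving, patience 1):
   regenerate pseudo-labels with the current teacher; rebuild the training
   set from scratch (fully labeled + completed partial rows + unlabeled
   rows); train the student with dropout (rate 0.3, applied before the
   output layer) and, when enabled, mixup; promote it to teacher.
3. The last student predicts the test split; hard predictions are the
   argmax class (lowest index wins ties) decoded back to the binary
   target vector.

MLP tiers follow a fixed width plan relative to the input length `L`:
Small has seven hidden layers of `2L, 4L, 4L, 2L, L, L/2, L/4`; Medium
inserts a `3L` layer after Small layers 1 and 3; Large additionally
inserts two `6L` layers after Small layer 2. Parameter counts are
strictly increasing Small < Medium < Large for any `L >= 4`.

**Mixup** draws a coefficient `lam ~ Beta(alpha, alpha)` (default
`alpha = 0.4`) per sample and mixes each batch with a random permutation
of itself: `x~ = lam*x_i + (1-lam)*x_j`, same combination for the soft
labels. It is applied only in student training.

**Balancing** (optional) counters the all-negative dominance: pool rows
whose pseudo-label argmax is class 0 are never added; other classes
receive pseudo-labeled unlabeled rows (in a seeded random order) until
their count reaches the all-negative count in the current training set.
Balancing is redone from scratch whenever a new teacher is promoted, and
the original labeled rows are always kept. Without balancing, the whole
unlabeled pool is added (controlled by `use_unlabeled`).

Defaults: Adam lr 1e-3, batch 64, 50 epochs with patience 5 (best
weights restored), dropout 0.3, split 0.7, 5 repeats with fresh random
splits. The paper-style training uses soft (not argmax-hardened)
pseudo-labels, preserving the knowledge-distillation rationale.

## Synthetic data generator

Real enzyme-panel data are optional inputs; the generator provides a
structurally faithful stand-in. Molecules are assembled from a weighted
vocabulary of valid fragments (alkyl chains, benzene/cyclohexane/pyridine
rings, hydroxy/amino/halogen/acid/amide/thioether substituents) joined by
single bonds at hydrogen-bearing atoms and sanitized with RDKit, so every
output is a valence-respecting SMILES. Activity against target `j` is
planted as "contains motif `j`" (default motifs: pyridine ring, carboxyl,
chlorine, sulfur, amide). Motif-bearing fragments are down-weighted so
the all-negative class dominates (roughly 55–65% of molecules with the
default vocabulary), emulating the imbalance of real panels. Labels are
then independently flipped with probability `label_noise`, a fraction
`unlabeled_fraction` of molecules is stripped of all labels, and the
remaining cells are masked independently with probability `missing_rate`
(missing-at-random); molecules with at least one masked cell form the
partially labeled pool. The complete (post-noise) label matrix is
retained separately so recovery tests never leak through the training
path.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, activity cliffs, correlated assay dropout
(missingness in real panels is not random), or inter-target label
dependence beyond shared motif co-occurrence. Passing tests on this data
demonstrate that the machinery (encoding, completion, staged training,
balancing) behaves as specified and that the semi-supervised gain exists
when labels derive from structure; they do not certify performance levels
on real assay data.

## Benchmark and test problem sizes

The packaged semi-supervised benchmark uses 1,000 molecules with expected
pool proportions 30% fully labeled / 40% partially labeled / 30%
unlabeled (per-cell masking rate 0.1558 yields the 40% molecule-level
partial share in expectation), 5% label noise, balancing on and mixup
off — mixup degraded the combination-class task in the original study, so
the benchmark mirrors the strongest non-mixup configuration. Features are
GINFP-300 from a GIN (3 layers, node MLPs 128/64) pretrained on a
separate 800-molecule unlabeled corpus to reconstruct 512-bit radius-2
ECFPs; MLP tiers therefore run at `L = 300`. Five repeats with fresh 7:3
splits are compared pairwise (same seeds) against a Large model trained
on the fully labeled rows alone. On this benchmark PLANS reaches a mean
held-out micro-F1 of ~0.45 versus ~0.16 for the fully-supervised
baseline, which frequently collapses to all-negative predictions — the
qualitative behaviour the method was designed to fix. The GIN
reconstruction sanity check uses 500 molecules at the same reduced
widths. These sizes are the package's chosen desk-scale study
conditions; the original study's headline numbers come from external
datasets (17k-molecule enzyme panel, 7.8k-molecule toxicity panel, 1.7M
unlabeled molecules) and are out of scope here.

## Numerical and design notes

- Determinism: every stochastic step takes an explicit seed or
  `numpy.random.Generator`; identical config + seed reproduces datasets,
  training curves and embeddings bitwise on the same platform.
- The dropout rate is the *drop* probability (0.3); keep probability 0.7.
- Argmax ties break to the lowest class index.
- Empty graphs cannot be embedded (mean pooling undefined) and raise.
- Unparseable SMILES are dropped and logged with their indices — never
  silently imputed.
- ECFP bit collisions from folding to `n_bits` are accepted as-is.
- Evaluation: accuracy is the exact-combination match rate; micro
  precision/recall/F1 pool TP/FP/FN across all targets of the decoded
  binary matrix; average precision is computed per target from soft
  scores (in one-hot mode, the summed probability of all classes in which
  the target is active) and macro-averaged, with a micro variant reported
  alongside; repeats aggregate as mean ± sample SD, accuracy formatted as
  a percentage.

## Known limitations

- CPU-scale only: the NumPy networks are adequate for thousands of
  molecules, not millions; there is no GPU path.
- The GIN ignores bond types and stereochemistry-aware 3D information.
- One-hot combination mode treats classes as unrelated, ignoring label
  dependence between evolutionarily related targets.
- Whether the multi-label (sigmoid) or combination (softmax) head is the
  right formulation for 12-target toxicity panels is left to the user;
  both are provided.
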