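# Methods

## Problem setting

Toluene/water partition coefficients (logP_tol/w) of neutral solutes matter
for drug discovery and separation design, but only a few hundred experimental
values exist. Cheap computed values (e.g. from continuum-solvation
thermodynamics) can be produced by the thousands, at the cost of bias and a
roughly ten-fold larger label noise. `mflogp` studies how a graph neural
network should consume both label tiers: not at all (single-task), in
sequence (transfer learning), as an input feature (feature-augmented
learning), or jointly through a two-head model with a masked loss
(multi-target learning).

## Thermodynamic background of the low-fidelity labels

The partition coefficient is equivalently

    logP = log10([S]_tol / [S]_w)
         = (dG_w^solv − dG_tol^solv) / (R T ln 10)
         = log10((γ_w^∞ / γ_tol^∞) · (ν_w / ν_tol)),

with solvation free energies in kcal/mol, R = 1.98720e-3 kcal mol⁻¹ K⁻¹ and
T defaulting to 298.15 K. Computed labels derive from the free-energy form,
so their uncertainty follows from independent Gaussian errors on the two
solvation energies:

    σ_logP = sqrt(σ_w² + σ_tol²) / (R T ln 10).

With the commonly quoted σ = 0.45 kcal/mol per solvation energy this gives
0.47 log units — the noise level the synthetic low-fidelity tier adopts.
Independence of the two errors is an assumption; no covariance information
is available for continuum-solvation energies in two different solvents.
The infinite-dilution activity-coefficient form is implemented alongside the
free-energy form without attempting to reconcile the slight difference
between infinite and low finite dilution.

## Encoder

The encoder is a directed message passing network: hidden states live on
directed bonds, and the message into edge v→w aggregates the states of edges
entering v *excluding* the reverse edge w→v, which suppresses immediate
message echo. After `depth − 1` update iterations a per-atom readout
concatenates raw atom features with incoming edge states, and molecule
embeddings are the mean (default) or sum over atoms. A feed-forward head
(relu hidden layers, linear output) maps the embedding — optionally
concatenated with extra input features — to one or two targets.

Because no deep-learning framework is part of the dependency set, forward
and backward passes are written directly in NumPy (float32), with the
edge→atom aggregation expressed as a sparse-matrix product. Gradients are
verified against central finite differences in the test suite, and the
forward pass against a separately written loop-unrolled reference.

Atom features: element one-hot over {H,C,N,O,F,Si,P,S,Cl,Br,I} plus an
unknown slot, total-degree / formal-charge / attached-H / hybridization
one-hots, an aromaticity flag, and atomic mass divided by 100. Bond
features: bond-order one-hot (single/double/triple/aromatic), conjugation
and ring flags. Hydrogens are implicit. Chirality is not encoded: the
property model here is 2D-topology-driven, a deliberate reduction relative
to feature sets that carry stereo slots.

Defaults: hidden size 128, depth 3, dropout 0, two feed-forward layers of
width 128. These are intentionally narrower than the 300-wide defaults
common in the field, sized so the full benchmark runs on one CPU core in
minutes. Optimization is Adam under a Noam-style schedule (linear warm-up
from 1e-4 to 1e-3 over two epochs, then exponential decay back to 1e-4),
mean squared error on z-scored targets (per-target statistics from the
training fold only, masked entries excluded), and the weights of the
best-validation epoch are kept. Early stopping by patience is available but
disabled by default: all epochs run and the best epoch wins.

Two efficiency choices worth knowing about: mini-batches are formed once per
training run from a seed-shuffled molecule order and their featurized batch
graphs cached, with only the batch *order* reshuffled each epoch; and
featurized molecular graphs are memoized per SMILES string process-wide.

## Training regimes

* **single** — one tier, one head, internal seeded 80-10-10 split (sizes
  floor(0.8 n) / floor(0.1 n) / remainder).
* **transfer** — the low-fidelity model's weights initialize the
  high-fidelity run; *all* weights train (freezing the encoder is exposed
  but off by default), and the target scaler is refit on the high-fidelity
  training fold. A zero-epoch fine-tune is an exact no-op — weights *and*
  scaler are kept — so the regime degrades continuously to the pretrained
  model.
* **multi_target** — the union of both tiers keyed by canonical SMILES
  feeds one model with two heads (column 0 low-fidelity, column 1
  high-fidelity). The loss is Σ mask·(pred−y)² / Σ mask, so missing entries
  contribute exactly nothing to loss or gradients; when a molecule carries
  both labels, both are kept without averaging — the inter-tier discrepancy
  is the signal. Both tiers weigh equally per observed entry (an
  `hf_weight` multiplier is exposed for the heavily imbalanced case).
  Validation tracks the high-fidelity column whenever the fold contains
  such labels.
* **feature_augmented** — a fresh high-fidelity model receives the
  low-fidelity model's prediction as one extra input feature, z-scored on
  the high-fidelity training fold with the standard deviation floored at
  1e-8 (a constant feature then simply carries no information instead of
  exploding).

Hyperparameter search is seeded random sampling over declared value lists
(default: hidden ∈ {64,128,256}, depth ∈ {2,3,4}, dropout ∈ {0,0.1,0.2},
ffn layers ∈ {1,2,3}; budget 20), scored by validation RMSE.

## Synthetic benchmark

The real computed tier is not redistributable, so the benchmark generates
its own: random valence-correct molecules of 3–20 heavy atoms over
{C,N,O,S,F,Cl,Br} (optionally seeded with an aromatic or aliphatic ring,
occasional carbonyls and extra ring closures), labelled by an additive
Crippen-style ground truth g: aliphatic C +0.45, aromatic C +0.30, O −1.00,
N −0.90, S +0.10, F +0.20, Cl +0.60, Br +0.80, +0.10 per ring. Labels:

    HF = g + N(0, 0.05),       LF = 0.9·g + 0.3 + N(0, 0.47),

i.e. the low-fidelity tier is biased (affine) and noisy at the level the
uncertainty propagation above predicts, yet highly correlated with the
truth (r > 0.9 at the default sizes). Default sizes: 4000 LF molecules,
150 HF training molecules (half of which also get an LF label), and a
disjoint 200-molecule held-out HF-style test set. Everything is a pure
function of the parameter set plus one seed.

The additive ground truth is deliberately representable by a depth-3
message passer, so the benchmark separates *strategy* quality from model
capacity. What it does **not** emulate: real activity cliffs,
conformation-dependent effects, tautomers, dimerization in the organic
phase, or the narrow, correlated chemical series of experimental
collections. Passing the benchmark therefore shows that a strategy exploits
a correlated auxiliary tier correctly — not that it attains any particular
accuracy on laboratory data.

The benchmark trains, per seed: the single-task high-fidelity model, a
single-task low-fidelity model (shared as the transfer starting point and
the feature-augmentation stage 1, which are defined identically), the
transfer fine-tune, the joint two-head model, and a 500-tree random forest
on 2048-bit radius-2 Morgan fingerprints of the combined tiers (HF label
retained for molecules present in both; `max_features="sqrt"`, the usual
choice for high-dimensional binary fingerprints). Schedules: 20 epochs at
batch 64 for runs that see the large tier, 30 epochs at batch 16 for the
150-molecule tier. Ten seeds by default; roughly one minute per seed on one
CPU core.

Expected outcome, asserted by the acceptance tests over 10 seeds: mean
held-out RMSE of multi-target and of transfer below single-task, and the
fingerprint baseline worst. Which multi-fidelity regime wins *within* a
seed varies at this scale — the stable finding is the gap between any
graph-based multi-fidelity regime and single-task or fingerprint training.

A separate capacity check trains the single-task model on 2000 noiseless
labels and requires held-out RMSE < 0.3. This run uses *sum* aggregation
and a longer schedule (100 epochs, batch 32, peak learning rate 2e-3):
the ground truth is extensive (a sum over atoms), which sum pooling can
represent exactly while mean pooling would have to reconstruct the atom
count it has discarded.

## Numerical conventions and degenerate inputs

* Dedup keys on canonical isomeric SMILES (aromaticity perceived,
  stereochemistry retained) *within* one fidelity tier; cross-tier
  duplicates are legitimate and required by multi-target training.
* Random splits: floor/floor/remainder with a seeded permutation.
* Single-atom molecules have zero directed edges; their embedding comes
  from atom features alone. Two-atom molecules exchange no messages beyond
  initialization (the reverse-edge exclusion empties every neighbor set) —
  both are exercised in tests.
* Target std is floored at 1e-8; a constant-label training set therefore
  predicts that constant rather than dividing by zero.
* Non-finite training loss aborts with a diagnostic rather than continuing.
* Out-of-vocabulary elements map to the unknown feature slot and predict
  without failure.
* Chemical-class assignment ships an explicit priority-ordered SMARTS table
  (most specific first, e.g. aminophenol before phenol and aniline);
  class-level results are convention-dependent and not comparable across
  different pattern tables.

## Known limitations

* The encoder is CPU-bound NumPy; it is sized for datasets of 10³–10⁴
  molecules, not 10⁶.
* No uncertainty heads, no ensembling beyond plain prediction averaging,
  at most two fidelity tiers.
* The synthetic generator's chemistry is simplistic by construction (see
  above); absolute RMSE numbers from the benchmark carry no meaning for
  laboratory data — only the ordering of strategies does.
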