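# Methods

This note documents the models and estimators implemented in `surfmae`, the
choices made where the design was genuinely open, the synthetic data the
package trains and tests on, and what those desk-scale results do and do not
demonstrate.

## Surface model

The molecular surface is the zero level set of a smooth signed distance
function over the chain's atoms,

    SDF(x) = -sigma * log( sum_k exp( -(||x - a_k|| - r_k) / sigma ) ),

with per-element van der Waals radii (C 1.70, H 1.10, O 1.52, N 1.55,
S 1.80, Se 1.90 Å) and smoothing temperature `sigma = 0.5` Å. This log-sum-exp
soft-min was chosen because it reduces *exactly* to `||x - a|| - r` for a
single atom — every geometric unit test then has a closed form — and its
gradient (the softmax-weighted mean of unit vectors from atoms to the query)
is available analytically, giving exact outward normals. The function is
negative inside the molecule and positive outside; note that the soft-min
inflates the surface slightly where many atom spheres overlap (by roughly
`sigma * log n_eff`), which is a property of the model, not an error.

**Level-set sampling.** Twenty candidates per atom are seeded uniformly in
a thin shell `[r_k, r_k + 1.5 sigma]` around each atom and Newton-projected
along the normalized gradient for up to 10 iterations; candidates with
`|SDF| > 0.05` Å or vanishing gradient are discarded. Survivors are thinned
on a cubic grid with 1 Å edge anchored at the origin, keeping the candidate
nearest each occupied cell's center — at most one point per cell, which is
the implementation's reading of "sampled at 1 Å resolution". The retained
set is then subsampled to exactly `target_points` (2048 by default) without
replacement, or with replacement when the raw surface is smaller. For
efficiency the projection step truncates the soft-min to the 128 nearest
atoms, with an explicit error bound that falls back to the exact sum
whenever the excluded tail could matter; the public `sdf`/`sdf_gradient`
functions always evaluate the full sum.

**Curvature.** Mean and Gaussian curvature are estimated per point at
scales 1, 2, 3, 5, 10 Å. At scale `s`, every neighbour within `3s`
contributes a normal-curvature sample `kappa_j = 2 z_j / d_j^2` (`z_j` its
height along the point's normal, `d_j` its distance) in tangent direction
`theta_j`, and the second fundamental form
`kappa(theta) = a cos^2 + 2b cos sin + c sin^2` is fitted by least squares
with Gaussian weights `exp(-d^2 / 2 s^2)`; then `H = -(a+c)/2` and
`K = ac - b^2`, signed so a sphere with outward normals has `H = +1/R`,
`K = +1/R^2`. The more obvious alternative — fitting the height quadric
`z = (a u^2 + 2b uv + c v^2)/2` directly — carries an `O((s/R)^2)` bias
(about +6 % on `H`, +12 % on `K` for a 5 Å sphere at scale 1) because the
quartic term of the height function leaks into the quadratic fit. The
normal-curvature form is exactly unbiased on spheres and planes by the
chord property (`d^2 = 2Rz` on a sphere), at no extra cost. Points with
fewer than 6 usable neighbours at a scale (coincident points excluded)
report (0, 0) at that scale. Fits use at most the 256 nearest neighbours;
the Gaussian weight of anything farther is negligible at every scale used.

**Chemical features.** Each surface point records its 16 nearest atoms
(ascending distance, ties broken by atom index): per slot the atom's
one-hot element type and the Euclidean distance. Chains with fewer than 16
atoms repeat their sorted neighbour list cyclically. These raw records —
not derived quantities like electrostatics — are the chemistry the network
sees; learning to interpret them is part of the model.

## Network

* **Point encoder**: a shared MLP (7 → 32 → 32) embeds each neighbour
  record; three message-passing blocks each compute per-neighbour messages
  from [local feature ⊕ neighbour embedding] (38 → 32 → 6), mean-aggregate
  over the 16 slots and residually update the 6-channel local feature
  (initialised to all-ones). Mean aggregation makes the output invariant to
  neighbour-slot permutations.
* **Fusion**: the 6 chemical channels are concatenated with the 10
  curvature channels (16 per point).
* **Tokenizer**: a shared MLP (16 → 128 → d) per point, channel-wise
  max-pool over each patch's k' members. Patches come from farthest point
  sampling (first center = farthest from centroid, ties to the lowest
  index, deterministic) and k-nearest-neighbour grouping; masked patches
  are never tokenized during pretraining.
* **Positional encoding**: the patch center coordinate is lifted to random
  Fourier features `[sin(Bc), cos(Bc)]` (32 frequencies per axis, bandwidth
  `1/1.5` Å⁻¹, fixed at construction) and passed through a 2-layer MLP to
  width d; encoder and decoder keep separate weights, added (not
  concatenated) to tokens. A plain coordinate MLP was tried first and
  carries a strong spectral bias toward smooth functions of position; at
  desk-scale step budgets it cannot regress patch-level geometry fast
  enough, which showed up as reconstruction loss plateaus insensitive to
  every optimizer setting. The Fourier lift removes that bias; bandwidth
  and frequency count are `ModelConfig` fields.
* **Encoder**: pre-norm transformer, 12 blocks × width 384 × 6 heads,
  MLP ratio 4 (defaults; the desk-scale experiments use d=64, depth 2).
  An optional learnable CLS token (with its own learnable position) is
  prepended for whole-surface classification and never reaches the decoder.
* **Decoder**: projected visible tokens plus one shared learnable mask
  token per masked slot, each with decoder-side positional encoding; 4
  self-attention blocks; a linear head maps each masked slot to k' × 3
  coordinates relative to the patch center. Center-relative prediction
  makes the loss translation-invariant per patch.
* **Chamfer loss**: per patch, mean squared distance from each target
  point to its nearest prediction plus the mirror term, summed over
  patches.
* **Heads**: binding-site — inverse-distance interpolation of the 3
  nearest patch tokens (weights normalised per point), concatenated with
  the point's fused 16-channel feature and the global max-pooled token,
  then an MLP to one logit per point. Pocket — CLS output concatenated
  with the max-pool of the other tokens, MLP to 7 logits. PPI — the same
  3-nearest-token interpolation, L2-normalised (optionally linearly
  projected when `descriptor_dim ≠ d`); the binding score of a point pair
  is a learnable-scaled dot product.

Dropout and stochastic depth are omitted: no rates are part of the recipe,
the package's determinism guarantees (bit-identical loss curves under fixed
seeds) are simpler without them, and the desk-scale datasets are far too
small for either to help.

The network and training loop run on `surfmae.nn`, a small reverse-mode
autodiff engine over float64 numpy arrays (broadcast arithmetic, matmul,
reductions, softmax, GELU/ReLU, gather, concat), with AdamW. Every
primitive and every composite block is gradient-checked against central
finite differences in the test suite. At the problem sizes this package
targets (hundreds of points, dozens of tokens) it is fast enough that the
full learning suite runs in minutes on one CPU core.

## Training protocols

Pretraining follows the published recipe: AdamW, initial learning rate
1e-3, batch 16, 50 epochs, mask ratio 0.6 resampled per sample per epoch,
2048-point clouds; the best epoch (minimal mean reconstruction loss, ties
to the earliest) initialises fine-tuning, and fine-tuning never masks.
Sample order is shuffled each epoch (seeded); without this, per-sample
optimizer steps on class-ordered datasets oscillate and the pocket task
never leaves chance level. The learning-rate schedule is constant by
default with an optional cosine decay. The binding-site loss is the
class-balanced binary cross-entropy (majority class subsampled, seeded, to
the minority count); pocket uses standard cross-entropy; PPI uses binary
cross-entropy on scaled descriptor dot products over a 1:1 seeded sample
of positive and random negative pairs.

### Desk-scale experiment conditions

The reference experiments (in `surfmae.experiments`, shared by the test
suite and `scripts/acceptance.py`) use a tiny configuration chosen once:
d=64, 2 encoder and 2 decoder blocks, 4 heads; g=32 patches of k'=16
points over 256-point surfaces — preserving g·k' = 2N, the same 2× patch
overlap as the full-scale 128/32/2048 setting; 24-residue synthetic
chains; batch 1 (with 8 samples per epoch, larger batches would starve the
run of optimizer steps).

* **Pretraining check**: 8 chains, 30 epochs, lr 1e-3 — the final-epoch
  mean chamfer loss falls below half the first-epoch mean.
* **Overfit smoke test**: 1 chain, 200 steps, fixed mask, lr 3e-2 with
  beta2 0.95 and cosine decay — the loss falls below 10 % of its initial
  value. The mask is deliberately frozen: this experiment isolates "can
  the network drive its own objective toward zero" from the fresh-mask
  generalisation that the 8-chain experiment measures, and an aggressive
  optimizer is the appropriate instrument for it.
* **Fine-tuning benchmarks**: site — 64 chains, labels "mean curvature at
  the second scale above its per-protein median", 20 epochs at lr 1e-4,
  held-out ROC-AUC; pocket — 7 balanced classes, 12 train + 4 test chains
  per class, 30 epochs at lr 1e-4 starting from the pretrained encoder
  (from-scratch runs at this data scale memorise the training chains and
  generalise erratically), balanced accuracy; PPI — 60 train + 6
  test mirrored pairs, 20 epochs at lr 1e-3, pooled pair ROC-AUC with 5
  random negatives per positive.

## Synthetic data

`synth_chain` emulates a protein chain as a self-avoiding random walk with
3.8 Å steps (the C-alpha spacing) and a weak centripetal bias for globular
packing, 1–4 pseudo side-chain atoms per residue within 2.5 Å, and
heavy-atom-dominant element frequencies (C .58 / O .20 / N .17 / H .03 /
S .015 / Se .005). The downstream benchmarks add label structure:

* **site**: the label is a deterministic function of local geometry (second-
  scale mean curvature above its median), so the task is learnable from the
  features the network actually receives;
* **pocket**: each of the 7 classes has a distinct side-chain
  (S, Se, O)-composition signature and a size offset — surrogates for the
  residue-composition and size differences between real cofactor pockets;
* **PPI**: a chain and its mirror image placed in surface contact across a
  plane, with sulfur-enriched atoms near the contact — mirror symmetry
  provides geometric complementarity and the enrichment gives the interface
  an intrinsic chemical signature, as real interfaces have. Positives are
  cross-surface point pairs within 1 Å in the complex frame.

What these fixtures do **not** emulate: real secondary structure, side-chain
rotamers, residue-level chemistry, crystallographic noise, or the label
processes of the real benchmarks (dMaSIF interaction sites, experimentally
annotated cofactor pockets, dMaSIF-search interfaces). A passing learning suite
therefore demonstrates that the pipeline is implemented coherently end to
end — features carry signal, gradients flow, pretraining transfers — not
that the published benchmark numbers are reproduced; those require the
authors' PDB-derived splits and pretraining on ~356 k chains.

## Numerical choices and degenerate inputs

* Ties everywhere (FPS, KNN, chemical neighbours) break to the lowest
  index; sorts are stable; all seeded randomness derives from
  `numpy.random.SeedSequence` keys, so every pipeline stage is
  bit-reproducible.
* `round(m*g)` masked patches, computed as `floor(m*g + 0.5)`.
* Curvature fits add `1e-12` Tikhonov mass to the 3×3 normal equations;
  coincident points (possible after with-replacement subsampling) are
  excluded from fits and from the "6 usable neighbours" count.
* The SDF gradient is undefined at an atom center and raises; the sampler
  never queries there.
* Chains with every raw surface point beyond the budget (`N > 20000`)
  return a rejection value rather than raising, so batch preprocessing can
  count and log them.
* The balanced losses raise on single-class inputs rather than silently
  returning an unbalanced mean.

## Known limitations

* The numpy engine is single-threaded per op and float64-only; it is meant
  for desk-scale and testing, not for pretraining at the published scale
  (the code paths are the same; only throughput differs).
* Patch-token interpolation limits per-point resolution of the PPI
  descriptors to roughly patch granularity; at desk scale, descriptor
  training is prone to memorising train pairs unless the interface carries
  an intrinsic signature and the dataset is large enough — the reason the
  PPI benchmark marks its interfaces chemically and uses 60 training pairs.
* The surface is the smooth-distance level set, not a solvent-excluded
  surface; cavities narrower than ~`sigma` are smoothed over, and the
  soft-min inflation means absolute radii differ from the hard-sphere
  surface by up to a few tenths of an Å for dense atom packings.
* mmCIF input and NMR ensembles beyond model 1 are out of scope; alternate
  locations other than blank/'A' are dropped.
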