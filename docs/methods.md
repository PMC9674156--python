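# Methods

## Problem and model

The package predicts, per residue of a protein sequence, the propensity to
carry one of five molecular functions of intrinsically disordered regions
(assembler, chaperone, display site, effector, scavenger), plus disorder
itself. Functional residues are a subset of disordered residues, which is
why a disorder-pretrained model transfers well to the function tasks.

Three encoders view one protein from complementary angles:

* **Sequence**: a bidirectional LSTM over the L×40 evolutionary profile
  (20 PSSM log-odds columns, 20 profile-HMM emission probabilities). The
  PSSM columns are consumed raw: their scale is absorbed by the LSTM's
  affine input maps, and an optional per-column standardisation flag exists
  in the readers for experiments. Profile rows at `X` (unknown) residues
  are zeroed, as is their one-hot encoding.
* **Structure**: the L×L contact map is correlated with a bank of
  c = 16 trainable 5×5 kernels (same zero padding); each residue i is then
  summarised by the mean and max over the partner axis of each feature map
  (L×2c), and an affine + relu layer projects to d_stc = 32. The
  convolution of an L×L map does not by itself yield the L×d block the
  alignment stage needs; per-residue pooling is the device that makes the
  encoder length-invariant. A caveat recorded here deliberately: with
  kernel size k > 1 a 2D convolution is translation-equivariant but *not*
  equivariant under simultaneous row/column permutation of the map, so the
  pooled block inherits only approximate permutation behaviour; the test
  suite asserts exact equivariance in the k = 1 case where it holds.
* **Function**: the one-hot sequence is scanned by convolution kernels
  copied verbatim from motif letter-probability matrices (one kernel per
  motif, anchored at floor(l/2), zero-padded at the ends so terminal
  residues are still covered). The kernels are frozen — the motif bank is
  prior knowledge — and only the per-motif bias trains; a flag allows
  unfreezing for experiments.

**Alignment (ALAN).** Every pair of encoder blocks (A, B) is aligned by
α = softmax over rows of (A H¹_A)(B H¹_B)ᵀ / √d_a; the complementary
block concatenates (αᵀ A) H²_A and (α B) H²_B. Design choices where the
construction was genuinely open: the softmax normalises over the second
index (each residue of A distributes attention over residues of B); the
logits are scaled by 1/√d_a — without the scaling the logit products
saturate the softmax at arbitrary positions, the alignment never learns
to localise, and adding the function encoder *hurts* (held-out AUC 0.844
versus 0.980 with scaling in otherwise identical runs), so the scaled
form is the default and a flag recovers the unscaled reading; the blocks
enter the weighted sums untransformed, with H² as the only projection;
the H¹/H² of a block are shared across the pairs it joins.
The stc–func pair is projected symmetrically with the other two pairs; a
`literal_stc_func` flag swaps its two H² maps (valid only when
d_stc equals the motif count) for comparison.

**Fusion and head.** The three complementary blocks are summed through
separate linear maps into an L×n fused representation (n = 64). A dense
layer over all positions is impossible with variable L, so the output head
is windowed position-wise: each residue's logit is W_f applied to the mean
of the fused rows in a width-15 window centred on it (w = 1 recovers a
literal position-wise head). Window means at the termini average only the
in-range rows.

**Ablations.** `use_stc`/`use_func` drop encoders (and with them their
alignment pairs); `use_alan=False` feeds the encoder blocks directly to
fusion. With fewer than two active blocks there is no pair to align and
the alignment stage is bypassed automatically.

## Training

One protein per optimisation step (variable L, no padding or masking),
epoch order shuffled by the run seed. The loss is the summed (not averaged)
binary cross-entropy per protein, with propensities clipped to
[1e-7, 1−1e-7]; the epoch log reports the per-protein mean. Adam uses
lr 1e-3 for pre-training, lr 1e-4 by default for fine-tuning (one order
below pre-training, the usual regime for full-model fine-tuning), and
β = (0.9, 0.999), ε = 1e-8. All layers are updated during fine-tuning.
The returned checkpoint is the epoch-minimum of validation loss — for
fine-tuning too, by symmetry with pre-training, since a separate rule for
that stage would be arbitrary. Default epoch budgets are 12 (pre-train) and
16 (fine-tune) with early stopping after 6 non-improving validation
epochs; on the synthetic benchmark the model converges within a handful of
epochs, and the experiment scripts state their explicit, smaller budgets
below. Decision thresholds are calibrated by scanning the midpoints of
consecutive distinct validation scores (plus 0 and 1) and maximising MCC,
ties broken toward the smaller threshold (higher sensitivity).

Determinism: all randomness flows from `numpy.random.default_rng(seed)`;
repeated runs with one seed produce bitwise-identical checkpoints under
single-threaded execution.

## Numerical core

No autodiff framework is used; `pclm.autodiff` is a compact float64
reverse-mode tape with fused ops for the Bi-LSTM (vectorised BPTT), the
2D convolution bank (im2col + one matrix product) and the motif scan.
Gradients of every trainable parameter are checked end to end against
central finite differences (relative error ≤ 1e-4 at eps = 1e-5) in the
test suite. Degenerate-input conventions: max-pool backward routes to the
first argmax; the clip op passes gradients only strictly inside its
interval; MCC with a degenerate confusion table is reported as 0 with a
warning flag; PBC with a zero-variance feature and ROC/MCC/threshold
calibration with single-class labels raise errors rather than guessing.
PBC uses the population (÷n) standard deviation, making it exactly
|Pearson| under 0/1 label coding. ROC handles score ties by stepping tie
groups simultaneously, which equals the tie-corrected Mann–Whitney
statistic. In the example-based multi-label metrics an empty predicted set
contributes precision 0 for its example, and F1 is the harmonic mean of
the aggregate precision and recall.

## Synthetic proteomes

The generator emulates the statistical structure the model assumes, not
protein evolution. Per protein, ordered and disordered segments alternate
with geometric lengths (disordered mean 30 residues; the ordered mean is
set by the target disorder fraction, default 0.3, the commonly cited
eukaryotic proportion). Disordered segments are enriched for the
disorder-promoting residues P/E/S/K/Q/A/G, ordered segments for
W/F/Y/I/L/V/C/N. Each of the five functions owns a disjoint bank of 3
PWMs (lengths 6–8, consensus probability 0.8); with probability 0.7 an
eligible disordered segment receives one planted motif (letters sampled
from the PWM rows), and the footprint ± 2 flanking residues becomes that
function's positive region — labels are region-like, as curated databases
annotate regions, and function labels are a subset of disorder labels by
construction. Pseudo-PSSM rows are the rounded scaled log-odds of the
segment composition against background plus ±1 integer noise;
pseudo-HHM rows are Dirichlet-perturbed segment compositions; contact
maps decay exponentially inside a width-8 band within ordered segments,
plus sparse long-range ordered-ordered pairs and a small noise floor
everywhere. Emission rows and contact maps are quantised to their on-disk
precision (the −1000·log2 integer codec, 6 decimals respectively) at
generation time so that written benchmarks re-read exactly; HHM row sums
therefore deviate from 1 by up to ~4e-4.

What passing tests on this data do and do not show: the generator's
signal is honest but far cleaner than real profiles — per-residue
profile rows depend on the segment type directly, motifs are drawn from
the same PWMs the model receives as kernels, and contact maps are
noise-free summaries of the segment structure. Success here demonstrates
that the architecture, training and transfer machinery recover a planted
signal of the assumed form; it says nothing about accuracy on real
annotated proteins, which additionally requires real profile tools and
curated labels.

## Experiment protocols (test suite)

Problem sizes are chosen so the full suite runs on one CPU at desk scale.

* **Signal recovery**: default benchmark (500 proteins, lengths 60–400,
  split 300/100/100), 3 simulation seeds; pre-train 2 epochs, fine-tune
  4 epochs at lr 2e-4 on the best-annotated function of each run; the
  mean held-out AUC must reach 0.85.
* **Ablation orderings**: reduced proteome (100 proteins, lengths 50–150),
  5 seeds; pre-train 3 / fine-tune 8 epochs at lr 3e-4. Expected orderings
  of mean AUC: sequence-only ≤ sequence+function ≤ full model, and
  without-alignment ≤ with-alignment. Note the sequence-only model enjoys
  a floor effect: function residues are a subset of disordered residues,
  so merely ranking disorder high already yields a substantial AUC; the
  function encoder's margin on top of that floor is what the ordering
  detects.
* **Transfer**: with fine-tuning restricted to 10 proteins (6 epochs), the
  mean absolute PBC between fused-feature columns and function labels on
  held-out proteins is higher after pre-training + fine-tuning than after
  direct training of an identical architecture on the same 10 proteins.

## Known limitations

* The structure encoder's permutation behaviour (above) is approximate
  for k > 1.
* Motif kernels must be supplied (or simulated); the package does not
  discover motifs.
* One-protein-per-step training is simple and deterministic but slow for
  large corpora; there is no GPU path.
* The windowed output head sees local context only through the fused
  features; w is a fixed hyper-parameter, not learned.
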