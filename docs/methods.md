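# Methods

This document records the model, the assumptions behind the synthetic data
generator, the fixed parameters, and the numerical choices made in the
implementation.

## Cutting scores

A pooled negative-selection screen compares guide abundances between a
no-nuclease control population and a nuclease-expressing treatment
population. For each sample, raw read counts are converted to relative
abundances (counts divided by the sample total); a pseudo-count of one
replaces any zero raw count first, so every guide has a finite abundance.
Replicate abundances are averaged per condition **before** taking the ratio,
and the cutting score is

```
CS = log2( mean control abundance / mean treatment abundance )
```

Active guides deplete their host cells in the treatment population, so
higher CS means higher activity. `cutting_score` also reports per-condition
means, standard deviations (ddof=1) and replicate counts. Guides are
binarized into active/inactive at CS > 1.67 (Cas12a) or CS > 4.91 (Cas9)
for ROC analysis; these thresholds are exposed as
`guidekit.model.ACTIVE_CS_THRESHOLDS` and can be overridden everywhere they
are used.

## Library design

- **PAM conventions.** Cas9: 20-nt spacer with a 3' NGG PAM. Cas12a: 25-nt
  spacer with a 5' PAM — TTTV for library design, TTTN for genome-wide
  indexing and counting. Patterns are IUPAC strings compiled to regular
  expressions with a lookahead so overlapping sites are all found; minus
  strand hits are found by matching the reverse-complement pattern on the
  plus strand, and all coordinates are 0-based leftmost plus-strand.
- **Uniqueness.** A guide is kept only if its 14-nt PAM-proximal seed (the
  5' end of a Cas12a spacer, the 3' end of a Cas9 spacer) occurs exactly
  once among all genome-wide candidates on both strands under the relaxed
  PAM (TTTN / NGG).
- **Selection.** Within each gene's CDS, candidates are walked 5'→3' and
  strands are alternated, starting from the strand of the 5'-most candidate;
  genes yielding fewer than the requested number of unique guides are
  reported as under-covered rather than padded.
- **Non-targeting controls.** Random spacers accepted only if their first
  10 nt occur nowhere in the genome on either strand.

## Context windows

The model input is a fixed-length window centered on the protospacer:
28 bp for Cas9 (`[2 up][20 spacer][3 PAM][3 down]`) and 32 bp for Cas12a
(`[1 up][4 PAM][25 spacer][2 down]`). For other lengths the extra sequence
beyond spacer+PAM is split `up = extra // 2`, `down = extra - up` on the
PAM-distal/proximal ends following the same layouts. Minus-strand windows
are reverse-complemented so the model always sees the spacer 5'→3'.
Lengths shorter than spacer+PAM are rejected rather than truncated into the
protospacer. Windows containing N cannot be one-hot encoded and raise.

## Network architecture

Input is one-hot DNA, shape `(4, n)` with row order A, C, G, T.

- **Encoder:** Conv1D(20 filters, kernel 5, same padding) → MaxPool(2) →
  BatchNorm → Conv1D(40 filters, kernel 5) → AvgPool(2) → BatchNorm.
  Pooling uses floor division, so the flattened feature dimension is
  `(n // 4) * 40` — 280 for n = 28, 320 for n = 32.
- **Head variants:** `encoder_only` (no dense hidden layers), `fc8` (80),
  `fc8+fc9` (80, 40), `fc8+fc9+fc10` (80, 40, 40), each followed by a
  single linear output unit. For n = 28 the dense weight matrices of the
  full stack are 280×80, 80×40 and 40×40 (22,400 / 3,200 / 1,600 weights).
- **Occupancy branch:** a Dense(1 → w) + ReLU transform of the per-guide
  normalized occupancy, where w is the width of the layer it merges with
  (the last hidden layer); the merge is element-wise multiplication with the
  sequence features, so a (near-)zero transformed occupancy can gate the
  sequence signal down.
- **Final configurations:** Cas12a uses n = 32 with `fc8+fc9` and no
  occupancy branch; Cas9 uses n = 28 with `fc8` plus the multiplication
  merge.
- **Autoencoder:** the decoder mirrors the encoder with upsampling and a
  final convolution back to 4 channels; reconstruction is trained with
  binary cross-entropy on logits. After pre-training the decoder is
  discarded and the encoder weights initialize the predictor (optionally
  frozen).

## Training

Glorot-uniform initialization; Adam with learning rate 1e-3; L2 weight decay
1e-4 applied to convolution and dense weight matrices only (not biases or
batch-norm parameters); batch size 64. The autoencoder trains for a fixed
epoch budget with no early stopping (default 200 epochs at full scale).
The predictor trains up to 150 epochs with early stopping on validation
loss (patience 15) and restores the best-validation weights. Data are split
60/20/20 into train/validation/test by a seeded shuffle. Regression uses
mean squared error; the classification mode uses binary cross-entropy with
a sigmoid output. A non-finite training loss aborts with diagnostics rather
than continuing.

## Synthetic data generator

The generator's defaults define the study conditions used by the tests and
the acceptance script; they were fixed before outcomes were observed.

- **Genomes** (`make_genome`): i.i.d. background with configurable GC,
  evenly spaced non-overlapping genes, and TTTV motifs planted every 70 bp
  inside each CDS on alternating strands, guaranteeing a predictable minimum
  number of Cas12a candidates per gene.
- **Occupancy** (`make_occupancy_track`): Gaussian-smoothed white noise
  (150 bp kernel) through a logistic squashing, scaled to [0, 10] —
  smooth, non-negative, nucleosome-scale structure without claiming
  biological realism.
- **Activity** (`ActivityFunction`): ground-truth
  `CS = intercept + Σ w[base, pos] + β·occupancy + N(0, σ)` with
  mean-centered per-position weights, β ≤ 0 (occupancy impedes cutting),
  default intercept 1.5.
- **Screens** (`make_screen`): control abundances from a symmetric
  Dirichlet(α = 10) (a roughly uniform library), treatment abundances
  proportional to `control · 2^(−CS)` renormalized, counts multinomial at
  the requested depth. The renormalization constant log2(Z) is folded back
  into the reported truth so the expected log2 abundance ratio equals the
  stored true CS exactly — which makes recovery-error tolerances derivable
  from depth alone. Non-targeting guides receive a fixed control-population
  offset of −1.5 (a fixture parameter, not a biological claim). |CS| > 20
  is clipped with a warning to avoid underflow.

The generator does not model cutting kinetics, growth dynamics, sequencing
error, or biophysically realistic chromatin.

## Numerical and format choices

- The network engine (`guidekit._nn`) is pure numpy: im2col convolutions via
  `sliding_window_view` and einsum, exact analytic backpropagation (verified
  against central finite differences to ~1e-5 relative error in the tests),
  batch norm with running statistics (momentum 0.9), per-layer Adam states.
  Identical seeds give bitwise-identical training runs.
- Model persistence uses a numpy `.npz` of named weight arrays plus a JSON
  sidecar with the estimator configuration — dependency-light and lossless;
  no hierarchical binary container is required at these model sizes.
- Pipeline reproducibility: a single global seed is fanned out per stage via
  SHA-256 (`stage_seed`), keeping every derived seed below 2^31; output
  directories carry a manifest with the config hash and SHA-256 checksums of
  every artifact.
- Standard statistics delegate to established libraries — scipy
  (correlations), scikit-learn (ROC/AUROC, K-fold), Biopython (FASTA/FASTQ),
  gffutils (GFF3), pandas (tables) — with independent brute-force oracles
  for the critical ones in the test suite.

## Limitations

- The context-length sweep refuses lengths shorter than spacer+PAM; it never
  truncates into the protospacer.
- `context_sweep` and the predictor operate on fixed-length windows; guides
  too close to a chromosome edge for the requested window are rejected
  rather than padded.
- The screen model assumes exact-match counting and independent multinomial
  sampling per sample; PCR amplification bias and chimeric reads are out of
  scope.
- Genome-scale count validation against the *Y. lipolytica* reference
  assembly requires a local copy of GCA_001761485.1 (not bundled); without
  it, that check reports as failing.
- Training-set sizes below 100 examples are rejected; the numpy engine is
  single-threaded and sized for datasets in the 10^4–10^5 range, not for
  GPU-scale training.
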