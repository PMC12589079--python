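# Methods

This note documents the models and procedures implemented in `vqstroke`, the
choices made where the design was genuinely open, and what the synthetic data
does and does not establish.

## Pipeline overview

Image → (optional resize / equalization) → 4 classical features →
z-scoring → 4-qubit angle encoding → 3 variational layers → Pauli-Z readout →
stroke probability and majority-vote label. Training optimizes the 12 layer
angles against binary cross-entropy with Adam.

## Synthetic phantom generator

The generator emulates the *structure* of a CT/MRI stroke dataset, not its
appearance: an elliptical bright "brain" (default intensity 120) on a dark
background (20), per-pixel Gaussian noise, and — for the stroke class — one
disc-shaped lesion of radius 10 px whose intensity offset is signed:
+80 mimics a hyper-intense (hemorrhagic-like) lesion, −60 a hypo-intense
(ischemic-like) one. Default image size is 128×128 with brain semi-axes
(48, 40) px; the default split layout is 1,500/500 normal and 1,400/400
stroke train/test images (3,800 total), mirroring the emulated dataset's
distribution table.

Lesion placement is uniform over the *morphological erosion* of the ellipse
mask by the same disc footprint used to draw the lesion. This makes the
"lesion entirely inside the brain" contract exact on the pixel grid. (A
scaled ellipse with semi-axes reduced by the radius is *not* contained in the
true erosion near the high-curvature ends of an eccentric ellipse, so the
naive shortcut would violate the contract.)

Reproducibility: one global seed spawns an independent, index-keyed substream
per image (`SeedSequence(seed, spawn_key=(index,))`), so datasets are bitwise
reproducible and independent of generation order. For a given substream, a
normal and a stroke image differ only inside the lesion disc, because the
placement draw is consumed for both labels.

What passing tests on phantoms show: that every stage — feature extraction,
encoding, optimization, evaluation — is implemented correctly and that the
classifier can learn a genuinely separable signal. What they do not show:
performance on real CT/MRI data. The phantoms have none of the anatomy,
partial-volume effects, modality mixtures, scanner artifacts or label noise
of a clinical dataset, and the headline accuracies on phantoms carry no
clinical meaning.

## Preprocessing

- **Bilinear resize.** The destination→source coordinate map is
  `src = dst * (src_size / dst_size)` with clamped fractional coordinates
  (`mapping="scale"`, the identity when sizes match); an `align_corners`
  variant (`src = dst * (src_size−1)/(dst_size−1)`) is exposed because the
  endpoint convention is a genuine free choice in the resize mapping.
- **Grayscale.** ITU-R 601 luma weights 0.2989/0.5870/0.1140. The result is
  kept real-valued; quantization to uint8 (`quantize_uint8`, round half up)
  is explicit, never implicit.
- **Normalization** divides by 255 and refuses floating-point input, so the
  scaling can never be applied twice silently.
- **Histogram equalization** maps intensity v to `floor(CDF(v)·(L−1))`. The
  floor is a documented choice — the CDF product alone does not fix a
  rounding rule. The map is monotone, so pixel ranking is preserved; a
  constant image maps to the top level.
- **Augmentation** applies rotate → horizontal flip → vertical flip →
  additive Gaussian noise, in that order. Rotations are restricted to
  multiples of 90° by default so augmentation is exactly
  intensity-preserving; noise is clipped to the image domain.
- **Class balancing** acts on the train split only. `oversample` duplicates
  minority rows with replacement; `undersample` drops majority rows without
  replacement; `over_then_under` runs both in sequence as a literal pipeline
  — after oversampling the classes are already equal, so the undersampling
  stage is a no-op and a warning is logged rather than silently reinterpreting
  the recipe.

## Features

Four features are extracted because the register is four qubits wide:

1. **Edge density** from a from-scratch Canny implementation: Gaussian
   smoothing (σ = 1), Sobel gradients, non-maximum suppression with gradient
   direction quantized to 4 bins, and double-threshold hysteresis with
   thresholds expressed as fractions (0.1 / 0.3) of the maximum smoothed
   gradient magnitude, weak pixels kept only when 8-connected to a strong
   seed. Fraction-of-max thresholds make edge density invariant to affine
   intensity rescaling.
2–4. **GLCM contrast, energy, correlation** (standard Haralick definitions;
   correlation is defined as 0 when a marginal standard deviation vanishes).
   The GLCM uses 16 levels via min–max linear quantization, offset (0, 1),
   symmetric and normalized. Min–max quantization makes all three statistics
   invariant to adding a constant to every pixel.

The GLCM is validated against a brute-force double-loop enumeration (exact
equality on random images over the four canonical offsets) and against
`skimage.feature.graycomatrix` on the (0, 1) offset.

In the default circuit only edge density and contrast can influence the
output (see below); energy and correlation are computed, stored and available
to alternative circuits or classical baselines.

## Quantum simulator and circuit

The statevector simulator stores all 2ⁿ complex amplitudes (qubit 0 = most
significant bit of the basis index; n ≤ 20). Gates are applied by reshaping
the amplitude vector to an n-dimensional tensor and contracting the affected
axis — no 2ⁿ×2ⁿ matrices are ever built outside the test oracle. The test
suite checks the full circuit against an independently constructed dense
16×16 Kronecker-product unitary to 1e-10, and gate algebra (H² = I,
CNOT² = I, RZ additivity, Z eigenvalues) to 1e-12.

**RZ convention.** RZ(θ) here is the phase gate diag(1, e^{iθ}). It differs
from the textbook e^{−iθZ/2} by a global phase only, so every expectation
value, probability and gradient is identical under either convention.

**Encoding.** H on every qubit, then RZ(π·x̃_q/3) with x̃ the standardized
feature clipped to ±3 standard deviations. The Hadamard must precede the
rotation: a phase on a basis state is an unobservable global phase, while on
(|0⟩+|1⟩)/√2 it rotates the state along the Bloch equator, making the
encoding injective on the clipped range. The π/3 scale maps the ±3σ range
onto a full ±π phase without wrapping.

**Layers.** Each of the 3 layers applies H(0), CNOT(0→1), then one RZ per
qubit — 12 trainable angles in total. A consequence worth stating plainly:
qubits 2 and 3 receive only diagonal gates after their encoding Hadamard, so
their Z expectations are identically zero, the 6 angles on those qubits have
exactly zero gradient, and the classifier's decision is carried by qubits
0–1 (hence by features 0–1) through 6 live parameters. The implementation
keeps the full 12-angle circuit as designed rather than silently rewiring it;
the pinned-qubit property is itself under test.

**Readout.** p_stroke = (1 − mean⟨Z⟩)/2, so all-zeros (⟨Z⟩ = +1 everywhere)
reads as confidently normal. The hard label is a majority vote over per-qubit
sign bits (≥3 of 4 ⇒ stroke); a 2–2 tie falls back to p ≥ 0.5. With the
pinned qubits the vote always lands in the tie branch, so in practice the
decision is the p ≥ 0.5 threshold.

**Measurement model.** Expectations are computed exactly from amplitudes; a
Born-rule sampler (`sample_bitstrings`) provides seeded shot-based
measurement for studying sampling noise, but the training path is
deterministic by default — that is what makes fixed-seed runs bitwise
reproducible.

## Training

- **Loss.** Binary cross-entropy on p_stroke (MSE selectable). p is clipped
  to [1e−12, 1−1e−12] inside the loss.
- **Gradients.** Each angle parametrises exactly one phase gate, so every
  ⟨Z_q⟩ — and therefore p, which is linear in them — is single-frequency in
  each angle and the parameter-shift rule
  ∂p/∂θ_k = [p(θ_k+π/2) − p(θ_k−π/2)]/2 is *exact*. The loss is nonlinear in
  p, so the rule is applied to p and chained with the analytic ∂L/∂p; applying
  the shift directly to the cross-entropy would not be a derivative. The
  shift-rule path is verified against central finite differences to 1e−6.
- **Optimizer.** Adam with lr = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
  bias-corrected, verified against a hand-rolled two-step oracle.
- **Batching.** Default minibatch size 32 for 50 epochs. This is a deliberate
  choice: each Adam step moves a parameter by at most ≈ lr, so 50 full-batch
  steps at lr = 0.001 bound the total angle movement by ~0.05 rad — no
  trajectory from a small-angle start can reach a useful decision boundary.
  Minibatching gives the same 50-epoch budget ~650 steps on a 400-sample
  set, which trains to high accuracy. Full batch remains available
  (`batch_size=None`).
- **Initialization.** θ ~ U(−0.1, 0.1) from the run seed; small angles avoid
  the flat region where large random phases cancel.
- **Reproducibility.** All randomness (init, shuffling) flows from
  `TrainConfig.seed`; fixed seed ⇒ bitwise-identical histories and angles.
  Per-epoch loss and accuracy are recorded from a full forward pass *after*
  the epoch's updates, so the final history entry equals a fresh evaluation
  of the fitted model on the training set.

## Evaluation

Implemented from first principles and cross-checked against independent
oracles in the tests:

- **ROC / AUC**: threshold sweep over unique scores (ties grouped), endpoints
  (0,0)/(1,1), trapezoidal area — exactly the Mann–Whitney pair-counting
  statistic with half-credit for ties (verified to 1e−12 on random
  instances).
- **PR / AUC-PR**: step-wise right-continuous area (the average-precision
  estimator), matching `sklearn.metrics.average_precision_score`; trapezoids
  in PR space are biased upward and are not used. An uninformative scorer's
  AUC-PR equals the positive prevalence.
- **Calibration**: 10 equal-width bins on [0,1], empty bins omitted, each
  point (mean predicted probability, empirical positive fraction).
- **Scalar metrics** use 0-by-convention (with a warning) when a denominator
  vanishes.
- **Learning curve**: stratified per-class subsampling with a
  fraction-independent base permutation, so subsets are nested and curves are
  comparable across fractions; fraction 1.0 reproduces a plain run exactly.

## Problem sizes

Defaults and test sizes were chosen as the smallest configurations that
exercise every code path with a clearly learnable signal: unit/property tests
use an 80-train/20-test phantom set at 64×64; the training-behavior checks
and the acceptance script use 200 train + 50 test images per class at
128×128 with lesion contrast +80 and noise σ = 5, trained for the full 50
epochs; the dataset-layout check generates all 3,800 images at 32×32.

## Known limitations

- The phantoms are structural stand-ins; no claim of modality or anatomical
  fidelity is made (see above).
- The default circuit uses only 2 of the 4 features and 6 of the 12 angles
  (the pinned-qubit property); richer entangling layouts would engage the
  full register but are outside this package's fixed architecture.
- p_stroke is confined to [0.25, 0.75] under the pinned qubits (two of four
  expectations are always 0), so predicted probabilities are conservative and
  calibration curves cover only the central bins.
- Training cost scales linearly in samples × parameters × epochs; the
  statevector backend caps registers at 20 qubits.
- `over_then_under` balancing is implemented literally and is a no-op after
  oversampling; use a single mode unless the literal pipeline is wanted.
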