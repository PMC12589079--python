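# vqstroke

A hybrid classical–quantum binary classifier for stroke vs. normal brain
images, built as a tested, reusable Python library with a thin command-line
pipeline. Classical preprocessing and feature extraction (Canny edge density
plus GLCM texture statistics) feed a simulated 4-qubit variational quantum
circuit whose 12 phase angles are trained with Adam on exact parameter-shift
gradients. A synthetic brain-phantom generator supplies reproducible labeled
datasets, so every stage of the pipeline runs and is testable with no external
data download.

The package is aimed at people studying variational quantum classifiers on
image-derived features: it provides a from-scratch statevector simulator with
verified gate algebra, a deterministic training loop, and an evaluation suite
(ROC/PR/calibration/learning curves) implemented from first principles.

## The model

Each image is reduced to a 4-dimensional feature vector

- edge density: fraction of Canny edge pixels,
- GLCM contrast Σᵢⱼ (i−j)² p(i,j),
- GLCM energy Σᵢⱼ p(i,j)²,
- GLCM correlation Σᵢⱼ (i−μᵢ)(j−μⱼ) p(i,j)/(σᵢσⱼ),

computed from a symmetric, normalized gray-level co-occurrence matrix
(16 levels, offset (0,1) by default). Features are z-scored with train-split
statistics, clipped to ±3, and angle-encoded into a 4-qubit register:

    |ψ(x)⟩ = ∏_q RZ_q(π x̃_q / 3) · H_q |0000⟩

followed by three variational layers, each

    H(q₀) → CNOT(q₀→q₁) → RZ_q(θ_{ℓ,q})  for q = 0..3,

for 12 trainable angles θ. RZ is the phase gate diag(1, e^{iθ}). The readout
is the Pauli-Z expectation of every qubit; the stroke probability is
p = (1 − mean⟨Z⟩)/2 and the hard label is a majority vote over per-qubit signs
(ties broken by p ≥ 0.5). Training minimises binary cross-entropy with Adam
(lr = 0.001, 50 epochs, minibatch 32); gradients are exact because ∂p/∂θ_k is
obtained with the parameter-shift rule [p(θ_k+π/2) − p(θ_k−π/2)]/2 and chained
with the analytic ∂L/∂p.

## Worked example

```python
from vqstroke import SyntheticConfig, generate_dataset, StrokeVQC, TrainConfig
from vqstroke.features import extract_features_table
from vqstroke.model import predict
from vqstroke.evaluate import evaluate_predictions

cfg = SyntheticConfig(
    n_normal_train=200, n_normal_test=50, n_stroke_train=200, n_stroke_test=50,
    lesion_delta=80.0, noise_sigma=5.0, seed=0,
)
manifest = generate_dataset(cfg, "demo")
features = extract_features_table(manifest, "demo")
results = StrokeVQC.from_features_table(features).fit(TrainConfig(seed=0))
print(results.summary())

test = features[features["split"] == "test"]
preds = predict(test, results)
report = evaluate_predictions(test["label"].to_numpy(),
                              preds["p_stroke"].to_numpy(),
                              preds["label"].to_numpy())
print(f"test accuracy={report.accuracy:.3f}  AUC-ROC={report.auc_roc:.3f}  "
      f"AUC-PR={report.auc_pr:.3f}")
```

which prints:

```
Variational Quantum Circuit Classifier Results
======================================================
No. observations:           400
Trainable angles:           12 (3 layers x 4 qubits)
Loss:                       bce
Optimizer:                  Adam (lr=0.001)
Epochs:                     50
Seed:                       0
Final train loss:           0.561420
Final train accuracy:       0.9800
------------------------------------------------------
theta (radians), layer-major:
  layer 0:   1.2089  -0.7629  -0.0918  -0.0967
  layer 1:  -0.6542   0.0826   0.0213   0.0459
  layer 2:   0.0087   0.0870   0.0632  -0.0995
======================================================
test accuracy=0.990  AUC-ROC=1.000  AUC-PR=1.000
```

The phantom dataset here has 200 training and 50 test images per class with a
strong (+80 intensity) lesion and mild noise: the circuit learns to separate
the classes almost perfectly (AUC 1.0 on the 100-image test split), with the
hard-label accuracy slightly lower because the vote threshold is fixed at
p = 0.5. Angles on qubits 2 and 3 barely move from their small random
initialization — those qubits see only diagonal gates after encoding, so
their expectations (and gradients) are pinned; see `docs/methods.md`.

## Command line

```bash
vqstroke generate --out data --seed 7          # phantom dataset + manifest.csv
vqstroke train    --data data --out model.json # features + 50-epoch fit
vqstroke evaluate --data data --model model.json --out metrics.json
vqstroke predict  --model model.json --out preds.csv img1.png img2.png
vqstroke run-all  --out run --seed 7           # all of the above in one go
```

All parameters live in a YAML config (`--config`); unknown keys are rejected.
Exit codes: 0 success, 1 runtime data failure, 2 usage/configuration error.

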