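# nodulekit

Computer-aided detection of pulmonary nodules on 2-D CT slices, built as a
set of small, testable stages:

1. **Lung-field segmentation** — a fixed morphological recipe (Otsu
   binarisation keeping the dark class, border clearing, two largest
   connected components, erosion radius 2, closing radius 10, hole
   filling) isolates the two lung fields; the ROI is the slice masked by
   the result.
2. **Nodule segmentation** — fuzzy C-means (FCM) clustering of per-pixel
   features inside the lung mask. FCM minimises
   `D(W, C) = Σᵢ Σₖ wᵢₖˣ ‖hₖ − dᵢ‖²` with row-stochastic memberships
   `wᵢₖ` and fuzzifier `x > 1`, alternating the classical membership and
   center updates. The brightest cluster becomes the nodule candidate
   mask, guarded by a separation gate so a nodule-free lung yields an
   empty mask.
3. **Feature extraction** — per candidate region: five population moments
   `[M, K, S, σ, ν]` (mean, non-excess kurtosis, skewness, standard
   deviation, variance), local ternary pattern (LTP) upper/lower
   histograms with dead-zone threshold τ, local optimal oriented pattern
   (LOOP) histograms whose bit weights follow the rank of Kirsch compass
   responses, and a pluggable backbone descriptor (default: multi-scale
   filter-bank statistics).
4. **Classification** — a single bidirectional LSTM layer reads the
   concatenated descriptor `E = [f_R, st_R, T_R]` as a short sequence and
   emits a malignancy probability. There is no gradient training: all
   weights and biases are optimised directly by **Cnidaria Herd
   Optimization (CHO)**, a bounded metaheuristic that alternates
   jellyfish-style passive foraging (exploration) with krill-style
   induced movement (exploitation) under a decaying stochastic
   time-control schedule ζ(t), with diffusion-based bounds repair.
5. **Phantom generator** — synthetic CT-like slices (bright body, two dark
   elliptical lung fields, vessel-like clutter, bright quasi-circular
   nodules with known masks and benign/malignant labels) make every stage
   testable without clinical data.

The fit/predict-shaped pieces are scikit-learn estimators
(`FuzzyCMeans`, `BiLSTMClassifier`) and compose with sklearn pipelines
and model selection; everything else is plain functions over numpy
arrays.

## Worked example

```python
from nodulekit import (PhantomConfig, generate_phantom, segment_lobes,
                       extract_roi, segment_nodules)
from nodulekit.pipeline import region_features
from nodulekit.experiments import classification_experiment

sample = generate_phantom(PhantomConfig(), seed=3)
lung = segment_lobes(sample.image)
roi = extract_roi(sample.image, lung)
nodules = segment_nodules(roi, lung)

gt = sample.nodule_masks[0].astype(bool)
dice = 2 * (nodules.astype(bool) & gt).sum() / (nodules.sum() + gt.sum())
print(f"lung area: {lung.sum()} px, nodule candidate: {nodules.sum()} px, "
      f"Dice vs truth: {dice:.3f}")

E = region_features(sample.image, nodules)
print(f"descriptor length: {E.size} (9 backbone + 5 moments + 3x32 texture bins)")

exp = classification_experiment(n_phantoms=100, seed=7)
print(f"held-out accuracy: {exp['test_accuracy']:.2f} "
      f"(majority baseline {exp['majority_baseline']:.2f}) "
      f"over {exp['n_test']} nodules")
```

prints

```
lung area: 17242 px, nodule candidate: 348 px, Dice vs truth: 0.965
descriptor length: 110 (9 backbone + 5 moments + 3x32 texture bins)
held-out accuracy: 0.70 (majority baseline 0.50) over 20 nodules
```

The first line says the morphological chain found a lung field of ~17k
pixels and FCM recovered the one true nodule almost exactly (Dice 0.965).
The last line is the desk-scale end-to-end experiment: 100 phantoms, a
stratified 80/20 split, the BiLSTM's ~1500 parameters tuned by CHO
(population 20, 50 iterations), evaluated on the held-out nodules —
comfortably above the 50% majority baseline.

A command-line interface mirrors the stages:

```bash
nodulekit phantom --n 100 --seed 7 --out data/
nodulekit preprocess --in data/phantom_0000.png --out-mask lung.png
nodulekit segment --in data/phantom_0000.png --mask lung.png --out nodules.png
nodulekit features --in data/phantom_0000.png --mask nodules.png --out feats.csv
nodulekit train --data data/ --cho-pop 20 --cho-iters 50 --seed 7 --out model.json
nodulekit predict --model model.json --in feats.csv
nodulekit run --data data/ --model model.json --out report.json
```

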