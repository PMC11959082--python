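# Methods

This note documents the models implemented in nodulekit, the defaults
that matter, the synthetic data the tests run on, and the design choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cnidaria Herd Optimization

CHO is a bounded, elitist, maximising metaheuristic over a population of
`pop_size` real vectors. Each iteration draws a time-control value

    ζ(t) = |(1 − t/t_max) · (2·r₂ − 1)|,   r₂ ~ U(0,1),

and each member then explores (probability ζ) or exploits (probability
1 − ζ), so the swarm drifts from exploration-heavy early iterations to
pure exploitation at `t_max`, where ζ = 0 exactly.

**Exploration (passive foraging).** With elitist best `B_G`, swarm mean
μ, differential fitness `αᵢ = F(Bᵢ) − F(B_G) ≤ 0`:

    B′ = VF·αᵢ + ϖ(t)·B + (B + r₃·(B_G − a·μ)) / 2,

`r₃ ~ U(0.1, 1)` and trial factor `a = 3·U(0,1)` redrawn per move.

**Exploitation (induced movement).** A cooperative random walk plus
neighbour effects:

    B′ = B + γ·r₄·(U_up − U_low)·(1 − t/t_max) + (B_G ⊙ φ_B + ϖ(t)·B_prev)/2,

where `φ_B = φ_local + φ_target`; `φ_local = Σⱼ F̂ⱼ·B̂ⱼ` sums each
member's fitness change (normalised by the swarm's worst-to-best range)
times its normalised displacement, and `φ_target` applies the same
construction with `B_G` standing in for the neighbour (switchable to
zero via `CHOConfig.target_effect`). A fitness-flat swarm defines
`F̂ := 0`, so no division by zero can occur.

**Bounds repair.** An out-of-bounds coordinate re-enters from the
opposite face displaced by its overshoot plus diffusion
`D_max·U(−1, 1)`, then a final clamp guarantees containment (a single
wrap can still overshoot for far-out points).

**Defaults and why.** `VF = 0.02`, `γ = 0.005`, `D_max = 0.005`,
`ε = 1e−10`, inertia ϖ decaying **geometrically** 0.9 → 0.01 over the
run, and the exploitation random walk damped by `(1 − t/t_max)`. The
damping mirrors how the krill-herd family anneals its physical-diffusion
term, and the geometric inertia decay keeps the exploration multiplier
(ϖ + ½) contractive for most of the run. These two choices are what give
the optimizer its late-stage precision: with a linear 0.9 → 0.1 schedule
and an undamped walk of amplitude γ = 0.1, the persistent O(γ·span)
noise floors the achievable error far above the documented sphere
benchmark (the acceptance suite verifies a median final best of
≥ −1e−2 on the 5-D sphere over 20 seeds against equal-budget random
search). All of these are exposed in `CHOConfig`.

Elitism: the global best is never overwritten, so the best-fitness
history is monotone non-decreasing. Candidates with non-finite fitness
are rejected (member keeps its previous position, warning logged). A run
is bit-reproducible from its seed.

Known limitation: like its jellyfish-search parent, the exploration
operator's `B_G − a·μ` trend (mean a = 1.5) carries a bias toward the
coordinate origin; objectives whose optimum is far off-centre converge
more slowly.

## Lung-field segmentation

The six-step chain assumes CT-like contrast (lung fields darker than the
surrounding body): Otsu threshold keeping the below-threshold class;
removal of blobs touching the border; 8-connected labelling; retention
of the `keep_k = 2` largest components (all of them, with a warning, on
single-lung slices); erosion with a disk of radius 2 (detaches
vessel-linked structures); closing with a disk of radius 10 followed by
hole filling (re-attaches wall-adherent nodules). Masking is the
element-wise product, so out-of-mask pixels are exactly zero. The chain
contains no randomness.

## FCM nodule segmentation

`fcm_cluster` implements the classical alternating scheme: membership
update `wᵢₖ = 1/Σⱼ (dᵢₖ/dⱼₖ)^{2/(x−1)}` (a point on a center takes the
limit value; coincidence with several centers splits uniformly), center
update as the `wˣ`-weighted mean, convergence when the maximum center
displacement falls below `tolerance` (default 1e−5) or after `max_iter`
(default 300). Each half-step decreases the objective, so the recorded
history is non-increasing. Default initialisation: `c` distinct random
data points, seeded; an explicit `init_centers` can be supplied.

`segment_nodules` builds per-pixel features for the in-lung pixels —
the Gaussian-smoothed intensity (`smoothing_sigma = 1.5` px) plus
optional backbone channels — standardises them, and clusters with
centers initialised evenly spread between the per-channel minima and
maxima, making the whole stage deterministic. Two choices here deserve
justification:

* **Near-hard fuzzifier (default 1.5).** A nodule occupies well under a
  percent of the lung pixels. With soft memberships (x = 2) the large
  parenchyma population drags the bright center off the nodule mode:
  the split-the-parenchyma partition has the lower objective whenever
  the bright mass fraction is below roughly 1.3·σ²/contrast². Near-hard
  memberships make the bright-center basin locally stable, and the
  smoothing shrinks σ so the basin is reached from the spread
  initialisation.
* **Separation gate.** The brightest cluster is accepted only when its
  mean raw intensity exceeds that of the remaining pixels by more than
  `separation_threshold = 4` pooled within-cluster standard deviations.
  On nodule-free lungs 2-cluster FCM necessarily splits the noise; the
  gate turns that split into an empty mask. On the phantom suite the
  measured ratio is 5–12 for true nodules and ~0.1 for noise-only
  lungs, so the gate has a wide margin in both directions.

A final opening (disk radius 1) removes single-pixel vessel-like
clutter. Cluster count defaults to 2 (nodule vs parenchyma) and is
configurable.

## Descriptors

The 8-neighbour convention is pinned: n = 0 at the east neighbour,
counterclockwise. LTP digits use a dead zone of half-width τ (default
5/255): +1 for a neighbour-center difference ≥ τ, −1 for ≤ −τ (the
boundary −τ maps to −1 so the three cases partition the line), else 0.
The primary representation is the conventional upper/lower binary split;
the literal signed base-3 sum is also returned. LOOP sets the bit of
neighbour N when its value is ≥ the center, weighted `2^{u_N}` where
`u_N` ranks the magnitudes of the eight Kirsch compass responses
(0 = smallest, ties broken by neighbour index). Kirsch kernels have zero
sum, so LOOP is invariant to adding a constant to the window — exactly
in real arithmetic, and for all non-degenerate windows in floating
point (exact rank ties can resolve differently after an offset).

Texture histograms are computed at every in-mask pixel whose 3×3
neighbourhood lies inside the image, rebinned from 0..255 to
`histogram_bins` (default 32) and normalised to sum 1 (all-zero for an
empty region).

Statistical features are population (biased) moments in the fixed order
[mean, kurtosis, skewness, std, variance], kurtosis non-excess; a
zero-variance region reports skewness = kurtosis = 0.

The backbone is pluggable; the default `FilterBankDescriptor` is a
deterministic, handcrafted summary: (mean, std) of Gaussian smooths and
gradient magnitudes at scales 1 and 2, plus a log-area term — 9 numbers
computed on the candidate's padded bounding-box crop. The log-area term
deliberately carries region size, which is a first-order malignancy cue
both in the phantom model and clinically.

The classifier input is the plain concatenation
`E = backbone ‖ stats ‖ texture` (length 9 + 5 + 96 = 110 under the
defaults); slicing recovers the parts exactly.

## BiLSTM classifier

`E` is chunked row-wise into `timesteps = 8` steps (zero-padded tail).
Each direction runs the standard gated recurrence (forget/input/output
gates sigmoid, candidate tanh, `c_t = Q⊙c_{t−1} + I⊙X̃`,
`h_t = P⊙tanh c_t`); the representation is `[h_fwd(T), h_bwd(1)]`, the
score a single linear readout, the probability its sigmoid, and the
decision threshold 0.5 with ties going to the malignant class. Hidden
size defaults to 8 per direction (~1.5k parameters at step width 14).

Training is pure CHO: parameters are flattened in a fixed documented
layout, searched in `[−w_max, w_max]^P` (w_max = 2), with fitness the
classification accuracy on a stratified inner validation split
(`val_fraction = 0.2`) of the training data. There is no
backpropagation anywhere; this keeps the training loop identical to the
optimizer the rest of the package uses and is honest about the model's
desk scale. One BiLSTM layer only; stacking is not implemented.

## Phantom generator

Each phantom emulates a single axial chest-CT slice at the level the
pipeline consumes: 256×256, background mean 0.85, two dark elliptical
lung fields (mean 0.25) clear of the border, 2–4 thin vessel-like
Bézier curves (mean 0.40) clipped to the lungs, and bright nodules
(mean 0.65) placed with clearance from the lung boundary; additive
Gaussian noise (σ = 0.03) is applied after ground truth is recorded.
The intensity ordering background > nodule > lung field is asserted in
the config because Otsu binarisation and brightest-cluster selection
rely on it.

Malignancy is encoded by size plus margin irregularity: benign nodules
are smooth discs with radius U(3, 6) px; malignant nodules have radius
U(8, 12) px and a sinusoidal boundary perturbation of amplitude 2 px
with 4–9 lobes. Real labels come from radiologist annotations and
correlate with many factors this model does not emulate (attenuation
statistics, spiculation, location); size-plus-irregularity is the
standard first-order proxy and makes the labels learnable from the
implemented descriptor set. `generate_samples` assigns labels from an
exactly balanced shuffled pool, so any dataset of ≥ 50 nodules holds
the configured class ratio to within rounding.

What passing tests on phantoms do **not** show: robustness to real CT
artefacts (beam hardening, motion, reconstruction kernels), to juxta-
pleural or ground-glass nodules, to Hounsfield calibration, or to 3-D
context — the pipeline is strictly 2-D and processes volumes
slice-by-slice.

## Experiment scales

The built-in experiments are sized for a single CPU: the sphere
benchmark uses 20 seeds × (30 × 200) evaluations; the classification
experiment uses 100 phantoms (one nodule each), an 80/20 stratified
split, and CHO with population 20 for 50 iterations. The experiment
builds its feature table from the ground-truth nodule annotations (as a
radiologist-annotated training set would); segmentation quality is
measured separately by Dice against ground truth and by nodule-free
negative controls, which keeps the two error sources identifiable.

## Evaluation

Malignant is the positive class. Accuracy, sensitivity and specificity
follow their confusion-matrix definitions; a ratio whose denominator is
zero is reported as absent (`None`), never as 0. Detection-to-truth
matching, where needed, is greedy on mask IoU with threshold 0.3.
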