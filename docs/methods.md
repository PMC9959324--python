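# Methods

## Problem setting

`hsipatho` classifies hepatocellular-carcinoma (HCC) tissue from H&E-stained
liver sections imaged with a visible/near-infrared (VNIR) push-broom
hyperspectral microscope. Each sample is a cube `(row, column, band)` of
transmittance values with per-band wavelengths in nanometres. Healthy and
tumor tissue differ in the fine shape of their transmittance spectra — H&E
staining produces characteristic absorption dips near 540 nm (eosin) and
650 nm — and the classifier's job is to exploit that spectral structure
together with spatial texture.

The pipeline is: radiometric calibration → band windowing (400–800 nm) →
optional spectral reduction → patch tiling with blank-glass rejection →
CNN training with a class-balanced focal loss → imbalance-aware evaluation.

## Radiometric calibration

Raw counts are converted to transmittance with the standard flat-field form

    T = clip((raw − dark) / (white − dark), 0, 1)

where the white reference is captured from blank illuminated glass and the
dark reference with the sensor capped. The white may be a full frame or a
push-broom per-column line average; both are accepted by broadcasting.
Pixels where `white − dark` falls below 1e-8 of the white dynamic range
raise an error rather than silently producing infinities. Band-window
endpoints are inclusive: the header's wavelength list is authoritative, and
cropping to [400, 800] nm keeps exactly the bands whose centres fall inside.

## Patch extraction and blank rejection

Sample images are tiled into non-overlapping S×S patches anchored at (0,0);
trailing remainders are discarded. A patch is discarded when *more than* 50%
of its pixels are blank glass (strict inequality; a patch at exactly 50% is
kept). Blank detection is unsupervised and image-local: Otsu's two-class
threshold on the band-averaged calibrated image separates bright transmitting
glass from absorbing stained tissue. Because it is unsupervised, computing
it per source image leaks no label information across splits.

## Spectral representations

Four representations are compared on identical patch geometry:

* **full** — all bands in the window (270 at acquisition scale, 30 at desk
  scale);
* **sampled** (`HSI-k`) — constant-stride subsampling: stride `floor(B/k)`,
  phase 0, so indices `0, s, 2s, …`;
* **PCA** (`PCA-n`) — incremental principal components over *training-split*
  pixel spectra only (each pixel one observation, chunked in batches of
  4096); components retained by exact count, or while the explained-variance
  ratio is ≥ a threshold (0.1% reproduces the 9-component choice on suitable
  data);
* **RGB** — Gaussian band synthesis: channel c integrates the spectrum under
  a normal weight centred at 630/540/480 nm (R/G/B) with SD 25 nm, weights
  normalized to unit sum so a flat spectrum maps to itself.

## Classifier

A compact four-block CNN: each block is a 'same'-padded convolution (ReLU)
with filter counts 4→8→16→32, followed by 3³ max-pooling with stride 2 and
batch normalization; then global average pooling, a 512-unit ReLU dense
layer, 10% dropout, and a single sigmoid output giving the probability of
the positive (tumor) class. In the 3D variant the cube is a single-channel
volume and 3×3×3 kernels slide along both spatial axes and the spectral
axis; in the 2D variant the bands become input channels and 3×3 kernels
slide over space only. 'Same' pooling maps an extent d to ceil(d/2), so a
100×100×270 input pools through spectral depths 135 → 68 → 34 → 17 before
global average pooling to a 32-vector. For inputs with ≤ 3 bands
(synthesized RGB), the spectral kernel/pool depth is capped at the band axis
and the spectral pooling stride drops to 1, leaving the rest of the topology
unchanged.

The engine is implemented in numpy with numba-compiled inner loops
(channels-first layout so the spectral axis is unit-stride); a pure-numpy
fallback computes identical results. The vectorised backend is verified in
the test suite against a literal sextuple-sum reference convolution and
against central finite differences through the whole network.

### Loss

Training minimizes the class-balanced focal loss

    FL(p_t) = −α_t (1 − p_t)^γ log(p_t),   p_t = p if y=1 else 1−p,
    α_t = α if y=1 else 1−α

with γ ≥ 0 focusing the loss on hard examples and α balancing the classes.
γ=0 recovers balanced cross-entropy; γ=0 with α_t≡1 is plain cross-entropy.
p_t is clamped from below at 1e-7 inside the logarithm; it is not clamped
from above, so a perfect prediction has exactly zero loss. The default
operating point is γ=2, α=0.5.

### Optimization profiles

Two profiles ship:

* **reference** — Adam(lr 1e-3, β₁ 0.9, β₂ 0.999), batch 128, 100 epochs,
  100 px patches, 270 bands: the configuration for full-scale data.
* **desk** — 16 px patches, 30 bands, batch 32, 20 epochs, Adam lr 5e-3
  with cosine decay to zero: sized so a full experiment trains in well under
  a minute on one CPU core. With only ~320 training patches the reference
  schedule provides too few optimizer steps, so the desk profile shortens
  the patch side (quadrupling the patch count at constant pixel budget) and
  raises the learning rate; the cosine decay prevents single late
  large-step collapses of an already-converged model, which a short
  constant-rate schedule is prone to. These are the only departures from
  the reference recipe.

Decision rule: a patch is called tumor iff p > 0.5 (strict); no calibration.

## Evaluation

All metrics derive from patch-level pooled confusion counts with tumor as
the positive class: accuracy, precision, recall, F1, and the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which remains informative under the ~9:1 tumor:healthy imbalance. Degenerate
denominators use the standard conventions (precision/recall/F1 = 0; MCC = 0
when a factor under the root vanishes). Test metrics are computed once, from
the final model, on held-out cases.

## Split protocol

Splitting is by *case* (patient): each case belongs to exactly one of
train/validation/test, the default design being 1 healthy + 9 unhealthy
cases per split with two sample images per case (6 healthy vs 54 unhealthy
samples over 30 cases). Any case overlap between splits raises a hard error.
The three cyclic rotations (train→val→test→train) provide an overfitting
check: a model that generalizes should score similarly under all three.
Fitted components never see held-out data: PCA bases come from training
pixels only, and blank thresholds are image-local and unsupervised.

## The synthetic phantom

Real microarray data of this kind is not redistributable, so every stage is
exercised on a generated H&E liver phantom. What it emulates:

* transmittance endmembers in (0, 1] for glass, background tissue
  (eosin-dominated, strong 540 nm dip) and cell nuclei
  (hematoxylin-dominated, deeper 650 nm absorption), with blank glass
  brighter than every tissue component at every band;
* nucleus disks 12–18 px in diameter at 0.55 µm/px on a background-tissue
  canvas, plus a blank-glass strip (10% of width by default);
* class contrast controlled by one knob δ (default 0.4): tumor dips shift by
  +20·δ nm and deepen by (1 + 0.5·δ), normal dips shift by −20·δ nm, so
  δ = 0 makes the classes identical (the negative control). By default the
  tumor−normal difference is additionally projected onto the orthogonal
  complement of the three RGB synthesis weights (*metameric mode*): tumor
  and normal endmembers then integrate to identical RGB triplets and the
  class contrast is visible only at spectral resolution;
* per-case biological variability shared by both sample images of a case:
  dip-depth scaling (lognormal, σ 0.12), dip-centre jitter (σ 1 nm) and a
  baseline tilt (σ 0.003) — small relative to the class contrast, because
  each split contains a single healthy case and a learner must generalize
  the healthy concept from it;
* per-image band-wise offsets (σ 0.01, sensor banding) and i.i.d. pixel
  noise (σ 0.02).

Dip widths are σ = 12 nm (540) and 14 nm (650); deliberately narrow so that
coarse band grids genuinely lose the dip-shape information that
distinguishes a shifted dip from a case with unusual staining depth.

What the phantom does **not** emulate: realistic nucleus morphology and
chromatin texture, stain-chemistry physics, optical blur/smile/keystone,
spatial correlation of noise, and multi-class pathology (cirrhosis,
cholangiocarcinoma). Passing end-to-end tests therefore demonstrates that
the pipeline's mechanics — calibration, leakage-free splitting, reduction,
training, evaluation — recover a known spectral signal under case-level
nuisance at desk scale; it does not certify clinical performance on real
tissue.

With these defaults the desk-profile 3D network on full bands reaches test
MCC well above 0.8; constant-stride band reduction degrades MCC
progressively and a single band carries essentially no signal; the
synthesized-RGB twin sits at chance by construction (metamerism); and the
δ = 0 control stays at chance. These statements are exactly what the
end-to-end test suite asserts (as medians over seeds).

## Numerical choices

* Convolution/pooling follow the TensorFlow 'same' convention (pad more at
  the trailing edge; pooled extent ceil(d/s)); max-pool ties resolve to the
  first element in C order.
* Batch normalization uses batch statistics in training, running averages
  (momentum 0.1) in evaluation, ε = 1e-5.
* He initialization for conv/dense weights; zero biases; seeded
  `numpy.random.Generator` everywhere — identical seed and configuration
  reproduce histories bit-for-bit on the same backend.
* Incremental PCA delegates to scikit-learn's `IncrementalPCA`; Otsu
  thresholds to scikit-image.
* An optional per-band standardization of patches (fitted on the training
  split) is available but off by default: on the phantom at desk scale it
  slowed convergence.

## Known limitations

* The desk-scale network is optimization-limited: with tens of images per
  split, test MCC has visible seed-to-seed variance, and comparisons between
  spectral variants are reported as medians over seeds.
* Patch-level pooled metrics are reported; per-case aggregation differs and
  real studies may prefer it.
* The 2D variant's flattened feature count differs from the 3D variant's
  (bands-as-channels changes the tensor shapes); only the topology — layer
  sequence, filter counts, pooling — is shared.
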