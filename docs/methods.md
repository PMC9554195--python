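# Methods

## The problem and the pipeline

Ovarian lesions are classified from grayscale ultrasound by texture and
morphology. Frames stored in clinical archives carry burned-in sonographer
marks (caliper crosses, dashed measurement lines, annotation text) that are
impossible to strip retroactively by metadata and that correlate with the
diagnosis, so a classifier trained on archived frames can learn the marks
instead of the tissue. The pipeline therefore has two learned stages: a
denoising convolutional autoencoder that maps a marked frame to its clean
counterpart, followed by a five-class convolutional classifier applied to
the decluttered image. An ablation arm trains the identical classifier on
the marked images to quantify what the mark removal buys.

## Phantom generator

Real images of this kind are private clinical data, so the package generates
seeded stand-ins that preserve the statistics the models depend on:

- **Field of view**: a circular sector of half-angle 35° with its apex above
  the top edge, mimicking a convex-probe fan; pixels outside are 0.
- **Speckle**: first-order multiplicative model — pixel = tissue template ×
  smoothed Rayleigh factor of unit mean. `speckle_scale` (default 0.35) sets
  texture contrast. No wave propagation or depth-dependent attenuation is
  simulated; the only acoustic artifact modeled is the distal shadow band
  below a teratoma.
- **Classes** (sonographic conventions): *normal* — no dominant lesion, a
  few small dark follicles, empty lesion mask; *cystadenoma* — large
  smooth-walled anechoic oval (interior ≈ 0.05 gray), optional thin septum;
  *teratoma* — heterogeneous hyperechoic interior with distal shadowing;
  *endometrioma* — cyst with homogeneous mid-gray (≈ 0.34) low-level
  interior echoes (speckle variance damped); *malignant* — irregular margin
  (harmonically modulated radius) around a dark cystic core with bright
  papillary nodules.
- **Marks**: caliper pairs ('+' or '×' strokes, 5–9 px) anchored on the
  lesion boundary, dashed lines between pair members, and 1–3 clusters of
  3×5-px pseudo-characters near the border, all drawn at ≥ 0.9 gray. The
  mark mask records exactly the overwritten pixels, so `marked == clean`
  outside it, bit for bit. Mark burden is class-dependent
  (`MARK_DENSITY_BY_CLASS`: normal 0.3× and unforced, malignant 2×),
  emulating the clinical reality that sonographers caliper lesions and
  rarely annotate normal ovaries — this correlation is what makes the
  ablation and the mark-reliance probe meaningful.
- **Seeding**: every record's seed is `master_seed + sha256(label, index)`,
  so datasets are pure functions of their parameters and adding a class
  never reshuffles another.
- **Class counts**: the desk profile uses the cohort totals ÷ 10
  ({21, 27, 36, 22, 54}, 160 images); the full profile uses
  {214, 272, 364, 224, 539} (1613).

A four-feature per-image summary (lesion-interior mean, interior variance,
area fraction, perimeter²/area) linearly separates ≥ 90% of a 500-phantom
sample — the classes carry learnable signal by construction. What passing
tests on phantoms do **not** show: robustness to probe/device variation,
acoustic artifacts beyond shadowing, operator framing, or any real-tissue
texture statistics. Results on phantoms bound nothing about clinical data.

## Denoising autoencoder

Encoder levels apply two 3×3 convolutions (ReLU), squeeze-and-excitation
gating (bottleneck width `max(C/reduction, 1)`, reduction 16, sigmoid gates
in (0, 1)), then 2× average pooling; channels double per level. The deepest
features pass a multi-dilation bottleneck: parallel same-padded 3×3
convolutions at dilations {1, 2, 4, 8}, concatenated and fused by a 1×1
convolution to twice the input channels. Decoder levels upsample with 2×2
stride-2 transposed convolutions, concatenate the matching encoder features,
and apply two 3×3 convolutions. A 1×1 convolution with sigmoid keeps the
output in (0, 1). Input size must be divisible by 2^levels.

Training minimizes MSE between the network output on the marked image and
the clean pair, with Adam and per-epoch exponential decay
lr(e) = lr₀ · γ^(e−1). Two profiles:

| profile | levels | base ch. | pairs | epochs | batch | lr₀    | γ    |
|---------|--------|----------|-------|--------|-------|--------|------|
| full    | 4      | 32       | 171   | 200    | 2     | 5·10⁻⁵ | 0.95 |
| desk    | 2      | 8        | 200   | 30     | 2     | 10⁻³   | 0.95 |

The full profile carries the study schedule; the desk profile is the
package's single-CPU configuration (≈ 1–2 min) with the learning rate
raised to compensate for the 6× shorter schedule — with lr₀ = 5·10⁻⁵ a
30-epoch run from random initialization barely moves. Weights are
He-initialized under the run seed; no pretraining. Images 64×64 in the desk
profile. Measured on this profile (seed 0): final-epoch training MSE ≈
0.015× the first epoch, and PSNR against the clean target improves on 40/40
held-out marked phantoms (median gain ≈ 13 dB).

## Classifier

Dense-block backbone: a 3×3 stem convolution, then stages of
[dense block → transition]. Each dense-block layer sees the concatenation
of the block input and all earlier layer outputs and adds `growth_rate`
channels via one 3×3 convolution (pre-activation ReLU); transitions are 1×1
convolutions with compression 0.5 followed by 2× average pooling. Global
average pooling feeds a five-way linear head; prediction is the softmax
argmax with ties to the first index. Presets `d121` [6,12,24,16] g=32,
`d161` [6,12,36,24] g=48, `d201` [6,12,48,32] g=32 mirror the standard
layouts; `desk` is [2,2] g=12 with a 24-channel stem (≈ 10⁴ parameters).
Deliberate simplifications relative to the canonical architecture: no batch
normalization and no 1×1 bottleneck inside dense layers — at desk scale
He-init + Adam trains these small networks reliably, and dropping the
normalization keeps the engine minimal and runs strictly deterministic.
Channel bookkeeping (block-input + ℓ·growth channels into layer ℓ,
compression, spatial halving) is kept exact.

Training: cross-entropy, Adam, the same exponential schedule. The study
schedule is 50 epochs, batch 8, lr₀ 5·10⁻⁵; the desk schedule is 30 epochs,
batch 8, lr₀ 3·10⁻³ (chosen like the denoiser's: large enough that a short
from-scratch run converges). The 8× dihedral augmentation is applied to
training images only. Initialization is seeded-random; ImageNet-pretrained
weights are supported only as externally supplied state dicts
(`net_.load_state_dict`) since the package downloads nothing. Measured desk
run (160 phantoms, fold-1 split, seed 0): 91% held-out accuracy on clean
images, 100% on marked images — the marked model exploits the
class-correlated mark burden, which is precisely the shortcut the denoiser
exists to remove.

## Evaluation protocol

- **Folds**: within each class, ids are shuffled by the plan seed and dealt
  so per-class fold sizes differ by ≤ 1, remainders to the lowest-numbered
  folds. This rule uniquely reproduces the cohort partition
  324/324/323/323/319 from the class totals. Stratification is image-level
  (each ovary contributes one image).
- **Metrics**: one-vs-rest collapse of the 5×5 confusion matrix; ratios
  with zero denominators are reported as missing (`None`/`NA`), never 0.
  AUC uses the class's softmax score and the rank statistic with ties
  credited 0.5 (equivalent to trapezoidal integration over thresholds).
- **Aggregation**: mean ± t₀.₉₇₅,ₙ₋₁·s/√n across folds for every metric
  (2.776 at five folds). A class absent from a fold flags that fold's AUC
  and the aggregate as missing; the run continues.

## Grad-CAM

Channel weights are the spatial means of ∂(class logit)/∂(feature map) at a
named feature tap (default: the last convolutional features before global
pooling); the rectified weighted sum is bilinearly upsampled and normalized
by its maximum (identically-zero maps stay zero, and downstream scores flag
them as undefined rather than 0). The localization score is the fraction of
heatmap mass inside a ground-truth mask. Two model-validation probes run in
the test suite:

- **Occlusion consistency**: blanking the top-decile heatmap region lowers
  the target-class score on a majority of correctly classified validation
  phantoms (measured: all of them).
- **Mark reliance**: the probe blanks the mark pixels of 50 fresh marked
  phantoms and compares the shift in true-class probability between the
  marked-trained and clean-trained classifiers (identical seeds). Measured:
  the marked-trained model shifts ≈ 2× more (0.27 vs 0.14 mean |Δp|). We
  use occlusion sensitivity rather than heatmap mass on the mark mask
  because the mask covers only ~2% of pixels and bright glyphs activate
  lesion-texture channels in both models, leaving the mass fraction nearly
  identical (≈ 0.043 both) — an insensitive instrument at this scale.

## Numerical and engineering choices

- All network arithmetic is float32 on a small NumPy reverse-mode autodiff
  engine; convolution uses im2col/col2im with explicit dilation, transposed
  convolution is implemented as the adjoint of the strided convolution.
  Every operator's gradient is tested against central finite differences.
- Determinism: a single master seed fans out to per-stage seeds by stable
  hashing; identical seeds reproduce datasets, training runs and reports
  byte-for-byte on the same platform (single-threaded NumPy kernels may
  differ across BLAS builds; the suite checks within-platform determinism).
- Degenerate inputs are rejected with explicit errors: unknown class labels,
  negative mark density, non-square augmentation input, input sizes
  incompatible with the pooling chain, empty pair lists, single-class AUC.
- The end-to-end determinism check runs a miniature pipeline configuration
  (20 phantoms, 2 folds, 2 epochs) twice; determinism is a property of the
  code path, not of the problem size. The desk-scale experiments in the
  suite use 64×64 phantoms — the criterion-relevant sample sizes (200 pairs,
  160 images, 30 epochs) at the resolution the desk networks are sized for.

## Known limitations

- Phantoms idealize ultrasound: no device variation, no depth-gain
  artifacts, no off-plane anatomy; class renderings are archetypes, so
  held-out accuracy here overstates what any model would achieve on
  clinical data.
- The full-profile architecture presets reproduce layer layouts and channel
  plans, not reference implementations (no BN, simplified stem), and the
  full profile's runtime (360×360, 200/50 epochs) is not exercised by the
  test suite.
- Caliper/annotation glyph shapes are plausible renderings of scanner
  overlays, not replicas of any vendor's.
- Confidence intervals are fold-wise Student's-t by design; no
  patient-level clustering or DeLong AUC intervals.
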