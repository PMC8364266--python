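# Methods

`mrsct` re-implements an MR-only synthetic-CT (sCT) workflow for pelvis
radiotherapy at 0.35 T: a U-NET translates TRUFI MRI slices into Hounsfield
-unit images, trained with a loss that equalizes the contribution of body,
fat, muscle and bone voxels.  Clinical paired MR/CT data is not
redistributable, so the package ships a controlled phantom generator and
every claim its tests make is a claim about those phantoms.  This note
records the model, the parameters that matter, what the phantoms do and do
not emulate, and the numerical choices a maintainer would want to know.

## The translation model

The network is a standard 2-D U-NET: `depth` encoder levels of two
(3x3 convolution -> batch normalization -> ReLU) stages followed by 2x2 max
pooling with filter doubling, a bottleneck block, and a mirrored decoder of
2x2 transposed-convolution upsampling, skip concatenation and two further
conv-BN-ReLU stages per level; a final linear 1x1 convolution produces the
one-channel output.  Same-padding keeps the output the size of the input, so
a 224x320 three-channel input yields a 224x320 sCT slice.  The final layer
has no activation: HU regression is unbounded below zero after scaling.
The input is three consecutive MRI slices (Z-1, Z, Z+1) so the network sees
through-plane context; at the volume ends the missing neighbor is replaced
by the second slice from that end.

There is no deep-learning framework dependency: convolutions, batch
normalization, pooling, transposed convolutions, backpropagation and Adam
are implemented in NumPy (channels-last, im2col + BLAS matmul; the backward
data pass of a convolution is a convolution with the flipped,
channel-transposed kernel, so no scatter operation is needed).  Gradients
are verified against central finite differences in float64 in the test
suite; training runs in float32.

## Tissue-equalized loss

With classification maps MAP_T for T in {body, fat, muscle, bone} computed
on each reference CT, the per-patient contributing factor is
CF_T = N_T / N_Total and the cohort enhancing factor is
EF_T = n / sum_i CF_T(i), the reciprocal of the cohort-mean CF.  The
equalization map

    MAP_eq = 1 + sum_T EF_T * MAP_T

weights the voxel-wise L1 loss

    L_eq = 1/(N*B) sum_p sum_k MAP_eq(p,k) * |CT(p,k) - sCT(p,k)|.

The identity EF_T * mean_i(CF_T(i)) = 1 holds by construction (and
EF_T * N_T = N_Total for a single-patient cohort); tests assert it.  The
loss difference term is read as an absolute difference (the L1/MAE form):
the MSE ablation replaces |d| by d^2 under the same weighting.  The body map
overlaps its sub-tissue maps, so a bone voxel weighs 1 + EF_body + EF_bone;
a config-free literal reading of the sum.  Internal air (rectal gas) sits in
the body map only and weighs 1 + EF_body.  Enhancing factors are a
training-cohort statistic: they are computed from training patients only and
frozen before any test-set use (a leakage test enforces this).

Training follows the reference protocol: Adam with beta1 = 0.975,
beta2 = 0.999, learning rate 1e-3, batch size 4, a checkpoint after every
epoch.  For numerical conditioning the network operates on scaled values —
MRI divided by 1000, CT mapped by (HU + 1000)/2000 — and all reported MAE
values are converted back to HU.

## Preprocessing

*MRI standardization* is a landmark method: the median intensities of a
muscle and a fat region are mapped to fixed values 400 and 800, air to 0,
linearly in between; above the fat landmark the muscle-to-fat segment's
slope continues (the natural monotone extension; no intensity cap).  The map
is built from ratios of differences so the anchors are exact in floating
point.  The even-count median is the midpoint of the central order
statistics — landmark-exactness tests depend on that convention.

*CT intensity matching* excludes air by thresholding (HU < -250), classifies
the remaining body voxels into fat/muscle/bone with fuzzy c-means on the
scalar HU values, replaces bone with the air value (bone is dark on TRUFI),
and applies the affine map sending the muscle/fat cluster centers to
400/800.  Fat lies below muscle in HU but above it on TRUFI, so the slope is
negative — a deliberate contrast inversion.  Bone replacement happens after
the affine map (the order is configurable through the pipeline but not
observable on phantoms, where both orders give 0 for bone).

*Fuzzy c-means* uses fuzziness m = 2, convergence tolerance 1e-5 on the
maximum center shift, at most 200 iterations, and deterministic
initialization at evenly spaced percentiles (10th..90th) of the sample — no
random restarts, so classification is reproducible.  Ties in the hard
assignment resolve to the lowest cluster index.  The FCM objective is
checked to be non-increasing and memberships renormalize to one within
1e-9.  Intensity-inhomogeneity correction is out of scope (the phantoms
control their bias field explicitly); an optional polynomial bias-flattening
utility exists but is disabled by default.

## Geometric normalization

The body center of mass is translated to the image center and the most
posterior body voxel is then placed 10 background rows from the posterior
image edge (the posterior rule overrides the center-of-mass result on the
anterior-posterior axis only).  Translations are integer-voxel, so values
are preserved exactly — no resampling anywhere in the geometry path.
Voxels outside the body become background: 0 for MRI and -1000 HU for CT,
because losses and MAE are computed in HU and background air must stay
physically sensible.  A body wider than the output shape raises an error
rather than silently clipping.  "Rows" run anterior -> posterior (supine
patient, posterior at the image bottom); the convention is documented on the
core containers.

## Augmentation

Two modes.  *Per-epoch*: every example is freshly mirrored (probability 1/2,
about the median plane) and rotated (uniform in ±10°) at the start of each
epoch — the dataset size stays constant but no image repeats across epochs.
*Traditional*: the dataset is expanded once with 5 random copies plus the
originals (six-fold) and trained as a fixed set.  One flip decision and one
angle apply identically to the three MRI channels, the CT target and the
equalization-map plane.  The MRI input channels interpolate linearly; the CT
target and the equalization map rotate by nearest neighbour.  The target is
supervision, not an input: linear interpolation invents intermediate HU at
air/bone boundaries (tissue that exists nowhere), and on structures only a
few voxels across — the phantom regime — that bias is the same order as the
bone-MAE effects under study (~60 HU inside rotated bone), so the sampled
rotation must preserve the target's HU distribution.  Out-of-frame voxels
take each plane's background value.
Rotation is about the image center (bodies are centered first, so no
translation augmentation is needed).  Epoch-indexed RNG substreams make
resumption at epoch k reproduce the same augmentations.

## The phantom cohort

Each phantom is a stack of analytically defined axial slices: an elliptical
body with a subcutaneous fat ring, muscle interior, two femoral-head
surrogates and a sacrum block (about 13% of the body cross-section — the
rare-tissue regime the equalized loss targets), and an optional rectal air
pocket on the middle slices (probability 0.5) to exercise the internal-air
path.  CT is piecewise-noisy-constant per tissue (air -1000±10, fat -100±15,
muscle +40±15, bone +700±100 HU); MRI has TRUFI-like ordering (fat 600,
muscle 300, bone 80, air 30, with per-tissue texture SDs), a multiplicative
low-frequency bias field (amplitude 0.15) and additive Gaussian noise
(SD 10).  Per-patient variation: ±6% geometry jitter on semi-axes and bone
structures, and an in-plane setup tilt uniform in ±10° — matched to the
protocol's rotation-augmentation range, so the phantoms present the
orientation variability that augmentation is designed to absorb.  One master
seed; patient i uses substream seed + i, so cohorts are reproducible and
stable under resizing.

Default grid: 6 slices of 96x96 (divisible by 2^depth for depth <= 5;
the clinical 224x320 shape is available through the spec).  The desk-scale
experiment uses 12 phantoms (8 training / 4 test), a depth-3 / base-16
U-NET and 15 epochs — sizes chosen so the full three-arm, three-seed
ablation runs on a single CPU at interactive timescales.

**What the phantoms do not emulate:** real anatomy (no organs, no cortical/
trabecular bone distinction, no anatomical meshes), MR physics (no TR/TE/
flip-angle modeling), registration error between MR and CT (pairs are
generated pre-aligned; externally registered pairs can be imported), CT
beam-hardening or metal artifacts, and inter-scanner histogram variation
beyond a global bias field.  Passing tests therefore demonstrate that the
pipeline's operators are implemented correctly and that the loss/augmentation
effects point the right way under controlled conditions — not that the model
reaches clinical accuracy on patients.

## Evaluation

Tissue-wise MAE in HU is computed inside each classification map of the
*reference* CT; an empty tissue is reported as missing and excluded from
means (logged, not imputed).  A dataset's *learning capacity* is the mean
test MAE over the final 5 epochs of a run.  Cross-validation is k-fold
(default 3) with fold-specific enhancing factors; summaries are mean ±
sample SD (n-1 denominator) across test patients, patient-first (each
patient's slices are averaged before patients are averaged).  One-factor
-at-a-time comparisons use a two-sided paired Student t-test on per-patient
learning-capacity MAE; zero-variance difference vectors are flagged as
degenerate rather than returned as NaN (identical samples: t = 0, p = 1; a
constant non-zero shift: p = 0).  No multiple-testing correction is applied.
Dataset-size experiments use nested subsets: a patient in the s-patient set
stays in every larger set, so the size curve varies only through added
patients.

## Known limitations

* Augmentation at desk scale rotates targets whose bone structures are only
  a few voxels across, so any interpolation artifact is amplified relative
  to clinical resolution (nearest-neighbour target rotation mitigates this;
  see Augmentation).  The directional augmentation comparison remains the
  tightest of the package's checks.
* The NumPy U-NET is single-threaded BLAS-bound; at clinical sizes
  (224x320, depth 4, base 64, 100 epochs) a GPU framework would be the
  practical choice.  The architecture and protocol are configuration, so
  nothing else would change.
* The FCM percentile initialization assumes the three non-air tissues each
  occupy a non-negligible HU mass; a patient with almost no visible bone
  could collapse two initial centers (they are nudged apart
  deterministically, but recovery is not guaranteed in pathological cases).
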