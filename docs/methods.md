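# Methods

`polsynth` implements computational polarization-sensitive OCT (PS-OCT):
an SSIM-augmented conditional GAN that maps a single-polarization OCT
intensity B-scan to the two standard polarization contrasts — the
degree of polarization uniformity (DOPU) and the phase retardation —
plus the machinery needed to exercise and validate that method end to
end: a birefringent tissue phantom, the preprocessing/partitioning
chain, masked-SSIM evaluation, and a downstream cancer/normal
classifier compared between real-trained and synthetic-trained
variants.  This note records the models, the parameters that matter,
the numerical choices, and what the desk-scale results do and do not
show.

## Tissue phantom

Real co-registered OCT/PS-OCT breast-tissue data are not publicly
deposited, so the package ships a simulator whose outputs play the role
of the acquired dataset.  A frame is a stack of horizontal slabs
(depth axis first).  Each slab carries a birefringence Δn, a
backscatter amplitude, and a per-pixel attenuation coefficient.

* **Retardation.** Single-pass retardation accumulates as
  δ(z) = (2π/λ) Σ_{z′≤z} Δn(z′)·Δz, is doubled for the round trip, and
  folded into [0, π/2] by triangular wrapping — the usual
  single-detector display convention.  Within a zero-Δn slab the
  unfolded value is constant in depth.
* **Intensity.** The noiseless signal decays exponentially through the
  overlying attenuation; speckle is a multiplicative Gamma(k, 1/k)
  factor (the average of k unit-mean exponential looks, k =
  `speckle_looks`); the result is log-compressed over a fixed window
  (10⁻⁵ to 10¹ in linear units) and quantized to 16 bits.
* **Polarization channels.** The retardation δ maps to the unit Stokes
  state (Q, U, V) = (cos 2δ, sin 2δ, 0) — a rotation of the incident
  state about the V axis.  Independent Gaussian perturbations of scale
  σ_DOPU = 0.10 and σ_ret = 0.25 are applied to (Q, U, V) for the two
  channels and the vector is re-clipped to |(Q,U,V)| ≤ I.  DOPU is the
  norm of the I-normalized Stokes vector averaged over a k×k window
  (default 5; windows shrink at borders so a trivial double-loop oracle
  matches exactly).  The displayed retardation is recovered from the
  *noisy* Stokes state as ½|atan2(U, Q)|.  Because σ_ret > σ_DOPU and
  DOPU additionally benefits from window averaging, retardation is the
  intrinsically noisier contrast, which the noise-asymmetry check
  quantifies (high-pass residual std, both channels scaled to [0, 1]).
* **Classes.** "Normal" tissue has organized birefringent layers
  (Δn ∈ [5·10⁻⁴, 2·10⁻³]); "cancer" has near-zero Δn plus a Poisson
  number (mean 6) of lesion blobs that both boost backscatter (×1.5—2.5)
  and scramble polarization (extra Stokes noise 0.3—0.7).  This is a
  deliberate caricature of the absence/derangement of collagen in
  tumors: classes are separable *by construction*, in retardation level,
  in DOPU texture, and (through the lesions) in intensity texture.
  The first-pass noise scales (0.12/0.45) left retardation with almost
  no visible structure, unlike real retardation B-scans, and were
  revised once to 0.10/0.25 when the simulator was frozen.

What the phantom does **not** emulate: wavelength-dependent scattering,
Jones-matrix processing chains of real PS-OCT hardware, fiber-bending
artifacts, lateral speckle correlation, and real histological texture.
Passing the downstream checks therefore demonstrates that the *method*
works when the contrasts are genuinely encoded in intensity, not that
it would reach the same numbers on human tissue.

## Preprocessing

Frames are margin-cropped (rows/columns whose mean is below 0.02 × the
global max; the window found on intensity is applied to all three
co-registered channels), center-cropped in depth to the tile side,
split laterally into two non-overlapping square tiles (256×512 frames
give two 202×202 tiles), and converted 16→8 bit with the global linear
map floor(v/257 + 0.5).  A per-image min–max mode exists as a flag but
makes no fidelity claim.  Splits: image-based 8:1:1 with
test = validation = ⌊N/10⌋ (this floor convention reproduces 4,414 test
tiles from 44,144), or case-based with one held-out case per class
split half/half between test and validation.  One manifest row covers
the co-registered tile triple, so paired integrity across channels is
structural.

## GAN

pix2pix-style: a U-Net generator (stride-2 conv encoder, nearest-
upsample + conv decoder with skip connections, instance norm, tanh
output; depth 5, base 64 by default) and a patch discriminator with
exactly three stride-2 conv feature layers before the 1-channel score
head, taking the (intensity, contrast) pair as input.  Tiles whose side
is not a multiple of 2^depth are reflect-padded and the output is
cropped back (202 → 224 at depth 5).

Generator objective:

    L_G = λ_adv·BCE(D(x, G(x)), 1) + λ_L1·mean|G(x) − y|
          + λ_SSIM·(1 − SSIM(G(x), y)),      (λ = 1, 100, 10)

λ_L1 = 100 follows the pix2pix lineage; λ_SSIM = 10 balances the two
reconstruction terms at the 8-bit scale.  λ_SSIM = 0 recovers the plain
pix2pix objective exactly (the term is skipped, not multiplied by
zero).  An LSGAN variant of the adversarial term is available as a
config option.  Training: Adam (lr 2·10⁻⁵ at full scale; the
desk-scale tasks use 2·10⁻⁴, see below), β = (0.5, 0.999), batch size 1
as required by instance normalization, alternating D/G updates.

Tiles are normalized to [−1, 1] internally.  SSIM is invariant under a
joint affine rescaling of both images and the data range, so the loss
term evaluated with data_range = 2 equals the 8-bit convention with
data_range = 255 exactly.

Per epoch the validation masked-SSIM of the current generator is
recorded and the best-epoch parameters are retained.  Downstream
synthesis uses the **final** generator: with heavily noisy targets
(retardation) the best-masked-SSIM checkpoint tends to be an early,
oversmoothed generator whose output carries little class information —
consistent with the observation that retardation SSIM and downstream
classification quality decouple.

All networks run on a small in-package reverse-mode autodiff engine
(`polsynth.nn`: broadcast-aware arithmetic, im2col convolution,
nearest upsampling, instance norm, Adam), validated against central
finite differences.  Numerics are float32 for training; the SSIM
evaluation path is float64.

## SSIM and masked SSIM

The local SSIM map uses an 11×11 Gaussian window (σ = 1.5, normalized),
stabilizers C1 = (0.01 L)², C2 = (0.03 L)², weighted covariance, and
*valid* window positions only; the scalar SSIM is the map mean and
matches `skimage.metrics.structural_similarity` (gaussian_weights,
use_sample_covariance=False) to machine precision.  For images smaller
than 11 px the window shrinks to the largest odd fitting size (a 1×1
window reduces SSIM to its luminance term).  Masked SSIM averages the
same map over positions whose center-pixel intensity is at or above the
threshold (default 8-bit value 10): masking selects map entries *after*
computation, so the map values themselves never depend on the
threshold, and threshold 0 is exactly the plain SSIM.  An alternative
mode that zeroes sub-threshold pixels before the map is computed exists
behind a flag.  Tiles whose mask is empty raise an explicit error and
are excluded (and counted) at the dataset level.  Reported statistics
are per-tile-then-averaged (mean ± std).

Overlays render the contrast through the standard jet colormap,
alpha-blended (α = 0.6) over the grayscale intensity wherever the
intensity passes the threshold; sub-threshold pixels show pure
grayscale.

## Downstream classification

A residual backbone with a 512-wide global-average penultimate layer
feeds a 512→2 head; scores are the softmax probability of the cancer
class.  The default "reduced" backbone has one residual block per stage
(4 blocks, channels 64→512); the classic two-blocks-per-stage variant
is available.  ImageNet-pretrained initialization would require a
network download, so the package trains the head on top of a *frozen
randomly initialized* backbone (random convolutional features are a
standard strong baseline for linear probes); `trainable_scope="all"`
unfreezes everything.  Training follows the transfer recipe: 24 epochs,
best-validation-accuracy checkpoint, frozen backbone bitwise unchanged.
ROC/AUC use grouped thresholds and trapezoidal integration
(`sklearn.metrics.roc_curve/auc`), which equals the Mann–Whitney
pairwise statistic with ties counted ½.  Real-trained and
synthetic-trained classifiers are compared on the same test positions —
each on its own modality, as in the original design — via |ΔAUC| and
per-item agreement.

## t-SNE

Exact O(N²) t-SNE on the 512-d activations: per-point bandwidths by
binary search until the conditional entropy matches log(perplexity)
(tolerance 10⁻⁶, 64 iterations), symmetrized affinities, early
exaggeration ×12 for 100 iterations, momentum 0.5→0.8 (switch at 250),
adaptive gains, 600 iterations, random N(0, 10⁻⁴) init.  The learning
rate defaults to max(N/12, 50): a fixed rate of 200 overshoots on
small point sets and makes the KL objective non-monotone.  The KL
divergence is recorded every 25 iterations after exaggeration ends and
is non-increasing up to momentum oscillation at the 10⁻⁴ level; the
implementation is in-package because the calibration diagnostics
(conditional distributions, KL trace) are part of its contract.
Perplexity is auto-reduced with a warning when N − 1 < 3·perplexity.

## Desk-scale problem sizes

The original study trains on 44,144 tiles for 50 epochs (~16 h on a
GPU); the package's experiment suite reproduces the *properties* of the
method at sizes that run in minutes on one CPU, with the reduced
generator (depth 3, base 16), lr 2·10⁻⁴:

* smooth-mapping recovery: 200 32×32 tiles (180/20), 8 epochs — the
  target is a logistic function of the blurred intensity, so a correct
  training loop must reach high masked SSIM (observed ≈ 0.98 ≥ 0.80);
* SSIM-loss ablation: 120/20 tiles, 6 epochs, 3 paired seeds — the
  median validation-SSIM gain of λ_SSIM = 10 over 0 is positive
  (direction only; the magnitude of the original ≥20% claim is not
  reproducible at this scale);
* end-to-end: 160 phantom frames per class (32×32 tiles), GAN 12
  epochs on 150 pairs, classifiers on 474 disjoint tiles split 6:3:1
  (142 test tiles).  On DOPU both classifiers exceed 0.95 AUC with
  |ΔAUC| ≤ 0.05.  On retardation the real-trained classifier is
  near-perfect but the synthetic-trained one lags (≈ 0.83—0.9): inverting layered
  intensity into a retardation ramp is the harder translation problem
  and does not fully resolve at this model/data size.  This gap is a
  known desk-scale limitation and is reported, not asserted.

## Known limitations

* The phantom is a geometric caricature; absolute SSIM/AUC values are
  not comparable to the human-tissue numbers, only orderings and
  closure properties (DOPU easier than retardation; real ≈ synthetic
  downstream on DOPU).
* The autodiff engine is single-threaded numpy; full-scale 202×202 /
  depth-5 / 50-epoch training is supported in code but impractical on
  CPU.
* Pretrained ImageNet weights are not bundled; the random frozen
  backbone is a capability surrogate, not a fidelity claim.
* Case-based splitting is implemented for arbitrary case counts by
  holding out one case per class; the original fixed 6+4/1+1 layout is
  the special case.
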