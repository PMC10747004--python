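# Methods

## The problem

Finger-vein recognition terminals can be attacked with printed prostheses
(vein patterns printed on A4 paper, PVC plastic or laser film).  A short
static video of the transilluminated finger carries a liveness cue that a
print cannot reproduce: blood flow slightly expands and contracts the
superficial veins, modulating near-infrared absorption in the vein region at
the cardiac frequency.  The signal is on the order of one to three gray
levels at 8-bit scale and is buried in sensor noise, so it is pooled
spatially (vein-edge block means), organised into an image-like
spatial–temporal map, and classified with a small hybrid CNN–transformer.

## Pipeline

1. **Static-window extraction.**  The three-frame difference on the
   channel-mean image flags frame *t* as moving when both
   `|f_t − f_{t−1}| > d` and `|f_{t+1} − f_t| > d` hold on more than a
   fraction `r` of pixels.  Defaults `d = 10` gray levels and `r = 0.002`
   keep sensor noise (σ ≈ 2) far below the motion threshold; both are
   config keys.  The longest static run (earliest on ties) is center-cropped
   to 180 frames (1.5 s at 120 fps); shorter runs are an error that reports
   the achievable length.

2. **Vein segmentation.**  The temporal-mean, channel-mean frame is filtered
   with a bank of real Gabor kernels

   `G(x, y) = exp(−(x₁² + γ² y₁²) / 2σ²) · cos(2π x₁ / λ + φ)`,

   with rotated coordinates `x₁ = x cos θ + y sin θ`,
   `y₁ = −x sin θ + y cos θ`.  Each kernel has its arithmetic mean
   subtracted (`G′ = G − mean(G)`), which removes the DC response exactly:
   a constant image produces a null response, so the large spatially varying
   transmission baseline cannot leak into the segmentation.  σ is tied to
   the half-response bandwidth *b* in octaves by
   `σ/λ = (1/π)·√(ln2/2)·(2ᵇ+1)/(2ᵇ−1)` (≈ 0.56 λ at one octave) and
   `ksize = 2·ceil(3σ)+1`.  Defaults: λ ∈ {4, 8, 12} px, 8 orientations,
   b = 1, γ = 0.5, φ = 0 — standard ridge-detection settings, all config
   keys.  The image is photometrically inverted (veins are dark), the
   response is the max over orientations summed over wavelengths, and the
   binary mask is Otsu's threshold of the response restricted to the finger
   region (bright Otsu foreground of the mean frame), followed by a 3×3
   opening and small-component removal.  Thresholding is contrast
   equivariant: scaling the image scales the response and leaves the mask
   unchanged.

3. **Vein-edge blocks.**  `Iedge = Ibw AND NOT erode(Ibw, 3×3)` with the
   border treated as foreground, so the image frame never produces an
   artificial edge.  The main vein is the largest connected component; its
   column span is divided into `p = 56` equal strips and each strip
   contributes the edge pixel nearest the strip's vein centroid, giving
   blocks ordered root→tip.  `p = 56` with scales {1, 2, 4, 8} yields
   56 + 28 + 14 + 7 = 105 rows, which upsample cleanly to 224; block size
   defaults to 16 px.  Both are config keys.

4. **MSTmap.**  Block means per frame and channel (p × 180 × 3) are
   aggregated into non-overlapping group means of 1, 2, 4 and 8 consecutive
   blocks (the multi-scale rows), min–max normalised per row and channel to
   [0, 255] (constant rows map to mid-gray 128 to avoid spurious extremes),
   and bilinearly resampled on the row axis to the fixed (224, 180, 3)
   8-bit map.  Min–max normalisation makes the map invariant to global
   offset and gain of the sensor up to 8-bit rounding ties.

5. **Classifier.**  The Light-ViT backbone interleaves
   * MN blocks — inverted residuals: 1×1 expand → batch norm → SiLU → 3×3
     depthwise (stride T ∈ {1, 2}) → norm → SiLU → 1×1 project → norm, with
     an identity residual when T = 1 and channels match; and
   * L-ViT blocks — 3×3 local conv, 1×1 projection to token dimension D,
     unfolding the H×W map into N = HW/P patches of P = w·h pixels, a
     learned additive positional encoding, L pre-norm multi-head
     self-attention + MLP encoder layers, folding back, 1×1 projection to C
     channels, concatenation with the block input and a 3×3 fusion conv.
   The reference configuration (stem 3×3/2 → 16 ch; MN/L-ViT stages rising
   to 80 ch / 96-dim tokens; 1×1 → 320; pool; linear → 2) totals 1.022 M
   parameters.  The published architecture gives the block designs but not
   the stage table, so this configuration brackets rather than matches the
   published 1.107 M; every width is config.  At 224×224 input the last
   attention stage sees a 7×7 map, which a 2×2 patch cannot tile, so that
   stage uses a 1×1 patch (plain token attention over the 49 positions).
   MSTmaps are bilinearly resized to a square model input; square inputs
   keep patch folding uniform.

6. **Training and metrics.**  Adam (β = 0.9/0.999) under cosine annealing
   to 1e-6, cross-entropy loss; the full-scale protocol is batch 32,
   300 epochs at lr 1e-4.  Splits are finger-disjoint and stratified by
   label — no finger identity appears on both sides — which is the
   leakage-safe reading of "no repeated samples".  Metrics follow
   ISO/IEC 30107-3: APCER per attack species (fraction of that species
   accepted as bona fide), BPCER (fraction of bona fide rejected), worst
   case `apcer_max`, and the accuracy identity
   `ACR = 1 − (Σ_s APCER_s·N_s + BPCER·N_BF)/N_total`.  Class encoding is
   0 = bona fide, 1 = attack with a 0.5 softmax threshold.

## Networks without a deep-learning framework

All networks run on `veinlive.nn`, a small reverse-mode autodiff engine on
NumPy arrays (fused im2col convolution and pooling primitives; composed
batch/layer norm, attention and activations; Adam with cosine schedule).
Gradient correctness is checked against central differences in the test
suite.  The baseline factories construct the standard published VGG-16,
ResNet-50, MobileNetV2 and ViT-B/16 topologies in this framework; with
2-class heads they count 134,268,738 / 23,512,130 / 2,226,434 / 85,800,194
trainable parameters respectively (the published ViT variant differs
slightly from the standard ViT-B/16 count and is excluded from exact
comparison).

## Synthetic data: what it emulates and what it does not

No public live/prosthetic finger-vein video data exists, so the generator
emulates the statistical structure the pipeline relies on:

* **Geometry** — a horizontal finger silhouette (bright transmission region
  with smooth roll-off on a dark housing background) crossed by 2–4 smooth
  cubic-spline veins plus 0–2 branches with Gaussian cross-sections (widths
  3.5–6.5 px at 640×480, chosen so default vein coverage of the finger
  region stays in the 2–15 % band across seeds).
* **Photometry** — Beer–Lambert transmission
  `I_c = B·exp(−A·(1 + live·m·s(t))·w_c) + noise`, with absorption strength
  scaled so the modulation depth `m = 0.02` maps to ~1–3 gray levels.  The
  cardiac waveform is `s(t) = sin(2πft) + 0.3·sin(4πft)` with f drawn
  uniformly from [1.0, 1.7] Hz per clip.  Channel weights (1.0, 0.7, 0.5)
  express that the NIR filter leaks differently into the RGB channels; the
  true values are unpublished, so these are plausible configurable defaults.
* **Corruption** — per-channel Gaussian sensor noise (default σ = 2 gray
  levels), optional shot noise, slow global drift and sub-pixel jitter
  (defaults off).
* **Attacks** — the same generative process rendered without modulation.
  The print-preparation transform (Gaussian blur → contrast-limited
  adaptive histogram equalisation → adaptive regional threshold → power law
  inside the thresholded mask) and species-dependent print grain are
  implemented but **off by default**: with them off, live and attack clips
  with m = 0 are bit-identical under equal seeds, so the pulse is provably
  the only class signal and the ablation study is meaningful.

Live clips reuse each finger identity exactly twice (two presentations of
one vein pattern with independent noise and pulse phase); attacks get one
presentation each, allocated over the three PAI species by largest-remainder
proportional counts.

What passing tests on this data do **not** show: robustness to real optical
blur, finger pose and pressure variation, inter-subject vein topology
statistics, real print texture, or camera compression.  The generator is a
contract for the pipeline's signal model, not a simulator of the physical
acquisition.

## Scaled-down study conditions

The published study (400 videos at 640×480, 300 epochs) is reproduced at
desk scale: 120 live + 120 attack clips at 320×240, the reduced Light-ViT
(62.6 k parameters, 48×48 inputs), 25 epochs of Adam at lr 1e-3, finger-
disjoint 8:2 split (192 train / 48 validation).  These sizes are the
package's default experiment conditions; under them the classifier reaches
validation ACR ≥ 0.90 with the pulse present and chance level with the
pulse ablated (m = 0), which is the causal claim the study supports.

## Numerical choices and edge cases

* Bank responses are computed with one padded FFT of the image per clip
  (reflect padding, "same" size); kernels with φ = 0 are symmetric, so
  convolution and correlation coincide.
* A flat image yields an exactly empty mask: the response range is compared
  to `1e-8 ×` the image scale before Otsu is attempted (Otsu on pure
  float-noise would otherwise threshold garbage).
* Erosion treats out-of-image as foreground; constant-true masks therefore
  have no edge.
* Constant MSTmap rows map to 128; non-constant rows attain both 0 and 255.
* Block centers are clip-shifted inside the image; the shift is monotone so
  root→tip column ordering is preserved.
* Ties among equal-length static runs go to the earliest run.
* All generators and model initialisations are pure functions of explicit
  seeds; manifests record per-clip seeds.

## Known limitations

* Segmentation quality against the generator's 0.1·max ground-truth band is
  precision-limited by design (the Otsu core is thinner than the band):
  mean Dice ≈ 0.66 across seeds, individual seeds 0.58–0.71.
* The 1.5 s window gives a DFT bin width of 0.67 Hz, so heart rate is only
  localised to the nearest bin.
* The reference Light-ViT stage table is a bracket of the published size,
  not a reconstruction.
* MP4/AVI input requires an ffmpeg imageio plugin; the lossless formats
  (PNG frame directories, NPZ stacks) are the supported interchange.
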