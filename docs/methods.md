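# Methods

## Problem setting

A backlit (transmission-illuminated) plate photograph shows a bright
circular culture-medium disk bounded by a dark annular dish rim, on a
mid-bright background. Colonies absorb transmitted light and appear as
dark blobs, isolated or grown together into *adhesive* clusters. The
pipeline must (i) find the dish interior, (ii) find colony pixels,
(iii) partition them into connected components, and (iv) assign each
component a count — one component may hold several colonies, and the
counting model, not a geometric splitter, resolves that ambiguity.

## Intensity correction

Raw luminosity is confounded by the medium batch (composition,
thickness) and by illumination level. Let `I0` be the mean luminosity
of culture-medium pixels and `I_i` a pixel's luminosity; the corrected
field is

    corrected_i = log10(I0) - log10(max(I_i, 1/65535))

Properties used by the tests: medium pixels map to ~0; colonies
(darker) map positive; the map is strictly decreasing in `I_i`; and
multiplying the image (hence `I0`) by any c > 0 cancels exactly — the
correction removes global illumination scale by construction. The
`1/65535` floor (one 16-bit quantum) keeps logarithms finite on dead
pixels.

Decisions taken where the procedure was underdetermined:

- "lg" is read as log10. Any fixed base rescales the field by a
  constant that the downstream [0, 1] input normalization absorbs.
- Correction is computed on luminosity (mean of R, G, B); each channel
  is then multiplied by `corrected / raw` luminosity so hue is
  preserved while the corrected image's luminosity equals the scalar
  corrected field. The alternative (per-channel correction) would
  discard hue differences between colony types.
- The rough medium mask needed for `I0` comes from classical operations
  only (bilateral denoise, Otsu threshold for the bright disk, Sobel
  gradient + darkness tests for a rough foreground estimate): it must
  not depend on the trained models, because it feeds their input. The
  gradient threshold is taken from the whole image so the dish rim sets
  its scale and in-dish noise stays below it; a 5-px erosion ignores the
  gradient ring the rim itself bleeds inward.
- Network inputs are the corrected field affinely windowed to [0, 1]
  with the fixed window [-0.2, 1.0] (chosen once from the dynamic range
  the correction produces: medium ~0, dark rim ~0.9). A fixed window —
  not per-image min/max — preserves the illumination invariance.

## Segmentation networks

Both segmenters are encoder–decoder stacks of residual U-blocks (RSU).
An RSU of height L applies an input convolution (the residual source),
an L−1 stage conv/pool encoder, a dilated bottom convolution, and a
mirrored decoder with skip concatenations; the block output adds the
residual. Blocks are stacked with pooling between stages; every decoder
stage and the bottom stage emit a 1-channel side output, and a 1×1
convolution fuses all side maps into the final logit map. The loss sums
foreground-weighted binary cross-entropy (on logits) over the side and
fused outputs with equal weight — deep supervision keeps mid-depth
features aligned with the mask.

Training regime (both models): AdamW, learning rate 1e-3, betas
(0.9, 0.999), eps 1e-8, weight decay 1e-4, cosine learning-rate decay
over all steps, batch size 1, inputs in [0, 1] without mean/std
standardization, random parameter initialization (He normal, seeded).
The dish-edge model weights foreground 8:1 — the rim covers roughly 1/8
of the background area, so this balances the classes — and uses no
augmentation (the rim is rotation-symmetric; a mirror adds nothing).
The colony model uses weight 1:1 and horizontal flips at rate 0.5.
Per epoch, the validation F-score (cutoff 0.5) and probability-map MAE
are recorded; the checkpoint kept is the best F-score, ties broken
toward lower MAE.

Scales: `small` (stage heights 4/3/2, 16 base channels, 64 px inputs,
~0.19 M parameters) is the desk-scale default used throughout the test
suite; `full` mirrors the published six-stage topology (heights
7/6/5/4/4/4, dilated final stages). Off-size images are resized
bilinearly to the model geometry and the probability map resized back —
bilinear resizing preserves the ordering thresholding depends on, while
masks use nearest resampling.

The engine beneath both networks is a compact numpy reverse-mode
autodiff library (`colonycount._nn`) providing conv2d (im2col),
max-pooling, nearest-neighbour upsampling, channel concatenation, batch
normalization, and stable BCE/softmax losses, with Adam/AdamW and cosine
decay. Nearest (not bilinear) upsampling is used *inside* the networks:
its backward pass is an exact scatter-sum, and at these scales the
fused output cannot be distinguished; all gradients are verified against
central finite differences in the test suite.

## ROI extraction

The edge map is binarized at t = 0.1 (strictly greater). A low cutoff
is deliberate: it yields a more complete, reliably closed annulus, and
over-covering the rim costs nothing downstream while a leak floods the
interior. The annulus is closed with a 3×3 structuring element, up to
3 iterations, until the region grown from the annulus centroid no
longer reaches the image border; that region is the ROI. A non-closing
annulus raises a stage-named error rather than guessing.

## Colony thresholding and components

The colony map is binarized at t = 0.9: a high cutoff suppresses
false-positive edges of the medium region and separates adhesive
colonies more cleanly, at slight cost in per-colony completeness.
Components are labeled with 8-connectivity (configurable); regions
under 9 px are dropped as threshold speckle (the floor is a free
parameter; 9 px is ~the smallest colony the synthetic generator
renders). Both cutoffs behave as the threshold-sweep tests show: MAE of
the binarized mask is minimized at an interior threshold, precision
rises and recall falls monotonically with t.

## Spatial normalization and crop standardization

For each component the second-order central moments of its pixel set
give an equal-moment ellipse; the orientation θ ∈ (−90°, 90°] is the
angle between the major axis and the vertical image axis. The crop
(bounding box + 4 px margin, masked to the pixel set dilated by the
margin — neighbours excluded, adhesion-boundary texture kept) is
rotated about the ellipse centre by −θ so the major axis ends up
vertical; re-fitting after normalization lands within 3° of vertical on
elongated synthetic components. Rotation is skipped when minor/major
> 0.95: a near-circular component has no meaningful orientation and
interpolating it would only blur. Crops are standardized to 128×128:
content ≤128 px is zero-padded and centred; larger crops are scaled so
the long side is 128 (short side rounded to nearest, minimum 1) and
padded. The operation is idempotent.

## Count classifier

A residual network with a 10-way head maps a standardized crop to its
count; components with ≥9 colonies share class 9, empty crops are
class 0. Training: Adam (default betas), learning rate 1e-4, loss
binary cross-entropy on logits over one-hot targets, with per-class
weights w_i = max_j(n_j)/n_i applied to each sample's positive term
(plain weighted softmax cross-entropy is a config option). Weights are
scale-free in the sample counts; classes absent from a training corpus
get the largest observed weight. The best-validation-accuracy epoch is
kept. `small-resnet` (stem + 3 residual stages, ~0.1 M parameters) is
the desk default; `resnet50-style` mirrors the 50-layer bottleneck
topology; backbones are registry entries so alternates can be swapped.

## Synthetic data generator

The generator renders what the pipeline consumes, with exact ground
truth:

- **Geometry.** Outer dish radius 0.44·min(H, W) with ±1% centre
  jitter; annulus thickness 0.095 of the radius, which makes the rim
  cover ≈1/8 of the background of a square image (the ratio the edge
  model's 8:1 loss weight assumes). All colonies lie strictly inside
  the interior.
- **Appearance.** Exterior 0.45, rim 0.10, medium 0.85 luminosity, a
  random-direction linear gradient (amplitude 0.08) emulating uneven
  backlighting, Gaussian pixel noise (σ 0.012), and a warm RGB tint.
  Colonies are darker-than-medium disks with a step edge at the rim and
  a radial dome toward the centre (contrast 0.55) — the transmission
  look of backlit plates.
- **Clusters.** A k-colony component places k disks on a random walk;
  consecutive disks overlap by 0.45 of their summed radii, so the
  rasterized union is connected by construction, and cluster elongation
  emerges naturally from the walk.
- **Class mix.** Component sizes follow the benchmark corpus mix:
  76.6% singles, 9% pairs, 2.2% triples, 1.2% larger (split evenly over
  4–9), with 10.9% empty crops in the crop dataset.
- **Crop dataset.** Crops are rendered on medium background, converted
  to the corrected unit scale, masked and rotation-normalized with the
  same component code the live pipeline uses, and standardized — so the
  counter trains on the distribution it will see. Rotation treatments
  (`normalized`, `none`, `random45`) support the normalization-benefit
  experiment.
- **Determinism.** Each sample's generator derives from
  `SeedSequence(master_seed, spawn_key=(stream, index))`: bit-identical
  per seed and order-independent across a dataset.

Free parameters the source material never fixes (colony radius range —
default 3–7 px at the 256-px default plate, test corpora use 2–4 px at
64 px; contrast; noise) were chosen once to look like backlit plates
and left alone.

What the generator does *not* emulate: species-specific morphology
(texture, translucency, satellite growth), camera optics (vignetting,
focus), impurities and scratches, and dish-placement variation beyond
small jitter. Passing tests therefore demonstrate that the pipeline's
machinery is correct and trainable, not that the shipped small models
transfer to real photographs — real deployments should retrain both
segmenters and the counter on annotated plates at `scale=full`.

## Experimental design notes

- **Rotation-treatment ordering.** The claim "training on
  rotation-normalized crops beats training on randomly 45°-rotated
  crops" is tested on a cluster-enriched corpus (25/40/25/10% for
  1/2/3/4+ colonies, 5% empty). Under the default 76.6%-singleton mix
  the treatments differ on only ~10% of crops — circular singletons
  have no orientation — and desk-scale runs cannot separate them; the
  enriched mix probes the mechanism the treatment targets. The ordering
  is asserted as a 3-seed majority of best validation accuracy.
- **Desk-scale corpora.** The suite trains on 36 plates (8 held out) at
  64×64, a 1 200-crop counter corpus, and 600-crop ordering corpora —
  sizes chosen so the full suite trains every model from scratch on one
  CPU in minutes. Accuracy floors asserted at this scale (edge F ≥ 0.90,
  colony F ≥ 0.85, easy-plate recovery ≥ 0.95) are property bounds for
  the synthetic conditions, not reproductions of any full-scale result.
- **Pipeline crops are cut from the interior-masked corrected image.**
  Near-rim components would otherwise include bright annulus pixels that
  the crop generator never produces; masking to the ROI keeps the
  counter's input distribution matched between training and inference.

## Numerical conventions

- Thresholding is strict (`p > t`); a pixel exactly at the cutoff is
  background.
- Precision with an empty prediction is 1 if the truth is empty, else
  0; recall with an empty truth is 1.
- The weighted F-score implements the printed coefficients
  1.3·P·R/(0.3·P + R) — an F-beta with β² = 0.3 favouring precision;
  `beta2=1` restores the harmonic mean. F(0, 0) is defined as 0.
- Sweep MAE compares the *binarized* mask to the truth (raw-map MAE
  would be threshold-independent).
- Count ties in the classifier resolve to the lowest class index.
- Recovery for the "9 or more" class treats the label as exactly 9;
  the class's true total is then a lower bound, and per-class recovery
  is reported alongside two aggregates (colony-total and class-mean)
  because no single aggregation is canonical.
- Class-0 recovery is the true-negative rate TP/(TP+FN) of an
  "is empty" binary classification; the ratio form is undefined at
  n_true = 0 and the API directs callers to the binary form.

## Known limitations

- The numpy engine trains small models in minutes but is not suited to
  full-resolution (2560×1922) training; `scale=full` exists for shape
  compatibility and transfer of the architecture, not for in-suite
  training.
- Batch normalization with batch size 1 normalizes over spatial
  positions only; validation uses running statistics, which lag early
  in training (visible as a slow first few epochs).
- The counter's accuracy on 2–3-colony clusters is the weakest link
  (as the per-class recovery spread of the benchmark table also
  shows); errors are almost always ±1 neighbouring classes.
- `extract_roi` assumes one dish per image and a roughly convex
  interior; multi-dish images are out of scope.
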