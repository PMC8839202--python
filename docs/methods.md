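# Methods

This note records the model, the protocol, the synthetic test stand, and the
design decisions taken where the architecture description left genuine
freedom.

## Model

A multi-path U-Net is a set of k parallel encoder–decoder pathways over the
same input.  Pathway i has a pooling window pᵢ and depth dᵢ (the length of
its encoder filter list); its decoder filter list is the reverse of the
encoder list.  Coherence — pᵢ^dᵢ equal across pathways — is validated at
configuration time, because the bottleneck feature maps must share spatial
dimensions to be concatenated.  The package's reference configuration is the
two-pathway network: pool 4 with filters [40, 240] and bottleneck 240, and
pool 2 with filters [40, 80, 160, 220] and bottleneck 220 (4² = 2⁴ = 16).

Blocks:

- **Convolution block** — two (3×3 conv, stride 1, size-preserving padding →
  instance norm → leaky ReLU, α = 0.1) stages.
- **Encoder level** — convolution block, pᵢ×pᵢ max pooling (window = stride),
  spatial dropout.
- **Bottleneck interconnect** — channel concatenation of all pathway
  bottleneck blocks, cross-channel layer normalization (statistics over all
  l·k channels per example and pixel; learned gain/bias of the spatial shape
  of one bottleneck feature map, broadcast over examples and channels),
  then spatial dropout.  The normalized stack feeds *every* pathway's
  decoder.
- **Decoder level** — transposed convolution with kernel = stride = pᵢ
  (blocks never overlap), instance norm, leaky ReLU; concatenation with the
  same-pathway, same-resolution encoder skip; convolution block; spatial
  dropout.
- **Head** — concatenation of all full-resolution pathway outputs, 1×1
  convolution to the class channels, per-pixel softmax.  Channel 0 is
  background, channel 1 foreground, everywhere in the package.

### Parameterization choices

- Convolutions and deconvolutions that are immediately followed by a
  normalization layer carry **no bias**: the normalization's learned shift
  makes a preceding bias redundant, and this is the standard conv+norm
  pairing.  Only the final 1×1 head convolution keeps its bias.  Under this
  convention the reference configuration has 10,082,010 trainable scalars
  (10.08 M), which is the count the package reports.
- σₙ in the interconnect is a mean of squared deviations (a variance); the
  normalization divides by √(σₙ + ε), the scale-consistent form.
- The interconnect gain/bias are per spatial position only (broadcast over
  channels), following the stated spatial shape of the adaptive parameters.
- Normalization ε = 1e-5 for both instance norm and the interconnect.
- Initialization: He-uniform for conv/deconv weights, gain 1 / bias 0 for
  all normalizations; seeded via `ModelConfig.seed`.
- Dropout rate defaults to 0.1 (mild regularization aimed at small
  datasets); it is configurable and the same rate is used at every dropout
  site.
- The final activation is a per-pixel softmax (probabilities sum to 1).

### Numerics

The layers are a self-contained numpy library (`multipath_unet.nn`) in
float64, with manual backpropagation: convolution via im2col, transposed
convolution via block expansion (exact because kernel = stride), max-pool
backward by argmax scatter, and the standard normalization gradients.  Every
backward pass is verified against central finite differences in the test
suite.  Spatial dropout draws one Bernoulli per (example, channel) and
rescales survivors by 1/(1−rate), so the training-mode expectation equals
the input; it is the identity at inference.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999) at initial learning rate 1e-4 with time-based
decay lr(e) = lr₀/(1 + δ·e); default δ = 5e-4, which leaves the epoch-200
rate at lr₀/1.1 — a deliberate ~9% total reduction.  The loss is the
unweighted sum of the Tversky loss (soft confusion counts on the foreground
probability channel, α = β = 0.5, smoothing constant 1.0 — at these weights
it is exactly one minus a smoothed DSC) and mean categorical cross-entropy
(probabilities clipped at 1e-7).  Both terms are computed per image and
averaged over the batch.

Epochs are capped at 200; training stops early when the epoch-mean training
loss has not improved by more than 1e-6 for 20 consecutive epochs
("improvement" = strict decrease beyond that tolerance).  After every epoch
the per-class validation DSC is computed from hard masks at threshold 0.5,
pooling pixel counts over the validation images; the per-class running
maximum is what cross-validation reports.  Five-fold cross-validation uses a
seeded random permutation split into equally sized validation folds (sizes
differ by at most one when 5 ∤ n) and a freshly initialized model per fold;
fold-level bests are aggregated as mean ± standard deviation per class.
Batch size defaults to 2 at 512×512 and is configurable.

## Preprocessing

Images are rescaled to 512×512 (bilinear, anisotropic for non-square inputs
— no padding or cropping) with Gaussian anti-aliasing when shrinking (sigma
s/3 per axis for shrink factor s), then standardized to per-image z-scores
with one mean and population standard deviation over all pixels and channels
(ε = 1e-8 guards constant images).  16-bit inputs are z-scored on their
native scale, since z-scoring removes scale anyway.  Masks are resized with
nearest-neighbor interpolation and therefore stay exactly binary.  The
pipeline is deterministic and affine-invariant (a·x + c yields the same
normalized image).

## CFU quantification

Colony counts are connected-component counts of the binary mask,
8-connectivity by default — a colony touching another diagonally is one
colony; 4-connectivity is available.  No minimum-size filter is applied by
default (very small colonies are the hard, interesting case); a size filter
can be layered on by callers.  Aggregate metrics: count MAE across images;
binning accuracy under the three food-safety intervals [0,40), [40,300),
[300,∞); and a fine-grained equal-width scheme (default 20 bins spanning
[0, max true count), last bin extended to ∞ — equal *width*, not equal
population, with the scheme object open to either choice).  Per-bin accuracy
groups records by the true bin; empty bins are reported as undefined rather
than zero.

## Synthetic test stand

`multipath_unet.synthetic` renders plate-like scenes: a circular plate on a
dark surround, smoothed low-frequency background texture, disk-shaped
colonies with a sigmoidal rim falloff (radius, contrast and count drawn from
the scene spec), and optional artifacts — thin dark glyph strokes and a
specular highlight — that are stamped into the image but never into the
mask.  A cell-scene variant replaces disks with rotated ellipses carrying a
low-order angular wobble (irregular, elongated shapes).  Placement is
rejection-sampled to keep objects disjoint (unless overlap is requested), so
the mask's 8-connected component count equals the seeded object count
exactly; placement, shape, background and artifact randomness are four
independent seeded streams, so toggling artifacts changes only image pixels.
Everything is deterministic under the scene seed.

The generator reproduces the *phenomena* that make plate segmentation hard
(small objects, texture, non-colony structures), not the statistics of any
real laboratory dataset: passing the synthetic end-to-end check shows that
the assembled architecture, loss, and counting pipeline work, and says
nothing about accuracy on real plates.

### Desk-scale study conditions

The end-to-end check trains a reduced model — pathways pool 2 / filters
[8, 16] and pool 4 / filters [8], both with bottleneck 16 — on 15 grayscale
128×128 scenes with 4–12 colonies of radius 4–10 px at contrast 0.6, using
learning rate 2e-3, batch 4, and at most 16 epochs per fold.  These sizes
were chosen once as a configuration that a single CPU trains in a few
minutes while leaving the full protocol (five folds, early-stopping rules,
per-epoch validation) intact.  The bar it is held to — best foreground DSC
above 0.9 on every fold and held-out count MAE below 2 — is an internal
sanity ceiling, not a reproduction of any published score.

## Known limitations

- Single-CPU numpy execution: the full 512×512 reference model is buildable
  and countable, but training it at that scale is impractical here; the
  training protocol is exercised at reduced scale.
- The synthetic scenes are far easier than real plates (no merged colonies,
  no inter-lab background shift, no annotation noise).
- Declumping of merged colonies (e.g. watershed) is out of scope: counts are
  component counts.
- Early stopping monitors the *training* loss, faithfully to the protocol;
  with very small folds this can stop before the validation optimum.
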