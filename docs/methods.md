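# Methods

## Problem setting

Imaging-based spatial transcriptomics assays measure, per detected cell, a
p-plex expression vector (as per-transcript positions that can be cropped
and summed per cell) together with multi-channel immunofluorescence images
— here a nuclear channel (DAPI role) and a membrane-marker channel
(CD298/B2M role).  Two cell populations are compared throughout: "normal"
(label 0) and "tumor" (label 1).  The package models the paired
(expression, image) distribution with a conditional generative model and
studies *in-silico* cellular state transitions: edit the expression of one
population toward the other and regenerate (or re-reconstruct) the images.

## Population-level expression editing

Let G_i be the n_i × p expression matrix of population i and
S_i = (1/n_i) G_iᵀ G_i its scaled **uncentered** second-moment matrix
(SCM); no mean is subtracted, matching the quantity the editing contract is
stated on (an optional centered variant is deliberately not provided — the
transform below is exact only for the uncentered form).  With
S_i = O_i diag(λ_i) O_iᵀ, λ sorted nonincreasing, the full-mode edit is

    G_i′ = G_i O_i diag(√(λ_j/λ_i)) O_jᵀ ,

giving (1/n_i) G_i′ᵀ G_i′ = S_j exactly when λ_i has no zeros.  This is a
whiten–rescale–recolor transform; the square root and the final transpose
are forced by the postcondition, which the test suite verifies to 1e-8
relative Frobenius error on random full-rank populations and exactly on the
worked 2×2 example.

Numerical conventions:

* eigenvectors get a deterministic sign (largest-magnitude entry positive,
  lowest index on ties); degenerate eigenvalues keep the symmetric solver's
  fixed output order, so repeated calls agree bit-for-bit;
* eigenvalues below −1e−10·λ_max raise; small negative round-off is clipped
  to zero;
* zero source eigenvalues use the pseudo-inverse rule (scale 0 on the null
  space); an all-zero source population is an error;
* the self-edit (identical decompositions) short-circuits to a bit-exact
  identity rather than multiplying out O O ᵀ ≈ I.

*Leading* mode keeps the full rotation sandwich but rescales only the top
eigenvalue, scale vector (√(λ_j[0]/λ_i[0]), 1, …, 1): the leading
eigenvalue dominates the spectrum and the trailing ones fluctuate.  With
coincident eigenbases the SCM perturbation is exactly |λ_j[0] − λ_i[0]| in
Frobenius norm (tested on constructed inputs).

Gene restriction: `edit_genes` is the set of genes **allowed to change**;
all other columns are copied bit-identically from the input.  The wording
of the underlying idea admits the opposite polarity (freeze the selected
genes); both are one flag apart, and this polarity is the one that yields
"edit only the genes of interest".  Restriction breaks exact SCM matching;
the achieved residual is recorded in the provenance of every edit.

Edited matrices are real-valued and may contain negative entries; clipping
at zero would break the exact-matching contract, and the generator
conditioning accepts real vectors (see standardization below).  Count-state
and post-edit matrices are distinguished by an explicit `real_valued` flag.

## Synthetic study conditions

The generator emulates the data structure the pipeline needs, with known
ground truth, at desk scale.  Defaults (`SimConfig.default`): p = 30 genes,
2000 cells per population, 32×32 crops, two driver genes.

* **Expression.**  Targets are per-population second-moment matrices
  σ = E[g gᵀ].  Draws follow a truncated-at-zero shifted Gaussian
  g = max(μ + Lz, 0) with μ = f·√diag(σ), LLᵀ = σ − μμᵀ and mean fraction
  f = 0.8 (capped at the feasibility bound f² · s̄ᵀσ⁺s̄ ≤ 1).  Truncation
  biases realized moments a few percent below the target; the exact
  realized moments follow from truncated-normal integrals and are what the
  moment tests assert against.  The defaults put the drivers at mean ≈ 2
  (normal) vs ≈ 8 (tumor) with correlation 0.6 in the tumor population,
  two "down-regulated in tumor" genes, and mildly structured background
  covariance distinct per population.  The empirical count distribution of
  real platforms is not modeled beyond nonnegativity and over-dispersion;
  any heavy-tailed choice would be defensible, and this one is chosen for
  exact moment control.  Datasets round expression to integer counts
  (transcript tables cannot hold fractional transcripts); the rounded
  matrix is the round-trip ground truth.
* **Images.**  Channel 0: centered ellipse with area
  clip(8·s + 30, 20, 0.35·S²) pixels², where s is the driver-gene sum, with
  area-preserving axis-ratio jitter (0.85–1.18) and bounded uniform noise;
  an ellipse keeps the area analytically known for oracle tests.  Channel
  1: a 3-pixel membrane ring at intensity clip(0.05·s, 0, 1) plus bounded
  noise.  Images are float in [0, 1], quantized to the 16-bit grid so that
  TIFF round-trips are bit-exact.  Only driver genes influence the image —
  the causal hook that makes editing-effect tests meaningful (verified:
  regressing segmented area on s gives positive slope, p < 0.01).
* **Layout.**  Cells sit on a non-overlapping grid of pitch S per slide;
  transcripts scatter uniformly on the integer pixel disc of radius
  S/2 − 2 around each centroid, strictly inside the cell's half-open crop
  window, so crop-and-sum recovers each cell's counts exactly.  What the
  fixture does **not** emulate: z-stacks, PSFs, segmentation errors,
  overlapping cells, 1000-plex panels.  Passing tests therefore certify the
  algorithms and their contracts, not performance on real CosMx/Xenium
  images.

Everything is a pure function of the configuration including its seed;
fixture files carry SHA-256 checksums that reproduce across runs.

## Data layer conventions

0-based pixel-center coordinates; crops are half-open windows
[c − ⌊S/2⌋, c + ⌈S/2⌉) so edge transcripts are unambiguous.  Transcripts
with missing/zero cell assignment are dropped.  Crop size defaults to
64 px for real data and 32 px in the synthetic conditions.  Slide
intensities rescale by a recorded affine (min / 99.9th-percentile when no
manifest value exists — robust to hot pixels).  Centroids outside the
slide clamp the window inside (flagged); windows partially outside are
zero-padded (flagged).

## Conditional generative model

The generator is style-based: a mapping network consumes the standardized
expression vector plus a class embedding and emits a latent w that
modulates each layer of a synthesis network seeded by a learned constant,
with per-layer noise as the only other stochasticity.  The expression
vector *is* the latent input; there is no separate random z, so a cell's
appearance is controlled by its (possibly edited) expression.  At this
package's scale the synthesis layers are style-modulated fully-connected
transforms rather than convolutions: crops are 32×32×2 and the fixture
morphology is low-dimensional, and this keeps a full training run in the
~1-minute range on one CPU.  The architectural structure that editing
relies on (mapping network, per-layer styles, noise, tanh output in
(−1, 1)) is retained.

Expression standardization: sign-preserving log1p (`sign(x)·log1p(|x|)`,
equal to log1p on counts but defined on real-valued edited vectors),
z-scored per gene with statistics frozen from the training split.  Raw
counts span decades; feeding them directly destabilizes training.

The discriminator is an MLP with projection conditioning: its penultimate
features are scored against both a binary-class embedding and a linear
embedding of the expression vector.  Conditioning on the expression — not
only the class — ties the generator to the joint (expression, image)
distribution; with label-only conditioning the generator could match both
class-conditional image marginals while orienting its expression→
morphology map arbitrarily, which would make expression editing
ineffective (or sign-reversed) at this training scale.

Objective: non-saturating logistic adversarial loss; R1 gradient penalty on
real samples (weight 10, lazily every 16 D-steps, frequency-compensated);
path-length regularization on the generator (weight 2, every 8 G-steps,
EMA decay 0.99).  Both penalties are losses on first-order gradients and
require double backprop, which the autodiff engine supports.  Adam with
β = (0, 0.99), lr 2e-3, batch 16.  Model selection: dFID (toy extractor,
subsampled) logged at every checkpoint, argmin selected.  A full-scale
profile (hundreds of thousands of iterations) is configurable but not part
of any test.

## Autodiff engine

`stedit.nn` is a compact reverse-mode automatic-differentiation engine over
NumPy arrays (float64): ~20 primitives, vector-Jacobian products expressed
as Tensor operations so gradients are themselves differentiable, with
leaky-ReLU masks treated as constants in the second pass (exact almost
everywhere).  Networks here are small enough that numerical transparency
in tests (closed-form loss values to 1e-12) outweighs speed.

## GAN inversion

Two encoders are trained against the frozen generator: a global-latent
encoder (editability pathway; also produces the L2-normalized contrastive
embedding) and a per-layer offset encoder (reconstruction pathway).  Both
image-derived terms are tanh-bounded (global scale 2.0, offset scale 1.0)
— unbounded latent heads were observed to destabilize late training, and
checkpoint selection by best SSIM guards against residual drift.  Latent
fusion is additive, w = mapping(expr, c) + global + offsets, the minimal
scheme under which expression substitution is well-defined at inference:
edited reconstruction encodes the ORIGINAL image and swaps only the
mapping term.  With unchanged expression this is bit-identical to plain
reconstruction.

Objective: λ1·L_moco + λ2·L2 + λ3·L_perc with defaults 0.1 / 1.0 / 0.2 and
temperature τ = 0.07.  L_moco is InfoNCE between embeddings of the
reconstruction (query) and a momentum copy of the encoder applied to the
input (keys; EMA momentum 0.99); other batch members are negatives, so a
batch of at least 2 is required.  L_perc is the feature-stack distance of
a fixed random-weight convolutional network — a valid perceptual metric
for testing; the interface accepts any feature stack (e.g. pretrained
weights at full scale, which are out of scope here).  A facial-identity
loss common in face-inversion work has no counterpart here and is
excluded.  PSNR/SSIM are logged on a held-out split; best-SSIM checkpoint
selected.

## Evaluation

* **dFID**: Fréchet distance ‖μ1−μ2‖² + Tr(Σ1+Σ2−2(Σ1Σ2)^{1/2}) between
  Gaussian fits to extracted features; the matrix square root uses the
  symmetric eigendecomposition of S1^{1/2} S2 S1^{1/2} with small negative
  eigenvalues clipped.  The default extractor is a fixed-seed random
  convolutional stack with global average pooling (64-D): deterministic,
  hardware-independent and sensitive to the fixture's morphology (the two
  populations sit > 3× farther apart than split-halves of one population).
  The protocol repeats the computation four times on random subsamples and
  reports mean ± sd.  Absolute dFID values depend on the feature network
  and are not comparable across extractors — only contrasts within one
  extractor are interpreted.
* **PSNR/SSIM**: reconstruction fidelity; SSIM uses the standard 11×11
  Gaussian window (σ 1.5, k1 = 0.01, k2 = 0.03), channels averaged; PSNR
  returns +inf on identical inputs.
* **Cellular features**: nuclear area from a pluggable segmenter (built-in
  fallback: Otsu threshold + connected components, centermost component);
  marker level as the marker-channel mean over a 3-pixel dilation ring of
  the nucleus mask, since the marker is membranous.  Empty masks yield
  area 0, whole-crop marker mean and a flag.
* **Expression shifts**: per-gene two-sided Mann–Whitney U with
  Benjamini–Hochberg correction across genes (the star annotations state
  p-levels only, so a standard FDR procedure is used); stars map ****
  to p ≤ 1e-4.  Constant columns return p = 1 instead of erroring.

## Editing-effect protocol and what it shows

`stedit.experiments.run_editing_effect_experiment(seed)`: simulate 2000
cells per class, smoke-train the GAN (1000 iterations, ≈1 minute on one
CPU), edit tumor→normal in full mode, regenerate, and compare three
quantities against the real normal population: dFID, mean nuclear area and
mean marker intensity (600 segmented cells per set).  The claim tested is
directional — the edit moves all three toward the normal population — and
is asserted over five seeded runs (≥ 4/5).  At these conditions the runs
typically close ~80% of the morphometric gap and reduce dFID several-fold.
Problem sizes throughout (2000 cells/class, 32×32 crops, 1000-iteration
training, 256-image dFID subsamples) are the package's desk-scale study
conditions: small enough to rerun anywhere, large enough that every
directional claim is decided by signal rather than noise.

## Known limitations

* The synthetic fixture's simplicity means generation quality saturates
  quickly; conclusions about real-tissue image fidelity require real data
  and a pretrained feature extractor, both outside the test surface.
* The fully-connected synthesis network would not scale to high-resolution
  crops; it is a deliberate desk-scale choice, not a recommendation.
* Editing matches second moments only; populations differing in higher
  moments at equal SCM are indistinguishable to the edit.
* The discriminator's expression projection is linear; richer conditioning
  might be needed where expression→morphology links are nonlinear in real
  panels.
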