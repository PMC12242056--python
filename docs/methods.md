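# Methods

`eeg2img` implements a two-stage EEG-to-image decoding pipeline at desk
scale: a contrastively trained EEG encoder aligns brain responses with
image embeddings; an embedding-space diffusion prior then refines EEG
embeddings into image-embedding space before (toy) image generation and
scoring.  Everything runs on one CPU on synthetic data with known latent
structure; no pretrained backbones are required or used.

## The synthetic data model

The generator emulates the structure of a large visual-EEG benchmark:
disjoint train/test stimulus categories (zero-shot by construction), several
images per training category and exactly one per test category, 0–1000 ms
trials, and repetition averaging.

* **Concepts.** Each category owns a unit-norm vector in image-embedding
  space (default `D_img` = 64), drawn around shared cluster centres
  (`cluster_spread` controls within-cluster correlation) so that broad
  semantic tags can be shared within clusters.
* **Image embeddings** are renormalized noisy copies of the concept
  (`sigma_img`, default 0.05).
* **EEG trials** come from a linear forward model: the concept is projected
  to `r` source coefficients through a fixed random matrix, mixed through
  per-channel spatial loadings and a unit-norm temporal basis, and corrupted
  by i.i.d. Gaussian sensor noise (`noise_sd`, default 0.1 — per-element
  SNR ≈ 1 against the ≈0.1 signal scale).  A `posterior_boost` gain
  (default 4, i.e. 16× power) concentrates signal on the six
  occipital/parieto-occipital channels O1, O2, Oz, PO3, PO4, POz, encoding
  the empirical dominance of visual-cortex electrodes.
* **Averaging** R repetitions shrinks the noise SD by 1/√R (default
  reps = 4).
* **Montages.** A 64-name 10-10 montage is the reference; an 18-channel
  subset (posterior six intact) is the desk-scale default.  The epoch is
  1 s, so `d = sampling_rate` samples; the preprocessed sampling rate is a
  free parameter (250 Hz reference, 100 Hz desk scale).

What the generator does **not** model: biophysical volume conduction (the
forward model is an arbitrary random linear map), non-stationarity,
artifacts, 1/f spectra, inter-subject variability (subjects share the
forward model and differ only through noise), and real image content.
Passing tests therefore demonstrate that the pipeline recovers the latent
structure this model plants — not performance on real recordings.

## NERV encoder

Input `(B, e, d)` trials pass through: fixed sinusoidal positional encoding
over time → a single-head transformer block over the *channel* axis
(channel attention) → two convolutional branches (spatial-then-temporal and
temporal-then-spatial, 40 feature maps each; the temporal-spatial branch is
a factorized spatiotemporal convolution whose temporal and spatial kernels
are merged at evaluation) → concatenation + linear fusion → adaptive average
pooling of the time axis to `L` tokens → 5-head self-attention → an 8-head
cross-attention block in which a learned class token queries the sequence,
its output added residually to every token → flatten (`L × 40 =
intermediate_dim`; 36 × 40 = 1440 at the reference configuration) → a fully
connected layer at that width.  A per-subject linear map
(identity-initialized, so untrained subjects are interchangeable) and a
residual GELU/dropout projection head produce the final embedding (1024-D
reference).  Head counts (5/1/8) are architecture constants; kernel size,
pooling and fusion are package choices — the constructor solves the pooled
length from `intermediate_dim` and fails loudly when the factorization is
impossible.

The network runs on a small reverse-mode autodiff core written on numpy
(`eeg2img._tensor`, `eeg2img.nn`): broadcasting arithmetic, matmul, an
unfold primitive for convolutions, softmax/layer-norm/attention, and AdamW.
Float64 throughout; gradients are verified against finite differences in
the test suite.

## Contrastive alignment

EEG and image embeddings are projected by one-hidden-layer GELU MLPs into a
shared space and scored by cosine similarity scaled by a learned
temperature, `exp(logit_scale)` with `logit_scale` initialized to
log(1/0.07) and clamped at log(100).  The loss is symmetric InfoNCE: mean
cross-entropy of the scaled similarity matrix against the diagonal, averaged
over the EEG→image and image→EEG directions.  Optimization uses AdamW with
lr 2e-4 and betas (0.5, 0.999); the nominal batch size 1024 is capped at
the dataset size.  Desk-scale runs use 80 epochs on a few hundred pairs
(~2 min); training loss identities (ln B at uniform similarity, the 2×2
closed form) are tested exactly.

## Zero-shot retrieval

Each test EEG embedding is ranked against `n_way` candidate image
embeddings (the truth plus distractors sampled without replacement from
other unseen categories) by cosine similarity; a similarity tie with any
distractor counts against the model.  Panels are resampled per trial with a
seeded generator (1000 trials default); the full-set task uses the single
deterministic panel and reports top-1 and top-5.  Presets: 2/4/10/50/100/200-way.

## Diffusion prior

The prior operates directly on embedding vectors.  Noise schedule: cosine
cumulative signal fraction `ᾱ_t = f(t)/f(0)`, `f(t) = cos²(((t/T + s)/(1 + s))·π/2)`
with offset `s = 0.008` and `T = 1000`; the terminal coefficient is floored
at 1e-9 so the ε→x₀ conversion stays finite.  The denoiser ε(I_t, t, E) is
a 6-block residual MLP with mirrored skip concatenations (3 “down”, 3 “up”
widths) — the vector-space reading of a 6-layer U-Net — each block
FiLM-modulated by a context vector built from a sinusoidal time embedding
plus the condition.  Training minimizes MSE between predicted and true
noise at uniformly sampled steps; with probability 0.10 the condition is
replaced by a learned null token (classifier-free training), and the
condition is additionally jittered by Gaussian noise (SD 0.2, renormalized)
so the conditional field generalizes to unseen EEG embeddings.  Sampling is
ancestral DDPM over an evenly strided subset of steps (50 by default) with
classifier-free guidance `ε̂ = ε_null + w·(ε_cond − ε_null)`, `w = 3.5`
default; x₀ estimates are clipped to ±5 (embeddings live near the unit
sphere) and the final step adds no noise.  The two-stage *refinement*
estimate used for evaluation and generation is the mean of 4 prior samples —
a conditional-mean estimator that trades sample diversity for variance
reduction, the desk-scale analogue of candidate selection in embedding
priors.  The prior is trained and sampled in the shared contrastive space,
where both modalities already live.

Noise prediction (rather than direct x₀ regression) and the affine guidance
form are the standard choices adopted where the source formulation is
ambiguous.

## CAT score and FID

CAT (Category-based Assessment Table) scores each generated image by how
many of the five annotation slots of its ground-truth test image it matches:
two broad categories, one specific category, one background, one attribute —
one point each, so 200 test images have a 1000-point ceiling.  Matching is
exact string equality after lowercasing/trimming; producing candidate tags
for a generated image is an external pluggable step (the pipeline's built-in
stand-in assigns each generated embedding the tag card of its
nearest-neighbour test image, so semantically correct embeddings earn that
category's points).  Whether looser matching (synonyms, partial credit)
should count is undecidable from the metric's definition; exact matching is
the implemented contract.

FID is `‖μ_r − μ_g‖² + Tr(Σ_r + Σ_g − 2(Σ_r Σ_g)^{1/2})` with 1/(n−1)
covariances; the square-root term is computed as
`Tr((Σ_r^{1/2} Σ_g Σ_r^{1/2})^{1/2})` by eigendecomposition with negative
eigenvalues (numerical noise) clipped.  The feature extractor is pluggable;
the desk-scale default is the identity on embeddings, paired with a
deterministic linear toy decoder that renders embeddings to 8×8 grayscale
images so the full generation→scoring loop is exercisable.  Small feature
clouds trigger a rank-deficiency warning rather than an error.

## Perturbation study

`perturb_channels` replaces the six posterior channels of the *test* trials
(training untouched, and perturbation is applied to the repetition-averaged
trials) with i.i.d. Gaussian noise, SD matched per channel to its empirical
SD by default (a fixed-SD mode exists for ablation); all other channels are
bitwise unchanged.  `run_perturbation_experiment` evaluates retrieval and
toy-FID under identical seeds with and without the perturbation and reports
per-subject deltas.  On generators with `posterior_boost` > 1 the
perturbation removes most of the usable signal, so accuracy falls toward
chance and FID rises; with a flat generator the deltas are correspondingly
small.

## Study configurations and problem sizes

* **Reference configuration** (structure only): 64 channels × 250 samples,
  1440-D intermediate, 1024-D embedding; 1654 train categories × 10 images
  + 200 test categories × 1 image = 16,740 unique images (counted from the
  manifest; EEG is not synthesized at that scale).
* **Scaled default** (pipeline defaults): 100 categories (80 train at 3
  images, 20 test), 18-channel montage at 100 Hz, 2 subjects, reps 4,
  noise_sd 0.1 — a full `run-all` completes in minutes.
* **High-SNR zero-shot condition** (the benchmark the heavy tests train
  on): 220 categories (200 train × 2 images, 20 test), noise_sd 0,
  `posterior_boost` 4, forward-model rank 18 — equal to the channel count,
  so the source coefficients are exactly recoverable from the sensors
  (invertible sensor map) — cluster_spread 0.5, one subject, 80 training
  epochs at batch 128.  A mini encoder (18 × 100 input, 240-D intermediate,
  64-D embedding) reaches ≈0.97 2-way zero-shot accuracy there in ~2 min.

## Numerical and design notes

* All randomness flows through explicit `numpy.random.Generator` seeds;
  training, sampling and evaluation are bit-reproducible.
* Retrieval ties break against the model (conservative reading of
  “ranked highest”).
* The subject-specific layers initialize to the identity; with weight decay
  off (the default) untrained subjects remain exactly interchangeable.
* The logit scale is learned jointly with everything else and clamped below
  100, as is standard for temperature-scaled contrastive training.
* Checkpoints are single-file `.npz` archives holding parameters, config
  and seed; round-trips are bitwise lossless in eval mode.

## Known limitations

* The autodiff core is single-threaded float64 numpy: fine at desk scale,
  not a training framework.
* Zero-shot accuracy depends on the diversity of training categories; with
  few categories the image projector overfits and transfer degrades — the
  high-SNR condition above was sized accordingly.
* The diffusion prior preserves retrieval accuracy and improves embedding
  alignment (mean cosine) on synthetic data, but large gains from two-stage
  refinement should not be expected when the raw contrastive embedding is
  already near ceiling.
* CAT here consumes tag-match decisions produced by exact string matching
  against synthetic vocabularies; it does not model the human/VLM
  adjudication loop used on real generated images.
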