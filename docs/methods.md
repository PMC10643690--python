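# Methods

`cellmol` trains two encoders — one for multi-channel fluorescence
microscopy images, one for molecular fingerprints — so that an image of
cells treated with a compound and the compound's chemical structure land
close together on a shared unit sphere.  Everything downstream (retrieval
of a structure given an image, zero-shot classification of unseen
molecules, linear probing of frozen features for bio-activity) is cosine
geometry in that space.

## Model

**Embeddings.** Encoders `h^x` (image) and `h^z` (structure) map inputs to
d-dimensional vectors, normalized to unit Euclidean norm; similarity is the
inner product `s_ij = x_i^T z_j ∈ [-1, 1]`.

**InfoNCE.** For a batch of N matched pairs, the symmetric objective

    L = -1/N Σ_i ln[ exp(τ⁻¹ s_ii) / Σ_j exp(τ⁻¹ s_ij) ]
        -1/N Σ_i ln[ exp(τ⁻¹ s_ii) / Σ_j exp(τ⁻¹ s_ji) ]

pulls matched pairs together against in-batch negatives.  The inverse
temperature τ⁻¹ scales similarities: low values concentrate the loss on
hard negatives, high values spread it over all pairs.  τ⁻¹ is a fixed
hyperparameter here (default 14.3 in the retrieval regime, 30 in the
activity regime), not a learned parameter.

**Hopfield retrieval and InfoLOOB.** The second objective first passes
both batches through continuous modern Hopfield memories.  With memory
rows M (by default the current batch: U = X for images, V = Z for
structures), a query q retrieves

    retrieve(M, q) = normalize( M^T softmax(β M q) ).

β = 0 returns the normalized memory mean for every query; β → ∞ returns
the stored row most similar to q; intermediate β (default 22) re-expresses
each embedding through the covariance structure of the batch.  Four
retrievals are formed (U_x, U_z, V_x, V_z) and scored with InfoLOOB, the
leave-one-out bound whose denominator omits the matched pair:

    L = -1/N Σ_i ln[ exp(τ⁻¹ U_xiᵀU_zi) / Σ_{j≠i} exp(τ⁻¹ U_xiᵀU_zj) ]
        -1/N Σ_i ln[ exp(τ⁻¹ V_xiᵀV_zi) / Σ_{j≠i} exp(τ⁻¹ V_xjᵀV_zi) ].

Excluding the positive pair avoids the saturation that can make the
InfoNCE bound stop learning ("explaining away").  N = 1 is rejected (the
denominator would be empty).  Both objectives are exposed as pure numpy
functions and, for training, as identical computations on the package's
autograd tensors; a test asserts the two routes agree to 1e-8.

**Numerical stability.** All log-sum-exp computations subtract a detached
per-row maximum, so both losses are finite for any finite input, including
τ⁻¹ = 30 with near-duplicate embeddings, and the InfoLOOB diagonal is
masked with a large negative constant rather than removed, keeping shapes
static.

## Encoders

The **image encoder** is a pre-activation residual network adapted to
C-channel input: a patchify convolution (non-overlapping stride = kernel,
first layer widened to C input channels) embeds each p×p patch, a learned
positional embedding is added (without it, the pooled representation would
be blind to where in the field a structure sits), and residual
fully-connected blocks act on patch features.  No nonlinearity sits on the
stem path — ReLU lives inside the blocks — so the trunk carries a full
linear image of the input alongside learned nonlinear corrections; this
matters for linear probing, where a post-stem ReLU was measured to discard
roughly a quarter of the linearly decodable signal.  The projection head
reduces the patch axis by concatenated mean + max pooling (diffuse
intensity plus sharply localized responses) and projects linearly to the
sphere.  The "penultimate feature" used for probing is the full last-stage
patch grid, flattened (patches × width): pooling belongs to the head, and
keeping the grid preserves position-resolved signal that pooled summaries
lose.  The choice of a patchify stem over a general sliding convolution is
a deliberate trade: on CPU, at the 32×32-pixel scale of the synthetic
screens, it gives residual-network behaviour at a fraction of the cost,
and the first-layer widening to 5 channels is exactly the "minor
adjustment" multi-channel microscopy requires of standard encoders.

The **structure encoder** is a descriptor-based fully-connected network on
fingerprint bits: by default 4 hidden layers of 1024 units, ReLU, batch
normalization, then the projection head.  Desk-scale runs shrink the
hidden widths (256, 256) and the embedding (d = 64); the defaults retain
the full-scale shape.

Both encoders are pure functions of (input, weights) in evaluation mode:
batch norm uses running statistics, and checkpoints (config JSON plus all
weights and buffers in one NPZ archive) round-trip embeddings
bit-for-bit.

## Training

Adam with decoupled weight decay (0.1): the decay multiplies weights
directly and never enters the moment estimates.  The learning rate ramps
linearly over a warm-up, then follows cosine annealing with hard restarts
every 7 epochs.  The nominal warm-up of 20,000 steps assumes full-scale
epochs; short runs auto-scale it to min(20,000, total_steps / 10), and the
desk-scale benchmark uses a single cosine cycle over the whole run — at a
few steps per epoch, an epoch-based restart period would trigger a restart
every few dozen steps and end runs at a high learning rate.  The base
learning rate is configurable (default 1e-3; the desk-scale benchmark uses
3e-3, chosen on the synthetic validation behaviour).  One
seed drives batch order and initialization; a fixed seed reproduces the
loss trace exactly on one device.  A non-finite loss aborts with a
diagnostic rather than continuing silently.

## Data plumbing

16-bit images are converted to 8-bit by clipping the brightest 0.0028% of
pixels per channel at the corresponding quantile and min-max rescaling to
0..255; a zero-dynamic-range channel maps to the full-scale constant 255
(shape-preserving convention for blank channels).  The clip quantile is
computed per image and channel — the protocol the conversion derives from
is ambiguous about scope, and the per-channel choice is robust to
channel-specific illumination.  Normalization statistics (per-channel
mean/SD) come from the training split only.  Crop policies: 520×520 random
(train) or centre (eval) crops for the retrieval regime; crop plus bilinear
rescale to 320×320 for the activity regime.

Molecules are featurized as 1024-bit Morgan fingerprints (radius 3,
chirality included) or as the 8192-bit element-wise max of a Morgan
fingerprint and a binarized (count ≥ 1) RDKit fingerprint folded into one
shared hash space — the spec of the "max-pooling combination" leaves the
folding order open, and one shared space is the simpler reading that
satisfies the max property bit-for-bit.  SMILES are canonicalized by the
toolkit before hashing, so kekulization variants agree.

Splits are molecule-grouped: every view of a molecule inherits the
molecule's set.  `random_by_molecule` shuffles sorted molecule ids by seed
and cuts at the cumulative fractions; `scaffold` groups by Bemis–Murcko
scaffold SMILES (the community standard where a "scaffold split" is named
but not defined) and fills sets greedily, largest group first, by largest
remaining deficit.  A test checks the greedy fill attains the enumerated
optimum on a small fixture.

External morphological feature tables are handled by dropping non-numeric
and zero-variance columns, then standardizing by training-row statistics.

## Synthetic screens

The generator emulates the *structure* of a cell-painting screen, not its
appearance.  Each molecule m has a latent phenotype t_m ~ N(0, I_k).  Its
fingerprint is sign(P t_m) for a fixed random ±1 projection P — binary
like Morgan bits and linearly decodable.  Each view renders the latent as
4 Gaussian blobs per channel sitting on a 2×2 grid over the field, with
amplitude and centre affine readouts of t_m: the amplitude carries the
bulk of the signal (exactly affine, hence linearly decodable — the
renderer is deliberately "smooth, decodable, cheap"), while centre shifts
of up to ±10% of the field add a nonlinear position component.  Pixels
get i.i.d. Gaussian noise of SD `noise_sd` on the [0, 1] intensity scale
and are quantized to 16 bits.  Under the benchmark conditions a ridge
decoder on raw pixels recovers the latent with R² ≈ 0.8, so the latent is
largely but not entirely linearly accessible — the residual nonlinearity
is what the encoders can still add.  Plates rotate with (molecule + view) mod n_plates,
so views of one molecule span plates while same-molecule/same-plate
collisions still occur whenever views exceed plates — both properties the
zero-shot plate filter needs to be exercised.  Mechanism-of-action classes
are k-means cluster indices of the latents.  One generator seed drives
every draw; identical specs are bit-identical.

Defaults (chosen once as the package's study conditions): 5 channels,
32×32 pixels (blobs of width ~4 px are fully resolved and CPU training
stays in minutes), 16-d latent, 1024-bit fingerprints, noise SD 0.3,
3 plates, 4 views.  What the generator does *not* model: cell-level
texture, segmentation-scale morphology, illumination gradients, or batch
effects beyond plate ids.  Passing tests therefore demonstrate that the
contrastive machinery recovers a shared latent from paired high-dimensional
observations under realistic noise — not that it reads real microscopy.

Activity labels are signs of random linear readouts of the latent with a
configurable flip probability and a missingness mask.  Label flips bound
the achievable AUC: with flip probability f, even a perfect decoder's
expected AUC is (1-f)² + f(1-f) (about 0.90 at f = 0.1, 0.95 at f = 0.05),
because flipped samples are ranked by a score that cannot know they were
flipped.  Probe benchmarks therefore use f = 0.02 (ceiling ≈ 0.98) so the
measured AUC reflects feature quality rather than label noise.

## Evaluation

**Retrieval.** Each query's matched candidate is ranked under descending
cosine similarity; ties break by candidate index (documented, determinism;
fixtures avoid exact ties).  Top-k accuracy (k = 1, 5, 10) is reported in
percent with exact Clopper–Pearson 95% intervals from beta quantiles.  A
subsampled 1-vs-m protocol (m drawn un-matched candidates per query) is
available.

**Zero-shot.** One reference image per class is drawn by seed; queries
exclude the references and any image sharing both molecule and plate with
its class reference, so plate effects cannot masquerade as recognition.
Classes left with no queries are dropped with a warning.  Scores are the
softmax (temperature 1) over reference cosine similarities; top-k hits are
judged on the raw similarity order, with the softmax reported for score
calibration.

**Linear probing.** One logistic regression per task on frozen features,
standardized by training-row statistics.  The L2 strength λ is selected
per task on validation AUC over a grid (default 10⁻⁶…10⁶); test AUC and F1
(at probability 0.5 — an assumption, no threshold is prescribed) are
reported with counts of tasks above AUC 0.9/0.8/0.7.  Tasks with a single
class in any split are skipped and recorded.  AUC is the rank statistic
with midrank tie handling.  In the synthetic benchmark, view features are
mean-aggregated per molecule before probing: the labels are
molecule-level, and aggregating replicate profiles per compound is the
standard practice of image-based profiling; a shuffled-label null run on
the same features reports the chance-level control.

## Desk-scale benchmark

`cellmol.workflows.run_benchmark` is the reference end-to-end experiment:
500 molecules × 4 views (2,000 pairs), 200 molecules held out entirely,
d = 64 encoders, batch 128, at most 2,000 optimizer steps (the default run
uses fewer; the loss plateaus well before the cap), one CPU core.
Retrieval evaluates one view per held-out molecule against all 200
held-out structures (chance 0.5%); zero-shot classifies held-out views
against one reference view per held-out molecule; probing fits latent-sign
labels on penultimate image features of all views.  Problem sizes were
chosen so the full benchmark completes in a few minutes.

## Known limitations

- The autograd engine supports exactly the operator set these models need;
  it is single-device, double-precision, and makes no attempt at
  performance beyond BLAS-backed matmuls.
- The Hopfield memory defaults to the current mini-batch; external
  memories are accepted through a hook but memory banks larger than the
  batch are not managed for the caller.
- The synthetic probe benchmark measures linear decodability of a latent
  through a contrastively trained encoder.  At desk scale (300 training
  molecules) contrastive training adds little linear decodability beyond
  what the pre-activation trunk already preserves; the probe result mainly
  certifies that the harness and the feature path are sound, not that
  contrastive pre-training itself aligns features (that claim needs
  full-scale data).
- The bilinear baseline is provided as scoring/objective functions; no
  trainer is wired for it.
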