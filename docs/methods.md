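# Methods

## The problem and the approach

Cell segmentation models are usually trained against one fixed labeling
strategy (a particular fluorescent marker, or label-free brightfield),
which makes strategies hard to compare and leaves models brittle when
labeling conditions change.  `stackseg` implements an alternative: each
training example is a *hyper-labeled stack* — many co-registered channels
of the same cells (three fluorescence markers and up to seven brightfield
focal planes) — and the network's 3-channel input is assembled on the fly
by a *loading code*.  Because assembly is re-randomized every time an
example is loaded, one modest dataset simulates a whole family of
labeling conditions, and different strategies can be compared on
identical cells with paired statistics.

## Loading codes

A loading code is an ordered list of per-output-channel specs.  Each spec
has a source — `Simple(name)`, `Random(candidates)` (uniform draw), or
`Merge(members, merge_dropout_rate)` — plus a `channel_dropout_rate`, the
probability that the fully resolved channel is replaced by a blank
(all-zero) image, emulating a cell whose marker is absent.

Merge semantics (a deliberate design choice): each member is
independently blanked with probability `merge_dropout_rate`, then the
pixelwise mean is taken over **all** members, dropped members
contributing zeros.  Dropout therefore *dims* the merged channel instead
of renormalizing it, and `merge_dropout_rate = 1` is exactly an all-black
channel — consistent with treating the 100% dropout row of a robustness
sweep as label-free input.  The alternative (average over surviving
members only) is available via `merge_renormalize=True`.

Single-channel codes (e.g. the cytoplasm-only model) carry one spec and
replicate the one resolved channel across all three network inputs, so
every model consumes the same 3-channel contract; `expand="pad-blank"`
substitutes blank co-channels instead.  Channel absence in a stack is an
error by default (`absence_policy="strict"`) so a missing channel cannot
silently degrade a model to the all-black control.

Summation order inside a merge is canonicalized (sorted by channel name)
so the average is exactly invariant to member order.

## The synthetic microscopy simulator

The simulator generates the structure the methodology needs, not the
physics of a microscope:

* **Geometry** — the center cell is an ellipse whose radius as a
  function of angle is perturbed by bounded low-frequency Fourier noise
  (harmonics 2–6, one `boundary_roughness` knob).  Radial contours are
  simple (non-self-intersecting) by construction.  A configurable
  fraction of cells (default 26%) is isolated; otherwise at least one
  neighbor cell touches the center cell (within 2 px).  The cell's
  position margin follows its *sampled* radius rather than the maximum,
  so smaller cells roam more; this keeps a constant-position prior (what
  an input-blind model can learn) well below what image content supports.
* **Fluorescence** — `cyto`: smooth fill reaching the contour exactly;
  `mem`: Gaussian band (sd `membrane_width`) centered on the contour;
  `mito`: point speckle blurred and strictly masked to the interior
  eroded by `mito_margin` (default 20 px at the 400 px reference scale),
  so mitochondrial signal never reaches the boundary.
* **Brightfield** — mid-gray base with smooth background texture; the
  cell interior carries organelle-scale texture (`bf_texture`) and a
  slight mean offset (`bf_interior_shift`), the learnable label-free
  signal an in-focus transmitted-light image has.  Out-of-focus planes
  add a contour-following band with signed amplitude
  `sign(offset) * rim_gain * |offset|` and width growing slowly with
  |offset|: positive defocus yields bright rims, negative dark rims, zero
  offset no rim at all.  This reproduces the peak/valley boundary
  profiles of defocused brightfield at negligible cost; it is not a PSF
  model.
* **Camera noise** is Gaussian truncated at ±3 sd, so support guarantees
  (e.g. mitochondrial signal above 3·`noise_sd` only inside eroded
  interiors) hold exactly rather than statistically.
* **Dataset structure** — per-image marker presence is independently
  Bernoulli per marker; a configurable fraction of images (default
  175/450) are cell-free negatives with all-background masks; the ground
  truth mask covers the center cell only.  Same seed ⇒ byte-identical
  files.

What the simulator does **not** emulate: real intensity statistics and
SNR, uneven illumination, instance-level labels of neighbor cells,
3-D structure, or genuine diffraction.  Passing tests on synthetic data
therefore demonstrate that the pipeline's mechanisms behave as specified
and that the *relative* ordering of labeling strategies emerges under
controlled conditions; they are not evidence about absolute accuracy on
real microscopy.

## Network

A U-Net with a ResNet34-topology descending arc (7×7 stem at stride 2,
3×3 max pool, stages of 3/4/6/3 basic blocks at widths 64/128/256/512;
total downsampling ×32) and an ascending arc that upsamples by pixel
shuffle: a 1×1 convolution expands channels fourfold and a pure index
rearrangement (`out[c, 2h+a, 2w+b] = in[4c+2a+b, h, w]`) doubles
resolution, avoiding checkerboard artifacts.  Skip connections
concatenate one encoder feature map per resolution level; two 3×3
conv-BN-ReLU layers refine each decoder level; a final pixel-shuffle
stage restores full resolution and a 1×1 head emits two-class logits.
Predicted masks are the per-pixel argmax with **ties assigned to
background**, erring against false-positive pixels.

Everything — convolution, batch norm, pooling, pixel shuffle, Adam — is
implemented directly on numpy arrays with hand-derived backward passes
(`stackseg.nn`).  Convolutions are evaluated as K² strided tensor
contractions that map to BLAS matmuls.  Every backward pass is pinned by
finite-difference gradient checks in the test suite (agreement ≲ 1e-9 in
float64).

`width_multiplier` and `blocks_per_stage` scale the topology for
CPU-scale runs; encoder initialization is random by default, with a hook
(`init_encoder_from`) for user-supplied pretrained encoder weights — no
weights are downloaded or shipped.

## Training

* **Loss** — two-class weighted cross entropy,
  `loss(x, cls) = weight[cls] · (−x[cls] + log Σⱼ exp x[j])`, with
  defaults cell = 1.0, background = 0.5: under-weighting background
  produces conservative segmentations with fewer false-positive pixels.
  Pixels are aggregated by a weighted mean (Σ weighted losses / Σ
  weights) so the weighting does not change the loss scale; the
  log-sum-exp is max-stabilized.
* **Split** — randomized 80:20 train/validation partition, seeded;
  within a comparison replicate all models share the same split and the
  same weight initialization, so differences are attributable to the
  loading codes (paired design).  Re-randomizing the split changes final
  accuracy; holding it fixed makes deterministic runs exactly
  reproducible — relative accuracy between models is therefore the
  meaningful quantity, not absolute percentages.
* **Schedule** — 1-cycle cosine: warm up from `max_lr/25` to `max_lr`
  over the first quarter of iterations (the peak equals `max_lr`
  exactly), anneal to `max_lr/1e4`.  Two phases: `frozen_epochs`
  (default 5) with the encoder frozen — parameters and batch-norm
  statistics both inert — then `unfrozen_epochs` (default 100, total
  105) with three parameter groups (early encoder, late encoder,
  decoder+head) whose peak rates interpolate geometrically across
  `lr_range_phase2` (default 2e-6 → 1e-4).  Warmup fraction and
  divisors are package defaults, exposed in the API.
* **LR finder** — geometric ramp 1e-7 → 1e-1 over 100 iterations,
  exponentially smoothed loss, early abort when the smoothed loss
  exceeds 4× its best; the suggestion is the lr at the steepest negative
  slope.  A closed-form quadratic proxy (gradient descent on
  ½λw², stable iff lr < 2/λ) anchors the suggestion logic in tests.
* **Optimizer** — Adam (β = 0.9/0.99), optional decoupled weight decay
  and global-norm gradient clipping.
* **Per-sample randomness** — every (epoch, sample) pair derives its own
  generator from `(run_seed, epoch, index)`, so loading-code dropout is
  re-rolled per sample per epoch (an augmentation, not a dataset
  attribute) while runs remain bit-reproducible.  Validation resolves
  loading-code randomness from a fixed per-(epoch, sample) stream so
  accuracies are comparable across models, and a
  `val_dropout_override` freezes the validation dropout rate for
  robustness sweeps.
* **Precise-BN refresh** — with only a handful of iterations per epoch,
  the EMA of batch-norm statistics lags the weights and makes eval-mode
  accuracy erratic; before each validation pass the running statistics
  are recomputed from the last few training batches with frozen weights
  (`bn_refresh_batches`, default 3).  Disabled by setting 0.

## Augmentation

Dihedral transforms are exact index operations; rotation, skew,
perspective/symmetric warp and jitter (interpreted as small integer
translation — the one genuinely ambiguous transform name) are composed
into a single projective warp applied with identical parameters and
identical bilinear resampling to image and mask; brightness/contrast
touch the image only; out-of-frame regions are zero-filled to avoid
twin-cell artifacts.  The mask stays continuous through the whole
geometric pipeline and is thresholded at 0.5 exactly once at the end —
this guarantees binarity and makes synchronization *exact*: a binary
image pushed through geometric-only augmentation, binarized, equals the
transformed mask pixel for pixel.  (Nearest-neighbor mask resampling was
considered and rejected: it cannot satisfy that exactness property
against a bilinearly resampled image.)  Validation applies only a
deterministic center square crop and resize to `target_size` (default
400 px, matching the full-scale input contract).

Default magnitudes (±10% brightness, ±15% contrast, rotation ±180°,
shear ±0.1, perspective ≤0.2, jitter ±4 px) are mild values chosen to
keep cells realistic; all are configurable.

## Evaluation protocols

* **Pixel accuracy** — fraction of agreeing pixels, pooled per image and
  averaged over images (unweighted); negatives are included.  A model's
  final score is the mean validation accuracy over the last 10 epochs
  (`rolling_final_accuracy`).
* **Strategy comparison** — one model per code per replicate, paired
  splits/initializations within replicates, paired two-sided t-test
  against a reference code (brightfield by default).  Zero-variance
  paired differences are reported as a degenerate case (NaN), not a
  p-value.
* **Dropout sweep** — models trained at each of a grid of dropout rates,
  each evaluated at every validation-time rate; the row range
  (max − min across validation rates) measures robustness.

## Desk-scale protocol and problem sizes

The full-scale regimen (400 px inputs, full-width ResNet34, 105 epochs)
is the package default.  The reference reproduction protocol
(`stackseg.presets`) keeps the structure and shrinks the sizes as the
package's own choice of desk-scale conditions: 96 px synthetic fields
standardized to 64 px inputs, width multiplier 0.125 with one block per
stage, 1 + 31 epochs, batch 10, peak LRs 1.5e-3 / (8e-4 → 2e-3),
gradient clipping at 2.0, rotation ±30° and perspective ≤0.1 (large
warps destroy thin membrane rims at 64 px).  Under this protocol the
acceptance suite reproduces the study's directional findings on
synthetic data: boundary-touching fluorescence (cytoplasm ≈ 97%,
membrane ≈ 98%) outranks mitochondria (≈ 92%) and brightfield (≈ 90%),
all beat the all-black control (≈ 85%); in the 3×3 merge-dropout sweep
the 50%-trained model is more consistent across validation rates than
the 0%-trained model, which in turn degrades sharply on label-free
input.

## Numerical and degenerate-case choices

* 16-bit TIFF quantization on disk (1/65535 round-trip error);
  `float32` pages for lossless storage.
* Masks: {0, 255} PNG on disk, {0, 1} in memory; any other value is an
  error naming the offending values.
* Argmax ties → background; zero-variance t-test differences → error;
  empty split side → error; input not divisible by 32 → error suggesting
  padding; non-finite training loss → abort with epoch/iteration.
* Replicate seeds are derived with a fixed stride and checked for
  collisions.

## Known limitations

* Absolute accuracies on synthetic data say nothing about real
  microscopy; only relative, directional findings transfer.
* The numpy network trains at CPU scale; the full-width 105-epoch
  regimen on 400 px data is expressible but not practical without
  hardware acceleration.
* Semantic (single-cell) masks only; no instance segmentation.
* The simulator's intensity statistics are plausible choices, not
  calibrated to any measured dataset.
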