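# Methods

## Problem

`gaitspeed` estimates the instantaneous forward speed of bipedal motion
(walking and running, 0–25 km/h) from raw windows of leg-worn IMU signals:
3-axis accelerometer and 3-axis gyroscope at up to three placements (thigh,
shin, foot).  The input is a 2 s window `X ∈ ℝ^{C×T}` (T = 1024 samples at
512 Hz, C = 6 per sensor) and the output a scalar speed `ŷ` in km/h.  No
hand-designed gait features (heel-strike detection, zero-velocity updates)
are used; the mapping is learned end to end.

## Model

The regressor is a semi-supervised variational autoencoder.  An encoder
`g_ψ` maps the window to a diagonal Gaussian posterior `q(z|X) =
N(μ_ψ(X), diag σ_ψ(X)²)` over a latent code of length L.  A draw uses the
reparameterization `z = μ + σ∘ε`, `ε ~ N(0, I)`.  Three heads consume `z`:

* a decoder `f_θ` reconstructing the window,
* a small dense prediction head `h_θ` emitting the speed,
* the closed-form KL term `KL(q ‖ N(0, I)) = ½ Σ_l (μ_l² + σ_l² − 1 − ln σ_l²)`.

The per-window training loss, with one shared latent draw for both the
prediction and reconstruction terms, is

    L(X, y) = α‖y − h_θ(z)‖² + ‖X − f_θ(z)‖² + β·KL(q ‖ N(0, I)).

`α → 0, β → 0` recovers a plain autoencoder; large `α` a feed-forward
regressor.  The reconstruction task regularizes the representation, which is
the point of the semi-supervised construction on small cohorts.

### Sine decoder

The flagship decoder exploits the quasi-periodicity of gait.  Three affine
maps generate, from `z`, channel-specific amplitudes `A = W₁z` (C×H), shared
frequencies `Ω = W₂z` (H) and phases `Φ = W₃z` (H), and the window is
reconstructed as a sum of H weighted sine waves

    X̂[c, τ] = Σ_{k=1..H} A[c,k] · sin(Ω_k·τ + Φ_k),

with τ the centered sample offsets −T/2 … T/2−1.  H is the decoder's
hidden-layer size (searchable over {10, 50, 100}).  Design choices here that
the loss formula leaves open:

* **Shape of the maps.**  A single Hadamard product of three linear maps
  cannot produce a C×T array from one z; interpreting H as a bank of sine
  components with shared (Ω, Φ) and per-channel amplitudes is the smallest
  reading that does.  The maps are affine (bias terms included); a bias-free
  mode exists and maps z = 0 to the all-zero window.
* **τ scaling.**  τ may be used as raw sample offsets (default) or
  normalized to [−1, 1) (`normalize_tau=True`), which conditions the
  frequency map better; with a 2 s window the normalized frequencies are
  then `2π·f[Hz]`.  The training experiments below use the normalized form.
* **Frequency-spread initialization.**  The frequency-map biases start at
  `2π·linspace(0.75, 12) Hz` (scaled appropriately for raw τ) so the sine
  bank covers the band that gait occupies — fundamentals of ~0.7 Hz (slow
  walk) up to the ~12 Hz harmonics of fast running — instead of clustering
  near zero frequency.  Without it, early reconstruction gradients are
  nearly uninformative and most of a short training budget is spent
  discovering the band; this is the periodic-network analogue of spreading
  first-layer frequencies in sinusoidal-activation networks.

### LSTM–deconvolution decoder

The conventional alternative mirrors the encoder: a dense map to a short
k-channel seed sequence, a single LSTM layer, then transposed convolutions
(kernel 9, stride 4) back up to ≥ T samples, center-cropped to T.  The seed
length is computed by inverting the encoder's length recursion, so the
decoder adapts to any window length.

### Encoder

Only the searchable sizes of the encoder are fixed by the protocol
(convolution channels, hidden size/depth, latent length); the topology is
this package's choice: `n_conv_layers` (default 3) valid 1-D convolutions
with kernel 9 and stride 4 and ReLU, a flatten, `hidden_depth` dense ReLU
layers, and two linear heads for μ and log σ.  σ is parameterized as
`exp(log σ)`, hence strictly positive; the log σ head's bias starts at −1 so
the posterior opens near σ ≈ 0.37.

### Training

Adam (lr 10⁻³ default), batch 64 default, one Monte-Carlo latent draw per
window per step.  Channels are standardized per channel and labels
z-scored on the training fold only.  Early stopping monitors the validation
prediction MSE once per epoch and stops after `patience = 20` consecutive
non-improving checks, restoring the best-validation weights.  Divergence
(non-finite loss) aborts with a diagnostic rather than returning silently.

Two further training options, both standard practice:

* **Loss reduction.**  Inside the estimator the reconstruction term is the
  *mean* squared error over window elements (the usual `MSELoss`
  convention), not the raw sum.  The absolute scale of the reconstruction
  term is a unit convention — training on raw physical units versus
  standardized channels already changes it by orders of magnitude — and
  with sum reduction over C×T = 6144 elements the α-weighted prediction
  term receives a vanishing share of the encoder gradient, so the
  supervised path barely trains on short budgets.  With mean reduction the
  α and β grids act on comparable scales.  The standalone `svae_loss`
  function keeps the sum form of the printed formula.
* **Tail weight averaging** (`weight_averaging=True`): a running average of
  the weights over the second half of the epochs (Polyak/SWA); at the end
  the averaged weights are adopted only if they beat the best checkpoint on
  validation.  This damps the fold-to-fold optimization noise of short
  runs.

`predict` uses the posterior mean z = μ and clips to the training label
range — speeds outside the observed range are extrapolations the model has
no support for.

The network stack is a compact reverse-mode autodiff engine over float64
numpy arrays (`gaitspeed.nn`), with exactly the primitives these models
need; float64 makes the finite-difference gradient checks in the test suite
meaningful at 10⁻⁴ relative tolerance.

## Pipeline

* **Units.**  Raw counts convert to physical units with fixed multipliers
  (accelerometer ×0.0024 → m/s², gyroscope ×0.061 → deg/s); sensors saturate
  at ±80 m/s² and ±2000 deg/s.  Saturated stretches are kept: they occur
  systematically during running and the estimator must cope with them.
* **Resampling.**  Recordings arrive at irregular ~400 Hz; each channel and
  the speed trace are linearly interpolated onto a 512 Hz grid.  Linear
  interpolation cannot overshoot on saturated plateaus, which polynomial or
  band-limited interpolation would.
* **Windowing.**  2 s windows, label = speed at index T/2 (the stated
  "middle element" of the even-length window).  Stride is configurable:
  512 samples (50 % overlap) for training, T (no overlap) for evaluation.
* **Split.**  85/15 train/validation, cut as contiguous per-subject blocks
  at a random position — random window assignment would leak samples
  between train and validation when windows overlap.
* **Augmentation** (training folds only; labels never touched): per
  augmented copy, one uniformly chosen sensor's accel and gyro triads are
  rotated by a single rotation with angle ~ N(0, 2.5°) about an axis uniform
  on the sphere (emulating a slightly different mounting), then every sample
  is scaled by (1 + η), η ~ N(0, 0.01) — relative white noise at 1 % of the
  observed value.
* **Evaluation.**  Leave-one-subject-out: the test subject contributes no
  window to training or validation and is touched exactly once per fold.
  The metric is the two-level MAE — mean over subjects of the per-subject
  mean |y − ŷ| — in km/h.
* **Hyper-parameter search.**  Uniform independent draws (default 15) from
  the protocol grids: conv channels {1,2,4,8,16}, hidden size
  {128,256,512}, hidden depth {1,2}, latent {64,128,256}, sine components
  {10,50,100}, α {0.1,…,10⁻⁴}, β {10⁻⁴,…,10⁻⁷}.

## Synthetic data generator

The generator is phenomenological, not biomechanical: it produces the
statistical structure that speed estimation exploits, so that every pipeline
stage and the end-to-end learning behaviour are testable without the real
recordings.

Per subject, a step-frequency law `f(v)` is drawn: piecewise linear with
distinct walking (`1.2 + 0.09·v` Hz) and running (`2.3 + 0.035·v` Hz)
regimes switching near 8 km/h, each coefficient perturbed per subject
(~10–20 % relative spread) so subjects have genuinely different gaits.
Each of the 18 channels is a sum of 3 harmonics of the accumulated gait
phase `2π∫f(v(t))dt` with speed-dependent amplitudes (e.g. foot
accelerometer ≈ 1.5 + 3.2·v m/s², reaching saturation at running speeds),
a static gravity component on accelerometer axes, and additive Gaussian
noise.  Placement gains (thigh 0.25, shin 0.55, foot 1.0) and noise factors
(thigh 2.0, shin 1.3, foot 1.0) make the foot the most informative sensor
and the thigh the least, matching the qualitative ordering reported for
real leg-worn recordings.  Speed profiles alternate 4–10 s dwells with
ramps bounded at 1.5 (km/h)/s, spanning ~1–24 km/h.  Timestamps are
jittered around 400 Hz; physical values are clipped at the sensor limits,
divided by the unit multipliers and rounded to integer counts, so unit
conversion, saturation and quantization are all exercised end to end.

What the generator does **not** emulate: heel-strike transients and other
waveform asymmetries, soft-tissue artifacts, sensor drift and bias
instability, magnetometer effects, and the measurement process of the
ground-truth reference.  Passing tests on synthetic cohorts therefore show
that the implementation learns the frequency/amplitude-coded speed
structure it is designed for — not that it reaches any particular accuracy
on real recordings.

## Problem sizes used in the automated checks

The end-to-end checks train a reduced configuration (latent 64, 10 sine
components, 4 convolution channels, 15 epochs, α = 0.1, β = 10⁻⁴,
normalized τ, lr 10⁻³, batch 32, weight averaging on, 2 augmented copies
per training window) on a 6-subject cohort with 5 minutes of signal per
subject, evaluated by full leave-one-subject-out against the constant-mean
predictor; the sensor-placement comparison (foot vs thigh) uses 4 subjects
× 240 s over 3 seeds with 1 augmented copy.  These sizes keep a full run
on one CPU core in the tens-of-minutes range while leaving the protocol
intact.

## Known limitations

* The autodiff engine is single-threaded numpy; it is adequate for the desk
  scale above but not for the full original protocol (8 subjects × 4
  architectures × 15 search draws).
* Frequencies/phases of the sine decoder are shared across channels;
  per-channel phase offsets are absorbed into the channel amplitudes only
  insofar as the component bank allows.
* The LSTM–deconvolution decoder is implemented for completeness and tested
  for shape, determinism and toy-problem capacity, but the training
  experiments in this repository focus on the sine decoder.
* `predict` uses the posterior mean (z = μ); predictive uncertainty from σ
  is exposed via `encode` but not propagated to a predictive interval.
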