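# Methods

This note documents the models, estimators and numerical choices behind
`icman`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Calibration and stimuli

All waveforms carry a single calibration convention: an RMS of 1
corresponds to 94 dB SPL. Levels are therefore pure rescalings
(`set_level` achieves any requested level within 0.01 dB) and no physical
pressure unit is carried. The default sampling rate is 24414.0625 Hz.

Bandpass noise is synthesized in the frequency domain — complex Gaussian
coefficients inside the band, zero outside, inverse FFT — so stated band
limits hold by construction (the only out-of-band energy is the negligible
leakage from truncating the FFT-friendly padded length). Tone, SAM and
narrowband generators use 100 ms segments with 10 ms raised-cosine ramps
and 100 ms pauses; SAM bursts use the envelope `1 + d·sin(2πf_m t)`;
narrowband maskers use a pink-noise envelope (1/f amplitude spectrum
between 1 and 100 Hz, shifted/scaled so (peak − trough)/peak = 1). Tone
streams are presented in grid order; consonant streams in seeded random
order. Pauses carry explicit `silence` labels, and every generator's
labels tile its stream exactly.

Consonant tokens are parametric synthetic stand-ins for licensed speech
corpora: 22 consonant ids are fixed to three spectral classes (ids 1–8
vowel-like: low-frequency harmonic; 9–14 plosive: broadband transient with
a band-limited tail; 15–22 fricative: high-frequency noise, ≥70% of power
above 4 kHz by construction), with a deterministic multiplicative
per-talker jitter (±12%) and small per-instance variability. Tokens are
200 ms with a 2 ms terminal ramp and 175 ms pauses, one intensity per
block. Babble sums 16 independent voice-like streams (drifting-f0
harmonic component plus pink-tilted noise under a slow syllabic
envelope); `mix_at_snr` sets the speech-to-noise ratio over the speech's
active (non-pause) samples.

## WDRC hearing aid

The simulated aid splits the input at 9 fixed crossovers (200…8500 Hz)
into 10 channels. The split uses zero-phase complementary Butterworth
pairs: forward–backward filtering of an order-2 Butterworth gives a real
transfer function equal to the squared magnitude, and Butterworth low/high
pairs are power-complementary, so each crossover's two branches sum to
exactly unity and the 10 bands sum to the input. Per channel, a one-pole
mean-square envelope follower with separate attack (5 ms) and release
(40 ms) coefficients `α = exp(−1/(τ·rate))` tracks the band level
(RMS-domain tracking; results at sharp transients would differ under
peak tracking, which the configuration does not expose). The static gain
rule applies the channel gain below the compression knee and 1 dB of
output per `ratio` dB of input above it; the analytic rule is continuous
at the knee. `static_io_curve` measures the settled response of one
channel in isolation so cross-band leakage (amplified differently per
band) cannot bias the slope; band-filter attenuation at the probe
frequency adds a constant offset that cancels in slopes.

`fit_from_audiogram` is a deliberately simple deterministic prescription
standing in for clinical fitting software: gain = 0.7 × interpolated
threshold shift at the channel center (clipped to [0, 30] dB), ratio
scaling linearly from 1 to 2.5 with gain. For a sloping mild-to-moderate
loss this lands near 10 dB of gain at low and 30 dB at high frequencies.

## Synthetic population recordings

The generator produces the statistical structure the downstream analyses
assume, with recorded ground truth:

1. **Tuning**: each unit has a characteristic frequency (log-spaced
   500–8000 Hz), a threshold (15 dB SPL baseline) and a Gaussian (in
   log-frequency) band of width 0.5 octaves. Its *drive* is a sigmoid
   (8 dB slope) of the per-bin band level relative to threshold. Bins are
   32 samples = 1.3108 ms.
2. **Latents**: units are partitioned into `signal_dim` CF groups; the
   true latents are the ZCA-whitened group-mean drives. Whitening is a
   design choice: tuning overlap correlates neighbouring group envelopes,
   and decorrelating them gives every latent dimension equal, independent
   variance — the "well-separated" regime in which latent dimensionality
   is a well-posed recovery target. Latents are identical across trials
   by construction.
3. **Rates**: `u = softplus(gain·(mixing @ latents) + bias)` with
   nonnegative block-dominant mixing (unit weight on the own-group latent,
   5% random cross-talk). Each unit's modulation is then standardized to
   a common mean and variance (rare sub-zero excursions clipped at zero),
   so all units contribute equal signal variance and the signal
   eigen-spectrum stays flat across dimensions. The default softplus bias
   (2.5) keeps the link near-linear; lowering it makes responses sparser
   and the spectrum less flat, degrading recovery of high dimensionalities
   first.
4. **Noise and the signal share**: counts are Poisson per (trial, unit)
   from independent child streams (adding units never perturbs existing
   ones). For a Poisson unit, signal variance is the variance of the rate
   and noise variance its mean, so the share `s` is enforced exactly in
   closed form by the per-unit scale `c = s·μ_u / ((1−s)·σ_u²)`; the
   default `signal_var_fraction = 0.4` mirrors the ~40% trial-reproducible
   share typical of real midbrain recordings. Realized mean counts land
   near 1.5–3 per 1.31 ms bin.

`make_probe_stimulus` provides the matched stimulus: 8 log-spaced noise
bands over 500–8000 Hz, each gated by an independent sparse slow envelope
(half-wave-rectified-squared 0.5–10 Hz noise), so band levels swing
through unit thresholds and different CFs are driven independently.

What the generator does **not** emulate: biophysical cochlear filtering,
adaptation and refractoriness, non-Poisson count statistics, correlated
(shared) trial-to-trial noise, across-trial drift, or the clustered
phenomenology of real hearing-loss dynamics. Passing tests therefore show
that the estimators recover the structure they are defined on — not that
real recordings contain that structure.

Raw-trace synthesis inserts a biphasic template (0.6 ms, positive peak
first) at given times into Gaussian noise bandlimited to 300–6000 Hz and
rescaled to a known SD. Evoked-sweep synthesis scales an ABR-like wavelet
by a sigmoid of (level − threshold) calibrated so the response RMS crosses
twice the silence RMS exactly at threshold in expectation, making
threshold recovery a meaningful ±5 dB test.

## Preprocessing

MUA extraction: zero-phase Butterworth bandpass 700–5000 Hz (order 2
twice, −3 dB cutoffs; the filter family is a configuration knob), noise SD
as MAD/0.6745, events at positive crossings of 3.5 SD, crossings within
1 ms merged (prevents double counts from one spike waveform), bins
anchored at t = 0 and half-open. At a 3.5 SD threshold, Gaussian
upcrossing theory (Rice's formula) predicts an irreducible false-event
rate of a few per second in this band; the tests treat that rate as the
oracle for noise-only traces rather than pretending spurious events can
be eliminated. Unit selection keeps units whose two-repeat correlation is
at least 0.2. The evoked-threshold rule returns the lowest level at which
the median-response RMS exceeds twice the silence RMS, `inf` when none
does; it is monotone (adding evoked signal never raises it).

## Manifold estimators

PCA is fit on row-mean-subtracted training activity (units are not
z-scored — only mean subtraction is part of the procedure). The headline
"variance explained" statistic is implemented literally as the normalized
covariance `cov(A, B)/√(var(A)·var(B))` over all matrix entries — a
correlation-like quantity — with a conventional R² (`1 − SSE/SST`)
variant exposed via `statistic="r2"`. Signal variance explained
reconstructs test-trial-1 activity from its projection and compares to
test trial 2 (with trial 2's row means restored); only trial-reproducible
structure survives. Cross-trial covariance estimators use the unbiased
(n−1) normalization, and all-zero time bins are retained.

Signal dimensionality is the smallest D whose curve value reaches 95% of
the curve's plateau; a curve still rising steeply at its end returns a
sentinel (None). The dimensionality-recovery suite runs on the R² curve:
with the generator's flat signal spectrum the normalized-covariance curve
rises like √D, which puts the 0.95 criterion exactly at the
√(9/10) ≈ 0.949 knife edge for 10 dimensions, whereas the R² curve rises
linearly in D ((dim−1)/dim = 0.90 at worst) and makes recovery
well-posed. Recovery holds for dimensionalities 2–10 with 40 units and
≈50k bins.

Cross-animal similarity regresses one set of latent dynamics on another
(OLS with intercept, in-sample, matching the definition of the
procedure; an optional train/test split is available through the caller)
and reports pooled `1 − SSE/SST`.

## Encoder

Architecture: 48 learnable sinc bandpass kernels of length 32 (band edges
parameterized as `f1 = 50 + |p1|`, `f2 = f1 + 50 + |p2|` Hz, mel-spaced
initialization over 50–12000 Hz, Hamming window, half-integer-centered
grid so no zero sample), symmetric-log activations
`sign(x)·log(1+|x|)`; five conv layers of 128 filters, kernel 32,
stride 2, per-channel PReLU; a bottleneck conv layer (`Db` filters,
default 8, kernel 32, stride 1, PReLU); and a per-unit linear readout
with exponential activations interpreted as expected counts per 1.3108 ms
bin. The cumulative stride is 2⁵ = 32, taking 8192-sample frames at
24414.0625 Hz to 256 bins at 762.9395 Hz, of which 32 are cropped at each
end (training frames of 192 bins) to remove convolutional edge effects.
Convolutions use "same"-style padding. The LN baseline keeps stages 1 and
4 with a single 128-filter kernel-256 convolution between them; its
stride is 32 so both models emit the same frame grid.

Training is single-precision Adam on the Poisson loss (gradient of the
exponential readout is simply `R̂ − R`), with seeded initialization and
batch order, a global gradient-norm clip of 10, and an abort-with-
diagnostic on non-finite loss. Streams are predicted with overlapped
frames whose cropped centers tile the timeline, so n·8192 input samples
yield n·192 + remainder bins contiguously; the crop must cover the
receptive-field half-width (24–32 bins depending on widths). Transfer
learning freezes all encoder parameters (verified bitwise in tests) and
retrains only the readout, initialized per unit from a randomly chosen
unit of the source animal (with replacement when unit counts differ).

Desk-scale configuration: the paper-scale widths train for hours, so the
scaled experiments use `EncoderSpec.small` (16 sinc filters, 24 conv
filters, kernel 16, LN kernel 64) with the stride schedule intact, 5
minutes of synthetic audio, 2 epochs, batch 16, and learning rate 3e-3
(the 1e-4 default belongs to the full-scale regime). Under that
configuration held-out Poisson loss drops strictly (≈0.48 → 0.31 per
bin) and the deep model reaches ~46% mean explainable variance explained
versus ~14% for the LN baseline on data from the nonlinear generator.

Validation uses explainable variance explained: per unit,
`100 · cov(Rtest1, R̂) / cov(Rtest1, Rtest2)`; units with non-positive
across-repeat covariance are excluded.

## Latent-dynamics comparison

RDMs: per-sound trajectories (all channels' time courses concatenated),
entries `1 − Pearson correlation`; consonant trajectories are averaged
across instances before RDM computation; similarity between RDMs is the
Pearson correlation of vectorized upper triangles. RDMs are invariant to
global scaling of all trajectories but not to per-channel rescaling.
Best intensity maximizes RDM (or CCA) similarity over candidate levels,
ties broken toward the lower level; CCA alignments are refit per
candidate intensity.

CCA uses the thin-SVD whitening route (equivalent to QR + SVD): the
singular values of the whitened cross-product are the canonical
correlations, verified in tests against the generalized-eigenvalue
solution on sample covariances. Rank-deficient dynamics are reduced to
their numerical rank and flagged. The similarity statistic is
`Σ_d ρ(U_d, V_d) · (ρ(X̂_d, X)² + ρ(Ŷ_d, Ŷ)²)/2`, where `X̂_d` is the
d-th rank-1 term of the exact expansion `X = U A⁺` (pseudo-inverse of the
canonical weight matrix). Under this reading the weights partition the
total variance (they sum to 1 for full-rank dynamics), the statistic
equals 1 exactly when the two sets of dynamics are invertible linear
transforms of each other, and it degrades monotonically under added
noise. MCCA concatenates the per-dataset whitened components (relative
eigenvalue floor 1e-8) and extracts joint components by PCA; for two
datasets the leading component correlations agree with pairwise CCA.

Decoding uses one-vs-one linear support-vector classifiers over all class
pairs with max-wins voting (the native multiclass rule of the underlying
SVC), C = 1, and stratified tenfold cross-validation; with 22 balanced
classes the permutation-null accuracy is 1/22 ≈ 4.5%. Envelope tracking
is the coefficient of variation of the condition-mean activation time
course, averaged over channels with positive mean. Masking grids present
each narrowband target alone and summed with each masker (identical
target waveform) and report the point-by-point correlation of the two
activation matrices per (target CF, masker CF, level).

Correlation throughout is Pearson on mean-centered vectors; constant
vectors are excluded with a warning.

## Pipeline and reproducibility

Experiment bundles are driven by a fully serializable config whose
content hash (output directory excluded) and root seed determine every
artifact; named substreams (stimulus, population, trials) derive from the
root seed by hashing, and re-running an identical config reproduces
byte-identical CSVs. Manifests record completed stages so partial runs
resume. WAV output rounds the sample rate to an integer (the exact rate
lives in the label sidecar and HDF5 attributes).

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to keep the
statistics meaningful: 20–70 s probe stimuli (15k–53k bins), populations
of 12–40 units, three trials, 5 minutes of training audio for the encoder
experiments, and 20 permutation seeds for the decoder chance level. The
full suite runs in a few minutes on one CPU.

## Known limitations

* The generator's equal-variance, whitened-latent construction is
  deliberately favourable to dimensionality recovery; real signal spectra
  decay, and the 95%-of-plateau criterion then measures an *effective*
  dimensionality that depends on the spectrum's shape.
* The WDRC band split is zero-phase and therefore non-causal;
  per-channel group delay of a deployable aid is not modelled.
* Consonant tokens and babble are spectral-class caricatures; decoding
  accuracies on them are not comparable to accuracies on real speech.
* The encoder is trained at reduced width and duration; absolute
  explainable-variance numbers at full scale would differ.
* No statistical-comparison machinery (omnibus tests across animal
  pairs) is provided beyond tidy tables; real-data significance values
  are out of scope.
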