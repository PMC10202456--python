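# icman

Signal-manifold analysis of auditory midbrain population dynamics under
hearing loss, on synthetic data with recorded ground truth.

## The scientific problem

Sensorineural hearing loss does more than raise thresholds: it distorts how
sound is represented by neural populations in the auditory midbrain
(inferior colliculus, IC), in ways that amplification cannot fully undo.
A productive way to study this is to look not at single neurons but at the
population's *signal manifold* — the low-dimensional linear subspace that
contains the trial-reproducible, sound-evoked component of activity — and
ask how the *signal dynamics* (trajectories within that subspace) change
with hearing loss, with amplification to a best intensity, and with a
simulated hearing aid.

`icman` implements that analysis chain end to end for researchers who want
to exercise, validate, or extend it at desk scale:

* **Stimulus synthesis** (`icman.stimgen`) — calibrated pure-tone grids
  (500–8000 Hz in 0.2-octave steps × 25–100 dB SPL in 5 dB steps),
  sinusoidally amplitude-modulated (SAM) bandpass noise sweeping modulation
  frequency (10–240 Hz) or depth (0.1–1 in 20 log steps), narrowband
  target/masker pairs, parametric consonant-like tokens in three spectral
  classes, and multi-talker babble. Levels follow the convention that unit
  RMS = 94 dB SPL.
* **Hearing-aid simulation** (`icman.hearing_aid`) — a 10-channel
  wide-dynamic-range-compression (WDRC) aid: fixed crossovers, per-channel
  knees/gains/ratios, 5 ms attack / 40 ms release.
* **Synthetic recordings** (`icman.synthetic_ic`) — trial-structured spike
  counts (1.31 ms bins) with a known low-dimensional signal, Poisson noise,
  per-unit frequency/intensity tuning, and configurable sloping hearing
  loss; plus raw-voltage traces and evoked-potential sweeps for testing the
  preprocessing stage.
* **Preprocessing** (`icman.preprocess`) — multi-unit activity (MUA) via
  700–5000 Hz filtering, MAD/0.6745 noise estimation, and 3.5 SD positive
  threshold crossings; repeat-reliability unit selection; the
  evoked-threshold rule (lowest level whose median response RMS exceeds
  twice the silence RMS).
* **Manifold analysis** (`icman.manifold`) — PCA on training activity,
  total/signal variance explained of test reconstructions, signal
  dimensionality (95% of plateau), per-PC signal fractions, and
  cross-animal similarity by linear regression of one set of latent
  dynamics onto another.
* **Encoder model** (`icman.encoder`) — a convolutional sound-to-activity
  network: learnable sinc bandpass front end with symmetric-log
  activations, five stride-2 conv layers (decimation 32×: 24414.0625 Hz
  audio → 762.9395 Hz bins), a low-dimensional bottleneck whose activations
  are the model's latent dynamics, and a per-unit linear–exponential
  readout trained with the Poisson loss `Σ (R̂ − R·log R̂)`. Includes a
  linear–nonlinear (LN) baseline, transfer learning with a frozen encoder,
  and the explainable-variance-explained validation metric. Implemented in
  NumPy with hand-written backpropagation and Adam.
* **Latent-dynamics comparison** (`icman.latent`) — representational
  similarity analysis (RDMs of 1 − correlation between per-sound
  trajectories), CCA alignment with a variance-weighted similarity
  statistic, multiway CCA for joint alignment, best-intensity selection,
  envelope-tracking strength, frequency response areas, consonant decoding
  (one-vs-one linear SVMs, max-wins voting, tenfold CV), and target/masker
  correlation grids.
* **Orchestration** (`icman.pipeline`, `icman` CLI) — seeded, resumable
  experiment bundles with tidy CSV outputs and pairwise similarity reports.

## Worked example

```python
import numpy as np
from icman import (HearingProfile, best_intensity, fit_pcs, make_population,
                   make_probe_stimulus, project, rdm_similarity,
                   signal_dimensionality, signal_noise_stats, simulate_response)
from icman.latent import compute_rdm, segment_dynamics
from icman.manifold import signal_variance_explained
from icman.stimgen import make_tone_stream, tone_freq_grid

probe = make_probe_stimulus(40.0, seed=0)
pop = make_population(n_units=32, signal_dim=5, signal_var_fraction=0.4, seed=1)
rec = simulate_response(probe, pop, n_trials=3, seed=2)

stats = signal_noise_stats(rec.trial(1), rec.trial(2))
print(f"median signal share of variance: {np.median(stats.signal_share):.2f}")

basis = fit_pcs(rec.trial(0))
curve = [signal_variance_explained(rec.trial(1), rec.trial(2), basis, D,
                                   statistic="r2") for D in range(1, 16)]
print(f"estimated signal dimensionality: {signal_dimensionality(np.array(curve))}"
      f" (true {pop.signal_dim})")

hl = make_population(n_units=32, signal_dim=5, signal_var_fraction=0.4,
                     hearing=HearingProfile.sloping(15.0, 45.0), seed=1)
freqs = tone_freq_grid()[::4]

def tone_rdm(population, level):
    w, labels = make_tone_stream(freqs=freqs, levels=np.array([level]))
    r = simulate_response(w, population, n_trials=1, seed=3, labels=labels)
    dyn = project(r.trial(0), fit_pcs(r.trial(0)), D=5)
    dyn.bin_s = r.bin_s
    return compute_rdm(segment_dynamics(dyn, labels, kinds=("tone",)))

ref = tone_rdm(pop, 55.0)
same = rdm_similarity(ref, tone_rdm(hl, 55.0))
lvl, best = best_intensity(ref, {l: tone_rdm(hl, l)
                                 for l in (55.0, 70.0, 85.0, 100.0)})
print(f"tone RDM similarity, normal vs hearing loss at 55 dB SPL: {same:.2f}")
print(f"best intensity for the hearing-loss model: {lvl:.0f} dB SPL "
      f"(similarity {best:.2f})")
```

Output:

```
median signal share of variance: 0.40
estimated signal dimensionality: 5 (true 5)
tone RDM similarity, normal vs hearing loss at 55 dB SPL: 0.64
best intensity for the hearing-loss model: 70 dB SPL (similarity 0.65)
```

Reading the numbers: the generator is built so that 40% of each unit's
count variance is trial-reproducible signal, and the estimator recovers
that share. The signal-variance-explained curve saturates at the true
latent dimensionality (5). Simulated sloping hearing loss (15 dB low → 45
dB high frequencies) distorts the representational geometry of tones —
the point-by-point RDM correlation with the normal-hearing model drops to
0.64 at matched 55 dB SPL — and presenting the tones louder (best
intensity 70 dB SPL) recovers audibility but only part of the similarity,
the signature of a distortion that is not a pure sensitivity loss.

## CLI

```sh
icman stimgen tones --out tones.wav --labels tones.csv --seed 1
icman wdrc tones.wav aided.wav            # built-in sloping-loss fit
icman run experiment.json                 # end-to-end bundle
icman report out_nh/ out_hl/              # pairwise similarity tables
```
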