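"""Synthetic auditory-midbrain population recordings with known ground truth.

The generator emulates the statistical structure that the manifold and
encoder analyses assume about real multi-unit recordings:

* a low-dimensional, trial-reproducible *signal* component shared across
  units (the true latent trajectories are recorded for parameter-recovery
  tests),
* independent per-trial Poisson *noise*,
* per-unit frequency/intensity tuning (a band envelope around the unit's
  characteristic frequency passed through a level sigmoid),
* configurable sloping hearing loss: elevated thresholds and broadened
  tuning.

Construction of a response: each unit's stimulus drive is the dB level of a
band envelope at its characteristic frequency passed through a threshold
sigmoid. Units are partitioned into ``signal_dim`` characteristic-frequency
groups and the true latents are the (variance-normalized) group-mean drives,
so each latent has a distinct spectral footprint. Unit rates are
``c * softplus(gain * (mixing @ latents) + bias)`` with nonnegative,
block-dominant mixing; ``c`` is set per unit in closed form so that the
expected trial-reproducible share of count variance equals
``signal_var_fraction`` under Poisson noise (signal variance = var of the
rate, noise variance = mean rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .waveform import Waveform, StimulusLabel

#: Default bin width: 32 samples at 24414.0625 Hz.
DEFAULT_BIN_S = 32.0 / 24414.0625

AUDIOGRAM_FREQS = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)


@dataclass
class HearingProfile:
    """Audiometric threshold elevations (dB) at the standard frequencies."""

    shift_db: dict

    def __post_init__(self) -> None:
        self.shift_db = {float(k): float(v) for k, v in self.shift_db.items()}
        for v in self.shift_db.values():
            if not np.isfinite(v):
                raise ValueError("threshold shifts must be finite")

    @classmethod
    def normal(cls) -> "HearingProfile":
        return cls({f: 0.0 for f in AUDIOGRAM_FREQS})

    @classmethod
    def sloping(cls, low_db: float = 15.0, high_db: float = 40.0) -> "HearingProfile":
        """Sloping mild-to-moderate loss interpolated across the audiogram."""
        fr = np.log2(np.array(AUDIOGRAM_FREQS) / 500.0) / 4.0
        return cls({f: low_db + (high_db - low_db) * x
                    for f, x in zip(AUDIOGRAM_FREQS, fr)})

    def shift_at(self, freq_hz: float) -> float:
        """Threshold shift interpolated linearly in log-frequency."""
        fs = np.array(sorted(self.shift_db))
        vals = np.array([self.shift_db[f] for f in fs])
        return float(np.interp(np.log2(freq_hz), np.log2(fs), vals))

    def is_sloping(self) -> bool:
        fs = sorted(self.shift_db)
        vals = [self.shift_db[f] for f in fs]
        return all(b >= a for a, b in zip(vals, vals[1:]))


@dataclass
class PopulationSpec:
    """Generative parameters of a synthetic population."""

    n_units: int
    cf_hz: np.ndarray
    threshold_db: np.ndarray
    tuning_bw_octaves: np.ndarray
    signal_dim: int
    signal_var_fraction: float
    mixing: np.ndarray          # units x signal_dim, nonnegative
    noise_scale: float = 1.0
    drive_gain: float = 1.0     # slope into softplus
    drive_bias: float = 2.5     # offset into softplus (sets link curvature)

    def __post_init__(self) -> None:
        if self.signal_dim > self.n_units:
            raise ValueError("signal_dim must not exceed n_units")
        if not 0.0 < self.signal_var_fraction < 1.0:
            raise ValueError("signal_var_fraction must be in (0, 1)")
        if np.any(self.mixing < 0):
            raise ValueError("mixing weights must be nonnegative")
        if self.mixing.shape != (self.n_units, self.signal_dim):
            raise ValueError("mixing must be n_units x signal_dim")


@dataclass
class SimulatedRecording:
    """Trial-structured spike counts with recorded ground truth."""

    counts: np.ndarray        # trials x units x bins, nonnegative integers
    true_latents: np.ndarray  # signal_dim x bins, identical across trials
    rates: np.ndarray         # units x bins, the Poisson means (ground truth)
    bin_s: float = DEFAULT_BIN_S
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be trials x units x bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def trial(self, i: int) -> np.ndarray:
        """Units x bins count matrix for one trial (an R matrix)."""
        return self.counts[i]


def make_population(n_units: int = 64, signal_dim: int = 6,
                    signal_var_fraction: float = 0.4,
                    hearing: HearingProfile | None = None,
                    seed: int = 0,
                    base_threshold_db: float = 15.0,
                    base_bw_octaves: float = 0.5,
                    broadening_at_30db: float = 2.0) -> PopulationSpec:
    """Build a population spec, applying a hearing profile if given.

    Characteristic frequencies are log-spaced over 500-8000 Hz. Hearing loss
    raises each unit's threshold by the interpolated audiogram shift at its
    CF and multiplies the tuning bandwidth by a factor that reaches
    ``broadening_at_30db`` at a 30 dB shift.
    """
    if n_units < signal_dim:
        raise ValueError("need at least signal_dim units")
    rng = np.random.default_rng(seed)
    cf = np.geomspace(500.0, 8000.0, n_units)
    thr = np.full(n_units, base_threshold_db)
    bw = np.full(n_units, base_bw_octaves)
    if hearing is not None:
        shift = np.array([hearing.shift_at(f) for f in cf])
        thr = thr + shift
        bw = bw * (1.0 + (broadening_at_30db - 1.0) * shift / 30.0)
    # block-dominant nonnegative mixing: each unit loads mostly on the latent
    # of its CF group, with weak random cross-talk
    group = np.minimum((np.arange(n_units) * signal_dim) // n_units, signal_dim - 1)
    mixing = 0.05 * rng.uniform(0.0, 1.0, (n_units, signal_dim))
    mixing[np.arange(n_units), group] = 1.0
    return PopulationSpec(n_units=n_units, cf_hz=cf, threshold_db=thr,
                          tuning_bw_octaves=bw, signal_dim=signal_dim,
                          signal_var_fraction=signal_var_fraction,
                          mixing=mixing)


def _band_levels_db(w: Waveform, cfs: np.ndarray, bws: np.ndarray,
                    bin_samples: int) -> np.ndarray:
    """Per-bin band levels (dB SPL) of Gaussian-shaped bands around each cf.

    The stimulus spectrum is computed once (zero-padded to an FFT-friendly
    length) and each unit's band is synthesized by a masked inverse FFT.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n = w.n_samples
    nf = next_fast_len(n, real=True)
    spec = rfft(w.samples, nf)
    freqs = np.fft.rfftfreq(nf, 1.0 / w.rate_hz)
    log_f = np.log2(np.maximum(freqs, 1e-6))
    n_bins = n // bin_samples
    out = np.empty((cfs.size, n_bins))
    for i, (cf, bw) in enumerate(zip(cfs, bws)):
        h = np.exp(-0.5 * ((log_f - np.log2(cf)) / (bw / 2.0)) ** 2)
        band = irfft(spec * h, nf)[: n_bins * bin_samples]
        rms = np.sqrt(np.mean(band.reshape(n_bins, bin_samples) ** 2, axis=1))
        out[i] = w.spl_ref_db + 20.0 * np.log10(rms + 1e-12)
    return out


def unit_drives(w: Waveform, pop: PopulationSpec,
                bin_samples: int = 32, sigmoid_slope_db: float = 8.0) -> np.ndarray:
    """Units x bins stimulus drives in [0, 1] (tuning sigmoid of band level)."""
    w._require_calibration()
    levels = _band_levels_db(w, pop.cf_hz, pop.tuning_bw_octaves, bin_samples)
    return 1.0 / (1.0 + np.exp(-(levels - pop.threshold_db[:, None])
                               / sigmoid_slope_db))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_response(w: Waveform, pop: PopulationSpec, n_trials: int,
                      seed: int = 0,
                      labels: list[StimulusLabel] | None = None) -> SimulatedRecording:
    """Simulate trial-structured spike counts for a calibrated waveform.

    The signal (rates and latents) is computed once and shared by all trials;
    only the Poisson draws differ across trials. Random streams are spawned
    per (trial, unit) so adding units never perturbs existing ones.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    bin_samples = int(round(DEFAULT_BIN_S * w.rate_hz))
    drives = unit_drives(w, pop, bin_samples)
    dim = pop.signal_dim
    group = np.minimum((np.arange(pop.n_units) * dim) // pop.n_units, dim - 1)
    latents = np.stack([drives[group == d].mean(axis=0) for d in range(dim)])
    latents = latents - latents.mean(axis=1, keepdims=True)
    # symmetric (ZCA) whitening: tuning overlap correlates neighbouring
    # group envelopes, so decorrelate to give the latent dimensions equal,
    # independent variance while staying close to the CF-group structure
    C = np.cov(latents) + 1e-9 * np.eye(dim)
    evals, evecs = np.linalg.eigh(C)
    latents = (evecs @ np.diag(evals ** -0.5) @ evecs.T) @ latents

    u = _softplus(pop.drive_gain * (pop.mixing @ latents) + pop.drive_bias)
    # standardize each unit's modulation to a common operating point so all
    # units contribute equal signal variance (keeps the signal spectrum flat
    # across latent dimensions); rare sub-zero excursions are clipped
    u = (u - u.mean(axis=1, keepdims=True)) / np.maximum(
        u.std(axis=1, keepdims=True), 1e-9)
    u = np.maximum(u + 1.5, 0.0)
    mu = u.mean(axis=1)
    var = u.var(axis=1)
    s = pop.signal_var_fraction
    # closed-form per-unit scale: share = c*var/(c*var + mean) == s
    c = s * mu / ((1.0 - s) * np.maximum(var, 1e-12)) * pop.noise_scale
    rates = c[:, None] * u

    counts = np.empty((n_trials, pop.n_units, rates.shape[1]), dtype=np.int64)
    for tr in range(n_trials):
        for ui in range(pop.n_units):
            rng = np.random.default_rng([seed, tr, ui])
            counts[tr, ui] = rng.poisson(rates[ui])
    return SimulatedRecording(counts=counts, true_latents=latents, rates=rates,
                              bin_s=bin_samples / w.rate_hz,
                              labels=list(labels) if labels else [])


def make_probe_stimulus(duration_s: float, seed: int = 0,
                        rate_hz: float = 24414.0625, n_bands: int = 8,
                        level_db_spl: float = 70.0) -> Waveform:
    """Spectrally rich probe: independently gated octave-band noises.

    Each of ``n_bands`` log-spaced bands over 500-8000 Hz carries its own
    sparse slow envelope (half-wave-rectified-squared 0.5-10 Hz noise), so
    band levels swing through unit thresholds and different characteristic
    frequencies are driven independently -- the "well-separated spectra"
    regime the latent-recovery analyses assume.
    """
    from .stimgen import bandpass_noise

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    edges = np.geomspace(500.0, 8000.0, n_bands + 1)
    x = np.zeros(n)
    for b in range(n_bands):
        car = bandpass_noise(n, rate_hz, edges[b], edges[b + 1], rng)
        env = np.maximum(bandpass_noise(n, rate_hz, 0.5, 10.0, rng), 0.0) ** 2
        band = car * env
        rms = np.sqrt(np.mean(band ** 2))
        x += band / max(rms, 1e-12)
    w = Waveform(x, rate_hz)
    target = 10.0 ** ((level_db_spl - 94.0) / 20.0)
    return w.replace(samples=w.samples * (target / w.rms()))


# ---------------------------------------------------------------------------
# raw traces and ABR sweeps (test inputs for the preprocessing stage)
# ---------------------------------------------------------------------------

def spike_template(rate_hz: float, width_ms: float = 0.6) -> np.ndarray:
    """Biphasic extracellular spike template, unit positive peak first."""
    n = max(int(round(width_ms * 1e-3 * rate_hz)), 8)
    t = np.linspace(-1.0, 1.0, n)
    tpl = np.exp(-((t + 0.3) / 0.25) ** 2) - 0.55 * np.exp(-((t - 0.35) / 0.4) ** 2)
    return tpl / tpl.max()


def synthesize_raw_trace(spike_times: np.ndarray, noise_sd: float,
                         rate_hz: float, seed: int = 0,
                         duration_s: float | None = None,
                         spike_amplitude: float | None = None) -> np.ndarray:
    """Raw voltage trace: spike templates at given times plus bandlimited noise.

    Noise is Gaussian bandlimited to the recording band (300-6000 Hz) and
    rescaled to standard deviation ``noise_sd``. Overlapping templates sum.
    Default spike amplitude is 10x the noise SD.
    """
    spike_times = np.asarray(spike_times, float)
    if duration_s is None:
        duration_s = float(spike_times.max() + 0.01) if spike_times.size else 0.0
    n = int(round(duration_s * rate_hz))
    if n == 0:
        raise ValueError("trace duration is zero")
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() >= duration_s):
        raise ValueError("spike times must lie within the trace duration")
    if spike_amplitude is None:
        spike_amplitude = 10.0 * noise_sd
    rng = np.random.default_rng(seed)
    trace = rng.standard_normal(n)
    sos = sp_signal.butter(2, [300.0 / (rate_hz / 2), 6000.0 / (rate_hz / 2)],
                           "bandpass", output="sos")
    trace = sp_signal.sosfiltfilt(sos, trace)
    trace *= noise_sd / trace.std()
    tpl = spike_amplitude * spike_template(rate_hz)
    for ts in spike_times:
        i = int(round(ts * rate_hz))
        j = min(i + tpl.size, n)
        trace[i:j] += tpl[: j - i]
    return trace


def simulate_abr_sweep(freq_hz: float, levels: np.ndarray,
                       true_threshold_db: float, seed: int = 0,
                       rate_hz: float = 24414.0625,
                       window_s: float = 0.030,
                       noise_rms: float = 1.0,
                       slope_db: float = 3.0) -> dict:
    """Median evoked-response windows per level, plus silence windows.

    The evoked wavelet amplitude is a sigmoid of (level - true_threshold)
    scaled so that, in expectation, the response RMS crosses twice the
    silence RMS exactly at the true threshold; residual noise is added to
    every window. Returns ``{"levels", "responses", "silence"}`` with
    ``responses`` shaped (n_levels, n_window).
    """
    levels = np.asarray(levels, float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be ascending")
    rng = np.random.default_rng(seed)
    n = int(round(window_s * rate_hz))
    t = np.arange(n) / rate_hz
    # ABR-like wavelet: windowed tone burst early in the 30 ms window
    wave = np.sin(2 * np.pi * 600.0 * t) * np.exp(-((t - 0.006) / 0.002) ** 2)
    wave = wave / np.sqrt(np.mean(wave ** 2))  # unit RMS
    # residual noise on the median response (median over many sweeps)
    resid = noise_rms / 6.0
    silence = rng.standard_normal(n) * resid
    sigma_s = np.sqrt(np.mean(silence ** 2))
    # amplitude at which RMS(resp) = 2*RMS(silence): a*1 = sqrt(3)*sigma_s
    responses = np.empty((levels.size, n))
    for i, lvl in enumerate(levels):
        a = np.sqrt(3.0) * sigma_s * 2.0 / (
            1.0 + np.exp(-(lvl - true_threshold_db) / slope_db))
        responses[i] = a * wave + rng.standard_normal(n) * resid
    return {"levels": levels, "responses": responses, "silence": silence}


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_recording(path, rec: SimulatedRecording, cf_hz: np.ndarray | None = None,
                   seed: int | None = None) -> None:
    """Write a recording to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=rec.counts, compression="gzip")
        f.create_dataset("latents", data=rec.true_latents)
        f.create_dataset("rates", data=rec.rates)
        f.attrs["bin_s"] = rec.bin_s
        if seed is not None:
            f.attrs["seed"] = seed
        if cf_hz is not None:
            f.create_dataset("cf_hz", data=np.asarray(cf_hz))


def load_recording(path) -> SimulatedRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return SimulatedRecording(counts=f["counts"][...],
                                  true_latents=f["latents"][...],
                                  rates=f["rates"][...],
                                  bin_s=float(f.attrs["bin_s"]))
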