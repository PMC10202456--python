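"""Stimulus synthesis for probing auditory encoding models.

Every generator is deterministic given a seed and returns a calibrated
:class:`~icman.waveform.Waveform` together with a list of
:class:`~icman.waveform.StimulusLabel` that tiles the stream exactly
(pauses carry an explicit ``silence`` label).

Stimulus classes
----------------
* pure-tone streams over a frequency x intensity grid,
* sinusoidally amplitude-modulated (SAM) bandpass noise, sweeping either
  modulation frequency or modulation depth,
* narrowband target / masker pairs (sinusoidal vs. pink-noise envelopes),
* parametric consonant-like tokens in three spectral classes with per-talker
  jitter, standing in for licensed speech corpora,
* multi-talker babble built by summing synthetic voice-like streams.

Bandpass noise is generated in the frequency domain (out-of-band bins zeroed,
uniformly random phases), so in-band power fractions hold by construction.
"""

from __future__ import annotations

import numpy as np

from .waveform import (DEFAULT_RATE_HZ, StimulusLabel, Waveform, set_level)

TONE_DUR_S = 0.100
TONE_PAUSE_S = 0.100
RAMP_S = 0.010

CONSONANT_DUR_S = 0.200
CONSONANT_PAUSE_S = 0.175

#: Spectral-class membership of the 22 consonant ids (fixed in config):
#: vowel-like (nasals/approximants), plosive, fricative.
CONSONANT_CLASSES = {
    "vowel_like": tuple(range(1, 9)),
    "plosive": tuple(range(9, 15)),
    "fricative": tuple(range(15, 23)),
}


def tone_freq_grid(f_lo: float = 500.0, f_hi: float = 8000.0,
                   octave_step: float = 0.2) -> np.ndarray:
    """Frequencies from ``f_lo`` to ``f_hi`` in fixed octave steps (inclusive)."""
    n = int(round(np.log2(f_hi / f_lo) / octave_step)) + 1
    return f_lo * 2.0 ** (octave_step * np.arange(n))


def level_grid(lo: float = 25.0, hi: float = 100.0, step: float = 5.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def narrowband_cf_grid() -> np.ndarray:
    """Center frequencies 500-8000 Hz in 0.5-octave steps (9 values)."""
    return tone_freq_grid(octave_step=0.5)


# ---------------------------------------------------------------------------
# low-level building blocks
# ---------------------------------------------------------------------------

def cosine_ramps(n: int, rate_hz: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Raised-cosine on/off gate of length ``n``; starts and ends at zero."""
    gate = np.ones(n)
    nr = int(round(ramp_s * rate_hz))
    nr = min(nr, n // 2)
    if nr > 0:
        t = np.arange(nr) / nr
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
        gate[:nr] = ramp
        gate[-nr:] = ramp[::-1]
    return gate


def bandpass_noise(n: int, rate_hz: float, f_lo: float, f_hi: float,
                   rng: np.random.Generator, tilt: float = 0.0) -> np.ndarray:
    """Gaussian noise with all power inside [f_lo, f_hi], unit RMS.

    Synthesized in the frequency domain: complex Gaussian coefficients inside
    the band, zero outside. ``tilt`` applies a 1/f**(tilt/2) amplitude slope
    (tilt=2 gives a pink power spectrum).
    """
    from scipy.fft import irfft, next_fast_len

    if not 0 < f_lo < f_hi <= rate_hz / 2:
        raise ValueError("band edges must satisfy 0 < f_lo < f_hi <= Nyquist")
    nf = next_fast_len(n, real=True)  # pad for FFT speed, then truncate
    freqs = np.fft.rfftfreq(nf, 1.0 / rate_hz)
    spec = np.zeros(freqs.size, dtype=complex)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    k = int(band.sum())
    amp = np.ones(k)
    if tilt:
        amp = freqs[band] ** (-tilt / 2.0)
    spec[band] = amp * (rng.standard_normal(k) + 1j * rng.standard_normal(k))
    x = irfft(spec, nf)[:n]
    return x / np.sqrt(np.mean(x ** 2))


def _pink_envelope(n: int, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative pink-noise envelope with depth (peak - trough)/peak = 1.

    1/f amplitude spectrum between 1 and 100 Hz, shifted/scaled so the trough
    sits at zero and the peak at one.
    """
    e = bandpass_noise(n, rate_hz, 1.0, 100.0, rng, tilt=2.0)
    e = e - e.min()
    return e / e.max()


class _StreamBuilder:
    """Accumulates segments and silence into one stream plus exact labels."""

    def __init__(self, rate_hz: float):
        self.rate_hz = rate_hz
        self.chunks: list[np.ndarray] = []
        self.labels: list[StimulusLabel] = []
        self._cursor = 0

    def add(self, samples: np.ndarray, kind: str, **fields) -> None:
        dur = samples.size / self.rate_hz
        self.labels.append(StimulusLabel(kind=kind, onset_s=self._cursor / self.rate_hz,
                                         duration_s=dur, **fields))
        self.chunks.append(samples)
        self._cursor += samples.size

    def add_silence(self, dur_s: float) -> None:
        n = int(round(dur_s * self.rate_hz))
        if n > 0:
            self.add(np.zeros(n), "silence")

    def build(self, spl_ref_db: float = 94.0) -> tuple[Waveform, list[StimulusLabel]]:
        samples = np.concatenate(self.chunks) if self.chunks else np.zeros(0)
        return Waveform(samples, self.rate_hz, spl_ref_db), self.labels


def _scaled(burst: np.ndarray, level_db_spl: float, spl_ref_db: float = 94.0) -> np.ndarray:
    rms = np.sqrt(np.mean(burst ** 2))
    target = 10.0 ** ((level_db_spl - spl_ref_db) / 20.0)
    return burst * (target / rms)


# ---------------------------------------------------------------------------
# stimulus generators
# ---------------------------------------------------------------------------

def make_tone_stream(freqs: np.ndarray | None = None,
                     levels: np.ndarray | None = None,
                     rate_hz: float = DEFAULT_RATE_HZ,
                     seed: int = 0) -> tuple[Waveform, list[StimulusLabel]]:
    """Stream of 100 ms pure tones over a frequency x intensity grid.

    Defaults: 500-8000 Hz in 0.2-octave steps (21 frequencies) crossed with
    25-100 dB SPL in 5 dB steps (16 levels); 10 ms cosine ramps and a 100 ms
    pause between tones. Tones are presented in grid order (level-major);
    ``seed`` is accepted for interface symmetry with the other generators.
    """
    del seed  # presentation order is deterministic for tones
    freqs = tone_freq_grid() if freqs is None else np.asarray(freqs, float)
    levels = level_grid() if levels is None else np.asarray(levels, float)
    if np.any(freqs >= rate_hz / 2):
        raise ValueError("tone frequency at or above Nyquist")
    n = int(round(TONE_DUR_S * rate_hz))
    t = np.arange(n) / rate_hz
    gate = cosine_ramps(n, rate_hz)
    sb = _StreamBuilder(rate_hz)
    for level in levels:
        amp = np.sqrt(2.0) * 10.0 ** ((level - 94.0) / 20.0)
        for f in freqs:
            tone = amp * np.sin(2 * np.pi * f * t) * gate
            sb.add(tone, "tone", frequency_hz=float(f), intensity_db_spl=float(level))
            sb.add_silence(TONE_PAUSE_S)
    return sb.build()


def make_sam_stream(mode: str = "freq_sweep",
                    levels: np.ndarray | None = None,
                    rate_hz: float = DEFAULT_RATE_HZ,
                    seed: int = 0) -> tuple[Waveform, list[StimulusLabel]]:
    """Stream of 100 ms SAM bandpass-noise bursts (carrier 500-8000 Hz).

    ``freq_sweep``: modulation frequencies 10-240 Hz in 10 Hz steps, depth 1.
    ``depth_sweep``: depths 0.1-1 in 20 logarithmic steps, 30 Hz modulation.
    Each burst gets fresh carrier noise; 10 ms ramps, 100 ms pauses.
    """
    if mode == "freq_sweep":
        conds = [(fm, 1.0) for fm in np.arange(10.0, 241.0, 10.0)]
    elif mode == "depth_sweep":
        conds = [(30.0, d) for d in np.geomspace(0.1, 1.0, 20)]
    else:
        raise ValueError("mode must be 'freq_sweep' or 'depth_sweep'")
    for _, d in conds:
        if not 0 < d <= 1:
            raise ValueError("modulation depth must be in (0, 1]")
    levels = level_grid() if levels is None else np.asarray(levels, float)
    rng = np.random.default_rng(seed)
    n = int(round(TONE_DUR_S * rate_hz))
    t = np.arange(n) / rate_hz
    gate = cosine_ramps(n, rate_hz)
    sb = _StreamBuilder(rate_hz)
    kind = "sam_freq" if mode == "freq_sweep" else "sam_depth"
    for level in levels:
        for fm, depth in conds:
            carrier = bandpass_noise(n, rate_hz, 500.0, 8000.0, rng)
            env = 1.0 + depth * np.sin(2 * np.pi * fm * t)
            burst = _scaled(carrier * env, level) * gate
            sb.add(burst, kind, intensity_db_spl=float(level),
                   mod_freq_hz=float(fm), mod_depth=float(depth))
            sb.add_silence(TONE_PAUSE_S)
    return sb.build()


def make_narrowband_pair(target_cf: float, masker_cf: float, level: float,
                         rate_hz: float = DEFAULT_RATE_HZ,
                         seed: int = 0,
                         dur_s: float = TONE_DUR_S) -> tuple[Waveform, Waveform]:
    """One 100 ms narrowband target / masker burst pair at matched level.

    Target: 0.5-octave bandpass noise with a 20 Hz sinusoidal envelope,
    depth 1. Masker: same band rule at ``masker_cf`` with a pink-noise
    envelope of depth (peak - trough)/peak = 1. Both have 10 ms ramps and the
    masker level is matched to the target.
    """
    rng = np.random.default_rng(seed)
    n = int(round(dur_s * rate_hz))
    t = np.arange(n) / rate_hz
    gate = cosine_ramps(n, rate_hz)

    def band(cf):
        return cf * 2.0 ** (-0.25), cf * 2.0 ** (0.25)

    lo, hi = band(target_cf)
    tgt = bandpass_noise(n, rate_hz, lo, hi, rng) * (1.0 + np.sin(2 * np.pi * 20.0 * t))
    tgt = _scaled(tgt * gate, level)
    lo, hi = band(masker_cf)
    msk = bandpass_noise(n, rate_hz, lo, hi, rng) * _pink_envelope(n, rate_hz, rng)
    msk = _scaled(msk * gate, level)
    return (Waveform(tgt, rate_hz), Waveform(msk, rate_hz))


# -- consonant-like tokens --------------------------------------------------

def _consonant_token(cid: int, talker: int, rate_hz: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Synthesize one 200 ms consonant-like token.

    The three spectral classes mirror the broad phonetic classes: vowel-like
    tokens carry low-frequency harmonic energy, plosives a broadband
    transient, fricatives high-frequency noise. Within a class, each
    consonant id has a fixed characteristic frequency parameter; each talker
    applies a deterministic multiplicative jitter. Token end is ramped to
    zero over 2 ms.
    """
    n = int(round(CONSONANT_DUR_S * rate_hz))
    t = np.arange(n) / rate_hz
    jitter = 1.0 + 0.12 * (talker - 5.5) / 5.5  # per-talker systematic shift
    micro = 1.0 + 0.02 * rng.standard_normal()  # per-instance variability
    if cid in CONSONANT_CLASSES["vowel_like"]:
        f0 = 95.0 + 12.0 * (cid - 1)
        f0 *= jitter * micro
        x = np.zeros(n)
        for h in range(1, 13):
            fh = f0 * h
            if fh >= rate_hz / 2:
                break
            x += np.sin(2 * np.pi * fh * t + rng.uniform(0, 2 * np.pi)) / h
        # slow vowel-like onset
        x *= np.minimum(t / 0.03, 1.0)
    elif cid in CONSONANT_CLASSES["plosive"]:
        burst_n = int(0.012 * rate_hz)
        hi = min(10000.0, 0.45 * rate_hz)
        x = np.zeros(n)
        x[:burst_n] = bandpass_noise(burst_n, rate_hz, 300.0 * jitter, hi, rng)
        tail_cf = (600.0 + 250.0 * (cid - 9)) * jitter * micro
        tail = bandpass_noise(n, rate_hz, tail_cf * 0.7, tail_cf * 1.5, rng)
        x += 0.25 * tail * np.exp(-t / 0.04)
    elif cid in CONSONANT_CLASSES["fricative"]:
        lo = (4200.0 + 350.0 * (cid - 15)) * jitter * micro
        hi = min(11500.0, 0.47 * rate_hz)
        lo = min(lo, hi * 0.8)
        x = bandpass_noise(n, rate_hz, lo, hi, rng)
        x *= 0.3 + 0.7 * np.minimum(t / 0.05, 1.0)
    else:
        raise ValueError(f"consonant id {cid} outside 1..22")
    # values after token end set to zero with a 2 ms linear ramp
    ramp_n = int(round(0.002 * rate_hz))
    x[-ramp_n:] *= np.linspace(1.0, 0.0, ramp_n)
    return x / np.sqrt(np.mean(x ** 2))


def make_consonant_tokens(n_consonants: int = 22, n_talkers: int = 10,
                          level: float = 60.0,
                          rate_hz: float = DEFAULT_RATE_HZ,
                          seed: int = 0) -> tuple[Waveform, list[StimulusLabel]]:
    """Stream of synthetic consonant tokens, one instance per talker.

    Tokens (200 ms) are presented in random order with 175 ms pauses, all at
    one intensity; present each intensity as a separate block. With defaults
    this yields 22 consonant ids x 10 talkers = 220 tokens.
    """
    n_classes = len(CONSONANT_CLASSES)
    if n_consonants < n_classes:
        raise ValueError(f"need at least {n_classes} consonants (one per spectral class)")
    if n_consonants > 22:
        raise ValueError("at most 22 consonant ids are defined")
    rng = np.random.default_rng(seed)
    order = [(cid, tk) for cid in range(1, n_consonants + 1)
             for tk in range(1, n_talkers + 1)]
    rng.shuffle(order)
    sb = _StreamBuilder(rate_hz)
    for cid, tk in order:
        tok = _scaled(_consonant_token(cid, tk, rate_hz, rng), level)
        sb.add(tok, "consonant", intensity_db_spl=float(level),
               consonant_id=cid, talker_id=tk)
        sb.add_silence(CONSONANT_PAUSE_S)
    return sb.build()


def make_babble(n_talkers: int = 16, duration_s: float = 2.0,
                rate_hz: float = DEFAULT_RATE_HZ,
                seed: int = 0) -> Waveform:
    """Multi-talker babble: sum of independent synthetic voice-like streams.

    Each stream is low-frequency-dominated (pink-tilted noise below ~4 kHz
    plus a drifting harmonic voice component) with a slow syllabic-rate
    envelope. Unit-RMS streams are summed, so the babble RMS grows ~ sqrt(k).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    total = np.zeros(n)
    for _ in range(n_talkers):
        voiced = np.zeros(n)
        f0 = rng.uniform(90.0, 220.0)
        for h in range(1, 9):
            voiced += np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi)) / h
        frict = 0.25 * bandpass_noise(n, rate_hz, 200.0, 4000.0, rng, tilt=2.0)
        syllabic = 0.3 + 0.7 * np.abs(bandpass_noise(n, rate_hz, 1.0, 8.0, rng))
        stream = (voiced / np.sqrt(np.mean(voiced ** 2)) + frict) * syllabic
        total += stream / np.sqrt(np.mean(stream ** 2))
    return Waveform(total, rate_hz)
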