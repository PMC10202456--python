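"""Multi-band wide-dynamic-range-compression (WDRC) hearing-aid simulation.

The simulated aid splits the input into 10 bands at fixed crossover
frequencies, runs a per-band RMS level estimator with asymmetric attack /
release time constants, applies level-dependent gain (linear below the
compression knee, 1 dB output per ``ratio`` dB input above it), and sums the
bands.

Band splitting uses zero-phase complementary Butterworth pairs: forward-
backward filtering squares the magnitude response, and Butterworth low/high
pairs are power-complementary, so at every crossover the two zero-phase
branches sum to an exactly flat (unity) response. Summing all 10 bands
reconstructs the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from numba import njit
from scipy import signal

from .waveform import Waveform

DEFAULT_CROSSOVERS_HZ = (200.0, 500.0, 1000.0, 1750.0, 2750.0,
                         4000.0, 5500.0, 7000.0, 8500.0)
DEFAULT_THRESHOLDS_DB = (45.0, 43.0, 40.0, 38.0, 35.0, 33.0, 28.0, 30.0, 36.0, 44.0)
#: Built-in per-channel gain table mimicking a typical sloping-loss fit
#: (about 10 dB at low frequencies rising to 30 dB at high frequencies).
DEFAULT_GAINS_DB = (10.0, 10.0, 12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0, 30.0)
DEFAULT_RATIOS = (1.5, 1.5, 1.7, 1.9, 2.0, 2.1, 2.2, 2.3, 2.5, 2.5)


@dataclass
class WDRCConfig:
    """Configuration of the 10-channel compressor.

    ``crossovers_hz`` has 9 ascending entries delimiting 10 channels; the
    per-channel arrays (``thresholds_db_spl`` = compression knees,
    ``gains_db`` = linear-region gains, ``ratios`` = compression ratios >= 1)
    have 10 entries each. Attack must be faster than release.
    """

    crossovers_hz: tuple = DEFAULT_CROSSOVERS_HZ
    thresholds_db_spl: tuple = DEFAULT_THRESHOLDS_DB
    gains_db: tuple = DEFAULT_GAINS_DB
    ratios: tuple = DEFAULT_RATIOS
    attack_ms: float = 5.0
    release_ms: float = 40.0

    def __post_init__(self) -> None:
        co = np.asarray(self.crossovers_hz, float)
        if co.size != 9 or np.any(np.diff(co) <= 0):
            raise ValueError("need 9 strictly ascending crossover frequencies")
        for name in ("thresholds_db_spl", "gains_db", "ratios"):
            if len(getattr(self, name)) != 10:
                raise ValueError(f"{name} must have 10 entries")
        if np.any(np.asarray(self.ratios, float) < 1.0):
            raise ValueError("compression ratios must be >= 1")
        if not self.attack_ms < self.release_ms:
            raise ValueError("attack must be shorter than release")

    @property
    def n_channels(self) -> int:
        return 10

    def band_edges(self, rate_hz: float) -> list[tuple[float, float]]:
        """(lo, hi) per channel; the outermost bands run to 0 / Nyquist."""
        co = list(self.crossovers_hz)
        edges = [0.0] + co + [rate_hz / 2.0]
        return [(edges[i], edges[i + 1]) for i in range(10)]

    def to_dict(self) -> dict:
        return {"crossovers_hz": list(self.crossovers_hz),
                "thresholds_db_spl": list(self.thresholds_db_spl),
                "gains_db": list(self.gains_db),
                "ratios": list(self.ratios),
                "attack_ms": self.attack_ms,
                "release_ms": self.release_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "WDRCConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


def split_bands(x: np.ndarray, cfg: WDRCConfig, rate_hz: float) -> np.ndarray:
    """Split a signal into the 10 compressor bands (rows); rows sum to x.

    Implemented as a cascade: at each crossover the remaining signal is split
    into a zero-phase Butterworth low/high power-complementary pair.
    """
    bands = np.empty((10, x.size))
    rest = x
    for i, fc in enumerate(cfg.crossovers_hz):
        wn = fc / (rate_hz / 2.0)
        sos_lo = signal.butter(2, wn, "lowpass", output="sos")
        sos_hi = signal.butter(2, wn, "highpass", output="sos")
        bands[i] = signal.sosfiltfilt(sos_lo, rest)
        rest = signal.sosfiltfilt(sos_hi, rest)
    bands[9] = rest
    return bands


@njit(cache=True)
def _envelope_ms(x2: np.ndarray, a_att: float, a_rel: float) -> np.ndarray:
    """One-pole mean-square follower with separate attack/release coefficients."""
    out = np.empty_like(x2)
    ms = x2[0]
    for i in range(x2.size):
        a = a_att if x2[i] > ms else a_rel
        ms = a * ms + (1.0 - a) * x2[i]
        out[i] = ms
    return out


def _band_gain_db(level_db: np.ndarray, knee: float, gain: float,
                  ratio: float) -> np.ndarray:
    """Static gain rule: linear below the knee, slope 1/ratio above it."""
    over = np.maximum(level_db - knee, 0.0)
    return gain + over * (1.0 / ratio - 1.0)


def wdrc_process(w: Waveform, cfg: WDRCConfig | None = None) -> Waveform:
    """Run the 10-channel WDRC compressor on a calibrated waveform.

    Per band, an RMS-tracking envelope follower (5 ms attack / 40 ms release
    one-pole smoothing of the squared signal) drives the static gain rule;
    bands are summed. Output length equals input length.
    """
    w._require_calibration()
    cfg = WDRCConfig() if cfg is None else cfg
    if w.n_samples == 0:
        return w
    rate = w.rate_hz
    a_att = float(np.exp(-1.0 / (cfg.attack_ms * 1e-3 * rate)))
    a_rel = float(np.exp(-1.0 / (cfg.release_ms * 1e-3 * rate)))
    bands = split_bands(w.samples, cfg, rate)
    out = np.zeros_like(w.samples)
    tiny = 1e-30
    for ch in range(10):
        ms = _envelope_ms(bands[ch] ** 2, a_att, a_rel)
        level_db = w.spl_ref_db + 10.0 * np.log10(ms + tiny)
        g_db = _band_gain_db(level_db, cfg.thresholds_db_spl[ch],
                             cfg.gains_db[ch], cfg.ratios[ch])
        out += bands[ch] * 10.0 ** (g_db / 20.0)
    return w.replace(samples=out)


def static_io_curve(cfg: WDRCConfig, channel: int,
                    input_levels: np.ndarray,
                    rate_hz: float = 24414.0625,
                    probe_hz: float | None = None,
                    probe_dur_s: float = 1.0) -> np.ndarray:
    """Steady-state output level per input level for one channel.

    A long sinusoidal probe at the channel's band center is run through the
    band split, the channel's level estimator, and the channel's gain rule in
    isolation, and the settled output level is measured over the final 30% of
    the probe (well past ten release time constants). Below the knee the
    curve has slope 1, above it slope 1/ratio; band-filter attenuation at the
    probe frequency adds a constant offset that cancels in slopes.
    """
    lo, hi = cfg.band_edges(rate_hz)[channel]
    if probe_hz is None:
        probe_hz = float(np.sqrt(max(lo, 50.0) * min(hi, 0.95 * rate_hz / 2.0)))
    elif not lo <= probe_hz <= hi:
        raise ValueError(f"probe {probe_hz} Hz outside channel band [{lo}, {hi}]")
    if probe_dur_s < 10.0 * cfg.release_ms * 1e-3:
        raise ValueError("probe must settle for at least ten release times")
    n = int(round(probe_dur_s * rate_hz))
    t = np.arange(n) / rate_hz
    settle = int(0.7 * n)
    a_att = float(np.exp(-1.0 / (cfg.attack_ms * 1e-3 * rate_hz)))
    a_rel = float(np.exp(-1.0 / (cfg.release_ms * 1e-3 * rate_hz)))
    out_levels = np.empty(len(input_levels))
    for i, lvl in enumerate(np.asarray(input_levels, float)):
        amp = np.sqrt(2.0) * 10.0 ** ((lvl - 94.0) / 20.0)
        probe = Waveform(amp * np.sin(2 * np.pi * probe_hz * t), rate_hz)
        band = split_bands(probe.samples, cfg, rate_hz)[channel]
        ms = _envelope_ms(band ** 2, a_att, a_rel)
        level_db = 94.0 + 10.0 * np.log10(ms + 1e-30)
        g_db = _band_gain_db(level_db, cfg.thresholds_db_spl[channel],
                             cfg.gains_db[channel], cfg.ratios[channel])
        y = (band * 10.0 ** (g_db / 20.0))[settle:]
        out_levels[i] = 94.0 + 20.0 * np.log10(np.sqrt(np.mean(y ** 2)))
    return out_levels


def fit_from_audiogram(profile) -> WDRCConfig:
    """Derive a WDRC configuration from audiometric threshold shifts.

    A simple deterministic prescription standing in for clinical fitting
    software: per-channel gain is 0.7x the threshold shift interpolated at the
    channel's center frequency (clipped to [0, 30] dB), which lands near
    10 dB for mild low-frequency loss and 30 dB for moderate high-frequency
    loss; compression ratios scale linearly with gain from 1 to 2.5.
    Negative shifts are clamped to zero with a warning.
    """
    from .synthetic_ic import HearingProfile  # local import to avoid a cycle

    if not isinstance(profile, HearingProfile):
        profile = HearingProfile(dict(profile))
    base = WDRCConfig()
    edges = base.band_edges(24414.0625)
    centers = np.array([np.sqrt(max(lo, 50.0) * hi) for lo, hi in edges])
    shifts = np.array([profile.shift_at(f) for f in centers])
    if np.any(shifts < 0):
        warnings.warn("negative threshold shifts clamped to 0")
        shifts = np.maximum(shifts, 0.0)
    gains = np.clip(0.7 * shifts, 0.0, 30.0)
    ratios = 1.0 + 1.5 * gains / 30.0
    return WDRCConfig(gains_db=tuple(np.round(gains, 2)),
                      ratios=tuple(np.round(ratios, 3)))
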