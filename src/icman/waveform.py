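"""Calibrated audio waveforms.

All stimuli carry a dB SPL calibration through a single reference: a waveform
with an RMS of 1 corresponds to ``spl_ref_db`` (94 dB SPL by default). Levels
are therefore pure re-scalings; no physical pressure units are carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default sampling rate (Hz) used throughout the package.
DEFAULT_RATE_HZ = 24414.0625

#: dB SPL corresponding to unit RMS.
DEFAULT_SPL_REF_DB = 94.0


@dataclass
class Waveform:
    """A calibrated audio signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitude sequence.
    rate_hz : float
        Sampling rate in Hz.
    spl_ref_db : float or None
        The sound level (dB SPL) corresponding to an RMS of 1. ``None`` marks
        an uncalibrated waveform, which level-dependent processing rejects.
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    spl_ref_db: float | None = DEFAULT_SPL_REF_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    # -- basic measures -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def level_db(self) -> float:
        """Measured level in dB SPL (via the RMS-1 reference)."""
        self._require_calibration()
        r = self.rms()
        if r == 0.0:
            raise ValueError("silent waveform has no defined level")
        return self.spl_ref_db + 20.0 * np.log10(r)

    def _require_calibration(self) -> None:
        if self.spl_ref_db is None:
            raise ValueError("waveform is uncalibrated (spl_ref_db is None)")

    def replace(self, **kwargs) -> "Waveform":
        return replace(self, **kwargs)


def set_level(w: Waveform, level_db_spl: float) -> Waveform:
    """Rescale a waveform to a requested level in dB SPL.

    The returned waveform has ``RMS = 10**((level - spl_ref)/20)``. Re-scaling
    is idempotent: setting the same level twice is a no-op.
    """
    w._require_calibration()
    r = w.rms()
    if r == 0.0:
        raise ValueError("cannot set the level of a silent waveform")
    target = 10.0 ** ((level_db_spl - w.spl_ref_db) / 20.0)
    return w.replace(samples=w.samples * (target / r))


def mix_at_snr(speech: Waveform, noise: Waveform, snr_db: float = 3.0,
               active_mask: np.ndarray | None = None) -> Waveform:
    """Add background noise to a foreground at a given signal-to-noise ratio.

    The noise is rescaled so that the foreground RMS over its *active*
    segments exceeds the noise RMS by ``snr_db``. Active samples default to
    those where the smoothed foreground magnitude exceeds 5% of its maximum
    (this skips the silent pauses between tokens); pass ``active_mask`` to
    override.
    """
    if speech.rate_hz != noise.rate_hz:
        raise ValueError("sampling rates must match")
    if noise.n_samples < speech.n_samples:
        raise ValueError("noise must be at least as long as the foreground")
    if noise.rms() == 0.0:
        raise ValueError("noise is silent, cannot set an SNR")
    if active_mask is None:
        active_mask = active_segments(speech)
    if not active_mask.any():
        raise ValueError("foreground has no active segments")
    s_rms = float(np.sqrt(np.mean(np.square(speech.samples[active_mask]))))
    n = noise.samples[: speech.n_samples]
    n_rms = float(np.sqrt(np.mean(np.square(n))))
    target_n_rms = s_rms / 10.0 ** (snr_db / 20.0)
    mixed = speech.samples + n * (target_n_rms / n_rms)
    return speech.replace(samples=mixed)


def active_segments(w: Waveform, rel_threshold: float = 0.05,
                    smooth_s: float = 0.005) -> np.ndarray:
    """Boolean mask of samples where the smoothed envelope is above threshold."""
    win = max(1, int(round(smooth_s * w.rate_hz)))
    env = np.convolve(np.abs(w.samples), np.ones(win) / win, mode="same")
    return env > rel_threshold * env.max()


@dataclass
class StimulusLabel:
    """One labelled segment of a generated stimulus stream.

    Labels tile the stream without overlap; pauses carry an explicit
    ``silence`` kind. Fields that do not apply to a given kind are ``nan``/0.
    """

    kind: str
    onset_s: float
    duration_s: float
    frequency_hz: float = np.nan
    intensity_db_spl: float = np.nan
    mod_freq_hz: float = np.nan
    mod_depth: float = np.nan
    consonant_id: int = 0
    talker_id: int = 0

    KINDS = ("tone", "sam_freq", "sam_depth", "consonant", "babble",
             "nb_target", "nb_masker", "silence")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.duration_s < 0:
            raise ValueError("duration must be nonnegative")


def labels_to_frame(labels: list[StimulusLabel]):
    """Tidy DataFrame view of a label list (the CSV sidecar schema)."""
    import pandas as pd

    cols = ["kind", "onset_s", "duration_s", "frequency_hz",
            "intensity_db_spl", "mod_freq_hz", "mod_depth",
            "consonant_id", "talker_id"]
    return pd.DataFrame([{c: getattr(l, c) for c in cols} for l in labels])
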