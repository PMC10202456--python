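"""Sound-to-spike-count convolutional encoder with a latent bottleneck.

Architecture (four stages):

1. a bank of learnable sinc bandpass filters (length-32 kernels, learnable
   center/bandwidth via band edges) followed by symmetric log activations,
2. a stack of five 1-D convolutional layers (128 filters, kernel 32,
   stride 2, per-channel PReLU) — cumulative temporal decimation 2^5 = 32,
   taking 24414.0625 Hz audio to 762.9395 Hz activity bins,
3. a bottleneck convolutional layer (Db filters, kernel 32, stride 1,
   PReLU) whose activations are the model's latent signal dynamics,
4. a per-unit linear readout with exponential activations producing
   expected spike counts per bin.

Training minimizes the Poisson negative log-likelihood
sum(R_hat - R*log(R_hat)) with Adam on frames of 8192 samples mapped to 192
output bins (32 bins cropped at each frame end to remove convolutional edge
effects). A linear-nonlinear (LN) baseline shares stages 1 and 4 with a
single wide convolution in between. All computation is single-precision
NumPy; see :mod:`icman.nn` for the primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

from . import nn
from .manifold import LatentDynamics
from .waveform import Waveform

DECIMATION = 32  # five stride-2 layers


def symmetric_log(x: np.ndarray) -> np.ndarray:
    """sign(x) * log(1 + |x|); odd and monotone."""
    x = np.asarray(x)
    return np.sign(x) * np.log1p(np.abs(x))


def poisson_loss(rhat: np.ndarray, r: np.ndarray) -> float:
    """Poisson regression loss: sum over units and bins of rhat - r*log(rhat)."""
    rhat = np.asarray(rhat, float)
    r = np.asarray(r, float)
    if np.any(rhat <= 0):
        raise ValueError("predicted rates must be strictly positive")
    if np.any(r < 0):
        raise ValueError("observed counts must be nonnegative")
    return float(np.sum(rhat - r * np.log(rhat)))


@dataclass
class EncoderSpec:
    """Architecture hyperparameters. ``bottleneck`` is the one varied knob."""

    n_units: int
    bottleneck: int = 8
    kind: str = "deep"            # "deep" | "ln"
    n_sinc: int = 48
    sinc_len: int = 32
    n_conv: int = 5
    conv_filters: int = 128
    conv_kernel: int = 32
    conv_stride: int = 2
    bottleneck_kernel: int = 32
    ln_filters: int = 128
    ln_kernel: int = 256
    rate_hz: float = 24414.0625

    def __post_init__(self) -> None:
        if self.kind not in ("deep", "ln"):
            raise ValueError("kind must be 'deep' or 'ln'")
        if self.kind == "deep" and self.conv_stride ** self.n_conv != DECIMATION:
            raise ValueError("conv stack must decimate by a factor of 32")

    @classmethod
    def small(cls, n_units: int, bottleneck: int = 8, **kw) -> "EncoderSpec":
        """Scaled-down widths for desk-scale training; strides unchanged."""
        return cls(n_units=n_units, bottleneck=bottleneck, n_sinc=16,
                   conv_filters=24, conv_kernel=16, ln_filters=24,
                   ln_kernel=64, **kw)

    def ln_variant(self) -> "EncoderSpec":
        return replace(self, kind="ln")


@dataclass
class TrainConfig:
    """Training hyperparameters (frame geometry fixed by the architecture)."""

    frame_in: int = 8192
    crop: int = 32
    batch: int = 64
    epochs: int = 10
    lr: float = 1e-4
    seed: int = 0
    grad_clip: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_in % DECIMATION:
            raise ValueError("frame_in must be divisible by 32")
        if self.frame_out <= 0:
            raise ValueError("crop leaves no output bins")

    @property
    def frame_out(self) -> int:
        return self.frame_in // DECIMATION - 2 * self.crop


def frame_geometry(cfg: TrainConfig, rate_hz: float = 24414.0625) -> tuple[float, int]:
    """(output rate in Hz, output bins per frame) for a training frame."""
    if cfg.frame_in % DECIMATION:
        raise ValueError("frame_in must be divisible by 32")
    return rate_hz / DECIMATION, cfg.frame_in // DECIMATION - 2 * cfg.crop


@dataclass
class EncoderResults:
    """Optimization record returned by :meth:`Encoder.fit`."""

    loss_history: list          # mean train loss per bin; entry 0 = pre-training
    val_loss_history: list
    spec: EncoderSpec
    cfg: TrainConfig


class Encoder:
    """The encoder model (deep or LN) with explicit parameter arrays."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        p_low, p_band = nn.mel_spaced_edges(spec.n_sinc, rate_hz=spec.rate_hz)
        p["sinc_low"], p["sinc_band"] = p_low.copy(), p_band.copy()

        def he(fan_in, shape):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        if spec.kind == "deep":
            c_in = spec.n_sinc
            for i in range(spec.n_conv):
                p[f"conv{i}_w"] = he(c_in * spec.conv_kernel,
                                     (spec.conv_filters, c_in, spec.conv_kernel))
                p[f"conv{i}_b"] = np.zeros(spec.conv_filters, np.float32)
                p[f"conv{i}_a"] = np.full(spec.conv_filters, 0.25, np.float32)
                c_in = spec.conv_filters
            p["bott_w"] = he(c_in * spec.bottleneck_kernel,
                             (spec.bottleneck, c_in, spec.bottleneck_kernel))
            p["bott_b"] = np.zeros(spec.bottleneck, np.float32)
            p["bott_a"] = np.full(spec.bottleneck, 0.25, np.float32)
            readout_in = spec.bottleneck
        else:
            p["ln_w"] = he(spec.n_sinc * spec.ln_kernel,
                           (spec.ln_filters, spec.n_sinc, spec.ln_kernel))
            p["ln_b"] = np.zeros(spec.ln_filters, np.float32)
            p["ln_a"] = np.full(spec.ln_filters, 0.25, np.float32)
            readout_in = spec.ln_filters
        p["read_w"] = he(readout_in, (spec.n_units, readout_in)) * 0.1
        p["read_b"] = np.zeros(spec.n_units, np.float32)
        self.params = p

    # -- plumbing -----------------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def encoder_param_names(self) -> list[str]:
        return [k for k in self.params if not k.startswith("read_")]

    def set_readout_bias_from_mean(self, mean_count: np.ndarray) -> None:
        """Start the exponential readout at each unit's mean count."""
        self.params["read_b"] = np.log(np.maximum(mean_count, 1e-4)).astype(np.float32)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, need_cache: bool = True):
        """x: (B, T) audio frames -> (rates (B, units, T//32), cache)."""
        sp = self.spec
        p = self.params
        x = np.ascontiguousarray(x, dtype=np.float32)[:, None, :]
        kern, sinc_cache = nn.sinc_kernels(p["sinc_low"], p["sinc_band"],
                                           sp.sinc_len, sp.rate_hz)
        h, c_sinc = nn.conv1d_forward(x, kern, np.zeros(sp.n_sinc, np.float32), 1)
        h, c_slog = nn.symlog_forward(h)
        caches = {"sinc": (sinc_cache, c_sinc, c_slog), "layers": []}
        if sp.kind == "deep":
            for i in range(sp.n_conv):
                h, cc = nn.conv1d_forward(h, p[f"conv{i}_w"], p[f"conv{i}_b"],
                                          sp.conv_stride)
                h, ca = nn.prelu_forward(h, p[f"conv{i}_a"])
                caches["layers"].append((f"conv{i}", cc, ca))
            h, cc = nn.conv1d_forward(h, p["bott_w"], p["bott_b"], 1)
            h, ca = nn.prelu_forward(h, p["bott_a"])
            caches["layers"].append(("bott", cc, ca))
        else:
            h, cc = nn.conv1d_forward(h, p["ln_w"], p["ln_b"], DECIMATION)
            h, ca = nn.prelu_forward(h, p["ln_a"])
            caches["layers"].append(("ln", cc, ca))
        caches["latent"] = h
        z = np.einsum("uc,bct->but", p["read_w"], h) + p["read_b"][None, :, None]
        z = np.clip(z, -30.0, 25.0)
        rates = np.exp(z)
        caches["readout"] = (h, z)
        return rates, (caches if need_cache else None)

    def backward(self, drates: np.ndarray, caches: dict,
                 trainable: set[str] | None = None) -> dict:
        """Gradients of the loss given dL/drates (drates already includes exp')."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h, z = caches["readout"]
        dz = drates  # caller passes dL/dz = (rates - counts)/N for Poisson+exp
        grads["read_w"] = np.einsum("but,bct->uc", dz, h).astype(np.float32)
        grads["read_b"] = dz.sum(axis=(0, 2)).astype(np.float32)
        if trainable is not None and not (set(trainable) - {"read_w", "read_b"}):
            return grads
        dh = np.einsum("uc,but->bct", p["read_w"], dz).astype(np.float32)
        for name, cc, ca in reversed(caches["layers"]):
            dh, da = nn.prelu_backward(dh, p[f"{name}_a"], ca)
            _, dw, db, bwd = nn.conv1d_backward(dh, cc)
            grads[f"{name}_w"], grads[f"{name}_b"] = dw, db
            grads[f"{name}_a"] = da.astype(np.float32)
            dh = nn.conv1d_backward_input(p[f"{name}_w"], bwd)
        sinc_cache, c_sinc, c_slog = caches["sinc"]
        dh = nn.symlog_backward(dh, c_slog)
        _, dkern, _, _ = nn.conv1d_backward(dh, c_sinc)
        g_low, g_band = nn.sinc_kernel_grads(dkern, sinc_cache)
        grads["sinc_low"], grads["sinc_band"] = g_low, g_band
        return grads

    # -- training -----------------------------------------------------------
    def _mean_loss(self, frames_x: np.ndarray, frames_r: np.ndarray,
                   crop: int, batch: int = 16) -> float:
        tot, n = 0.0, 0
        for i in range(0, frames_x.shape[0], batch):
            rates, _ = self.forward(frames_x[i:i + batch], need_cache=False)
            rh = rates[:, :, crop:rates.shape[2] - crop]
            rr = frames_r[i:i + batch][:, :, crop:rates.shape[2] - crop]
            tot += poisson_loss(rh, rr)
            n += rh.size
        return tot / n

    def fit(self, frames_x: np.ndarray, frames_r: np.ndarray,
            cfg: TrainConfig | None = None,
            val: tuple[np.ndarray, np.ndarray] | None = None,
            trainable: set[str] | None = None) -> EncoderResults:
        """Train with Adam on aligned (sound, count) frames.

        ``frames_x``: (N, frame_in) audio; ``frames_r``: (N, units,
        frame_in//32) counts. Loss history entries are mean Poisson loss per
        bin; entry 0 is evaluated before any update. ``trainable`` restricts
        optimization to a subset of parameter names (used for transfer
        learning with a frozen encoder). Deterministic given cfg.seed.
        """
        cfg = TrainConfig() if cfg is None else cfg
        if frames_x.shape[0] != frames_r.shape[0]:
            raise ValueError("sound and count frames must be aligned")
        if not np.issubdtype(frames_r.dtype, np.integer):
            if np.any(frames_r != np.round(frames_r)):
                raise ValueError("count frames must be integers")
        frames_x = np.asarray(frames_x, np.float32)
        frames_r = np.asarray(frames_r, np.float32)
        names = set(self.params) if trainable is None else set(trainable)
        opt = nn.Adam({k: self.params[k] for k in names}, lr=cfg.lr)
        rng = np.random.default_rng(cfg.seed)
        n_frames = frames_x.shape[0]
        crop = cfg.crop
        history = [self._mean_loss(frames_x, frames_r, crop)]
        val_history = []
        if val is not None:
            val_history.append(self._mean_loss(val[0], val[1], crop))
        for _ in range(cfg.epochs):
            order = rng.permutation(n_frames)
            epoch_loss, epoch_n = 0.0, 0
            for i in range(0, n_frames, cfg.batch):
                idx = order[i:i + cfg.batch]
                xb, rb = frames_x[idx], frames_r[idx]
                rates, caches = self.forward(xb)
                t_out = rates.shape[2]
                sl = slice(crop, t_out - crop)
                n_entries = rates[:, :, sl].size
                loss = poisson_loss(rates[:, :, sl], rb[:, :, sl])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at step {opt.t}: {loss}")
                epoch_loss += loss
                epoch_n += n_entries
                dz = np.zeros_like(rates)
                dz[:, :, sl] = (rates[:, :, sl] - rb[:, :, sl]) / n_entries
                grads = self.backward(dz, caches, trainable=names)
                gn = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                 for k, g in grads.items() if k in names))
                if cfg.grad_clip and gn > cfg.grad_clip:
                    grads = {k: g * (cfg.grad_clip / gn) for k, g in grads.items()}
                opt.step({k: g for k, g in grads.items() if k in names})
            history.append(epoch_loss / epoch_n)
            if val is not None:
                val_history.append(self._mean_loss(val[0], val[1], crop))
        return EncoderResults(history, val_history, self.spec, cfg)

    # -- inference on streams ----------------------------------------------
    def _stream_forward(self, w: Waveform, cfg: TrainConfig) -> np.ndarray:
        """Latent activations (C x T//32) over a whole waveform.

        Overlapped frames tile the output contiguously: each frame
        contributes its cropped center, with zero padding at the stream
        edges. Waveforms shorter than one frame are silence-padded.
        """
        x = np.asarray(w.samples, np.float32)
        n_bins = x.size // DECIMATION
        out_len = cfg.frame_out
        pad = cfg.crop * DECIMATION
        n_frames = max(1, -(-n_bins // out_len))
        total = n_frames * out_len * DECIMATION + 2 * pad
        xp = np.zeros(total, np.float32)
        xp[pad:pad + x.size] = x
        outs = []
        for k in range(n_frames):
            fr = xp[k * out_len * DECIMATION:
                    k * out_len * DECIMATION + cfg.frame_in]
            if fr.size < cfg.frame_in:
                fr = np.pad(fr, (0, cfg.frame_in - fr.size))
            rates, caches = self.forward(fr[None, :], need_cache=True)
            lat = caches["latent"][0]
            outs.append(lat[:, cfg.crop:cfg.crop + out_len])
        return np.concatenate(outs, axis=1)[:, :n_bins]

    def predict(self, w: Waveform, cfg: TrainConfig | None = None) -> np.ndarray:
        """Expected counts (units x bins) for a calibrated waveform."""
        cfg = TrainConfig() if cfg is None else cfg
        lat = self._stream_forward(w, cfg)
        z = self.params["read_w"] @ lat + self.params["read_b"][:, None]
        return np.exp(np.clip(z, -30.0, 25.0))

    def extract_bottleneck(self, w: Waveform,
                           cfg: TrainConfig | None = None) -> LatentDynamics:
        """Bottleneck activations as latent dynamics at 762.9395 Hz bins."""
        cfg = TrainConfig() if cfg is None else cfg
        lat = self._stream_forward(w, cfg)
        return LatentDynamics(X=lat, bin_s=DECIMATION / self.spec.rate_hz,
                              provenance="bottleneck")

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        spec_json = json.dumps(self.spec.__dict__)
        np.savez(path, __spec__=np.frombuffer(spec_json.encode(), np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "Encoder":
        data = np.load(path)
        spec = EncoderSpec(**json.loads(bytes(data["__spec__"]).decode()))
        model = cls(spec)
        model.params = {k: data[k] for k in data.files if k != "__spec__"}
        return model


def build_ln_baseline(spec: EncoderSpec, seed: int = 0) -> Encoder:
    """LN comparison model: same sinc front end and readout, one wide conv."""
    return Encoder(spec.ln_variant(), seed=seed)


def frame_stream(w: Waveform, counts: np.ndarray,
                 cfg: TrainConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Chop a waveform and aligned counts into non-overlapping frames."""
    cfg = TrainConfig() if cfg is None else cfg
    t_full = cfg.frame_in // DECIMATION
    n_frames = min(w.n_samples // cfg.frame_in, counts.shape[1] // t_full)
    if n_frames == 0:
        raise ValueError("stream shorter than one training frame")
    X = w.samples[:n_frames * cfg.frame_in].reshape(n_frames, cfg.frame_in)
    R = counts[:, :n_frames * t_full].reshape(counts.shape[0], n_frames, t_full)
    return X.astype(np.float32), np.ascontiguousarray(R.transpose(1, 0, 2))


def explainable_variance_explained(pred: np.ndarray, Rtest1: np.ndarray,
                                   Rtest2: np.ndarray) -> np.ndarray:
    """Per-unit percent of explainable variance captured by a prediction.

    100 x cov(Rtest1, pred) / cov(Rtest1, Rtest2) per unit; units whose
    across-repeat covariance is not positive are excluded (nan). 100% means
    the prediction captures all trial-reproducible structure.
    """
    pred = np.atleast_2d(pred)
    R1 = np.atleast_2d(Rtest1).astype(float)
    R2 = np.atleast_2d(Rtest2).astype(float)
    out = np.full(R1.shape[0], np.nan)
    for i in range(R1.shape[0]):
        c_pr = np.cov(R1[i], pred[i])[0, 1]
        c_rr = np.cov(R1[i], R2[i])[0, 1]
        if c_rr > 0:
            out[i] = 100.0 * c_pr / c_rr
    return out


def transfer_learn(model: Encoder, frames_x: np.ndarray, frames_r: np.ndarray,
                   cfg: TrainConfig | None = None, seed: int = 0,
                   init: str = "mapped") -> tuple[Encoder, EncoderResults]:
    """Retrain only the linear readout of a frozen encoder for a new animal.

    The new readout is initialized per unit from the readout weights of a
    random unit of the original animal (sampling with replacement when unit
    counts differ); ``init="random"`` skips the mapping. Encoder parameters
    are shared read-only semantics: they are copied and verified unchanged
    by the caller's tests.
    """
    cfg = TrainConfig() if cfg is None else cfg
    n_new = frames_r.shape[1]
    new_spec = replace(model.spec, n_units=n_new)
    new_model = Encoder(new_spec, seed=seed)
    for k in model.encoder_param_names():
        new_model.params[k] = model.params[k].copy()
    rng = np.random.default_rng(seed)
    if init == "mapped":
        src = rng.integers(0, model.spec.n_units, size=n_new)
        new_model.params["read_w"] = model.params["read_w"][src].copy()
        new_model.params["read_b"] = model.params["read_b"][src].copy()
    res = new_model.fit(frames_x, frames_r, cfg,
                        trainable={"read_w", "read_b"})
    return new_model, res
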