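"""End-to-end experiment orchestration from a single serializable config.

A run synthesizes a stimulus, optionally processes it with the simulated
hearing aid, simulates a synthetic population response, projects it onto
its PCA signal manifold, and writes the requested analyses as tidy CSVs
into a bundle directory with a manifest (config hash, seed, completed
stages). Re-running an identical config reproduces identical outputs; a
partial run can be resumed because the manifest records completed stages.

All randomness flows from the single root seed through named substreams
(stimulus, population, trials), so bundles are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import stimgen
from .hearing_aid import WDRCConfig, wdrc_process
from .latent import compute_rdm, rdm_similarity, segment_dynamics
from .manifold import (fit_pcs, project, signal_noise_stats, variance_curves,
                       curves_to_frame)
from .synthetic_ic import HearingProfile, make_population, simulate_response
from .waveform import Waveform, labels_to_frame


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    stimulus: dict = field(default_factory=lambda: {
        "kind": "tones", "levels": [55.0, 70.0, 85.0]})
    hearing: dict | None = None          # audiogram shifts, None = normal
    wdrc: dict | None = None             # WDRC config dict, None = aid off
    population: dict = field(default_factory=lambda: {
        "n_units": 32, "signal_dim": 4, "signal_var_fraction": 0.4})
    n_trials: int = 3
    analyses: tuple = ("signal_noise", "manifold", "rdm")
    seed: int = 0
    out_dir: str = "icman_out"

    def to_json(self) -> str:
        d = asdict(self)
        d["analyses"] = list(d["analyses"])
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["analyses"] = tuple(d.get("analyses", ()))
        return cls(**d)

    def hash(self) -> str:
        """Content hash of the experiment (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        d["analyses"] = list(d["analyses"])
        text = json.dumps(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _seed_for(cfg: ExperimentConfig, stream: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _make_stimulus(cfg: ExperimentConfig):
    spec = dict(cfg.stimulus)
    kind = spec.pop("kind")
    seed = _seed_for(cfg, "stimulus")
    levels = np.asarray(spec.pop("levels", [60.0]), float)
    if kind == "tones":
        freqs = np.asarray(spec.pop("freqs", stimgen.tone_freq_grid()), float)
        return stimgen.make_tone_stream(freqs=freqs, levels=levels, seed=seed)
    if kind in ("sam_freq", "sam_depth"):
        mode = "freq_sweep" if kind == "sam_freq" else "depth_sweep"
        return stimgen.make_sam_stream(mode=mode, levels=levels, seed=seed)
    if kind == "consonants":
        waves, labels = [], []
        offset = 0.0
        for i, lvl in enumerate(levels):
            w, ls = stimgen.make_consonant_tokens(level=float(lvl), seed=seed + i,
                                                  **spec)
            for l in ls:
                l.onset_s += offset
            waves.append(w.samples)
            labels.extend(ls)
            offset += w.duration_s
        return Waveform(np.concatenate(waves)), labels
    raise ValueError(f"unknown stimulus kind {kind!r}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Execute a config; returns the bundle directory.

    Writes ``stimulus.wav``/``labels.csv``, per-analysis CSVs and a
    ``manifest.json``. Stages already recorded as complete for the same
    config hash are skipped on re-run.
    """
    from scipy.io import wavfile

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": []}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg.hash():
            manifest = old

    def done(stage):
        return stage in manifest["stages"]

    def mark(stage):
        manifest["stages"].append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=1))

    (out / "config.json").write_text(cfg.to_json())
    w, labels = _make_stimulus(cfg)
    if not done("stimulus"):
        wavfile.write(out / "stimulus.wav", int(round(w.rate_hz)),
                      w.samples.astype(np.float32))
        _write_csv(labels_to_frame(labels), out / "labels.csv")
        mark("stimulus")
    if cfg.wdrc is not None:
        w = wdrc_process(w, WDRCConfig.from_dict(cfg.wdrc))
    hearing = HearingProfile(cfg.hearing) if cfg.hearing else None
    pop = make_population(hearing=hearing, seed=_seed_for(cfg, "population"),
                          **cfg.population)
    rec = simulate_response(w, pop, n_trials=max(cfg.n_trials, 3),
                            seed=_seed_for(cfg, "trials"), labels=labels)
    basis = fit_pcs(rec.trial(0))
    if "signal_noise" in cfg.analyses and not done("signal_noise"):
        st = signal_noise_stats(rec.trial(1), rec.trial(2))
        df = pd.DataFrame({"unit": np.arange(pop.n_units),
                           "total_var": st.total_var,
                           "signal_var": st.signal_var,
                           "noise_var": st.noise_var})
        _write_csv(df, out / "signal_noise.csv")
        mark("signal_noise")
    if "manifold" in cfg.analyses and not done("manifold"):
        curves = variance_curves(rec.trial(1), rec.trial(2), basis)
        _write_csv(curves_to_frame(cfg.hash(), curves), out / "variance_curves.csv")
        mark("manifold")
    if "rdm" in cfg.analyses and not done("rdm"):
        dyn = project(rec.trial(1), basis, D=min(8, basis.max_dim))
        dyn.bin_s = rec.bin_s
        kinds = {"tones": "tone", "sam_freq": "sam_freq",
                 "sam_depth": "sam_depth", "consonants": "consonant"}
        kind = kinds[cfg.stimulus.get("kind", "tones")]
        rows = []
        for lvl in sorted({l.intensity_db_spl for l in labels
                           if l.kind == kind}):
            labs = [l for l in labels if l.kind == kind
                    and l.intensity_db_spl == lvl]
            trajs = segment_dynamics(dyn, labs, kinds=(kind,),
                                     average_instances=(kind == "consonant"))
            rdm = compute_rdm(trajs)
            iu = np.triu_indices(rdm.n_sounds, k=1)
            for i, j in zip(*iu):
                rows.append({"level": lvl,
                             "sound_i": str(rdm.sound_labels[i]),
                             "sound_j": str(rdm.sound_labels[j]),
                             "dissimilarity": rdm.matrix[i, j]})
        _write_csv(pd.DataFrame(rows), out / "rdm.csv")
        mark("rdm")
    return out


def report(bundle_dirs: list) -> pd.DataFrame:
    """Pairwise RDM-similarity table across bundles (incl. self = 1)."""
    rdms = {}
    for d in bundle_dirs:
        df = pd.read_csv(Path(d) / "rdm.csv")
        rdms[str(d)] = df
    names = list(rdms)
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            da, db = rdms[a], rdms[b]
            levels = sorted(set(da["level"]) & set(db["level"]))
            for lvl in levels:
                va = da[da.level == lvl]
                vb = db[db.level == lvl]
                if list(va.sound_i) != list(vb.sound_i):
                    raise ValueError("mismatched label sets between bundles")
                x = va.dissimilarity.to_numpy()
                y = vb.dissimilarity.to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                den = np.sqrt((xc @ xc) * (yc @ yc))
                sim = 1.0 if a == b else float(xc @ yc / den)
                rows.append({"bundle_a": a, "bundle_b": b, "level": lvl,
                             "rdm_similarity": sim})
    return pd.DataFrame(rows)
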