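"""Comparison of latent dynamics across animals and hearing conditions.

Tools operating on D x T latent trajectories (PCA projections or encoder
bottleneck activations):

* representational similarity analysis (RSA): per-sound trajectories are
  flattened into rows, a representational dissimilarity matrix (RDM) holds
  1 - correlation between rows, and two conditions are compared by the
  correlation of their RDMs' upper triangles;
* canonical correlation analysis (CCA) alignment with a variance-weighted
  similarity statistic, plus multiway CCA (MCCA) for joint alignment of
  three or more datasets (concatenate-whitened-datasets-then-PCA);
* "best intensity" selection: the presentation level for a hearing-loss
  condition that maximizes similarity to a normal-hearing reference,
  removing pure audibility effects;
* envelope-tracking strength (coefficient of variation of activations),
  frequency response areas (FRAs) from tone streams, consonant decoding
  with one-vs-one linear SVMs and max-wins voting, and target/masker
  correlation grids.

Correlation throughout is Pearson on mean-centered vectors; constant
vectors are excluded with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .manifold import LatentDynamics
from .waveform import StimulusLabel


def _as_matrix(X) -> np.ndarray:
    return X.X if isinstance(X, LatentDynamics) else np.atleast_2d(np.asarray(X, float))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        warnings.warn("constant vector in correlation; returning nan")
        return float("nan")
    return float(a @ b / den)


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """S x S representational dissimilarity matrix (1 - correlation)."""

    matrix: np.ndarray
    sound_labels: list

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise ValueError("RDM must be symmetric")

    @property
    def n_sounds(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_sounds, k=1)
        return self.matrix[iu]


def segment_dynamics(X: LatentDynamics, labels: list[StimulusLabel],
                     kinds: tuple = ("tone", "sam_freq", "sam_depth",
                                     "consonant", "nb_target"),
                     key_fields: tuple | None = None,
                     average_instances: bool = False) -> dict:
    """Split latent dynamics into per-sound trajectories keyed by label.

    Keys are tuples of the label fields that identify a sound (defaults per
    kind: tone -> frequency, SAM -> modulation frequency or depth, consonant
    -> consonant id). All trajectories are cut to the common minimum segment
    length. With ``average_instances`` the trajectories of repeated
    instances of the same key are averaged (used for consonants).
    """
    default_key = {"tone": ("frequency_hz",), "sam_freq": ("mod_freq_hz",),
                   "sam_depth": ("mod_depth",), "consonant": ("consonant_id",),
                   "nb_target": ("frequency_hz",)}
    Xm = _as_matrix(X)
    bin_s = X.bin_s if isinstance(X, LatentDynamics) else None
    if bin_s is None:
        raise ValueError("segment_dynamics needs LatentDynamics with bin_s")
    segs: dict = {}
    for lab in labels:
        if lab.kind not in kinds:
            continue
        fields = key_fields or default_key[lab.kind]
        key = tuple(getattr(lab, f) for f in fields)
        key = key[0] if len(key) == 1 else key
        i0 = int(round(lab.onset_s / bin_s))
        i1 = int(round((lab.onset_s + lab.duration_s) / bin_s))
        i1 = min(i1, Xm.shape[1])
        if i1 > i0:
            segs.setdefault(key, []).append(Xm[:, i0:i1])
    if not segs:
        raise ValueError("no labelled sounds of the requested kinds")
    ts = min(s.shape[1] for group in segs.values() for s in group)
    out = {}
    for key, group in segs.items():
        cut = np.stack([s[:, :ts] for s in group])
        if average_instances:
            out[key] = cut.mean(axis=0)
        else:
            for i, s in enumerate(cut):
                out[(key, i) if len(cut) > 1 else key] = s
    return out


def compute_rdm(trajectories: dict) -> RDM:
    """RDM from per-sound trajectories {label: Db x TS array}.

    Each trajectory is flattened (all channels' time courses concatenated);
    the entry for a pair of sounds is 1 - Pearson correlation. Sounds with a
    zero-variance trajectory yield nan entries with a warning.
    """
    keys = sorted(trajectories)
    rows = [np.asarray(trajectories[k], float).ravel() for k in keys]
    if len({r.size for r in rows}) != 1:
        raise ValueError("all sounds must have equal trajectory lengths")
    S = len(rows)
    m = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = _pearson(rows[i], rows[j])
            if np.isnan(c):
                warnings.warn(f"zero-variance trajectory for pair {keys[i]}, {keys[j]}")
            m[i, j] = m[j, i] = 1.0 - c
    return RDM(matrix=m, sound_labels=keys)


def rdm_similarity(rdm1: RDM, rdm2: RDM) -> float:
    """Pearson correlation of the vectorized upper triangles of two RDMs."""
    if rdm1.sound_labels != rdm2.sound_labels:
        raise ValueError("RDMs must share sounds and label order")
    return _pearson(rdm1.upper_triangle(), rdm2.upper_triangle())


def best_intensity(reference: RDM, candidates: dict) -> tuple[float, float]:
    """Level whose candidate RDM best matches the reference (ties -> lower).

    ``candidates`` maps presentation level to the RDM obtained at that
    level. Returns (best level, similarity at that level).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    best = None
    for level in sorted(candidates):
        sim = rdm_similarity(reference, candidates[level])
        if best is None or sim > best[1] + 1e-12:
            best = (level, sim)
    return best


# ---------------------------------------------------------------------------
# CCA / MCCA
# ---------------------------------------------------------------------------

@dataclass
class CCAAlignment:
    """Paired canonical bases with per-component correlations and weights.

    ``A``/``B`` map centered dynamics (time x dim) to canonical projections
    U = Xc A, V = Yc B with unit variance; ``rho`` holds the canonical
    correlations in descending order; ``weights`` the averaged squared
    correlations between each component's rank-1 reconstruction and its
    source dynamics (they partition the total variance, summing to 1 for
    full-rank dynamics).
    """

    A: np.ndarray
    B: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    rho: np.ndarray
    weights: np.ndarray
    rank_reduced: bool = False

    @property
    def n_components(self) -> int:
        return self.rho.size


def _qr_reduced(Xc: np.ndarray, tol: float = 1e-10):
    """Economic QR with rank truncation via SVD when needed."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * tol)) if s.size and s[0] > 0 else 0
    return U[:, :rank], s[:rank], Vt[:rank], rank


def cca_align(X, Y) -> CCAAlignment:
    """Canonical correlation alignment of two sets of latent dynamics.

    Computed via the QR/SVD route: whiten each centered dataset by its
    thin SVD, take the SVD of the cross-product of the whitened bases; the
    singular values are the canonical correlations. Rank-deficient dynamics
    are reduced to their numerical rank (flagged). The result is invariant
    to invertible linear transforms of either input.
    """
    Xm = _as_matrix(X).T  # time x dim
    Ym = _as_matrix(Y).T
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("dynamics must share the stimulus timeline")
    T = Xm.shape[0]
    x_mean, y_mean = Xm.mean(0), Ym.mean(0)
    Xc, Yc = Xm - x_mean, Ym - y_mean
    Px, sx, Vtx, rx = _qr_reduced(Xc)
    Py, sy, Vty, ry = _qr_reduced(Yc)
    reduced = (rx < Xm.shape[1]) or (ry < Ym.shape[1])
    if reduced:
        warnings.warn("rank-deficient dynamics: components reduced")
    d = min(rx, ry)
    Uu, rho, Vvt = np.linalg.svd(Px.T @ Py)
    Uu, rho, Vv = Uu[:, :d], np.clip(rho[:d], 0.0, 1.0), Vvt.T[:, :d]
    scale = np.sqrt(T - 1)
    A = Vtx.T @ (Uu / sx[:, None]) * scale
    B = Vty.T @ (Vv / sy[:, None]) * scale
    wx = _component_weights(Xc, A, Px @ Uu * scale)
    wy = _component_weights(Yc, B, Py @ Vv * scale)
    return CCAAlignment(A=A, B=B, x_mean=x_mean, y_mean=y_mean, rho=rho,
                        weights=0.5 * (wx + wy), rank_reduced=reduced)


def _component_weights(Xc: np.ndarray, A: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Squared correlation between each rank-1 reconstruction and the source.

    The reconstruction of X from component d is the d-th rank-1 term of the
    exact expansion X = U A^+ (pseudo-inverse of the canonical weights), so
    the weights partition the total variance and sum to 1 when the
    components span the dynamics.
    """
    Ainv = np.linalg.pinv(A)
    total = np.sum(Xc ** 2)
    w = np.empty(U.shape[1])
    for dd in range(U.shape[1]):
        Xhat = np.outer(U[:, dd], Ainv[dd, :])
        w[dd] = (np.sum(Xhat * Xc) / np.sqrt(np.sum(Xhat ** 2) * total)) ** 2
    return w


def cca_similarity(X, Y, align: CCAAlignment | None = None) -> float:
    """Weighted similarity of two sets of dynamics after CCA alignment.

    sum_d rho_d * w_d where w_d averages the squared correlations between
    each side's rank-1 reconstruction and its source dynamics. Bounded above
    by 1; equals 1 exactly when X and Y are invertible linear transforms of
    one another (in particular X = Y).
    """
    if align is None:
        align = cca_align(X, Y)
    return float(np.sum(align.rho * align.weights))


@dataclass
class MCCAAlignment:
    """Joint alignment of several datasets into one common space."""

    maps: list            # per-dataset dim x K projection matrices
    means: list
    common: np.ndarray    # T x K summary components (mean of projections)
    projections: list     # per-dataset T x K

    def component_correlations(self) -> np.ndarray:
        """Mean pairwise correlation between datasets per component."""
        K = self.common.shape[1]
        n = len(self.projections)
        out = np.zeros(K)
        for k in range(K):
            cs = [_pearson(self.projections[i][:, k], self.projections[j][:, k])
                  for i in range(n) for j in range(i + 1, n)]
            out[k] = np.nanmean(cs)
        return out


def mcca_align(datasets: list, n_components: int | None = None,
               eig_floor: float = 1e-8) -> MCCAAlignment:
    """Multiway CCA via the concatenate-whiten-PCA construction.

    Each dataset (D x T dynamics) is centered and whitened (PCA whitening,
    eigenvalues below ``eig_floor`` relative to the largest are dropped and
    flagged); the whitened datasets are concatenated along dimensions and a
    final PCA extracts joint components maximizing inter-set correlation.
    For two datasets this reduces to pairwise CCA up to component scale.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    mats = [_as_matrix(d).T for d in datasets]
    T = mats[0].shape[0]
    if any(m.shape[0] != T for m in mats):
        raise ValueError("datasets must share the stimulus timeline")
    whitened, whiteners, means = [], [], []
    for m in mats:
        mu = m.mean(0)
        mc = m - mu
        U, s, Vt = np.linalg.svd(mc, full_matrices=False)
        keep = s > np.sqrt(eig_floor) * s[0]
        if not keep.all():
            warnings.warn("rank-deficient dataset in MCCA: components dropped")
        Wh = Vt[keep].T / s[keep]           # dim x r whitener (up to sqrt(T-1))
        whitened.append(mc @ Wh)
        whiteners.append(Wh)
        means.append(mu)
    Z = np.concatenate(whitened, axis=1)
    Uz, sz, Vtz = np.linalg.svd(Z - Z.mean(0), full_matrices=False)
    K = sz.size if n_components is None else min(n_components, sz.size)
    V = Vtz[:K].T                            # sum(r_i) x K
    maps, projections = [], []
    offset = 0
    for Wh, mc in zip(whiteners, [m - m.mean(0) for m in mats]):
        r = Wh.shape[1]
        block = V[offset:offset + r]
        maps.append(Wh @ block)
        projections.append(mc @ (Wh @ block))
        offset += r
    common = np.mean(np.stack(projections), axis=0)
    return MCCAAlignment(maps=maps, means=means, common=common,
                         projections=projections)


# ---------------------------------------------------------------------------
# envelope tracking, FRAs, decoding, masking
# ---------------------------------------------------------------------------

def envelope_tracking_cv(traj: np.ndarray) -> float:
    """Envelope tracking strength: mean coefficient of variation (SD/mean)
    of the condition-mean activation time course over channels with positive
    mean. ``traj`` is a Db x TS mean trajectory for one condition with ramps
    excluded. Constant activations give 0."""
    traj = np.atleast_2d(np.asarray(traj, float))
    means = traj.mean(axis=1)
    pos = means > 0
    if not pos.any():
        raise ValueError("no channel with positive mean activation")
    return float(np.mean(traj[pos].std(axis=1) / means[pos]))


@dataclass
class FRA:
    """Per-channel frequency x level response surfaces from a tone stream."""

    response: np.ndarray   # channels x n_freqs x n_levels, nan where absent
    freqs_hz: np.ndarray
    levels_db: np.ndarray

    def normalized(self) -> np.ndarray:
        out = np.empty_like(self.response)
        for c in range(self.response.shape[0]):
            r = self.response[c]
            lo, hi = np.nanmin(r), np.nanmax(r)
            out[c] = (r - lo) / (hi - lo) if hi > lo else np.zeros_like(r)
        return out

    def best_frequency(self, channel: int, level_db: float) -> float:
        j = int(np.argmin(np.abs(self.levels_db - level_db)))
        return float(self.freqs_hz[np.nanargmax(self.response[channel, :, j])])


def compute_fra(X: LatentDynamics, labels: list[StimulusLabel]) -> FRA:
    """Mean activation per (tone frequency, level) cell per channel."""
    Xm = _as_matrix(X)
    bin_s = X.bin_s
    freqs = np.array(sorted({l.frequency_hz for l in labels if l.kind == "tone"}))
    levels = np.array(sorted({l.intensity_db_spl for l in labels if l.kind == "tone"}))
    if freqs.size == 0:
        raise ValueError("no tone labels")
    resp = np.full((Xm.shape[0], freqs.size, levels.size), np.nan)
    for lab in labels:
        if lab.kind != "tone":
            continue
        i = int(np.argmin(np.abs(freqs - lab.frequency_hz)))
        j = int(np.argmin(np.abs(levels - lab.intensity_db_spl)))
        b0 = int(round(lab.onset_s / bin_s))
        b1 = min(int(round((lab.onset_s + lab.duration_s) / bin_s)), Xm.shape[1])
        if b1 > b0:
            resp[:, i, j] = Xm[:, b0:b1].mean(axis=1)
    return FRA(response=resp, freqs_hz=freqs, levels_db=levels)


def decode_consonants(instances: np.ndarray, labels: np.ndarray,
                      folds: int = 10, C: float = 1.0,
                      seed: int = 0) -> float:
    """Cross-validated consonant identification accuracy.

    One-vs-one linear support-vector classifiers over all class pairs with
    max-wins voting (the native multiclass rule of the underlying SVC) and
    stratified k-fold cross-validation. Each row of ``instances`` is the
    flattened latent trajectory of one consonant instance. With 22 balanced
    classes, chance is 1/22 = 4.5%.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    instances = np.asarray(instances, float)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` instances")
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=int(seed) % (2 ** 31))
    scores = cross_val_score(clf, instances, labels, cv=cv)
    return float(scores.mean())


def masking_correlation(X_target, X_with_masker) -> float:
    """Point-by-point correlation between activations with/without masker."""
    a, b = _as_matrix(X_target), _as_matrix(X_with_masker)
    if a.shape != b.shape:
        raise ValueError("misaligned timelines: activation shapes differ")
    return _pearson(a, b)


def masking_correlation_grid(extract, target_cfs: np.ndarray,
                             masker_cfs: np.ndarray, level: float,
                             seed: int = 0):
    """Target/masker interaction grid for an encoder.

    ``extract`` is a callable Waveform -> LatentDynamics (e.g. a trained
    encoder's ``extract_bottleneck``). For every (target cf, masker cf) pair
    the target burst is presented alone and summed with the masker (same
    target waveform in both conditions), and the correlation between the two
    activation matrices is recorded. Returns a long-format DataFrame
    (target_cf, masker_cf, level, correlation).
    """
    import pandas as pd

    from .stimgen import make_narrowband_pair

    rows = []
    for i, tcf in enumerate(target_cfs):
        for j, mcf in enumerate(masker_cfs):
            tgt, msk = make_narrowband_pair(tcf, mcf, level,
                                            seed=seed * 10000 + i * 100 + j)
            alone = extract(tgt)
            mixed = extract(tgt.replace(samples=tgt.samples + msk.samples))
            rows.append({"target_cf": float(tcf), "masker_cf": float(mcf),
                         "level": float(level),
                         "correlation": masking_correlation(alone, mixed)})
    return pd.DataFrame(rows)
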