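"""Identification and quantification of the neural signal manifold.

Terminology: for a units x bins count matrix R recorded twice under
identical stimulation (Rtest1, Rtest2), the *signal* is the trial-
reproducible component (estimated via cross-trial covariances) and the
*noise* is the per-trial residual. PCA on a separate training matrix Rtrain
(row means subtracted; units are not z-scored) gives the principal
components Z; projecting test activity onto the first D PCs gives the
latent dynamics X = Z R, and reconstructions Zᵀ X are compared to the test
matrices to measure how much total and signal variance D dimensions retain.

The headline variance-explained statistic is a normalized covariance
(correlation-like), implemented literally as
cov(A, B) / sqrt(var(A) var(B)) over all matrix entries; a conventional
R-squared variant is available via ``statistic="r2"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_ic import DEFAULT_BIN_S


@dataclass
class PCBasis:
    """Principal components of a training recording (rows orthonormal)."""

    Z: np.ndarray            # D x M projection matrix
    unit_means: np.ndarray   # length M
    explained_variance: np.ndarray

    @property
    def max_dim(self) -> int:
        return self.Z.shape[0]


@dataclass
class LatentDynamics:
    """A D x T latent trajectory matrix with provenance."""

    X: np.ndarray
    bin_s: float = DEFAULT_BIN_S
    provenance: str = "pca"   # "pca" | "bottleneck"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("latent dynamics must be finite")

    @property
    def dim(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]


@dataclass
class SignalNoiseStats:
    """Per-unit variance and per-pair correlation decomposition.

    The decomposition is additive by construction: per unit,
    total = signal + noise variance exactly; per pair, total correlation =
    signal + noise correlation (all three normalized by the total
    variances, so the shares are directly comparable).
    """

    total_var: np.ndarray
    signal_var: np.ndarray
    noise_var: np.ndarray
    total_corr: np.ndarray
    signal_corr: np.ndarray
    noise_corr: np.ndarray
    valid: np.ndarray

    @property
    def signal_share(self) -> np.ndarray:
        """Per-unit fraction of variance that is trial-reproducible."""
        return self.signal_var / self.total_var


def _center_rows(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    R = np.asarray(R, float)
    m = R.mean(axis=1, keepdims=True)
    return R - m, m


def signal_noise_stats(rec1: np.ndarray, rec2: np.ndarray) -> SignalNoiseStats:
    """Decompose activity into signal and noise across two repeats.

    Per unit: signal variance is the cross-trial covariance, total variance
    the average single-trial variance, noise their difference. Per pair of
    units: the signal covariance is the symmetrized cross-trial cross-unit
    covariance; correlations are normalized by the total variances. Unbiased
    (n-1) covariance estimators are used throughout. Zero-variance units are
    flagged invalid and their correlations set to nan.
    """
    R1, R2 = np.atleast_2d(rec1).astype(float), np.atleast_2d(rec2).astype(float)
    if R1.shape != R2.shape:
        raise ValueError("repeats must have equal shapes")
    M, T = R1.shape
    A, _ = _center_rows(R1)
    B, _ = _center_rows(R2)
    n1 = T - 1
    cov11 = A @ A.T / n1
    cov22 = B @ B.T / n1
    cov12 = A @ B.T / n1
    total_cov = 0.5 * (cov11 + cov22)
    signal_cov = 0.5 * (cov12 + cov12.T)
    noise_cov = total_cov - signal_cov
    total_var = np.diag(total_cov).copy()
    signal_var = np.diag(signal_cov).copy()
    noise_var = total_var - signal_var
    valid = total_var > 0
    denom = np.sqrt(np.outer(total_var, total_var))
    with np.errstate(invalid="ignore", divide="ignore"):
        total_corr = total_cov / denom
        signal_corr = signal_cov / denom
        noise_corr = noise_cov / denom
    for m in (total_corr, signal_corr, noise_corr):
        m[~valid, :] = np.nan
        m[:, ~valid] = np.nan
    return SignalNoiseStats(total_var, signal_var, noise_var,
                            total_corr, signal_corr, noise_corr, valid)


def fit_pcs(Rtrain: np.ndarray, n_components: int | None = None) -> PCBasis:
    """PCA of a training recording after subtracting each row's mean.

    Components are ordered by explained variance (descending); degenerate
    rank is handled by truncating to the numerical rank.
    """
    R = np.atleast_2d(np.asarray(Rtrain, float))
    M, T = R.shape
    if T <= M:
        raise ValueError("need more time bins than units for PCA")
    Rc, means = _center_rows(R)
    U, s, _ = np.linalg.svd(Rc, full_matrices=False)
    ev = s ** 2 / (T - 1)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    d = rank if n_components is None else min(n_components, rank)
    return PCBasis(Z=U[:, :d].T, unit_means=means.ravel(),
                   explained_variance=ev[:d])


def project(R: np.ndarray, basis: PCBasis, D: int | None = None,
            provenance: str = "pca") -> LatentDynamics:
    """Project a recording onto the first D PCs (training means removed)."""
    D = basis.max_dim if D is None else D
    Z = basis.Z[:D]
    X = Z @ (np.asarray(R, float) - basis.unit_means[:, None])
    return LatentDynamics(X=X, provenance=provenance)


def _norm_cov(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized covariance over all entries: cov/sqrt(var*var)."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / den) if den > 0 else 0.0


def _r2(target: np.ndarray, recon: np.ndarray) -> float:
    t = target.ravel()
    sse = np.sum((t - recon.ravel()) ** 2)
    sst = np.sum((t - t.mean()) ** 2)
    return float(1.0 - sse / sst) if sst > 0 else 0.0


def _reconstruct(R: np.ndarray, Z: np.ndarray, means: np.ndarray,
                 restore_means: np.ndarray) -> np.ndarray:
    X = Z @ (R - means[:, None])
    return Z.T @ X + restore_means[:, None]


def total_variance_explained(Rtest1: np.ndarray, basis: PCBasis, D: int,
                             statistic: str = "normalized_cov") -> float:
    """Variance of a test recording retained by its own D-dim reconstruction."""
    if D == 0:
        return 0.0
    R = np.atleast_2d(np.asarray(Rtest1, float))
    m = R.mean(axis=1)
    Rhat = _reconstruct(R, basis.Z[:D], m, m)
    return _norm_cov(R, Rhat) if statistic == "normalized_cov" else _r2(R, Rhat)


def signal_variance_explained(Rtest1: np.ndarray, Rtest2: np.ndarray,
                              basis: PCBasis, D: int,
                              statistic: str = "normalized_cov") -> float:
    """Signal variance explained: reconstruct trial 1, compare to trial 2.

    Only trial-reproducible structure can survive this comparison, so the
    statistic isolates the signal component. The reconstruction restores the
    row means of trial 2.
    """
    if D == 0:
        return 0.0
    R1 = np.atleast_2d(np.asarray(Rtest1, float))
    R2 = np.atleast_2d(np.asarray(Rtest2, float))
    if R1.shape != R2.shape:
        raise ValueError("repeats must have equal shapes")
    Rhat2 = _reconstruct(R1, basis.Z[:D], R1.mean(axis=1), R2.mean(axis=1))
    return _norm_cov(R2, Rhat2) if statistic == "normalized_cov" else _r2(R2, Rhat2)


def variance_curves(Rtest1: np.ndarray, Rtest2: np.ndarray, basis: PCBasis,
                    dims: np.ndarray | None = None) -> dict:
    """Total- and signal-variance-explained as functions of D (tidy dict)."""
    dims = np.arange(1, basis.max_dim + 1) if dims is None else np.asarray(dims)
    return {"D": dims,
            "total": np.array([total_variance_explained(Rtest1, basis, d)
                               for d in dims]),
            "signal": np.array([signal_variance_explained(Rtest1, Rtest2, basis, d)
                                for d in dims])}


def signal_dimensionality(curve: np.ndarray, criterion: float = 0.95) -> int | None:
    """Smallest D whose curve value reaches ``criterion`` x the plateau.

    ``curve[i]`` is the signal variance explained with D = i + 1. The plateau
    is the curve maximum. Returns None (sentinel) if the curve is still
    rising steeply at its end, i.e. has not saturated.
    """
    curve = np.asarray(curve, float)
    plateau = curve.max()
    if plateau <= 0:
        return None
    d_star = int(np.argmax(curve >= criterion * plateau)) + 1
    if d_star == curve.size and curve.size >= 2:
        if curve[-1] - curve[-2] > 0.01 * plateau:
            return None  # not saturated
    return d_star


def per_pc_signal_fraction(Rtest1: np.ndarray, Rtest2: np.ndarray,
                           basis: PCBasis) -> np.ndarray:
    """Per-PC fraction of projected variance that is signal.

    For each PC, the cross-trial covariance of the two repeats' projections
    divided by their average projection variance; in [-1, 1]. PCs with zero
    projection variance yield nan.
    """
    R1c, _ = _center_rows(np.atleast_2d(Rtest1))
    R2c, _ = _center_rows(np.atleast_2d(Rtest2))
    x1 = basis.Z @ R1c
    x2 = basis.Z @ R2c
    T = x1.shape[1]
    cov = np.sum(x1 * x2, axis=1) / (T - 1)
    v = 0.5 * (x1.var(axis=1, ddof=1) + x2.var(axis=1, ddof=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / v
    out[v == 0] = np.nan
    return out


def cross_animal_similarity(X: LatentDynamics | np.ndarray,
                            Y: LatentDynamics | np.ndarray) -> float:
    """Variance in Y's dynamics explained by linear regression on X's.

    Ordinary least squares of Y on X with an intercept, computed in-sample;
    returns 1 - SSE/SST pooled over the target dimensions. Both dynamics
    must share the stimulus timeline (equal T).
    """
    Xm = X.X if isinstance(X, LatentDynamics) else np.atleast_2d(X)
    Ym = Y.X if isinstance(Y, LatentDynamics) else np.atleast_2d(Y)
    if Xm.shape[1] != Ym.shape[1]:
        raise ValueError("dynamics must share the stimulus timeline")
    T = Xm.shape[1]
    if T <= Xm.shape[0]:
        raise ValueError("need more time bins than predictor dimensions")
    design = np.column_stack([np.ones(T), Xm.T])
    coef, *_ = np.linalg.lstsq(design, Ym.T, rcond=None)
    resid = Ym.T - design @ coef
    sse = np.sum(resid ** 2)
    sst = np.sum((Ym.T - Ym.T.mean(axis=0)) ** 2)
    return float(1.0 - sse / sst) if sst > 0 else 0.0


def curves_to_frame(animal_id: str, curves: dict):
    """Tidy (animal_id, D, metric, value) DataFrame for CSV export."""
    import pandas as pd

    rows = []
    for metric in ("total", "signal"):
        for d, v in zip(curves["D"], curves[metric]):
            rows.append({"animal_id": animal_id, "D": int(d),
                         "metric": metric, "value": float(v)})
    return pd.DataFrame(rows)
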