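"""Filtering (scanning) source estimators: UNG beamformer and dipole scan.

Both methods sweep the whole source space and score each candidate location
independently.

Unit noise gain (Borgiotti-Kaplan) beamformer: at location k and orientation
theta the spatial filter minimizes the filtered error power w^T Sigma w
subject to w^T L_k theta = tau and the unit-noise-gain constraint
w^T w = 1, which gives

    w_k(theta) = Sigma^-1 L_k theta / sqrt(theta^T L_k^T Sigma^-2 L_k theta).

The orientation is taken as the power-maximizing direction, the top
eigenvector of (L_k^T Sigma^-2 L_k)^-1 (L_k^T Sigma^-1 L_k).

Dipole scan: per-location least-squares dipole fit scored by the goodness

    g_k = 1 - ||y - L_k L_k^+ y||^2 / ||y||^2  in [0, 1].

Model classes (`UnitNoiseGainBeamformer`, `DipoleScan`) wrap the functional
operations in a fit() -> results interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .exceptions import (
    CovarianceError,
    RankError,
    SilentSourceError,
    UndefinedFitError,
)
from .headmodel import LeadField, Measurement
from .svd_transform import location_svd

__all__ = [
    "SpatialCovariance",
    "ScanResult",
    "estimate_covariance",
    "ung_filter",
    "ung_orientation",
    "ung_scan",
    "ds_goodness",
    "ds_scan",
    "UnitNoiseGainBeamformer",
    "DipoleScan",
]

#: singular values below this fraction of the largest are truncated in L_k^+
PINV_RTOL = 1e-10


@dataclass(frozen=True)
class SpatialCovariance:
    """Measurement-space covariance with its provenance and loading."""

    Sigma: np.ndarray
    regularization: float = 0.0
    provenance: str = "noise_plus_signal"  # or "sample_over_time"

    def __post_init__(self):
        S = np.asarray(self.Sigma, dtype=float)
        object.__setattr__(self, "Sigma", S)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise CovarianceError("Sigma must be square")
        if not np.allclose(S, S.T, atol=1e-12 * max(1.0, np.abs(S).max())):
            raise CovarianceError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise CovarianceError("Sigma must be positive definite") from exc

    def inv(self) -> np.ndarray:
        return np.linalg.inv(self.Sigma)


@dataclass(frozen=True)
class ScanResult:
    """Per-location scores, orientations and dipole moments of a scan."""

    scores: np.ndarray
    orientations: np.ndarray  # (n, 3), unit norm
    best_index: int
    ties: tuple[int, ...] = ()
    moments: np.ndarray | None = None  # (n, 3), dipole-scan only
    method: str = ""
    degenerate: np.ndarray | None = None

    def peak(self) -> tuple[int, np.ndarray]:
        """Best location index and its moment (or unit orientation)."""
        k = self.best_index
        mom = self.moments[k] if self.moments is not None else self.orientations[k]
        return k, mom

    def summary(self) -> str:
        k = self.best_index
        lines = [
            f"{self.method or 'scan'} over {len(self.scores)} locations",
            f"  best location index : {k}",
            f"  best score          : {self.scores[k]:.6g}",
            f"  orientation         : "
            + np.array2string(self.orientations[k], precision=4),
        ]
        if self.moments is not None:
            lines.append(
                f"  moment (nAm)        : "
                + np.array2string(self.moments[k], precision=4)
            )
        if len(self.ties) > 1:
            lines.append(f"  tied locations      : {list(self.ties)}")
        return "\n".join(lines)


def estimate_covariance(
    data: Measurement | np.ndarray,
    mode: str = "noise_plus_signal",
    noise_cov: np.ndarray | None = None,
    loading: float = 0.05,
) -> SpatialCovariance:
    """Build the scan covariance Sigma from data.

    ``sample_over_time``: sample covariance of a channels x samples window
    plus Tikhonov diagonal loading ``loading * trace/m``.
    ``noise_plus_signal``: rank-one signal surrogate y y^T plus the noise
    covariance, for single-vector simulated data.
    """
    if isinstance(data, Measurement):
        y = data.y
        if noise_cov is None:
            noise_cov = data.noise_cov
    else:
        y = np.asarray(data, dtype=float)
    if mode == "sample_over_time":
        if y.ndim != 2 or y.shape[1] < 2:
            raise CovarianceError("sample_over_time needs a channels x samples array")
        yc = y - y.mean(axis=1, keepdims=True)
        S = yc @ yc.T / (y.shape[1] - 1)
        lam = loading * np.trace(S) / S.shape[0]
        return SpatialCovariance(S + lam * np.eye(S.shape[0]), lam, "sample_over_time")
    if mode == "noise_plus_signal":
        v = y if y.ndim == 1 else y[:, 0]
        if noise_cov is None:
            raise CovarianceError("noise_plus_signal needs a noise covariance")
        return SpatialCovariance(np.outer(v, v) + noise_cov, 0.0, "noise_plus_signal")
    raise CovarianceError(f"unknown covariance mode {mode!r}")


def ung_filter(Sigma: SpatialCovariance | np.ndarray, L_k: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unit-noise-gain spatial filter for an oriented dipole.

    Satisfies ||w|| = 1 analytically and w^T L_k theta > 0.
    """
    S = Sigma.Sigma if isinstance(Sigma, SpatialCovariance) else np.asarray(Sigma, float)
    theta = np.asarray(theta, dtype=float)
    lt = L_k @ theta
    if np.linalg.norm(lt) == 0.0:
        raise SilentSourceError("L_k theta = 0: oriented source produces no signal")
    z = np.linalg.solve(S, lt)  # Sigma^-1 L_k theta
    denom = z @ z  # theta^T L_k^T Sigma^-2 L_k theta
    if denom <= 0.0:
        raise SilentSourceError("filter denominator vanished")
    return z / np.sqrt(denom)


def ung_orientation(
    Sigma: SpatialCovariance | np.ndarray, L_k: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Power-maximizing orientation of the UNG beamformer at one location.

    Solves the 3x3 generalized symmetric eigenproblem
    (L^T Sigma^-1 L) v = lambda (L^T Sigma^-2 L) v and returns the top
    eigenvector.  When the top two eigenvalues agree within 1e-8 relative
    the orientation is ambiguous; a deterministic fallback (the strongest
    output direction v_1 of L_k, fixed sign) is returned with the flag set.
    """
    S = Sigma.Sigma if isinstance(Sigma, SpatialCovariance) else np.asarray(Sigma, float)
    sv = np.linalg.svd(L_k, compute_uv=False)
    if sv[-1] <= 1e-12 * sv[0]:
        raise RankError("sub-lead-field is rank deficient")
    Z = np.linalg.solve(S, L_k)  # Sigma^-1 L_k
    P = L_k.T @ Z  # L^T Sigma^-1 L
    Q = Z.T @ Z  # L^T Sigma^-2 L
    P = 0.5 * (P + P.T)
    Q = 0.5 * (Q + Q.T)
    evals, evecs = sla.eigh(P, Q)
    degenerate = (evals[-1] - evals[-2]) <= 1e-8 * abs(evals[-1])
    if degenerate:
        v = location_svd(L_k, 0).V[:, 0]
    else:
        v = evecs[:, -1]
        v = v / np.linalg.norm(v)
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
    return v, bool(degenerate)


def _ties(scores: np.ndarray, rtol: float) -> tuple[int, ...]:
    """Indices scoring within ``rtol`` of the maximum (always includes it)."""
    top = scores.max()
    tol = rtol * abs(top) if top != 0 else rtol
    return tuple(int(i) for i in np.flatnonzero(scores >= top - tol))


def ung_scan(
    data: Measurement | np.ndarray,
    L: LeadField,
    cov_mode: str = "noise_plus_signal",
    noise_cov: np.ndarray | None = None,
    loading: float = 0.05,
    tie_rtol: float = 1e-9,
) -> ScanResult:
    """UNG beamformer scan: per-location orientation and output power."""
    Sigma = estimate_covariance(data, cov_mode, noise_cov=noise_cov, loading=loading)
    y = data.vector if isinstance(data, Measurement) else np.asarray(data, float)
    if y.ndim == 2:
        # orient the sign at the dominant sample of the series
        dom = int(np.argmax(np.abs(y).max(axis=0)))
        yref = y[:, dom]
    else:
        yref = y
    n = L.n_sources
    scores = np.empty(n)
    orients = np.empty((n, 3))
    degen = np.zeros(n, dtype=bool)
    for k in range(n):
        Lk = L.sub(k)
        theta, dflag = ung_orientation(Sigma, Lk)
        w = ung_filter(Sigma, Lk, theta)
        if w @ yref < 0:
            theta = -theta
            w = -w
        scores[k] = w @ Sigma.Sigma @ w
        orients[k] = theta
        degen[k] = dflag
    return ScanResult(
        scores=scores,
        orientations=orients,
        best_index=int(np.argmax(scores)),
        ties=_ties(scores, tie_rtol),
        method="ung",
        degenerate=degen,
    )


def ds_goodness(y: np.ndarray, L_k: np.ndarray) -> float:
    """Residual-variance goodness of fit of a single dipole at one location."""
    y = np.asarray(y, dtype=float)
    if np.linalg.norm(y) == 0.0:
        raise UndefinedFitError("goodness of fit undefined for y = 0")
    coef, *_ = np.linalg.lstsq(L_k, y, rcond=PINV_RTOL)
    resid = y - L_k @ coef
    g = 1.0 - (resid @ resid) / (y @ y)
    return float(min(max(g, 0.0), 1.0))


def ds_scan(
    y: np.ndarray | Measurement,
    L: LeadField,
    tie_rtol: float = 0.01,
) -> ScanResult:
    """Dipole scan: goodness of fit and fitted moment at every location.

    The best index takes the lowest-index maximum; locations scoring within
    ``tie_rtol`` (default 1%) of the maximum are reported as ties.
    """
    yv = y.vector if isinstance(y, Measurement) else np.asarray(y, dtype=float)
    if np.linalg.norm(yv) == 0.0:
        raise UndefinedFitError("dipole scan undefined for y = 0")
    n = L.n_sources
    scores = np.empty(n)
    moments = np.empty((n, 3))
    yy = yv @ yv
    for k in range(n):
        Lk = L.sub(k)
        coef, *_ = np.linalg.lstsq(Lk, yv, rcond=PINV_RTOL)
        resid = yv - Lk @ coef
        scores[k] = min(max(1.0 - (resid @ resid) / yy, 0.0), 1.0)
        moments[k] = coef
    norms = np.linalg.norm(moments, axis=1)
    orients = np.divide(
        moments, np.where(norms > 0, norms, 1.0)[:, None], out=np.zeros_like(moments)
    )
    return ScanResult(
        scores=scores,
        orientations=orients,
        best_index=int(np.argmax(scores)),
        ties=_ties(scores, tie_rtol),
        moments=moments,
        method="ds",
    )


# ---------------------------------------------------------------------------
# model-style wrappers


class UnitNoiseGainBeamformer:
    """Unit-noise-gain beamformer scan as a fit()-style model.

    Parameters
    ----------
    data : Measurement or ndarray
        Potential vector (or channels x samples window).
    leadfield : LeadField
    cov_mode : {"noise_plus_signal", "sample_over_time"}
        Covariance estimator; the rank-one-plus-noise surrogate is the
        default for single-vector simulated data.
    """

    def __init__(self, data, leadfield: LeadField, cov_mode: str = "noise_plus_signal",
                 noise_cov: np.ndarray | None = None, loading: float = 0.05):
        self.data = data
        self.leadfield = leadfield
        self.cov_mode = cov_mode
        self.noise_cov = noise_cov
        self.loading = loading

    def fit(self) -> ScanResult:
        return ung_scan(
            self.data,
            self.leadfield,
            cov_mode=self.cov_mode,
            noise_cov=self.noise_cov,
            loading=self.loading,
        )


class DipoleScan:
    """Exhaustive single-dipole least-squares scan as a fit()-style model."""

    def __init__(self, data, leadfield: LeadField, tie_rtol: float = 0.01):
        self.data = data
        self.leadfield = leadfield
        self.tie_rtol = tie_rtol

    def fit(self) -> ScanResult:
        return ds_scan(self.data, self.leadfield, tie_rtol=self.tie_rtol)
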