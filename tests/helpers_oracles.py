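"""Independent oracles used by the test suite.

Everything here is deliberately implemented along different algorithmic
routes than the package (proximal gradient instead of MM-LQA, explicit
Legendre series instead of the shell recursion, explicit rotation matrices
instead of projection algebra) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, lpmv


def fista_l1(yt: np.ndarray, Lt: np.ndarray, gamma: np.ndarray, iters: int = 40000) -> np.ndarray:
    """Accelerated proximal gradient for 1/2||yt - Lt x||^2 + sum gamma|x|."""
    Lip = np.linalg.norm(Lt, 2) ** 2
    x = np.zeros(Lt.shape[1])
    z = x.copy()
    t = 1.0
    for _ in range(iters):
        g = Lt.T @ (Lt @ z - yt)
        xn = z - g / Lip
        xn = np.sign(xn) * np.maximum(np.abs(xn) - gamma / Lip, 0.0)
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = xn + (t - 1.0) / tn * (xn - x)
        x, t = xn, tn
    return x


def fista_group(yt: np.ndarray, Lt: np.ndarray, gamma: np.ndarray, iters: int = 40000) -> np.ndarray:
    """Accelerated proximal gradient with the block (3-vector) soft threshold."""
    Lip = np.linalg.norm(Lt, 2) ** 2
    p = Lt.shape[1]
    x = np.zeros(p)
    z = x.copy()
    t = 1.0
    for _ in range(iters):
        g = Lt.T @ (Lt @ z - yt)
        v = (z - g / Lip).reshape(-1, 3)
        nrm = np.linalg.norm(v, axis=1)
        scale = np.maximum(1.0 - (gamma / Lip) / np.where(nrm > 0, nrm, 1.0), 0.0)
        xn = (v * scale[:, None]).ravel()
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = xn + (t - 1.0) / tn * (xn - x)
        x, t = xn, tn
    return x


def objective_l1(yt, Lt, gamma, x):
    r = yt - Lt @ x
    return 0.5 * (r @ r) + (gamma * np.abs(x)).sum()


def objective_group(yt, Lt, gamma, x):
    r = yt - Lt @ x
    return 0.5 * (r @ r) + (gamma * np.linalg.norm(x.reshape(-1, 3), axis=1)).sum()


def single_sphere_potential(epos: np.ndarray, r0: np.ndarray, moment: np.ndarray,
                            radius: float, sigma: float, n_terms: int = 80) -> np.ndarray:
    """Textbook homogeneous-sphere dipole potential (microvolt).

    Scalar Legendre series with the dipole rotated onto the z axis and
    associated Legendre functions from scipy (Condon-Shortley phase), summed
    pointwise per electrode.
    """
    b = np.linalg.norm(r0)
    zhat = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    out = np.empty(len(epos))
    for idx, e in enumerate(epos):
        ed = e / np.linalg.norm(e)
        u = float(np.clip(ed @ zhat, -1.0, 1.0))
        tang = ed - u * zhat
        tn = np.linalg.norm(tang)
        that = tang / tn if tn > 1e-14 else np.zeros(3)
        mr = moment @ zhat
        mt = moment @ that
        tot = 0.0
        for n in range(1, n_terms + 1):
            Pn = eval_legendre(n, u)
            Pn1 = lpmv(1, n, u)
            tot += ((2 * n + 1) / n) * (b / radius) ** (n - 1) * (n * mr * Pn - mt * Pn1)
        out[idx] = tot / (4.0 * np.pi * sigma * radius**2) * 1.0e3
    return out


def grid_search_orientation(Sigma: np.ndarray, Lk: np.ndarray,
                            directions: np.ndarray) -> np.ndarray:
    """Brute-force power-ratio maximizer over a precomputed direction grid."""
    Z = np.linalg.solve(Sigma, Lk)
    P = Lk.T @ Z
    Q = Z.T @ Z
    num = np.einsum("ij,jk,ik->i", directions, P, directions)
    den = np.einsum("ij,jk,ik->i", directions, Q, directions)
    return directions[int(np.argmax(num / den))]


def unit_sphere_grid(step_deg: float = 1.0) -> np.ndarray:
    th = np.radians(np.arange(0.0, 180.0, step_deg))
    ph = np.radians(np.arange(0.0, 360.0, step_deg))
    T, P = np.meshgrid(th, ph, indexing="ij")
    return np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    ).reshape(-1, 3)


def rotation_angular_errors(true_moment, est_moment, a1, a2, r):
    """Explicit rotation-matrix version of the two-step angular error.

    Expresses both moments in the local frame, measures the azimuth gap,
    rotates the estimate about the radial axis by exactly that gap with an
    explicit rotation matrix, and then reads off the elevation difference.
    """
    from scipy.spatial.transform import Rotation

    t = np.asarray(true_moment, float)
    e = np.asarray(est_moment, float)
    if t @ e < 0:
        e = -e
    B = np.column_stack([a1, a2, r])
    tl = B.T @ t
    el = B.T @ e
    phi_t = np.arctan2(tl[1], tl[0])
    phi_e = np.arctan2(el[1], el[0])
    dphi = np.degrees(abs(np.angle(np.exp(1j * (phi_e - phi_t)))))
    rot = Rotation.from_rotvec(np.array([0.0, 0.0, 1.0]) * (phi_t - phi_e))
    el_aligned = rot.apply(el)
    pol = lambda v: np.degrees(np.arctan2(v[2], np.hypot(v[0], v[1])))
    dtheta = abs(pol(tl) - pol(el_aligned))
    if dtheta > 90.0:
        dtheta = 180.0 - dtheta
    return float(dphi), float(dtheta)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR with positive determinant."""
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
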