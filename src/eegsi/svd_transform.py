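"""Per-location SVD orientation bases and the block coordinate transform.

Every source location k contributes an m x 3 sub-lead-field L_k.  Its
singular value decomposition L_k = U_k diag(s_k) V_k^T orders the three
moment directions by how strongly they drive the electrodes: v_1 is the
strongest output direction (tangential for superficial sources under the
montage), v_3 the weakest (radial there).  Stacking the V_k along the block
diagonal gives an orthogonal 3n x 3n operator ``V`` with ``x = V xi``;
enforcing componentwise sparsity on ``xi`` instead of on the Cartesian
moments removes the arbitrary MRI-axis alignment from the L1 prior.

The block operator is never materialized densely; it is stored as the
(n, 3, 3) stack of V_k together with the singular values and (optionally)
the left singular vectors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import h5py

from .exceptions import DegenerateLocationError, ProvenanceError
from .headmodel import LeadField

__all__ = [
    "LocationBasis",
    "BlockBasis",
    "TransformedLeadField",
    "location_svd",
    "build_block_basis",
    "transform_leadfield",
    "back_transform",
    "leadfield_hash",
]

#: relative gap below which two singular values count as degenerate
DEGENERACY_RTOL = 1e-6


def leadfield_hash(gain: np.ndarray) -> str:
    """SHA-256 of the raw gain bytes; used for basis provenance checks."""
    return hashlib.sha256(np.ascontiguousarray(gain, dtype=float).tobytes()).hexdigest()


@dataclass(frozen=True)
class LocationBasis:
    """SVD triple of one sub-lead-field, with a deterministic sign convention.

    Each pair (u_i, v_i) is flipped so the largest-magnitude entry of u_i is
    positive (ties broken by lowest channel index), which makes the
    decomposition reproducible across LAPACK implementations.
    ``degenerate`` flags near-equal consecutive singular values.
    """

    U: np.ndarray  # (m, 3)
    s: np.ndarray  # (3,), descending
    V: np.ndarray  # (3, 3), columns v_1, v_2, v_3
    degenerate: bool = False


@dataclass(frozen=True)
class BlockBasis:
    """Block-diagonal orientation basis for a whole lead field.

    ``V[k]`` is the 3x3 right-singular-vector block of location k; the
    implied 3n x 3n operator acts blockwise and is orthogonal.
    """

    V: np.ndarray  # (n, 3, 3)
    s: np.ndarray  # (n, 3)
    U: np.ndarray | None  # (n, m, 3) or None
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    source_hash: str = ""

    @property
    def n_sources(self) -> int:
        return self.V.shape[0]

    def block(self, k: int) -> LocationBasis:
        return LocationBasis(
            U=self.U[k] if self.U is not None else None,
            s=self.s[k],
            V=self.V[k],
            degenerate=bool(self.degenerate[k]),
        )

    def apply(self, xi: np.ndarray) -> np.ndarray:
        """x = V xi (moments from transformed coefficients)."""
        xi = np.asarray(xi, dtype=float)
        if xi.shape[-1] != 3 * self.n_sources:
            raise ValueError("coefficient vector length must be 3n")
        blocks = xi.reshape(*xi.shape[:-1], self.n_sources, 3)
        out = np.einsum("kij,...kj->...ki", self.V, blocks)
        return out.reshape(xi.shape)

    def apply_transpose(self, x: np.ndarray) -> np.ndarray:
        """xi = V^T x (transformed coefficients from moments)."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != 3 * self.n_sources:
            raise ValueError("moment vector length must be 3n")
        blocks = x.reshape(*x.shape[:-1], self.n_sources, 3)
        out = np.einsum("kji,...kj->...ki", self.V, blocks)
        return out.reshape(x.shape)

    def to_hdf5(self, path) -> None:
        with h5py.File(str(path), "w") as fh:
            fh.create_dataset("V", data=self.V)
            fh.create_dataset("S", data=self.s)
            if self.U is not None:
                fh.create_dataset("U", data=self.U)
            fh.create_dataset("degenerate", data=self.degenerate.astype("u1"))
            fh.attrs["source_hash"] = self.source_hash

    @classmethod
    def from_hdf5(cls, path) -> "BlockBasis":
        with h5py.File(str(path), "r") as fh:
            return cls(
                V=fh["V"][()],
                s=fh["S"][()],
                U=fh["U"][()] if "U" in fh else None,
                degenerate=fh["degenerate"][()].astype(bool),
                source_hash=str(fh.attrs.get("source_hash", "")),
            )


@dataclass(frozen=True)
class TransformedLeadField:
    """A = L V, the lead field expressed in the SVD orientation bases.

    Column 3k+i equals s_k[i] * U_k[:, i]; the transform is orthogonal so
    the Frobenius norm of A equals that of L.
    """

    A: np.ndarray
    basis: BlockBasis
    source_hash: str = ""


def _signed_svd(Lk: np.ndarray, k: int) -> LocationBasis:
    U, s, Vt = np.linalg.svd(Lk, full_matrices=False)
    if not np.isfinite(s).all() or s[0] <= 0.0:
        raise DegenerateLocationError(k)
    V = Vt.T
    # deterministic signs: largest-|entry| of each u_i positive
    for i in range(3):
        j = int(np.argmax(np.abs(U[:, i])))  # argmax takes the lowest index on ties
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    degenerate = ((s[0] - s[1]) / s[0] < DEGENERACY_RTOL) or (
        (s[1] - s[2]) / s[0] < DEGENERACY_RTOL
    )
    return LocationBasis(U=U, s=s, V=V, degenerate=bool(degenerate))


def location_svd(L: LeadField | np.ndarray, k: int) -> LocationBasis:
    """SVD orientation basis of location ``k`` (0-based)."""
    gain = L.gain if isinstance(L, LeadField) else np.asarray(L, dtype=float)
    n = gain.shape[1] // 3
    if not 0 <= k < n:
        raise IndexError(f"location {k} out of range [0, {n})")
    return _signed_svd(gain[:, 3 * k : 3 * k + 3].copy(), k)


def build_block_basis(
    L: LeadField | np.ndarray,
    exclude: np.ndarray | None = None,
    store_u: bool = True,
) -> BlockBasis:
    """Factor every sub-lead-field; raises on a degenerate location unless
    it is listed in ``exclude`` (excluded blocks get an identity basis)."""
    gain = L.gain if isinstance(L, LeadField) else np.asarray(L, dtype=float)
    m, p = gain.shape
    n = p // 3
    excl = np.zeros(n, dtype=bool)
    if exclude is not None:
        excl[np.asarray(exclude, dtype=int)] = True
    V = np.empty((n, 3, 3))
    s = np.empty((n, 3))
    U = np.empty((n, m, 3)) if store_u else None
    degen = np.zeros(n, dtype=bool)
    for k in range(n):
        if excl[k]:
            V[k] = np.eye(3)
            s[k] = 0.0
            if store_u:
                U[k] = 0.0
            continue
        b = _signed_svd(gain[:, 3 * k : 3 * k + 3].copy(), k)
        V[k] = b.V
        s[k] = b.s
        if store_u:
            U[k] = b.U
        degen[k] = b.degenerate
    return BlockBasis(V=V, s=s, U=U, degenerate=degen, source_hash=leadfield_hash(gain))


def transform_leadfield(L: LeadField | np.ndarray, basis: BlockBasis) -> TransformedLeadField:
    """A = L V, built blockwise.  ``basis`` must come from this lead field."""
    gain = L.gain if isinstance(L, LeadField) else np.asarray(L, dtype=float)
    h = leadfield_hash(gain)
    if basis.source_hash and basis.source_hash != h:
        raise ProvenanceError("basis was not built from this lead field")
    m, p = gain.shape
    n = p // 3
    A = np.einsum("mkj,kji->mki", gain.reshape(m, n, 3), basis.V).reshape(m, p)
    return TransformedLeadField(A=A, basis=basis, source_hash=h)


def back_transform(basis: BlockBasis, xi: np.ndarray) -> np.ndarray:
    """Moments x = V xi from transformed coefficients."""
    return basis.apply(xi)
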