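"""Electrode montages, source spaces and the analytic spherical forward model.

The observation model throughout the package is

    y = L x + n,        n ~ N(0, C),

with ``y`` the m-channel potential vector (microvolt), ``x`` the stacked
dipole-moment field of n source locations (3 Cartesian components each, in
nanoampere-meter) and ``L`` the m x 3n lead field (microvolt per nAm).

The lead field is produced by the classical concentric-shell (multi-sphere)
volume conductor: the potential of a current dipole inside a set of nested
spherical shells with piecewise-constant conductivity is a Legendre series
whose per-degree shell gains follow from continuity of potential and radial
current at every interface plus a no-flux condition at the scalp.  A
three-shell brain/skull/scalp model with canonical radii and conductivities
is the default; it is a desk-scale stand-in for subject-specific FEM models
and supports the same downstream algebra.

Units convention (used consistently across the package): positions mm,
dipole moments nAm, potentials microvolt, conductivities S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py

from .exceptions import (
    DegenerateMeasurementError,
    FormatError,
    GeometryError,
    ModelError,
)

__all__ = [
    "ElectrodeMontage",
    "SourceSpace",
    "SphereModel",
    "LeadField",
    "Measurement",
    "build_sphere_leadfield",
    "simulate_measurement",
    "read_montage",
    "read_leadfield",
    "write_leadfield",
    "read_measurement",
    "write_measurement",
]

#: conversion from (nAm, mm) dipole algebra to microvolt: a dipole potential
#: computed with moments in nAm and distances in mm comes out in units of
#: 1e-3 V / (4 pi sigma); multiply by 1e3 to report microvolt.
_UV_SCALE = 1.0e3

_FIDUCIAL_NAMES = {"nasion", "nz", "lpa", "rpa", "inion", "iz"}


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrode positions in a head-centered RAS-like frame.

    ``positions`` are mm, axes right/anterior/superior with the origin at the
    sphere center ("anterior" is +y).  ``reference`` is either
    ``"common_average"`` or ``"monopolar"``.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    reference: str = "common_average"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("electrode positions must be (m, 3)")
        m = pos.shape[0]
        if m < 4:
            raise GeometryError("a montage needs at least 4 electrodes")
        if len(self.labels) != m:
            raise GeometryError("labels and positions disagree in length")
        if len(set(self.labels)) != m:
            raise GeometryError("electrode labels must be unique")
        # all positions pairwise distinct
        d = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        dist[np.diag_indices(m)] = np.inf
        if dist.min() <= 0.0:
            raise GeometryError("electrode positions must be distinct")
        if self.reference not in ("common_average", "monopolar"):
            raise ModelError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SourceSpace:
    """Candidate dipole locations with their outward radial axes."""

    positions: np.ndarray
    head_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radial_axes: np.ndarray | None = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        center = np.asarray(self.head_center, dtype=float).reshape(3)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "head_center", center)
        if pos.shape[0] < 1 or pos.shape[1] != 3:
            raise GeometryError("source positions must be (n, 3), n >= 1")
        if self.radial_axes is None:
            rel = pos - center
            norms = np.linalg.norm(rel, axis=1, keepdims=True)
            if np.any(norms == 0.0):
                # a source exactly at the center has no radial direction;
                # fall back to +z so the frame stays well defined
                rel = np.where(norms == 0.0, [0.0, 0.0, 1.0], rel)
                norms = np.where(norms == 0.0, 1.0, norms)
            object.__setattr__(self, "radial_axes", rel / norms)
        else:
            ax = np.atleast_2d(np.asarray(self.radial_axes, dtype=float))
            if ax.shape != pos.shape:
                raise GeometryError("radial_axes must match positions in shape")
            if not np.allclose(np.linalg.norm(ax, axis=1), 1.0, atol=1e-8):
                raise GeometryError("radial axes must be unit norm")
            object.__setattr__(self, "radial_axes", ax)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def radii(self) -> np.ndarray:
        """Distance of every source from the head center (mm)."""
        return np.linalg.norm(self.positions - self.head_center, axis=1)


@dataclass(frozen=True)
class SphereModel:
    """Concentric-shell conductor: ascending boundary radii (mm) and
    per-shell conductivities (S/m), innermost shell first."""

    shell_radii: tuple[float, ...] = (80.0, 85.0, 92.0)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)
    series_order: int = 60

    def __post_init__(self):
        radii = tuple(float(r) for r in self.shell_radii)
        cond = tuple(float(c) for c in self.conductivities)
        object.__setattr__(self, "shell_radii", radii)
        object.__setattr__(self, "conductivities", cond)
        if len(radii) != len(cond) or len(radii) < 1:
            raise ModelError("need one conductivity per shell")
        if any(np.diff(radii) <= 0):
            raise ModelError("shell radii must be strictly ascending")
        if any(c <= 0 for c in cond):
            raise ModelError("conductivities must be positive")
        if self.series_order < 20:
            raise ModelError("series_order must be >= 20")

    @property
    def inner_radius(self) -> float:
        return self.shell_radii[0]

    @property
    def outer_radius(self) -> float:
        return self.shell_radii[-1]


@dataclass(frozen=True)
class LeadField:
    """m x 3n gain matrix, microvolt per nAm.

    Column ``3*k + i`` is the potential pattern of a unit dipole moment along
    Cartesian axis i at location k (location-major triples).  When the
    montage is common-average referenced every column sums to zero.
    """

    gain: np.ndarray
    montage: ElectrodeMontage | None = None
    source_space: SourceSpace | None = None
    column_order: str = "location_major_xyz"

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        if g.ndim != 2 or g.shape[1] % 3 != 0:
            raise ModelError("gain must be (m, 3n)")
        if self.montage is not None and self.montage.n_channels != g.shape[0]:
            raise ModelError("montage size disagrees with gain rows")
        if self.source_space is not None and self.source_space.n_sources * 3 != g.shape[1]:
            raise ModelError("source space disagrees with gain columns")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3

    def sub(self, k: int) -> np.ndarray:
        """The m x 3 sub-lead-field of location ``k`` (0-based)."""
        if not 0 <= k < self.n_sources:
            raise IndexError(f"location {k} out of range")
        return self.gain[:, 3 * k : 3 * k + 3]


@dataclass(frozen=True)
class Measurement:
    """A potential vector (or channels x samples series) with its noise model."""

    y: np.ndarray
    noise_cov: np.ndarray
    noise_pct: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        C = np.asarray(self.noise_cov, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "noise_cov", C)
        m = y.shape[0]
        if C.shape != (m, m):
            raise CovarianceShapeError(m, C.shape)
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ModelError("noise covariance must be symmetric")

    @property
    def vector(self) -> np.ndarray:
        """The measurement collapsed to a single m-vector (first sample)."""
        return self.y if self.y.ndim == 1 else self.y[:, 0]


class CovarianceShapeError(ModelError):
    def __init__(self, m, shape):
        super().__init__(f"noise covariance must be ({m}, {m}), got {shape}")


# ---------------------------------------------------------------------------
# analytic shell gains


def _shell_gains(model: SphereModel, n_max: int) -> np.ndarray:
    """Per-degree surface gains of the concentric-shell conductor.

    Works in radii normalized by the scalp radius.  For degree n the primary
    (infinite-medium) dipole potential contributes a term ``r**-(n+1)`` in
    the innermost region with unit coefficient; the returned value is the
    total potential coefficient evaluated on the scalp surface (rho = 1).
    For a homogeneous sphere this reduces to the textbook (2n+1)/n.
    """
    radii = np.asarray(model.shell_radii, dtype=float)
    rho = radii / radii[-1]
    sig = np.asarray(model.conductivities, dtype=float)
    S = len(rho)
    out = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        size = 2 * S - 1
        M = np.zeros((size, size))
        rhs = np.zeros(size)

        def a_idx(j):  # region j regular coefficient
            return 0 if j == 0 else 2 * j - 1

        def b_idx(j):  # region j singular coefficient (j >= 1)
            return 2 * j

        row = 0
        for j in range(S - 1):  # interface between region j and j+1
            r = rho[j]
            # potential continuity
            M[row, a_idx(j)] += r**n
            if j > 0:
                M[row, b_idx(j)] += r ** -(n + 1)
            M[row, a_idx(j + 1)] -= r**n
            M[row, b_idx(j + 1)] -= r ** -(n + 1)
            if j == 0:
                rhs[row] = -(r ** -(n + 1))  # primary term lives in region 0
            row += 1
            # radial current continuity
            M[row, a_idx(j)] += sig[j] * n * r ** (n - 1)
            if j > 0:
                M[row, b_idx(j)] += sig[j] * -(n + 1) * r ** -(n + 2)
            M[row, a_idx(j + 1)] -= sig[j + 1] * n * r ** (n - 1)
            M[row, b_idx(j + 1)] -= sig[j + 1] * -(n + 1) * r ** -(n + 2)
            if j == 0:
                rhs[row] = -sig[j] * -(n + 1) * r ** -(n + 2)
            row += 1
        # outermost boundary: no radial current into air at rho = 1
        j = S - 1
        M[row, a_idx(j)] += n
        if j > 0:
            M[row, b_idx(j)] += -(n + 1)
            rhs[row] = 0.0
        else:
            rhs[row] = n + 1  # primary derivative term, -(n+1) r^-(n+2) at r=1
        coef = np.linalg.solve(M, rhs)
        # potential on the scalp surface (rho = 1)
        g = coef[a_idx(j)]
        if j > 0:
            g += coef[b_idx(j)]
        else:
            g += 1.0  # primary term itself
        out[n] = g
    return out


def build_sphere_leadfield(
    montage: ElectrodeMontage,
    sources: SourceSpace,
    model: SphereModel | None = None,
) -> LeadField:
    """Analytic lead field of the concentric-shell sphere.

    Electrodes must sit on (or within 1% outside of) the scalp shell; they
    are evaluated at their radial projection onto the scalp surface.  Sources
    must be strictly inside the brain shell.
    """
    model = model or SphereModel()
    center = sources.head_center
    e_rel = montage.positions - center
    e_norm = np.linalg.norm(e_rel, axis=1)
    r_out = model.outer_radius
    if np.any(e_norm < 0.99 * r_out):
        raise GeometryError("electrodes must lie on or outside the scalp shell (within 1%)")
    if np.any(e_norm > 1.01 * r_out + 1e-9):
        raise GeometryError("electrodes more than 1% outside the scalp shell")
    e_dir = e_rel / e_norm[:, None]

    s_rel = sources.positions - center
    b = np.linalg.norm(s_rel, axis=1)
    if np.any(b >= model.inner_radius):
        raise GeometryError("sources must be strictly inside the innermost shell")

    n_max = model.series_order
    gains = _shell_gains(model, n_max)
    sigma1 = model.conductivities[0]
    pref = _UV_SCALE / (4.0 * np.pi * sigma1 * r_out**2)

    m = montage.n_channels
    n = sources.n_sources
    G = np.empty((m, 3 * n))
    b_hat = b / r_out
    for k in range(n):
        if b[k] == 0.0:
            s_dir = np.array([0.0, 0.0, 1.0])  # only n=1 survives; direction unused
        else:
            s_dir = s_rel[k] / b[k]
        u = e_dir @ s_dir  # cos(angle electrode-source), per channel
        # Legendre recurrences: P_n(u) and P_n'(u)
        P_prev = np.ones_like(u)   # P_0
        P = u.copy()               # P_1
        Pd_prev = np.zeros_like(u)  # P_0'
        Pd = np.ones_like(u)       # P_1'
        S1 = np.zeros_like(u)
        S2 = np.zeros_like(u)
        t = 1.0  # b_hat**(n-1) accumulator
        for deg in range(1, n_max + 1):
            w = gains[deg] * t
            S1 += w * (deg * P - u * Pd)
            S2 += w * Pd
            t *= b_hat[k]
            if deg < n_max:
                P_next = ((2 * deg + 1) * u * P - deg * P_prev) / (deg + 1)
                Pd_next = Pd_prev + (2 * deg + 1) * P  # P'_{n+1} = P'_{n-1} + (2n+1) P_n
                P_prev, P = P, P_next
                Pd_prev, Pd = Pd, Pd_next
        # column for unit moment along axis j:
        #   V = pref * [ S1 * (e_j . s_dir) + S2 * e_dir[:, j] ]
        G[:, 3 * k : 3 * k + 3] = pref * (np.outer(S1, s_dir) + S2[:, None] * e_dir)

    if montage.reference == "common_average":
        G -= G.mean(axis=0, keepdims=True)
    return LeadField(G, montage=montage, source_space=sources)


# ---------------------------------------------------------------------------
# measurement simulation


def simulate_measurement(
    L: LeadField,
    x_true: np.ndarray,
    noise_pct: float,
    seed: int | None = None,
) -> Measurement:
    """Simulate ``y = L x + n`` with i.i.d. Gaussian channel noise.

    The noise standard deviation is ``noise_pct/100`` times the maximum
    absolute clean-signal channel amplitude, so the stated percentage is
    scale free.  With ``noise_pct = 0`` the returned covariance is the
    floor ``(1e-6 * max|Lx|)**2 * I`` so whitened solvers stay defined.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    x_true = np.asarray(x_true, dtype=float).ravel()
    if x_true.shape[0] != L.gain.shape[1]:
        raise ValueError("x_true length must be 3n")
    clean = L.gain @ x_true
    peak = np.abs(clean).max() if clean.size else 0.0
    if peak == 0.0:
        raise DegenerateMeasurementError(
            "clean signal is identically zero; cannot define a noise scale"
        )
    m = clean.shape[0]
    if noise_pct == 0.0:
        eps = 1e-6 * peak
        return Measurement(clean, (eps**2) * np.eye(m), noise_pct=0.0, seed=seed)
    sigma = (noise_pct / 100.0) * peak
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, sigma, size=m)
    return Measurement(y, (sigma**2) * np.eye(m), noise_pct=float(noise_pct), seed=seed)


# ---------------------------------------------------------------------------
# file formats


def read_montage(path, format: str | None = None) -> ElectrodeMontage:
    """Read an electrode montage from an SFP or ELC text file.

    SFP: one ``label x y z`` row per channel; rows whose label starts with
    ``fid`` or is a standard fiducial name (nasion/nz/lpa/rpa/inion/iz,
    case-insensitive) are skipped.  ELC: the ASA dialect with
    ``NumberPositions``, ``Positions`` and ``Labels`` sections.
    """
    path = str(path)
    if format is None:
        low = path.lower()
        format = "elc" if low.endswith(".elc") else "sfp"
    with open(path) as fh:
        text = fh.read()
    if format == "sfp":
        return _parse_sfp(text)
    if format == "elc":
        return _parse_elc(text)
    raise FormatError(f"unknown montage format {format!r}")


def _parse_sfp(text: str) -> ElectrodeMontage:
    labels, rows = [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"SFP line {lineno}: expected 'label x y z'")
        label = parts[0]
        low = label.lower()
        if low.startswith("fid") or low in _FIDUCIAL_NAMES:
            continue
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"SFP line {lineno}: non-numeric coordinate") from exc
        labels.append(label)
    if not labels:
        raise FormatError("SFP file contains no channel rows")
    return ElectrodeMontage(tuple(labels), np.array(rows))


def _parse_elc(text: str) -> ElectrodeMontage:
    lines = [ln.strip() for ln in text.splitlines()]
    n_pos = None
    positions: list[list[float]] = []
    labels: list[str] = []
    i = 0
    while i < len(lines):
        ln = lines[i]
        low = ln.lower()
        if low.startswith("numberpositions"):
            try:
                n_pos = int(ln.split("=")[-1])
            except ValueError as exc:
                raise FormatError("ELC: bad NumberPositions") from exc
        elif low.startswith("positions"):
            if n_pos is None:
                raise FormatError("ELC: Positions section before NumberPositions")
            for j in range(n_pos):
                i += 1
                if i >= len(lines):
                    raise FormatError("ELC: truncated Positions section")
                row = lines[i].replace(":", " ").split()
                vals = row[-3:]
                try:
                    positions.append([float(v) for v in vals])
                except ValueError as exc:
                    raise FormatError(f"ELC: bad position row {j + 1}") from exc
        elif low.startswith("labels"):
            while len(labels) < (n_pos or 0):
                i += 1
                if i >= len(lines):
                    raise FormatError("ELC: truncated Labels section")
                labels.extend(lines[i].split())
        i += 1
    if n_pos is None or len(positions) != n_pos:
        raise FormatError("ELC: missing or incomplete Positions section")
    if len(labels) < n_pos:
        raise FormatError("ELC: missing or incomplete Labels section")
    return ElectrodeMontage(tuple(labels[:n_pos]), np.array(positions))


def write_leadfield(path, L: LeadField, format: str | None = None) -> None:
    """Write a lead field to HDF5 (``.h5``/``.hdf5``) or whitespace text."""
    path = str(path)
    if format is None:
        format = "hdf5" if path.lower().endswith((".h5", ".hdf5")) else "text"
    if format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("gain", data=L.gain)
            fh.attrs["units"] = "uV/nAm"
            fh.attrs["column_order"] = L.column_order
            if L.source_space is not None:
                fh.create_dataset("positions", data=L.source_space.positions)
                fh.create_dataset("radial_axes", data=L.source_space.radial_axes)
                fh.attrs["head_center"] = L.source_space.head_center
            if L.montage is not None:
                fh.create_dataset("electrode_positions", data=L.montage.positions)
                fh.create_dataset(
                    "labels",
                    data=np.array([s.encode() for s in L.montage.labels]),
                )
                fh.attrs["reference"] = L.montage.reference
    elif format == "text":
        m, p = L.gain.shape
        with open(path, "w") as fh:
            fh.write(f"{m} {p // 3} uV/nAm\n")
            for row in L.gain:
                fh.write(" ".join(f"{v:.17e}" for v in row) + "\n")
    else:
        raise FormatError(f"unknown lead-field format {format!r}")


def read_leadfield(path, format: str | None = None) -> LeadField:
    path = str(path)
    if format is None:
        format = "hdf5" if path.lower().endswith((".h5", ".hdf5")) else "text"
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            if "gain" not in fh:
                raise FormatError("HDF5 lead field lacks /gain")
            gain = fh["gain"][()]
            montage = None
            sources = None
            if "electrode_positions" in fh and "labels" in fh:
                labels = tuple(s.decode() for s in fh["labels"][()])
                montage = ElectrodeMontage(
                    labels,
                    fh["electrode_positions"][()],
                    reference=str(fh.attrs.get("reference", "common_average")),
                )
            if "positions" in fh:
                sources = SourceSpace(
                    fh["positions"][()],
                    head_center=np.asarray(fh.attrs.get("head_center", np.zeros(3))),
                    radial_axes=fh["radial_axes"][()] if "radial_axes" in fh else None,
                )
        try:
            return LeadField(gain, montage=montage, source_space=sources)
        except ModelError as exc:
            raise FormatError(str(exc)) from exc
    if format == "text":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 3:
                raise FormatError("text lead field: header must be 'm n units'")
            try:
                m, n = int(header[0]), int(header[1])
            except ValueError as exc:
                raise FormatError("text lead field: non-integer header") from exc
            rows = []
            for lineno, line in enumerate(fh, 2):
                if line.strip():
                    vals = line.split()
                    if len(vals) != 3 * n:
                        raise FormatError(f"text lead field: row {lineno} has wrong width")
                    rows.append([float(v) for v in vals])
        if len(rows) != m:
            raise FormatError(f"text lead field: expected {m} rows, found {len(rows)}")
        return LeadField(np.array(rows))
    raise FormatError(f"unknown lead-field format {format!r}")


def write_measurement(path, meas: Measurement) -> None:
    """Write a measurement to HDF5 (``/y``, ``/C``) or delimited text."""
    path = str(path)
    if path.lower().endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("y", data=meas.y)
            fh.create_dataset("C", data=meas.noise_cov)
            fh.attrs["noise_pct"] = meas.noise_pct
            if meas.seed is not None:
                fh.attrs["seed"] = meas.seed
    else:
        arr = meas.y if meas.y.ndim == 2 else meas.y[:, None]
        np.savetxt(path, arr)


def read_measurement(path, noise_cov: np.ndarray | None = None) -> Measurement:
    path = str(path)
    if path.lower().endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            if "y" not in fh:
                raise FormatError("HDF5 measurement lacks /y")
            y = fh["y"][()]
            C = fh["C"][()] if "C" in fh else noise_cov
            pct = float(fh.attrs.get("noise_pct", 0.0))
            seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    else:
        y = np.loadtxt(path)
        if y.ndim == 2 and y.shape[1] == 1:
            y = y[:, 0]
        C, pct, seed = noise_cov, 0.0, None
    if C is None:
        C = np.eye(y.shape[0])
    return Measurement(y, C, noise_pct=pct, seed=seed)
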