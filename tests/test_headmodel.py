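"""Spherical forward model, measurement simulation and file formats."""

import numpy as np
import pytest

from eegsi.exceptions import (
    DegenerateMeasurementError,
    FormatError,
    GeometryError,
    ModelError,
)
from eegsi.headmodel import (
    ElectrodeMontage,
    LeadField,
    SourceSpace,
    SphereModel,
    build_sphere_leadfield,
    read_leadfield,
    read_montage,
    simulate_measurement,
    write_leadfield,
)
from helpers_oracles import single_sphere_potential


def _cap_montage(m=16, radius=92.0, zmin=-0.25, reference="monopolar"):
    i = np.arange(m)
    z = zmin + (1.0 - zmin) * (i + 0.5) / m
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    pos = radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return ElectrodeMontage(tuple(f"E{j:02d}" for j in range(m)), pos, reference=reference)


class TestSphereLeadfield:
    def test_center_dipole_equatorial_symmetry(self):
        """A +z dipole at the center produces zero potential on the equator."""
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        eq = 92.0 * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(8)])
        montage = ElectrodeMontage(tuple(f"Q{i}" for i in range(8)), eq, "monopolar")
        model = SphereModel((92.0,), (0.33,), series_order=30)
        L = build_sphere_leadfield(montage, SourceSpace(np.zeros((1, 3))), model)
        col_norm = np.linalg.norm(L.gain[:, 0])
        assert np.abs(L.gain[:, 2]).max() <= 1e-10 * col_norm

    def test_series_truncation_converged(self, rng):
        """Order 60 matches order 200 for sources within 80% of the brain shell."""
        montage = _cap_montage()
        d = rng.normal(size=(6, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        sources = SourceSpace(d * rng.uniform(10, 0.8 * 80.0, size=(6, 1)))
        lo = build_sphere_leadfield(montage, sources, SphereModel(series_order=60))
        hi = build_sphere_leadfield(montage, sources, SphereModel(series_order=200))
        rel = np.linalg.norm(lo.gain - hi.gain) / np.linalg.norm(hi.gain)
        assert rel <= 1e-6

    def test_matches_textbook_single_sphere_series(self, rng):
        """One-shell model equals the independently coded homogeneous formula."""
        montage = _cap_montage()
        model = SphereModel((92.0,), (0.33,), series_order=80)
        r0 = np.array([30.0, 20.0, 45.0])
        sources = SourceSpace(r0[None, :])
        L = build_sphere_leadfield(montage, sources, model)
        for moment in (np.array([1.0, 0, 0]), np.array([0.3, -1.2, 0.7])):
            ours = L.gain[:, :3] @ moment
            oracle = single_sphere_potential(montage.positions, r0, moment, 92.0, 0.33, 80)
            assert np.abs(ours - oracle).max() <= 1e-8 * np.abs(oracle).max()

    def test_common_average_columns_sum_to_zero(self, fixture_bundle):
        _, _, _, L, _ = fixture_bundle
        sums = np.abs(L.gain.sum(axis=0))
        norms = np.linalg.norm(L.gain, axis=0)
        assert np.all(sums <= 1e-10 * norms)

    def test_tangential_dominates_radial_for_superficial_sources(self, fixture_bundle):
        """Under the cap, both tangential output norms exceed the radial one."""
        _, sources, model, L, _ = fixture_bundle
        radii = sources.radii()
        superficial = np.flatnonzero(radii >= 0.7 * model.inner_radius)[:40]
        for k in superficial:
            sub = L.sub(int(k))
            r = sources.radial_axes[k]
            t1 = np.cross(r, [0.0, 0.0, 1.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(r, t1)
            nr = np.linalg.norm(sub @ r)
            assert np.linalg.norm(sub @ t1) > nr
            assert np.linalg.norm(sub @ t2) > nr

    def test_geometry_errors(self):
        montage = _cap_montage()
        with pytest.raises(GeometryError):
            build_sphere_leadfield(montage, SourceSpace(np.array([[0.0, 0, 85.0]])),
                                   SphereModel())
        with pytest.raises(ModelError):
            SphereModel((92.0, 85.0, 80.0), (0.33, 0.0042, 0.33))
        inside = ElectrodeMontage(("A", "B", "C", "D"),
                                  50.0 * np.eye(4, 3) + [[0, 0, 1], [0, 0, 2], [0, 0, 3], [0, 0, 4]],
                                  "monopolar")
        with pytest.raises(GeometryError):
            build_sphere_leadfield(inside, SourceSpace(np.array([[0.0, 0, 40.0]])),
                                   SphereModel())


@pytest.fixture(scope="module")
def small_L():
    rng = np.random.default_rng(0)
    return LeadField(rng.normal(size=(8, 15)))


class TestSimulateMeasurement:
    def test_zero_noise_exact_with_floor_covariance(self, small_L):
        x = np.zeros(15)
        x[4] = 10.0
        meas = simulate_measurement(small_L, x, 0.0, seed=3)
        clean = small_L.gain @ x
        assert np.array_equal(meas.y, clean)
        eps = 1e-6 * np.abs(clean).max()
        assert np.allclose(meas.noise_cov, eps**2 * np.eye(8))

    def test_noise_std_matches_definition(self, small_L):
        """Monte-Carlo: per-channel std of the noise is pct/100 * max|Lx|."""
        x = np.zeros(15)
        x[4] = 10.0
        clean = small_L.gain @ x
        draws = np.array([
            simulate_measurement(small_L, x, 5.0, seed=s).y - clean
            for s in range(10000)
        ])
        target = 0.05 * np.abs(clean).max()
        std = draws.std(axis=0, ddof=1)
        assert np.all(np.abs(std - target) <= 0.02 * target)

    def test_seed_reproducibility(self, small_L):
        x = np.arange(15.0)
        a = simulate_measurement(small_L, x, 5.0, seed=11)
        b = simulate_measurement(small_L, x, 5.0, seed=11)
        c = simulate_measurement(small_L, x, 5.0, seed=12)
        assert np.array_equal(a.y, b.y)
        assert not np.array_equal(a.y, c.y)

    def test_degenerate_measurement_error(self, small_L):
        with pytest.raises(DegenerateMeasurementError):
            simulate_measurement(small_L, np.zeros(15), 0.0, seed=0)


class TestMontageIO:
    def test_sfp_skips_fiducials(self, tmp_path):
        path = tmp_path / "cap.sfp"
        path.write_text(
            "FidNz 0 90 0\nLPA -80 0 0\nRPA 80 0 0\n"
            "Cz 0 0 92\nPz 0 -60 70\nFz 0 60 70\nOz 0 -90 10\n"
        )
        montage = read_montage(path)
        assert montage.labels == ("Cz", "Pz", "Fz", "Oz")
        assert montage.positions.shape == (4, 3)

    def test_sfp_malformed_row_raises(self, tmp_path):
        path = tmp_path / "bad.sfp"
        path.write_text("Cz 0 0\nPz 0 -60 70\n")
        with pytest.raises(FormatError):
            read_montage(path)

    def test_elc_roundtrip_fields(self, tmp_path):
        path = tmp_path / "cap.elc"
        path.write_text(
            "# ASA electrode file\nReferenceLabel avg\nUnitPosition mm\n"
            "NumberPositions= 4\nPositions\n0 0 92\n0 -60 70\n0 60 70\n0 -90 10\n"
            "Labels\nCz Pz\nFz Oz\n"
        )
        montage = read_montage(path)
        assert montage.labels == ("Cz", "Pz", "Fz", "Oz")
        assert np.allclose(montage.positions[0], [0, 0, 92])

    def test_elc_truncated_raises(self, tmp_path):
        path = tmp_path / "trunc.elc"
        path.write_text("NumberPositions= 4\nPositions\n0 0 92\n0 -60 70\n")
        with pytest.raises(FormatError):
            read_montage(path)


class TestLeadFieldIO:
    def test_hdf5_roundtrip_identical(self, tmp_path, rng):
        L = LeadField(rng.normal(size=(8, 12)))
        path = tmp_path / "lf.h5"
        write_leadfield(path, L)
        back = read_leadfield(path)
        assert np.array_equal(back.gain, L.gain)

    def test_hdf5_roundtrip_with_provenance(self, tmp_path, fixture_bundle):
        _, _, _, L, _ = fixture_bundle
        path = tmp_path / "lf.h5"
        write_leadfield(path, L)
        back = read_leadfield(path)
        assert np.array_equal(back.gain, L.gain)
        assert back.montage.labels == L.montage.labels
        assert np.array_equal(back.source_space.positions, L.source_space.positions)

    def test_text_roundtrip(self, tmp_path, rng):
        L = LeadField(rng.normal(size=(6, 9)))
        path = tmp_path / "lf.txt"
        write_leadfield(path, L)
        back = read_leadfield(path)
        assert np.abs(back.gain - L.gain).max() <= 1e-9 * np.abs(L.gain).max()

    def test_truncated_text_raises(self, tmp_path, rng):
        L = LeadField(rng.normal(size=(6, 9)))
        path = tmp_path / "lf.txt"
        write_leadfield(path, L)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(FormatError):
            read_leadfield(path)

    def test_header_width_mismatch_raises(self, tmp_path):
        path = tmp_path / "lf.txt"
        path.write_text("2 2 uV/nAm\n1 2 3\n4 5 6\n")
        with pytest.raises(FormatError):
            read_leadfield(path)
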