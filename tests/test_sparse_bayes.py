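"""Hierarchical adaptive sparse solvers: updates, inner solves, estimators."""

import numpy as np
import pytest

from eegsi.exceptions import InfeasibleSelectionError, NoSourceError, ProvenanceError
from eegsi.headmodel import LeadField, simulate_measurement
from eegsi.sparse_bayes import (
    AdaptiveGroupLasso,
    GammaHyperprior,
    HierarchicalAdaptiveL1,
    SolverSettings,
    fitted_glasso,
    glasso_estimate,
    glasso_gamma_update,
    hal1r_estimate,
    hal1r_gamma_update,
    select_hyperparameters,
    svd_hal1r_estimate,
    weighted_group_solve,
    weighted_l1_solve,
    zero_solution_threshold,
)
from eegsi.sparse_bayes import _whiten
from eegsi.svd_transform import build_block_basis, transform_leadfield
from eegsi.evaluation import extract_peak_dipole, tangent_frame
from helpers_oracles import (
    fista_group,
    fista_l1,
    objective_group,
    objective_l1,
    random_rotation,
)


class TestGammaUpdates:
    @pytest.mark.parametrize(
        "beta,theta,x,expect",
        [(1.0, 1.0, 0.0, 2.0), (2.0, 0.5, 1.5, 1.5), (2.0, 0.5, -1.5, 1.5)],
    )
    def test_componentwise_values(self, beta, theta, x, expect):
        prior = GammaHyperprior(beta, theta)
        assert hal1r_gamma_update(np.array([x]), prior)[0] == pytest.approx(expect)

    @pytest.mark.parametrize(
        "beta,theta,norm,expect",
        [(1.0, 1.0, 0.0, 4.0), (0.5, 2.0, 1.0, 3.5 / 3.0)],
    )
    def test_group_values(self, beta, theta, norm, expect):
        prior = GammaHyperprior(beta, theta)
        xk = np.array([norm, 0.0, 0.0])
        assert glasso_gamma_update(xk, prior)[0] == pytest.approx(expect)

    def test_monotone_decreasing_in_magnitude(self):
        prior = GammaHyperprior(1.3, 0.7)
        mags = np.linspace(0, 5, 50)
        gam = hal1r_gamma_update(mags, prior)
        assert np.all(np.diff(gam) < 0)

    def test_group_update_rotation_invariant(self, rng):
        prior = GammaHyperprior(1.0, 2.0)
        xk = rng.normal(size=3)
        R = random_rotation(rng)
        assert glasso_gamma_update(xk, prior)[0] == pytest.approx(
            glasso_gamma_update(R @ xk, prior)[0]
        )


class TestWeightedSolves:
    def test_zero_condition_returns_exact_zero(self, rng):
        m, n = 8, 6
        L = rng.normal(size=(m, 3 * n))
        y = rng.normal(size=m)
        C = np.eye(m)
        gam = np.abs(L.T @ y) * 1.0001
        x, _, converged = weighted_l1_solve(y, L, C, gam)
        assert converged and np.all(x == 0.0)
        gam_g = np.linalg.norm((L.T @ y).reshape(n, 3), axis=1) * 1.0001
        xg, _, cg = weighted_group_solve(y, L, C, gam_g)
        assert cg and np.all(xg == 0.0)

    def test_unpenalized_square_system(self, rng):
        m = 9
        L = rng.normal(size=(m, m))
        y = rng.normal(size=m)
        x, _, _ = weighted_l1_solve(y, L, np.eye(m), np.zeros(m))
        assert np.abs(x - np.linalg.solve(L, y)).max() <= 1e-8

    def test_l1_matches_proximal_oracle(self, rng):
        """Objective within 1e-6 of an independent FISTA solve, random sizes."""
        for _ in range(8):
            m, n = int(rng.integers(6, 11)), int(rng.integers(3, 9))
            L = rng.normal(size=(m, 3 * n))
            y = rng.normal(size=m)
            C = np.eye(m) * rng.uniform(0.5, 2.0)
            gam = rng.uniform(0.3, 2.0, size=3 * n)
            x, trace, _ = weighted_l1_solve(y, L, C, gam)
            yt, Lt = _whiten(y, L, C)
            xo = fista_l1(yt, Lt, gam, iters=30000)
            assert objective_l1(yt, Lt, gam, x) <= objective_l1(yt, Lt, gam, xo) + 1e-6
            assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)

    def test_group_matches_proximal_oracle_and_equivariance(self, rng):
        for _ in range(5):
            m, n = 10, 8
            L = rng.normal(size=(m, 3 * n))
            y = rng.normal(size=m)
            C = np.eye(m)
            gam = rng.uniform(0.3, 2.0, size=n)
            x, _, _ = weighted_group_solve(y, L, C, gam)
            yt, Lt = _whiten(y, L, C)
            xo = fista_group(yt, Lt, gam, iters=30000)
            assert objective_group(yt, Lt, gam, x) <= objective_group(yt, Lt, gam, xo) + 1e-6
            # per-location rotation of the columns rotates the solution blocks
            rots = [random_rotation(rng) for _ in range(n)]
            L2 = np.hstack([L[:, 3 * k : 3 * k + 3] @ rots[k] for k in range(n)])
            x2, _, _ = weighted_group_solve(y, L2, C, gam)
            n1 = np.linalg.norm(x.reshape(n, 3), axis=1)
            n2 = np.linalg.norm(x2.reshape(n, 3), axis=1)
            assert np.abs(n1 - n2).max() <= 1e-6 * max(n1.max(), 1e-12)


class TestThresholdsAndSelection:
    def test_zero_data_thresholds_vanish(self, rng):
        L = rng.normal(size=(6, 12))
        assert np.all(zero_solution_threshold(np.zeros(6), L, np.eye(6), "l1") == 0)

    def test_svd_thresholds_equal_componentwise_on_transformed(self, rng):
        L = LeadField(rng.normal(size=(8, 15)))
        basis = build_block_basis(L)
        A = transform_leadfield(L, basis).A
        y = rng.normal(size=8)
        t_svd = zero_solution_threshold(y, A, np.eye(8), "svd")
        assert np.abs(t_svd - np.abs(A.T @ y)).max() <= 1e-12
        # and equals |s_i u_i' y| blockwise
        for k in range(5):
            expect = np.abs(basis.s[k] * (basis.U[k].T @ y))
            assert np.abs(t_svd[3 * k : 3 * k + 3] - expect).max() <= 1e-10

    def test_group_vs_componentwise_norm_relation(self, rng):
        L = rng.normal(size=(7, 12))
        y = rng.normal(size=7)
        C = np.eye(7)
        t1 = zero_solution_threshold(y, L, C, "l1").reshape(-1, 3)
        tg = zero_solution_threshold(y, L, C, "group")
        assert np.all(tg >= t1.max(axis=1) - 1e-12)
        assert np.all(tg <= np.sqrt(3) * t1.max(axis=1) + 1e-12)

    def test_selection_postconditions(self, rng):
        L = rng.normal(size=(8, 18))
        y = rng.normal(size=8) * 5
        C = np.eye(8)
        prior = select_hyperparameters(y, L, C, strength_nam=10.0, margin=0.5)
        T = zero_solution_threshold(y, L, C, "l1").max()
        assert (prior.beta + 1.0) / prior.theta == pytest.approx(0.5 * T, rel=1e-12)
        assert prior.theta / prior.beta == pytest.approx(10.0, rel=1e-12)
        assert (prior.beta + 1.0) / prior.theta < T
        # doubling the data doubles the threshold and preserves the margin
        prior2 = select_hyperparameters(2 * y, L, C, strength_nam=10.0, margin=0.5)
        assert (prior2.beta + 1.0) / prior2.theta == pytest.approx(T, rel=1e-12)

    def test_zero_data_selection_raises(self, rng):
        L = rng.normal(size=(6, 12))
        with pytest.raises(InfeasibleSelectionError):
            select_hyperparameters(np.zeros(6), L, np.eye(6))


def _noiseless_case(fixture_bundle, direction="axis"):
    _, sources, _, L, test_index = fixture_bundle
    n = sources.n_sources
    x_true = np.zeros(3 * n)
    if direction == "axis":
        moment = np.array([0.0, 10.0, 0.0])  # anterior Cartesian axis
    else:
        frame = tangent_frame(sources, test_index)
        moment = 10.0 * frame.a1
    x_true[3 * test_index : 3 * test_index + 3] = moment
    meas = simulate_measurement(L, x_true, 0.0, seed=0)
    return L, sources, test_index, moment, meas


class TestEstimators:
    def test_zero_data_returns_zero(self, rng):
        L = LeadField(rng.normal(size=(6, 12)))
        est = hal1r_estimate(np.zeros(6), L, np.eye(6))
        assert est.converged and np.all(est.x_hat == 0)
        est_g = glasso_estimate(np.zeros(6), L, np.eye(6))
        assert est_g.converged and np.all(est_g.x_hat == 0)

    def test_noiseless_axis_dipole_recovered(self, fixture_bundle):
        """All three hierarchy members peak at the true location."""
        L, sources, k_true, moment, meas = _noiseless_case(fixture_bundle)
        y, C = meas.y, meas.noise_cov
        for est in (
            hal1r_estimate(y, L, C),
            glasso_estimate(y, L, C),
            svd_hal1r_estimate(y, L, None, C),
        ):
            k, _, _ = extract_peak_dipole(est)
            assert k == k_true

    def test_objective_traces_non_increasing(self, fixture_bundle):
        L, sources, k_true, moment, meas = _noiseless_case(fixture_bundle)
        est = hal1r_estimate(meas.y, L, meas.noise_cov)
        for tr in est.objective_trace:
            assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]) + 1e-12)

    def test_glasso_magnitudes_invariant_under_global_rotation(self, rng):
        m, n = 12, 10
        L = LeadField(rng.normal(size=(m, 3 * n)))
        x_true = np.zeros(3 * n)
        x_true[12:15] = [5.0, -3.0, 8.0]
        y = L.gain @ x_true
        C = np.eye(m) * 1e-4
        R = random_rotation(rng)
        G2 = np.hstack([L.sub(k) @ R for k in range(n)])
        est1 = glasso_estimate(y, L, C)
        est2 = glasso_estimate(y, LeadField(G2), C)
        n1 = np.linalg.norm(est1.x_hat.reshape(n, 3), axis=1)
        n2 = np.linalg.norm(est2.x_hat.reshape(n, 3), axis=1)
        assert np.abs(n1 - n2).max() <= 1e-6 * max(n1.max(), 1e-12)

    def test_svd_hal1r_identity_basis_case(self, rng):
        """Sub-blocks with orthogonal, norm-ordered columns make V an identity
        up to signs, so SVD-HAL1R and basic HAL1R coincide."""
        m, n = 12, 4
        blocks = []
        for k in range(n):
            Q, _ = np.linalg.qr(rng.normal(size=(m, 3)))
            blocks.append(Q * np.array([3.0, 2.0, 1.0]) * rng.uniform(1, 2))
        L = LeadField(np.hstack(blocks))
        x_true = np.zeros(3 * n)
        x_true[3:6] = [6.0, 0.0, 0.0]
        y = L.gain @ x_true
        C = np.eye(m) * 1e-4
        prior = GammaHyperprior(1.0, 10.0)
        e_cart = hal1r_estimate(y, L, C, prior)
        e_svd = svd_hal1r_estimate(y, L, None, C, prior)
        assert np.abs(np.abs(e_cart.x_hat) - np.abs(e_svd.x_hat)).max() <= 1e-5 * np.abs(
            e_cart.x_hat
        ).max()
        assert abs(np.linalg.norm(e_svd.x_hat) - np.linalg.norm(e_svd.xi_hat)) <= 1e-12

    def test_svd_hal1r_provenance_check(self, rng):
        L = LeadField(rng.normal(size=(8, 12)))
        other = LeadField(rng.normal(size=(8, 12)))
        basis = build_block_basis(other)
        with pytest.raises(ProvenanceError):
            svd_hal1r_estimate(rng.normal(size=8), L, basis, np.eye(8))

    def test_all_zero_fixed_point_warning(self, rng):
        L = LeadField(rng.normal(size=(8, 12)))
        y = rng.normal(size=8)
        # gigantic (beta+1)/theta: the t=0 condition holds everywhere
        prior = GammaHyperprior(beta=1.0, theta=1e-9)
        est = hal1r_estimate(y, L, np.eye(8), prior)
        assert "all_zero_fixed_point" in est.warnings
        assert np.all(est.x_hat == 0)

    def test_cartesian_bias_ordering(self, fixture_bundle):
        """Basic HAL1R orientations concentrate near Cartesian axes; the
        SVD-transformed variant does not (noiseless random orientations)."""
        _, sources, _, L, _ = fixture_bundle
        n = sources.n_sources
        basis = build_block_basis(L)
        A = transform_leadfield(L, basis).A
        rng = np.random.default_rng(42)
        conc = {"hal1r": [], "svd": []}
        eligible = np.flatnonzero(sources.radii() >= 48.0)
        for _ in range(60):
            k = int(eligible[rng.integers(eligible.size)])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            x_true = np.zeros(3 * n)
            x_true[3 * k : 3 * k + 3] = 10.0 * d
            meas = simulate_measurement(L, x_true, 0.0, seed=int(rng.integers(2**31)))
            y, C = meas.y, meas.noise_cov
            for name, est in (
                ("hal1r", hal1r_estimate(y, L, C)),
                ("svd", svd_hal1r_estimate(y, L, basis, C)),
            ):
                try:
                    _, mom, _ = extract_peak_dipole(est)
                except NoSourceError:
                    continue
                conc[name].append(np.abs(mom).max() / np.linalg.norm(mom))
        assert np.mean(conc["hal1r"]) > np.mean(conc["svd"])


class TestFittedGlasso:
    def test_aligned_case_recovers_v1(self, rng):
        """A noiseless dipole along v1 comes back at the right location with
        the right singular direction (low-coherence lead field, where the
        group optimum provably sits at the truth)."""
        from eegsi.svd_transform import location_svd

        m, n = 24, 6
        L = LeadField(rng.normal(size=(m, 3 * n)))
        k_true = 2
        v1 = location_svd(L, k_true).V[:, 0]
        x_true = np.zeros(3 * n)
        x_true[3 * k_true : 3 * k_true + 3] = 10.0 * v1
        y = L.gain @ x_true
        C = (1e-6 * np.abs(y).max()) ** 2 * np.eye(m)
        est = fitted_glasso(y, L, C)
        k, mom, _ = extract_peak_dipole(est)
        assert k == k_true
        direction = mom / np.linalg.norm(mom)
        assert min(np.abs(direction - v1).max(), np.abs(direction + v1).max()) <= 1e-6

    def test_orientation_choice_matches_bruteforce(self, fixture_bundle):
        """The selected singular direction maximizes |s_i u_i' y| over i."""
        _, sources, _, L, k_true = fixture_bundle
        frame = tangent_frame(sources, k_true)
        x_true = np.zeros(3 * sources.n_sources)
        x_true[3 * k_true : 3 * k_true + 3] = 10.0 * (0.8 * frame.a1 + 0.6 * frame.a2)
        meas = simulate_measurement(L, x_true, 5.0, seed=3)
        est = fitted_glasso(meas.y, L, meas.noise_cov)
        k, mom, _ = extract_peak_dipole(est)
        yt, Lt = _whiten(meas.y, L.gain, meas.noise_cov)
        from eegsi.svd_transform import location_svd

        blk = location_svd(Lt, k)
        i_best = int(np.argmax(np.abs(blk.s * (blk.U.T @ yt))))
        direction = mom / np.linalg.norm(mom)
        cand = blk.V[:, i_best]
        assert min(np.abs(direction - cand).max(), np.abs(direction + cand).max()) <= 1e-10

    def test_zero_data_raises(self, rng):
        L = LeadField(rng.normal(size=(8, 12)))
        with pytest.raises(NoSourceError):
            fitted_glasso(np.zeros(8), L, np.eye(8))


class TestModelClasses:
    def test_fit_and_summary(self, fixture_bundle):
        L, sources, k_true, moment, meas = _noiseless_case(fixture_bundle)
        model = HierarchicalAdaptiveL1(meas, L, basis="svd")
        res = model.fit()
        assert res.converged
        k, mom, _ = res.peak_dipole()
        assert k == k_true
        text = res.summary()
        assert "svd" in text and str(k) in text
        res_g = AdaptiveGroupLasso(meas, L).fit()
        assert res_g.peak_dipole()[0] == k_true
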