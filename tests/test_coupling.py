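"""Dynamical Bayesian inference of phase-oscillator coupling."""

import numpy as np
import pytest

import hemoconn as hc
from hemoconn.coupling import infer_window, _auto_fs_inference


class TestBaseFunctions:
    @pytest.mark.parametrize("K,expected", [(1, 9), (2, 25), (3, 49)])
    def test_basis_size(self, K, expected):
        basis = hc.build_base_functions(K)
        assert basis.size == expected == (2 * K + 1) ** 2

    def test_evaluation_at_zero_phases(self):
        basis = hc.build_base_functions(2)
        col = basis.design(np.zeros(1), np.zeros(1))[:, 0]
        assert col[0] == 1.0
        assert np.all(col[1::2] == 0.0)  # all sines vanish
        assert np.all(col[2::2] == 1.0)  # all cosines are 1

    def test_representatives_unique_under_sign_flip(self):
        basis = hc.build_base_functions(2)
        seen = set()
        for k1, k2 in basis.harmonics:
            assert (k1, k2) not in seen and (-k1, -k2) not in seen
            seen.add((k1, k2))
        assert len(seen) == ((2 * 2 + 1) ** 2 - 1) // 2

    def test_order_bounds_enforced(self):
        with pytest.raises(ValueError):
            hc.build_base_functions(0)
        with pytest.raises(ValueError):
            hc.build_base_functions(6)

    def test_divergence_matches_finite_difference(self, rng):
        basis = hc.build_base_functions(2)
        p1, p2 = rng.uniform(0, 2 * np.pi, (2, 5))
        eps = 1e-6
        for wrt in (0, 1):
            grad = basis.divergence(p1, p2, wrt)
            if wrt == 0:
                num = (basis.design(p1 + eps, p2) - basis.design(p1 - eps, p2))
            else:
                num = (basis.design(p1, p2 + eps) - basis.design(p1, p2 - eps))
            np.testing.assert_allclose(grad, num / (2 * eps), atol=1e-6)


class TestInferWindow:
    def test_flat_prior_equals_ols_on_lattice_phases(self):
        """With midpoint phases on a regular lattice every harmonic sum
        vanishes exactly, the divergence correction drops out, and the flat-
        prior DBI solution equals ordinary least squares of the phase
        velocities on the design matrix."""
        basis = hc.build_base_functions(2)
        n = 63  # 62 increments = 2 full periods of the 31-point lattice
        h = 1.0
        i = np.arange(n)
        # steps 1/31 and 13/31 of a turn: no two K<=2 harmonics alias
        # (k1 + 13 k2 is never 0 mod 31 for distinct representatives), and
        # every harmonic sum over full periods vanishes exactly
        phi1 = 2 * np.pi / 31 * i
        phi2 = 2 * np.pi * 13 / 31 * i
        fit = infer_window(phi1, phi2, basis, None, 1.0 / h)
        mid1 = 0.5 * (phi1[1:] + phi1[:-1])
        mid2 = 0.5 * (phi2[1:] + phi2[:-1])
        p_mat = basis.design(mid1, mid2)
        assert np.linalg.cond(p_mat @ p_mat.T) < 1e6  # genuinely full rank
        # harmonic sums vanish on the lattice -> v-term is exactly zero
        for wrt in (0, 1):
            assert np.abs(basis.divergence(mid1, mid2, wrt).sum(axis=1)).max() < 1e-9
        phidot = np.diff(np.vstack([phi1, phi2]), axis=1) / h
        ols = np.linalg.lstsq(p_mat.T, phidot.T, rcond=None)[0].T
        np.testing.assert_allclose(fit.c, ols, atol=1e-6)

    def test_noiseless_uncoupled_recovery(self):
        osc = [hc.OscillatorSpec(0.1), hc.OscillatorSpec(0.11)]
        phi = hc.simulate_coupled_phases(osc, [], 600.0, 0.01, seed=0)
        p = hc.decimate_phases(phi, 0.01, 2.0)
        res = hc.PhaseCouplingModel(p[0], p[1], 2.0).fit()
        assert abs(res.natural_frequency(0) - 0.1) / 0.1 < 0.01
        assert abs(res.natural_frequency(1) - 0.11) / 0.11 < 0.01
        assert res.coupling_strength(1, 0, debias=False) < 0.01
        assert res.coupling_strength(0, 1, debias=False) < 0.01

    def test_known_coupling_recovered(self, coupled_pair_phases):
        p = coupled_pair_phases
        res = hc.PhaseCouplingModel(p[0], p[1], 2.0).fit()
        basis = res.basis
        idx = 1 + 2 * basis.harmonics.index((1, -1))
        # a sin(phi2 - phi1) = -a sin(phi1 - phi2): coefficient -0.3
        assert res.params[0, idx] == pytest.approx(-0.3, abs=0.1)
        assert res.coupling_strength(1, 0) == pytest.approx(0.3, rel=0.35)

    def test_inferred_noise_matrix_scale(self, coupled_pair_phases):
        # residual covariance recovers 2*D_true within a factor of 2
        p = coupled_pair_phases
        res = hc.PhaseCouplingModel(p[0], p[1], 2.0).fit()
        for i in range(2):
            ratio = res.noise_matrix[i, i] / (2 * 0.05)
            assert 0.5 < ratio < 2.0

    def test_phase_offset_invariance(self, coupled_pair_phases):
        p = coupled_pair_phases
        a = hc.PhaseCouplingModel(p[0], p[1], 2.0).fit()
        b = hc.PhaseCouplingModel(p[0] + 2 * np.pi * 3,
                                  p[1] + 2 * np.pi * 5, 2.0).fit()
        assert abs(a.coupling_strength(1, 0) - b.coupling_strength(1, 0)) < 1e-8
        assert abs(a.natural_frequency(0) - b.natural_frequency(0)) < 1e-10

    def test_short_series_rejected(self):
        basis = hc.build_base_functions(1)
        with pytest.raises(ValueError):
            infer_window(np.zeros(2), np.zeros(2), basis, None, 1.0)


class TestPropagatePrior:
    def test_zero_pw_identity(self, rng):
        c = rng.standard_normal(10)
        sigma = np.eye(10) * 0.5
        c2, s2 = hc.propagate_prior((c, sigma), 0.0)
        np.testing.assert_array_equal(c2, c)
        np.testing.assert_array_equal(s2, sigma)

    def test_positive_pw_inflates_diagonal(self, rng):
        c = rng.standard_normal(10)
        sigma = np.diag(rng.uniform(0.1, 1.0, 10))
        _, s2 = hc.propagate_prior((c, sigma), 0.3)
        assert np.all(np.diag(s2) >= np.diag(sigma))
        np.testing.assert_allclose(np.diag(s2) - np.diag(sigma),
                                   0.09 * c ** 2, atol=1e-15)

    def test_repeated_identical_windows_consistent(self, coupled_pair_phases):
        """Feeding the same window twice with pw = 0 leaves the posterior
        mean essentially unchanged (information accumulation is
        consistent)."""
        p = coupled_pair_phases
        basis = hc.build_base_functions(2)
        w = 400
        first = infer_window(p[0][:w], p[1][:w], basis, None, 2.0)
        sigma = np.linalg.inv(first.xi)
        prior = hc.propagate_prior((first.c.ravel(), sigma), 0.0)
        second = infer_window(p[0][:w], p[1][:w], basis,
                              (prior[0], np.linalg.inv(prior[1])), 2.0)
        denom = max(np.linalg.norm(first.c), 1e-9)
        assert np.linalg.norm(second.c - first.c) / denom < 1e-3


class TestCouplingStrength:
    def test_zero_cross_coefficients_give_zero(self):
        osc = [hc.OscillatorSpec(0.1), hc.OscillatorSpec(0.11)]
        phi = hc.simulate_coupled_phases(osc, [], 300.0, 0.01, seed=1)
        p = hc.decimate_phases(phi, 0.01, 2.0)
        res = hc.PhaseCouplingModel(p[0], p[1], 2.0).fit()
        assert res.coupling_strength(1, 0) == pytest.approx(0.0, abs=5e-3)

    def test_single_coefficient_norm(self, coupled_pair_phases):
        # construct a synthetic window fit with one nonzero cross term
        from hemoconn.coupling import PhaseCouplingResults, WindowFit
        model = hc.PhaseCouplingModel(*coupled_pair_phases, 2.0)
        basis = model.basis
        m = basis.size
        c = np.zeros((2, m))
        idx = 1 + 2 * basis.harmonics.index((1, -1))
        c[0, idx] = 0.3
        fit = WindowFit(c, np.eye(2 * m) * 1e12, np.eye(2), 0.0, True)
        res = PhaseCouplingResults(model, [fit])
        assert res.coupling_strength(1, 0) == pytest.approx(0.3, abs=1e-5)
        assert res.coupling_strength(0, 1) == pytest.approx(0.0, abs=1e-5)

    def test_directional_monotonicity(self):
        meds = []
        for a in (0.0, 0.15, 0.4):
            vals = []
            for seed in range(5):
                osc = [hc.OscillatorSpec(0.10, 0.05),
                       hc.OscillatorSpec(0.16, 0.05)]
                cpl = [hc.CouplingSpec(1, 0, a)] if a else []
                phi = hc.simulate_coupled_phases(osc, cpl, 600.0, 0.01,
                                                 seed=seed)
                p = hc.decimate_phases(phi, 0.01, 2.0)
                vals.append(hc.PhaseCouplingModel(p[0], p[1], 2.0)
                            .fit().coupling_strength(1, 0))
            meds.append(np.median(vals))
        assert meds[0] < meds[1] < meds[2]


class TestPairwiseEc:
    def test_region_counts_and_directionality(self, two_region_recording):
        res = hc.pairwise_ec(two_region_recording, "III",
                             n_surrogates=0, seed=0)
        assert len(res.directed_pairs()) == len(res.regions) * (len(res.regions) - 1)
        assert res.region_matrix.shape == (4, 4)
        assert np.all(res.region_matrix >= 0)
        assert np.all(np.diag(res.region_matrix) == 0)

    def test_surrogate_fields_populated(self, two_region_recording):
        res = hc.pairwise_ec(two_region_recording, "III",
                             n_surrogates=3, seed=0)
        off = ~np.eye(len(res.regions), dtype=bool)
        assert np.isfinite(res.surrogate_mean[off]).all()
        assert np.isfinite(res.surrogate_sd[off]).all()
        assert res.significant.dtype == bool

    def test_short_record_rejected(self):
        rec = hc.Recording(np.zeros((2, 100)), 10.0, ("LPFC", "RPFC"))
        with pytest.raises(ValueError):
            hc.pairwise_ec(rec, "III", n_surrogates=0, seed=0)

    def test_auto_inference_rate(self):
        assert _auto_fs_inference(0.052) == 2.0
        assert _auto_fs_inference(0.021) == 1.0


def test_summary_mentions_key_quantities(coupled_pair_phases):
    res = hc.PhaseCouplingModel(*coupled_pair_phases, 2.0).fit()
    text = res.summary()
    assert "coupling strength" in text.lower()
    assert "natural frequencies" in text.lower()
    assert f"K = 2" in text
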