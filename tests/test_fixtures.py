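"""Analytic cases, synthetic profiles and sigma*Vmax recovery."""

import numpy as np
import pytest

import zonesim as zs


class TestPoiseuilleCase:
    def test_hand_computed_wall_shear(self):
        # 6 mu Q / (w h^2) = 6 * 0.7e-3 * 2.5e-9 / (2e-2 * 1e-6)
        case = zs.poiseuille_case(2.5e-9, 1e-3, 2e-2, viscosity=0.7e-3)
        assert case.analytic["wall_shear"] == pytest.approx(5.25e-4, rel=1e-12)
        case.self_check()

    def test_shear_linear_in_flow_rate(self):
        base = zs.poiseuille_case(2.5e-9, 1e-3, 2e-2)
        double = zs.poiseuille_case(5.0e-9, 1e-3, 2e-2)
        assert double.analytic["wall_shear"] == pytest.approx(
            2 * base.analytic["wall_shear"], rel=1e-12
        )

    def test_shear_inverse_square_in_gap(self):
        base = zs.poiseuille_case(2.5e-9, 1e-3, 2e-2)
        wide = zs.poiseuille_case(2.5e-9, 2e-3, 2e-2)
        assert wide.analytic["wall_shear"] == pytest.approx(
            base.analytic["wall_shear"] / 4, rel=1e-12
        )

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            zs.poiseuille_case(0.0, 1e-3, 2e-2)


class TestStagnantCase:
    def test_no_uptake_keeps_supply_concentration(self):
        case = zs.stagnant_mm_case(0.21, 5e-3, 3e-9, sigma_vmax=0.0, km=5e-3)
        assert case.analytic["surface_conc"] == pytest.approx(0.21, rel=1e-12)

    def test_root_agrees_with_brute_force_solve(self):
        params = dict(c0=0.21, depth=5e-3, diffusivity=3e-9, sigma_vmax=3e-8, km=5e-3)
        case = zs.stagnant_mm_case(**params)
        case.self_check()
        fd = zs.finite_difference_surface_conc(**params)
        assert fd == pytest.approx(case.analytic["surface_conc"], rel=1e-6)

    def test_km_must_be_positive(self):
        with pytest.raises(ValueError):
            zs.stagnant_mm_case(0.21, 5e-3, 3e-9, 3e-8, km=0.0)


class TestSyntheticProfile:
    CASE = dict(c0=0.21, depth=5e-3, diffusivity=3e-9, sigma_vmax=3e-8, km=5e-3)

    def test_zero_noise_reproduces_exact_values(self):
        case = zs.stagnant_mm_case(**self.CASE)
        p = zs.synthetic_profile(case, noise_sd=0.0, n_points=10, seed=1)
        assert np.allclose(p.values, case.analytic["surface_conc"])

    def test_same_seed_is_bit_identical(self):
        case = zs.stagnant_mm_case(**self.CASE)
        a = zs.synthetic_profile(case, 1e-3, 50, seed=42)
        b = zs.synthetic_profile(case, 1e-3, 50, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        case = zs.stagnant_mm_case(**self.CASE)
        a = zs.synthetic_profile(case, 1e-3, 50, seed=1)
        b = zs.synthetic_profile(case, 1e-3, 50, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_residual_spread_matches_requested_noise(self):
        case = zs.stagnant_mm_case(**self.CASE)
        signal = case.analytic["surface_conc"]
        p = zs.synthetic_profile(case, noise_sd=0.05 * signal, n_points=50, seed=7)
        sd = np.std(p.values - signal, ddof=1)
        assert 0.035 * signal <= sd <= 0.065 * signal

    def test_too_few_points_rejected(self):
        case = zs.stagnant_mm_case(**self.CASE)
        with pytest.raises(ValueError):
            zs.synthetic_profile(case, 0.0, 2, seed=1)


class TestRecoverVmax:
    CASE = dict(c0=0.21, depth=5e-3, diffusivity=3e-9, sigma_vmax=3e-8, km=5e-3)

    def _recover(self, profile):
        return zs.recover_vmax(
            profile,
            c0=self.CASE["c0"],
            depth=self.CASE["depth"],
            diffusivity=self.CASE["diffusivity"],
            km=self.CASE["km"],
        )

    def test_noiseless_recovery_is_exact(self):
        case = zs.stagnant_mm_case(**self.CASE)
        est = self._recover(zs.synthetic_profile(case, 0.0, 10, seed=3))
        assert est.estimate == pytest.approx(3e-8, rel=1e-6)

    def test_five_percent_noise_single_replicate_within_ten_percent(self):
        case = zs.stagnant_mm_case(**self.CASE)
        signal = case.analytic["surface_conc"]
        p = zs.synthetic_profile(case, 0.05 * signal, 50, seed=11)
        est = self._recover(p)
        assert est.estimate == pytest.approx(3e-8, rel=0.10)
        assert est.significant()

    def test_bias_over_replicates_below_two_percent(self):
        case = zs.stagnant_mm_case(**self.CASE)
        signal = case.analytic["surface_conc"]
        estimates = [
            self._recover(zs.synthetic_profile(case, 0.05 * signal, 50, seed=s)).estimate
            for s in range(100)
        ]
        bias = abs(np.mean(estimates) - 3e-8) / 3e-8
        assert bias <= 0.02

    def test_zero_uptake_truth_not_significant(self):
        case = zs.stagnant_mm_case(c0=0.21, depth=5e-3, diffusivity=3e-9,
                                   sigma_vmax=0.0, km=5e-3)
        p = zs.synthetic_profile(case, 0.002, 50, seed=3)
        est = self._recover(p)
        assert not est.significant()

    def test_flat_zero_profile_not_identifiable(self):
        p = zs.SurfaceProfile(
            np.linspace(-6e-3, 6e-3, 10), np.zeros(10), "oxygen", "mol/m^3"
        )
        with pytest.raises(ValueError, match="identifiable"):
            self._recover(p)


def test_verify_all_oracles_pass():
    table = zs.verify_all(refinement_level=1)
    assert table["passed"].all(), table.to_string()
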