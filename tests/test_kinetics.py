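import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from dynpet.framing import (
    DynamicImage,
    TimeActivityCurve,
    ValidationError,
    build_frame_schedule,
)
from dynpet.input_function import InputFunction, cumulative_integrals, feng_aif
from dynpet.kinetics import (
    KineticParams,
    fit_2tci_nls,
    fit_2tci_nnls,
    fit_voxelwise,
    macro_ki,
    patlak_ki,
    simulate_tissue_tac,
)


class TestMacroKi:
    def test_benign_median_rates(self):
        # direct evaluation of K1*k3/(k2+k3) for typical benign lung kinetics
        ki = macro_ki(KineticParams(0.1661, 0.4077, 0.0330))
        assert ki == pytest.approx(0.01244, abs=5e-6)

    def test_no_trapping_gives_zero(self):
        assert macro_ki(KineticParams(0.2, 0.5, 0.0)) == 0.0

    def test_no_efflux_traps_everything(self):
        assert macro_ki(KineticParams(0.2, 0.0, 0.07)) == pytest.approx(0.2)

    def test_zero_turnover_defined(self):
        assert macro_ki(KineticParams(0.2, 0.0, 0.0)) == 0.0


class TestForwardModel:
    def test_zero_delivery_zero_tac(self, aif, protocol_schedule):
        tac = simulate_tissue_tac(KineticParams(0.0, 0.3, 0.05), aif, protocol_schedule)
        np.testing.assert_array_equal(tac.values, 0.0)

    def test_pure_accumulation_closed_form(self, aif, protocol_schedule):
        """k2 = k3 = 0: CT(t) = K1 * Int(Cp), so frame values are the frame
        averages of the input's first integral."""
        k1 = 0.1
        tac = simulate_tissue_tac(KineticParams(k1, 0.0, 0.0), aif, protocol_schedule)
        s = protocol_schedule
        # frame average of Int(Cp) = difference quotient of IntInt(Cp) at edges
        _, i2_end = cumulative_integrals(aif, s.end_min)
        _, i2_start = cumulative_integrals(aif, s.start_min)
        expect = k1 * (i2_end - i2_start) / s.duration_min
        # fine-grid trapezoid of the piecewise-quadratic integrand is only
        # second-order accurate; the bolus-onset frame carries a kink
        np.testing.assert_allclose(tac.values, expect, rtol=5e-3)

    def test_against_stiff_ode_oracle(self, aif, protocol_schedule, lesion_truth):
        tac = simulate_tissue_tac(lesion_truth, aif, protocol_schedule)

        def rhs(t, y):
            cp = np.interp(t, aif.sample_times, aif.cp)
            return [
                lesion_truth.k1 * cp - (lesion_truth.k2 + lesion_truth.k3) * y[0],
                lesion_truth.k3 * y[0],
            ]

        grid = np.linspace(0, 65, 65 * 600 + 1)
        sol = solve_ivp(
            rhs, (0, 65), [0, 0], t_eval=grid, method="LSODA",
            rtol=1e-10, atol=1e-12, max_step=1 / 60,
        )
        ct = sol.y[0] + sol.y[1]
        cum = cumulative_trapezoid(ct, grid, initial=0.0)
        s = protocol_schedule
        oracle = (np.interp(s.end_min, grid, cum) - np.interp(s.start_min, grid, cum)) / s.duration_min
        nz = oracle > 1e-6
        np.testing.assert_allclose(tac.values[nz], oracle[nz], rtol=1e-3)
        np.testing.assert_allclose(tac.values[~nz], oracle[~nz], atol=1e-9)

    def test_schedule_beyond_support_rejected(self, lesion_truth, protocol_schedule):
        short = InputFunction(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            simulate_tissue_tac(lesion_truth, short, protocol_schedule)


class TestLinearizedNNLS:
    def test_noiseless_round_trip(self, aif, protocol_schedule, lesion_truth, lesion_tac):
        est, lin = fit_2tci_nnls(lesion_tac, aif)
        assert est.k1 == pytest.approx(lesion_truth.k1, rel=0.02)
        assert est.k2 == pytest.approx(lesion_truth.k2, rel=0.02)
        assert est.k3 == pytest.approx(lesion_truth.k3, rel=0.02)
        assert est.ki == pytest.approx(lesion_truth.ki, rel=0.01)
        assert not est.degenerate

    def test_theta_mapping_identity(self, aif, lesion_tac):
        est, lin = fit_2tci_nnls(lesion_tac, aif)
        th1, th2, th3 = lin.theta
        assert est.ki == pytest.approx(th2 / th3, rel=1e-12)
        assert est.ki == pytest.approx(
            est.k1 * est.k3 / (est.k2 + est.k3), rel=1e-12
        )

    def test_all_zero_tac_degenerate(self, aif, protocol_schedule):
        tac = TimeActivityCurve(protocol_schedule, np.zeros(28))
        est, lin = fit_2tci_nnls(tac, aif)
        assert est.k1 == est.k2 == est.k3 == 0.0
        assert est.degenerate
        assert lin.theta == (0.0, 0.0, 0.0)

    def test_too_few_frames_rejected(self, aif):
        s = build_frame_schedule(((3, 60.0),))
        with pytest.raises(ValidationError):
            fit_2tci_nnls(TimeActivityCurve(s, np.ones(3)), aif)

    def test_zero_input_rejected(self, protocol_schedule):
        f = InputFunction(np.array([0.0, 65.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValidationError):
            fit_2tci_nnls(TimeActivityCurve(protocol_schedule, np.ones(28)), f)

    def test_nonnegativity_on_arbitrary_inputs(self, aif, protocol_schedule, rng):
        """NNLS guarantees fitted rates are never negative, even on noise."""
        for _ in range(30):
            v = rng.normal(0, 5, 28)
            est, _ = fit_2tci_nnls(TimeActivityCurve(protocol_schedule, v), aif)
            assert min(est.k1, est.k2, est.k3, est.ki) >= 0.0

    def test_ki_monotone_in_k3(self, aif, protocol_schedule):
        fitted = []
        for k3 in [0.01, 0.03, 0.06, 0.09, 0.12]:
            tac = simulate_tissue_tac(KineticParams(0.12, 0.25, k3), aif, protocol_schedule)
            est, _ = fit_2tci_nnls(tac, aif)
            fitted.append(est.ki)
        assert np.all(np.diff(fitted) > 0)

    def test_noise_ki_more_stable_than_k3(self, aif, protocol_schedule, lesion_truth, lesion_tac):
        """Under the moderate noise model Ki has small median bias and a
        tighter relative spread than the micro-parameter k3."""
        from dynpet.synthetic import NOISE_ALPHA

        s = protocol_schedule
        sigma = NOISE_ALPHA["moderate"] * np.sqrt(
            np.maximum(lesion_tac.values, 0.1) / s.duration_min
        )
        rng = np.random.default_rng(42)
        kis, k3s = [], []
        for _ in range(200):
            v = lesion_tac.values + rng.normal(0, 1, 28) * sigma
            est, _ = fit_2tci_nnls(TimeActivityCurve(s, v), aif)
            kis.append(est.ki)
            k3s.append(est.k3)
        kis, k3s = np.array(kis), np.array(k3s)
        med_bias = np.median((kis - lesion_truth.ki) / lesion_truth.ki)
        assert abs(med_bias) <= 0.05
        iqr = lambda x: np.subtract(*np.percentile(x, [75, 25]))
        assert iqr(kis) / lesion_truth.ki < iqr(k3s) / lesion_truth.k3


class TestNonlinearOracle:
    def test_self_fit_from_truth(self, aif, lesion_truth, lesion_tac):
        est = fit_2tci_nls(lesion_tac, aif, init=lesion_truth, n_starts=1)
        assert est.k1 == pytest.approx(lesion_truth.k1, rel=1e-4)
        assert est.k2 == pytest.approx(lesion_truth.k2, rel=1e-3)
        assert est.k3 == pytest.approx(lesion_truth.k3, rel=1e-3)

    def test_recovers_from_perturbed_init(self, aif, lesion_truth, lesion_tac):
        bad = KineticParams(0.24, 0.50, 0.12)  # 2x truth
        est = fit_2tci_nls(lesion_tac, aif, init=bad)
        assert est.k1 == pytest.approx(lesion_truth.k1, rel=0.01)
        assert est.k2 == pytest.approx(lesion_truth.k2, rel=0.01)
        assert est.k3 == pytest.approx(lesion_truth.k3, rel=0.01)

    def test_zero_delivery_data(self, aif, protocol_schedule):
        tac = TimeActivityCurve(protocol_schedule, np.zeros(28))
        est = fit_2tci_nls(tac, aif)
        assert est.k1 < 1e-6


class TestPatlak:
    def test_slope_matches_macro_ki(self, aif, protocol_schedule, lesion_truth, lesion_tac):
        slope, _ = patlak_ki(lesion_tac, aif, t_star=20.0)
        assert slope == pytest.approx(lesion_truth.ki, rel=0.05)

    def test_no_trapping_gives_zero_slope(self, aif, protocol_schedule):
        tac = simulate_tissue_tac(KineticParams(0.12, 0.25, 0.0), aif, protocol_schedule)
        slope, _ = patlak_ki(tac, aif, t_star=20.0)
        assert abs(slope) < 1e-3

    def test_exact_linear_data(self, aif, protocol_schedule):
        """Data constructed as CT = a*Int(Cp) + b*Cp recover (a, b) exactly."""
        a, b = 0.02, 0.3
        s = protocol_schedule
        grid = np.linspace(0, 65, 65 * 600 + 1)
        cp = aif.cp_at(grid)
        i1 = cumulative_trapezoid(cp, grid, initial=0.0)
        ct = a * i1 + b * cp
        cum = cumulative_trapezoid(ct, grid, initial=0.0)
        vals = (np.interp(s.end_min, grid, cum) - np.interp(s.start_min, grid, cum)) / s.duration_min
        slope, intercept = patlak_ki(TimeActivityCurve(s, vals), aif, t_star=20.0)
        assert slope == pytest.approx(a, rel=1e-4)
        assert intercept == pytest.approx(b, rel=1e-3)

    def test_insufficient_late_frames_rejected(self, aif, lesion_tac):
        with pytest.raises(ValidationError):
            patlak_ki(lesion_tac, aif, t_star=62.0)


class TestVoxelwise:
    def _image_from_tacs(self, tacs, schedule):
        vox = np.asarray(tacs)[None, :, None, :]  # (1, n, 1, frames)
        return DynamicImage(vox, (1, 1, 1), np.eye(4), schedule)

    def test_matches_scalar_path_exactly(self, aif, protocol_schedule):
        params = [
            KineticParams(0.08, 0.30, 0.02),
            KineticParams(0.12, 0.25, 0.06),
            KineticParams(0.30, 0.60, 0.10),
        ]
        tacs = [simulate_tissue_tac(p, aif, protocol_schedule).values for p in params]
        img = self._image_from_tacs(tacs, protocol_schedule)
        maps = fit_voxelwise(img, aif, np.ones((1, 3, 1), bool))
        for j, p in enumerate(params):
            est, _ = fit_2tci_nnls(
                TimeActivityCurve(protocol_schedule, tacs[j]), aif
            )
            assert maps.k1_map[0, j, 0] == pytest.approx(est.k1, rel=1e-10)
            assert maps.k2_map[0, j, 0] == pytest.approx(est.k2, rel=1e-10)
            assert maps.ki_map[0, j, 0] == pytest.approx(est.ki, rel=1e-10)

    def test_uniform_noiseless_lesion_recovers_truth(self, aif, protocol_schedule, lesion_truth):
        tac = simulate_tissue_tac(lesion_truth, aif, protocol_schedule).values
        img = self._image_from_tacs([tac] * 4, protocol_schedule)
        maps = fit_voxelwise(img, aif, np.ones((1, 4, 1), bool))
        kis = maps.ki_map[0, :, 0]
        assert np.ptp(kis) / kis.mean() < 0.01  # uniform within 1%
        np.testing.assert_allclose(kis, lesion_truth.ki, rtol=0.02)

    def test_empty_mask_rejected(self, aif, protocol_schedule):
        img = self._image_from_tacs([np.ones(28)], protocol_schedule)
        with pytest.raises(ValidationError):
            fit_voxelwise(img, aif, np.zeros((1, 1, 1), bool))

    def test_mask_respected_and_zero_outside(self, aif, protocol_schedule, lesion_truth):
        tac = simulate_tissue_tac(lesion_truth, aif, protocol_schedule).values
        img = self._image_from_tacs([tac, tac], protocol_schedule)
        mask = np.zeros((1, 2, 1), bool)
        mask[0, 0, 0] = True
        maps = fit_voxelwise(img, aif, mask)
        assert maps.ki_map[0, 1, 0] == 0.0
        assert not maps.fitted_mask[0, 1, 0]
        assert maps.ki_map[0, 0, 0] > 0
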