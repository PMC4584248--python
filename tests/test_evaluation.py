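"""Rotational-variance evaluation: rotations, noise model, deviations."""

import numpy as np
import pytest

from koges import (
    AcquisitionParams,
    MCConfig,
    TensorCoeffs,
    adc,
    design_matrix,
    embed_second_order,
    fit_tensor,
    make_rotation_grid,
    rotate_tensor4,
    rotational_variance_experiment,
    signal_deviation,
    simulate_signals,
)
from koges.fixtures import direction_set, tensor

from conftest import random_directions


class TestRotationGrid:
    def test_default_grid_has_343_rotations(self):
        grid = make_rotation_grid(7)
        assert len(grid) == 343

    def test_all_rotations_are_proper(self):
        grid = make_rotation_grid(3)
        for R in grid.rotations:
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_single_step_grid_is_identity(self):
        grid = make_rotation_grid(1)
        assert len(grid) == 1
        np.testing.assert_allclose(grid.rotations[0], np.eye(3), atol=1e-15)


class TestRotateTensor4:
    def test_identity_rotation_is_a_noop(self):
        t = tensor("t02")
        np.testing.assert_allclose(rotate_tensor4(t, np.eye(3)).coeffs, t.coeffs)

    def test_isotropic_tensor_is_rotation_invariant(self):
        t = embed_second_order(np.eye(3))
        R = make_rotation_grid(5).rotations[17]
        np.testing.assert_allclose(rotate_tensor4(t, R).coeffs, t.coeffs, atol=1e-12)

    def test_adc_transforms_contravariantly(self, rng):
        # the defining contract: ADC_t'(g) = ADC_t(R'g)
        t = TensorCoeffs(4, rng.standard_normal(15))
        R = make_rotation_grid(7).rotations[123]
        tp = rotate_tensor4(t, R)
        for _ in range(100):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            assert abs(adc(tp, g) - adc(t, R.T @ g)) < 1e-10

    def test_rotations_compose(self, rng):
        t = TensorCoeffs(4, rng.standard_normal(15))
        grid = make_rotation_grid(5).rotations
        R1, R2 = grid[7], grid[99]
        np.testing.assert_allclose(
            rotate_tensor4(rotate_tensor4(t, R1), R2).coeffs,
            rotate_tensor4(t, R2 @ R1).coeffs,
            atol=1e-10,
        )

    def test_non_orthogonal_matrix_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            rotate_tensor4(tensor("t01"), np.eye(3) * 1.01)


class TestSimulateSignals:
    def test_infinite_snr_reproduces_clean_signals(self, rng):
        dirs = direction_set("koptimal30")
        t = tensor("t01")
        acq = AcquisitionParams(b=1500, S0=1.0, snr=np.inf)
        s = simulate_signals(t, dirs, acq, rng)
        clean = np.exp(-1500 * (design_matrix(dirs, 4) @ t.coeffs))
        np.testing.assert_allclose(s, clean, atol=1e-15)

    def test_single_fiber_signal_along_its_axis(self, rng):
        # t01's x^4 coefficient is 17e-4 mm^2/s, so at b = 1500 s/mm^2 the
        # clean signal along x is exp(-2.55)
        from koges import DirectionSet
        acq = AcquisitionParams(b=1500, S0=1.0, snr=np.inf)
        s = simulate_signals(tensor("t01"), DirectionSet([[1.0, 0, 0]]), acq, rng)
        assert s[0] == pytest.approx(np.exp(-2.55), rel=1e-12)

    def test_zero_signal_limit_is_rayleigh(self, rng):
        # when the clean signal vanishes the Rician magnitude has mean
        # sigma * sqrt(pi/2)
        dirs = random_directions(30, seed=2)
        t = embed_second_order(0.025 * np.eye(3))  # b*d = 37.5, S ~ 5e-17
        acq = AcquisitionParams(b=1500, S0=1.0, snr=12.5)
        s = simulate_signals(t, dirs, acq, rng, n_trials=4000)
        expected = acq.sigma * np.sqrt(np.pi / 2)
        assert s.mean() == pytest.approx(expected, rel=0.01)


class TestSignalDeviation:
    def test_zero_for_noiseless_exact_fit(self, rng):
        dirs = random_directions(30, seed=4)
        t = tensor("t04")
        acq = AcquisitionParams(b=1500, S0=1.0, snr=np.inf)
        meas = simulate_signals(t, dirs, acq, rng)
        s = -np.log(meas / acq.S0) / acq.b
        eta = signal_deviation(meas, fit_tensor(s, dirs, 4), dirs, acq)
        assert eta == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_S0_scale(self):
        # the same relative noise realization at two S0 scales yields the
        # same eta: both S and S_hat carry the S0 factor
        dirs = random_directions(30, seed=6)
        t = tensor("t05")
        t_hat = TensorCoeffs(4, t.coeffs * 1.05)
        acq1 = AcquisitionParams(b=1500, S0=1.0, snr=12.5)
        acq2 = AcquisitionParams(b=1500, S0=250.0, snr=12.5)
        meas1 = simulate_signals(t, dirs, acq1, np.random.default_rng(0))
        meas2 = simulate_signals(t, dirs, acq2, np.random.default_rng(0))
        np.testing.assert_allclose(meas2, 250.0 * meas1, rtol=1e-12)
        assert signal_deviation(meas1, t_hat, dirs, acq1) == pytest.approx(
            signal_deviation(meas2, t_hat, dirs, acq2), rel=1e-12
        )

    def test_vectorized_matches_per_direction_loop(self, rng):
        dirs = random_directions(30, seed=8)
        t = tensor("t03")
        acq = AcquisitionParams()
        meas = simulate_signals(t, dirs, acq, rng)
        t_hat = TensorCoeffs(4, t.coeffs * 0.97)
        eta = signal_deviation(meas, t_hat, dirs, acq)
        pred = acq.S0 * np.exp(-acq.b * (design_matrix(dirs, 4) @ t_hat.coeffs))
        loop = sum(abs(meas[i] - pred[i]) for i in range(30)) / 30 / acq.S0
        assert eta == pytest.approx(loop, abs=1e-14)


class TestRotationalVariance:
    def test_seeded_runs_are_bit_identical(self):
        dirs = direction_set("koptimal30")
        grid = make_rotation_grid(2)
        mc = MCConfig(n_mc=20, seed=77)
        r1 = rotational_variance_experiment(dirs, tensor("t01"), grid, mc)
        r2 = rotational_variance_experiment(dirs, tensor("t01"), grid, mc)
        np.testing.assert_array_equal(r1.eta_bar, r2.eta_bar)
        assert r1.mean_eta == r2.mean_eta and r1.sd_eta == r2.sd_eta

    def test_noiseless_deviation_is_zero_everywhere(self):
        dirs = direction_set("koptimal30")
        mc = MCConfig(n_mc=3, seed=1,
                      acquisition=AcquisitionParams(snr=np.inf))
        res = rotational_variance_experiment(dirs, tensor("t01"),
                                             make_rotation_grid(2), mc)
        np.testing.assert_allclose(res.eta_bar, 0.0, atol=1e-10)

    def test_deviation_decreases_with_snr(self):
        dirs = direction_set("koptimal30")
        grid = make_rotation_grid(3)
        means = []
        for snr in (12.5, 25.0, 50.0):
            mc = MCConfig(n_mc=200, seed=5,
                          acquisition=AcquisitionParams(snr=snr))
            means.append(
                rotational_variance_experiment(dirs, tensor("t01"), grid, mc).mean_eta
            )
        assert means[0] > means[1] > means[2]

    def test_summary_consistent_with_per_rotation_values(self):
        dirs = direction_set("koptimal30")
        res = rotational_variance_experiment(
            dirs, tensor("t06"), make_rotation_grid(2), MCConfig(n_mc=10, seed=3)
        )
        assert np.all(res.eta_bar >= 0)
        assert res.mean_eta == pytest.approx(res.eta_bar.mean(), abs=1e-12)
        assert res.sd_eta == pytest.approx(res.eta_bar.std(ddof=1), abs=1e-12)
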