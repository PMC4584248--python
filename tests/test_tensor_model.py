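"""Tensor model: monomial vectors, design matrices, least squares."""

import numpy as np
import pytest

from koges import (
    DirectionSet,
    SingularDesignError,
    TensorCoeffs,
    adc,
    condition_numbers,
    design_matrix,
    embed_second_order,
    fit_tensor,
    monomial_vector,
)
from koges.fixtures import direction_set

from conftest import random_directions


class TestMonomialVector:
    def test_z_axis_hits_only_the_z4_slot(self):
        a = monomial_vector((0, 0, 1), 4)
        expected = np.zeros(15)
        expected[0] = 1.0
        np.testing.assert_allclose(a, expected)

    def test_x_axis_hits_only_the_x4_slot(self):
        a = monomial_vector((1, 0, 0), 4)
        expected = np.zeros(15)
        expected[-1] = 1.0
        np.testing.assert_allclose(a, expected)

    def test_isotropic_profile_is_one_everywhere(self, rng):
        # (x^2+y^2+z^2)^2 = 1 on the sphere, so the embedded identity
        # contracts with any monomial vector to exactly 1
        t_iso = embed_second_order(np.eye(3))
        for _ in range(50):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            assert monomial_vector(g, 4) @ t_iso.coeffs == pytest.approx(1.0, abs=1e-12)

    def test_order2_listing(self):
        a = monomial_vector((0.6, 0.8, 0.0), 2)
        np.testing.assert_allclose(a, [0.36, 0.64, 0.0, 2 * 0.48, 0.0, 0.0])

    def test_rejects_non_unit_and_odd_order(self):
        with pytest.raises(ValueError, match="unit"):
            monomial_vector((1.0, 1.0, 0.0), 4)
        with pytest.raises(ValueError, match="order"):
            monomial_vector((1.0, 0.0, 0.0), 3)


class TestDesignMatrix:
    def test_single_direction_row_equals_monomial_vector(self):
        d = DirectionSet([[1.0, 0.0, 0.0]])
        G = design_matrix(d, 4)
        assert G.shape == (1, 15)
        np.testing.assert_allclose(G[0], monomial_vector((1, 0, 0), 4))

    @pytest.mark.parametrize("order,n", [(2, 8), (4, 20)])
    def test_information_matrix_matches_termwise_accumulation(self, order, n):
        # brute-force oracle: G'G accumulated as sum_i a_i a_i'
        dirs = random_directions(n, seed=order * 100 + n)
        G = design_matrix(dirs, order)
        acc = np.zeros((G.shape[1], G.shape[1]))
        for g in dirs:
            a = monomial_vector(g, order)
            acc += np.outer(a, a)
        np.testing.assert_allclose(G.T @ G, acc, atol=1e-12)

    def test_empty_set_is_rejected(self):
        with pytest.raises(ValueError):
            DirectionSet(np.empty((0, 3)))


class TestFitTensor:
    def test_noiseless_round_trip_recovers_coefficients(self, rng):
        dirs = random_directions(20, seed=7)
        t = TensorCoeffs(4, rng.standard_normal(15))
        s = design_matrix(dirs, 4) @ t.coeffs
        t_hat = fit_tensor(s, dirs, 4)
        np.testing.assert_allclose(t_hat.coeffs, t.coeffs, rtol=1e-10)

    def test_square_full_rank_system_interpolates_exactly(self, rng):
        dirs = random_directions(15, seed=11)
        s = rng.standard_normal(15)
        t_hat = fit_tensor(s, dirs, 4)
        resid = s - design_matrix(dirs, 4) @ t_hat.coeffs
        assert np.max(np.abs(resid)) < 1e-8 * np.max(np.abs(s))

    def test_scale_equivariance(self, rng):
        dirs = random_directions(25, seed=13)
        s = rng.standard_normal(25)
        t1 = fit_tensor(s, dirs, 4)
        t2 = fit_tensor(3.5 * s, dirs, 4)
        np.testing.assert_allclose(t2.coeffs, 3.5 * t1.coeffs, rtol=1e-12)

    def test_repeated_direction_design_is_singular(self):
        dirs = DirectionSet(np.tile([[1.0, 0.0, 0.0]], (30, 1)))
        with pytest.raises(SingularDesignError, match="rank"):
            fit_tensor(np.zeros(30), dirs, 4)


class TestEmbedSecondOrder:
    def test_identity_embeds_to_unit_adc(self, rng):
        t = embed_second_order(np.eye(3))
        for _ in range(10):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            assert adc(t, g) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_form_oracle(self, rng):
        A = rng.standard_normal((3, 3))
        D = (A + A.T) / 2
        t = embed_second_order(D)
        for _ in range(100):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            assert abs(g @ D @ g - adc(t, g)) < 1e-12

    def test_diagonal_tensor_has_zero_cross_slots(self):
        t = embed_second_order(np.diag([1.7, 0.3, 0.9]))
        # slots multiplying monomials with any odd power must vanish
        odd_slots = [1, 3, 5, 6, 7, 8, 10, 12, 13]
        np.testing.assert_allclose(t.coeffs[odd_slots], 0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            embed_second_order(np.array([[1, 1e-3, 0], [0, 1, 0], [0, 0, 1.0]]))

    def test_order4_fit_of_gaussian_profile_matches_embedding(self, rng):
        # a second-order profile fitted with the order-4 model reproduces
        # the same ADC everywhere (consistency of the embedding)
        A = rng.standard_normal((3, 3))
        D = (A + A.T) / 2
        dirs = random_directions(24, seed=23)
        s = np.array([g @ D @ g for g in dirs])
        t_hat = fit_tensor(s, dirs, 4)
        t_emb = embed_second_order(D)
        probe = random_directions(100, seed=29)
        np.testing.assert_allclose(
            design_matrix(probe, 4) @ t_hat.coeffs,
            design_matrix(probe, 4) @ t_emb.coeffs,
            atol=1e-10,
        )


class TestConditionNumbers:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("order,n", [(2, 10), (4, 18)])
    def test_kappa_G_squared_equals_kappa_M(self, order, n, seed):
        cn = condition_numbers(random_directions(n, seed=seed), order)
        assert cn.kappa_G**2 == pytest.approx(cn.kappa_M, rel=1e-8)

    def test_published_fourth_order_scheme(self):
        cn = condition_numbers(direction_set("koptimal30"), 4)
        assert cn.kappa_G == pytest.approx(1.9141, rel=0.01)

    def test_published_dti_scheme(self):
        cn = condition_numbers(direction_set("koptimal-dti6"), 2)
        assert cn.kappa_G == pytest.approx(np.sqrt(7) / 2, rel=0.005)

    def test_singular_design_is_flagged_not_raised(self):
        cn = condition_numbers(DirectionSet(np.tile([[0.0, 0.0, 1.0]], (16, 1))), 4)
        assert cn.singular and np.isinf(cn.kappa_G) and np.isinf(cn.kappa_M)
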