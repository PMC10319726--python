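"""GLV model construction, boosting, integration and cohort generation."""

import numpy as np
import pytest

from keystone import (
    GLVModel,
    KeystoneSpec,
    apply_boosts,
    boost_species,
    generate_cohort,
    lognormal_boosts,
    make_ba_model,
    make_er_model,
    simulate_steady_state,
)


class TestERModel:
    def test_edge_count_matches_density(self):
        model = make_er_model(100, 10.0, 0.1, seed=0)
        n_edges = np.count_nonzero(model.A) - 100  # exclude diagonal
        # Binomial(9900, 10/99): mean 1000, sd ~30; allow 5 sd
        assert abs(n_edges - 1000) < 150

    def test_diagonal_minus_one_and_values_bounded(self):
        model = make_er_model(50, 8.0, 0.2, seed=1)
        np.testing.assert_array_equal(np.diag(model.A), -1.0)
        off = model.A[~np.eye(50, dtype=bool)]
        assert np.all(np.abs(off) <= 0.2)

    def test_sigma_zero_gives_no_interactions(self):
        model = make_er_model(20, 5.0, 0.0, seed=2)
        assert np.count_nonzero(model.A) == 20  # diagonal only

    def test_deterministic_given_seed(self):
        a = make_er_model(30, 5.0, 0.1, seed=3)
        b = make_er_model(30, 5.0, 0.1, seed=3)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.r, b.r)

    def test_unit_growth_option(self):
        model = make_er_model(10, 3.0, 0.1, seed=4, growth="unit")
        np.testing.assert_array_equal(model.r, 1.0)


class TestBAModel:
    def test_hub_degree_dominates(self):
        model = make_ba_model(100, 3, 0.1, 0.1, seed=0)
        deg = ((model.A != 0).sum(axis=0) + (model.A != 0).sum(axis=1) - 2)
        assert deg.max() > 3 * np.median(deg)

    def test_seed_core_complete_when_n0_equals_n(self):
        model = make_ba_model(6, 6, 0.0, 0.1, seed=1)
        mask = model.A != 0
        # every unordered pair carries exactly one directed interaction
        pair_count = (mask | mask.T)[np.triu_indices(6, k=1)]
        assert pair_count.all()

    def test_directionality_preserves_skeleton(self):
        a = make_ba_model(50, 3, 0.0, 0.1, seed=5)
        b = make_ba_model(50, 3, 1.0, 0.1, seed=5)
        skel_a = (a.A != 0) | (a.A != 0).T
        skel_b = (b.A != 0) | (b.A != 0).T
        np.testing.assert_array_equal(skel_a, skel_b)
        assert (a.A != 0).sum() == (b.A != 0).sum()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_ba_model(10, 0, 0.1, 0.1, seed=0)
        with pytest.raises(ValueError):
            make_ba_model(10, 3, 1.5, 0.1, seed=0)


class TestBoosting:
    def test_identity_when_k_is_one(self):
        model = make_er_model(20, 5.0, 0.2, seed=7)
        boosted = boost_species(model, KeystoneSpec(4, 1.0))
        np.testing.assert_array_equal(boosted.A, model.A)

    def test_scales_outgoing_column_only(self):
        model = make_er_model(20, 5.0, 0.2, seed=8)
        boosted = boost_species(model, KeystoneSpec(3, 10.0))
        np.testing.assert_allclose(
            np.delete(boosted.A[:, 3], 3), 10.0 * np.delete(model.A[:, 3], 3))
        assert boosted.A[3, 3] == -1.0
        # in-going interactions untouched
        np.testing.assert_array_equal(np.delete(boosted.A[3, :], 3),
                                      np.delete(model.A[3, :], 3))
        # all other columns untouched
        others = np.delete(np.arange(20), 3)
        np.testing.assert_array_equal(boosted.A[:, others], model.A[:, others])

    def test_boost_then_inverse_restores(self):
        model = make_er_model(15, 4.0, 0.3, seed=9)
        twice = boost_species(boost_species(model, KeystoneSpec(2, 7.0)),
                              KeystoneSpec(2, 1.0 / 7.0))
        np.testing.assert_allclose(twice.A, model.A, atol=1e-12)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            KeystoneSpec(0, 0.0)

    def test_lognormal_boost_vector(self):
        model = make_er_model(30, 5.0, 0.1, seed=10)
        K = lognormal_boosts(30, 0.5, 1.0, seed=11)
        assert np.all(K > 0)
        boosted = apply_boosts(model, K)
        np.testing.assert_array_equal(np.diag(boosted.A), -1.0)
        np.testing.assert_allclose(np.delete(boosted.A[:, 5], 5),
                                   K[5] * np.delete(model.A[:, 5], 5))


class TestSteadyState:
    def test_logistic_fixed_point(self):
        model = GLVModel(r=[0.7], A=[[-1.0]])
        x = simulate_steady_state(model, [0.1])
        assert x[0] == pytest.approx(0.7, abs=1e-6)

    def test_independent_logistic_fixed_points(self):
        model = GLVModel(r=[0.4, 0.6], A=[[-1.0, 0.0], [0.0, -1.0]])
        x = simulate_steady_state(model, [0.2, 0.9])
        np.testing.assert_allclose(x, [0.4, 0.6], atol=1e-6)

    def test_absent_taxon_stays_absent(self):
        model = make_er_model(10, 3.0, 0.1, seed=12)
        init = np.full(10, 0.5)
        init[4] = 0.0
        x = simulate_steady_state(model, init)
        assert x[4] == 0.0

    def test_full_output_reports_convergence(self):
        model = GLVModel(r=[0.5], A=[[-1.0]])
        ss = simulate_steady_state(model, [0.1], full_output=True)
        assert ss.converged
        assert ss.residual < 1e-8


class TestGenerateCohort:
    def test_columns_sum_to_one(self):
        model = make_er_model(20, 5.0, 0.15, seed=13)
        cohort = generate_cohort(model, 10, seed=14)
        np.testing.assert_allclose(cohort.abundances.sum(axis=0), 1.0,
                                   atol=1e-9)
        assert cohort.absolute is not None
        assert cohort.converged.all()

    def test_non_interacting_analytic_fixed_point(self):
        # presence_prob=1 and no interactions: every sample equals r / sum(r)
        model = make_er_model(8, 2.0, 0.0, seed=15)
        cohort = generate_cohort(model, 3, presence_prob=1.0, seed=16)
        expected = model.r / model.r.sum()
        for k in range(3):
            np.testing.assert_allclose(cohort.abundances[:, k], expected,
                                       atol=1e-8)

    def test_bit_identical_given_seed(self):
        model = make_er_model(15, 4.0, 0.1, seed=17)
        a = generate_cohort(model, 5, seed=18)
        b = generate_cohort(model, 5, seed=18)
        np.testing.assert_array_equal(a.abundances, b.abundances)

    def test_stability_screening(self):
        # sigma_A = 0.5/sqrt(mean degree) keeps nearly all samples convergent
        model = make_er_model(50, 10.0, 0.5 / np.sqrt(10), seed=19)
        cohort = generate_cohort(model, 20, seed=20)
        assert cohort.converged.mean() >= 0.95
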