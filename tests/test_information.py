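import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmmdesign import (
    CorrelationSpec,
    DropoutSpec,
    FisherInfo,
    FixedEffectsSpec,
    LMMSpec,
    RandomEffectsSpec,
    build_fixed_design,
    build_response_covariance,
    d_criterion,
    expected_information,
    pattern_information,
    relative_d_efficiency,
)
from lmmdesign.dropout import pattern_probabilities
from lmmdesign.errors import CovarianceError

from conftest import two_arm_design


class TestPatternInformation:
    def test_full_length_equals_gls_information(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        A = rng.normal(size=(4, 4))
        V = A @ A.T + 4 * np.eye(4)
        np.testing.assert_allclose(
            pattern_information(X, V, 4), X.T @ np.linalg.inv(V) @ X, rtol=1e-10
        )

    def test_single_observation_scalar_case(self):
        X = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        V = np.diag([2.0, 3.0])
        M = pattern_information(X, V, 1)
        expected = np.zeros((3, 3))
        expected[0, 0] = 0.5
        np.testing.assert_allclose(M, expected)

    def test_two_observation_truncation_against_explicit_inverse(self):
        """Independent small-matrix oracle: explicit 2x2 inversion."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3))
        A = rng.normal(size=(5, 5))
        V = A @ A.T + 5 * np.eye(5)
        a, b, c = V[0, 0], V[0, 1], V[1, 1]
        Vinv2 = np.array([[c, -b], [-b, a]]) / (a * c - b * b)
        np.testing.assert_allclose(
            pattern_information(X, V, 2), X[:2].T @ Vinv2 @ X[:2], rtol=1e-10
        )


class TestExpectedInformation:
    def test_no_dropout_reduces_to_complete_data_form(self, ri_ar1_model):
        design = two_arm_design([0.0, 42.0, 126.0, 210.0, 364.0], 0.4, 100)
        info = expected_information(design, ri_ar1_model, DropoutSpec("constant_one"))
        expected = np.zeros((3, 3))
        for g in design.groups:
            X = build_fixed_design(ri_ar1_model.fixed, g.t, dose=g.dose)
            V = build_response_covariance(
                g.t, ri_ar1_model.random, ri_ar1_model.sigma2, ri_ar1_model.corr
            )
            expected += design.N * g.w * X.T @ np.linalg.inv(V) @ X
        np.testing.assert_allclose(info.matrix, expected, rtol=1e-9)

    def test_monte_carlo_pattern_draws_match_expectation(
        self, ri_ar1_model, logistic_dropout, xi_d_star
    ):
        """Sampling realized pattern counts reproduces the expected matrix."""
        reps = 100_000
        rng = np.random.default_rng(7)
        total = np.zeros((3, 3))
        for g, n in zip(xi_d_star.groups, (61, 83)):
            X = build_fixed_design(ri_ar1_model.fixed, g.t, dose=g.dose)
            V = build_response_covariance(
                g.t, ri_ar1_model.random, ri_ar1_model.sigma2, ri_ar1_model.corr
            )
            pi = pattern_probabilities(logistic_dropout, g.t, g.dose)
            mean_counts = rng.multinomial(n, pi, size=reps).mean(axis=0)
            for j in range(1, 6):
                total += mean_counts[j - 1] * pattern_information(X, V, j)
        info = expected_information(xi_d_star, ri_ar1_model, logistic_dropout)
        # per-entry Monte-Carlo tolerance ~ 3/sqrt(reps) relative
        np.testing.assert_allclose(total, info.matrix, rtol=3e-2)

    def test_linearity_in_sample_size(self, ri_ar1_model, logistic_dropout):
        d1 = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 100)
        d2 = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 200)
        m1 = expected_information(d1, ri_ar1_model, logistic_dropout).matrix
        m2 = expected_information(d2, ri_ar1_model, logistic_dropout).matrix
        np.testing.assert_allclose(2 * m1, m2, rtol=1e-10)

    def test_loewner_monotone_in_pattern_mass(self, ri_ar1_model, logistic_dropout):
        """More retained subjects never reduce information (PSD ordering)."""
        design = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 100)
        full = expected_information(design, ri_ar1_model, logistic_dropout).matrix
        trunc = expected_information(
            design, ri_ar1_model, logistic_dropout, include_baseline_only=False
        ).matrix
        assert np.linalg.eigvalsh(full - trunc)[0] >= -1e-9

    def test_group_relabel_invariance_md(self, ri_ar1_model, logistic_dropout):
        d = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.4, 100)
        swapped = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.6, 100, doses=(100.0, 0.0))
        c1 = d_criterion(expected_information(d, ri_ar1_model, logistic_dropout))
        c2 = d_criterion(expected_information(swapped, ri_ar1_model, logistic_dropout))
        assert c1 == pytest.approx(c2, rel=1e-12)


class TestDCriterion:
    def test_identity_and_closed_form(self):
        assert d_criterion(FisherInfo(np.eye(3))) == 0.0
        assert d_criterion(FisherInfo(np.array([[2.0, 1.0], [1.0, 2.0]]))) == (
            pytest.approx(np.log(3))
        )

    def test_scaling_shifts_by_p_log_c(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(4, 4))
        M = A @ A.T + 4 * np.eye(4)
        assert d_criterion(FisherInfo(3.0 * M)) == pytest.approx(
            d_criterion(FisherInfo(M)) + 4 * np.log(3.0)
        )

    def test_singular_matrix_rejected(self):
        assert d_criterion(FisherInfo(np.zeros((3, 3)))) == -np.inf
        assert d_criterion(FisherInfo(-np.eye(2))) == -np.inf


class TestRelativeDEfficiency:
    def test_identical_designs_have_unit_efficiency(self):
        M = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert relative_d_efficiency(M, M, 2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "det_cand, det_ref, printed",
        [(2.828, 1.526, 0.8140), (1.526, 1.169, 0.9150)],
    )
    def test_determinant_ratio_consistency(self, det_cand, det_ref, printed):
        """Published determinant pairs imply the published efficiencies."""
        cand = np.diag([det_cand, 1.0, 1.0])
        ref = np.diag([det_ref, 1.0, 1.0])
        assert relative_d_efficiency(cand, ref, 3) == pytest.approx(printed, abs=3e-4)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 10.0))
    def test_scale_free(self, scale):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        B = rng.normal(size=(3, 3))
        Ca, Cb = A @ A.T + 3 * np.eye(3), B @ B.T + 3 * np.eye(3)
        assert relative_d_efficiency(scale * Ca, scale * Cb, 3) == pytest.approx(
            relative_d_efficiency(Ca, Cb, 3), rel=1e-10
        )

    def test_non_pd_input_rejected(self):
        with pytest.raises(CovarianceError):
            relative_d_efficiency(-np.eye(2), np.eye(2), 2)
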