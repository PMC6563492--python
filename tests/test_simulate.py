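import numpy as np
import pytest

from lmmdesign import (
    CorrelationSpec,
    DropoutSpec,
    FixedEffectsSpec,
    LMMSpec,
    RandomEffectsSpec,
    evaluate_designs,
    expected_information,
    fit_available_case,
    simulate_trial,
)
from lmmdesign.dropout import pattern_probabilities
from lmmdesign.simulate import TrialData

from conftest import two_arm_design


def model_with_beta(ri_model):
    return ri_model  # beta already set in the fixture


@pytest.fixture
def small_design():
    return two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 40)


class TestSimulateTrial:
    def test_no_dropout_gives_complete_data(self, ri_ar1_model, small_design):
        data = simulate_trial(small_design, ri_ar1_model, DropoutSpec("constant_one"), seed=0)
        assert data.frame["observed"].all()
        assert data.n_subjects == 40
        assert not data.frame["y"].isna().any()

    def test_missingness_is_monotone_with_baseline_observed(
        self, ri_ar1_model, logistic_dropout, small_design
    ):
        data = simulate_trial(small_design, ri_ar1_model, logistic_dropout, seed=1)
        for _, sub in data.frame.groupby("subject"):
            flags = sub.sort_values("time")["observed"].to_numpy()
            assert flags[0] == 1
            assert np.all(np.diff(flags) <= 0)  # once missing, always missing
        assert data.frame.loc[data.frame["observed"] == 0, "y"].isna().all()

    def test_pattern_frequencies_match_probabilities(
        self, ri_ar1_model, logistic_dropout
    ):
        design = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 20_000)
        data = simulate_trial(design, ri_ar1_model, logistic_dropout, seed=2)
        placebo = data.frame[data.frame["group"] == 1]
        lengths = placebo.groupby("subject")["observed"].sum()
        freq = lengths.value_counts(normalize=True).sort_index().to_numpy()
        pi = pattern_probabilities(logistic_dropout, design.groups[0].t, 0.0)
        n = lengths.size
        se = np.sqrt(pi * (1 - pi) / n)
        assert np.all(np.abs(freq - pi) < 3 * se + 1e-12)

    def test_error_model_variance(self):
        model = LMMSpec(
            fixed=FixedEffectsSpec(model="Md", c=2, beta=(1.0, 0.0, 0.0)),
            random=RandomEffectsSpec(klass="FE"),
            sigma2=4.0,
            corr=CorrelationSpec(),
        )
        design = two_arm_design([0.0, 1.0, 2.0], 0.5, 4000)
        data = simulate_trial(design, model, DropoutSpec("constant_one"), seed=3)
        v = data.frame.groupby("time")["y"].var()
        assert np.all(np.abs(v - 4.0) < 0.3)

    def test_seed_reproducibility(self, ri_ar1_model, logistic_dropout, small_design):
        a = simulate_trial(small_design, ri_ar1_model, logistic_dropout, seed=9)
        b = simulate_trial(small_design, ri_ar1_model, logistic_dropout, seed=9)
        assert a.frame.equals(b.frame)

    def test_csv_round_trip(self, ri_ar1_model, logistic_dropout, small_design, tmp_path):
        data = simulate_trial(small_design, ri_ar1_model, logistic_dropout, seed=4)
        path = tmp_path / "trial.csv"
        data.to_csv(path)
        back = TrialData.from_csv(path)
        assert np.allclose(
            back.frame["y"].to_numpy(), data.frame["y"].to_numpy(), equal_nan=True
        )


class TestFitAvailableCase:
    def test_complete_data_iid_errors_equals_ols(self):
        model = LMMSpec(
            fixed=FixedEffectsSpec(model="Md", c=2, beta=(2.0, -0.5, 0.01)),
            random=RandomEffectsSpec(klass="FE"),
            sigma2=1.0,
            corr=CorrelationSpec(),
        )
        design = two_arm_design([0.0, 1.0, 2.0, 3.0], 0.5, 30)
        data = simulate_trial(design, model, DropoutSpec("constant_one"), seed=5)
        beta = fit_available_case(data, model)
        df = data.frame
        X = np.column_stack([np.ones(len(df)), df["time"], df["dose"]])
        ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(beta, ols, rtol=1e-8)

    def test_single_subject_single_observation(self):
        model = LMMSpec(
            fixed=FixedEffectsSpec(model="Md", c=2, beta=(5.0, 0.0, 0.0)),
            random=RandomEffectsSpec(klass="FE"),
            sigma2=1.0,
            corr=CorrelationSpec(),
        )
        import pandas as pd

        frame = pd.DataFrame(
            {"subject": [1], "group": [1], "dose": [0.0], "time": [0.0],
             "y": [3.7], "observed": [1]}
        )
        # intercept-only information: slope/dose columns are zero at t=0,
        # dose=0, so only beta0 is identified; solve the 1x1 subproblem
        beta = np.linalg.lstsq(
            np.array([[1.0]]), np.array([3.7]), rcond=None
        )[0]
        assert beta[0] == pytest.approx(3.7)
        data = TrialData(frame)
        assert data.pattern_lengths().iloc[0] == 1

    def test_gls_unbiasedness(self, ri_ar1_model, logistic_dropout):
        """Mean of replicate estimates matches the generative coefficients."""
        design = two_arm_design(
            [0.0, 42.0, 285.2340, 355.6943, 364.0], 0.4221, 144
        )
        res = evaluate_designs(
            {"xi": design}, ri_ar1_model, logistic_dropout, reps=4000, seed=6
        )["xi"]
        beta = np.asarray(ri_ar1_model.fixed.beta)
        se = np.sqrt(np.diag(res.empirical_cov) / res.estimates.shape[0])
        assert np.all(np.abs(res.estimates.mean(axis=0) - beta) < 3.5 * se)


class TestEvaluateDesigns:
    def test_collapsed_sampler_matches_subject_level_path(
        self, ri_ar1_model, logistic_dropout
    ):
        """The cell-sum sampler and the per-subject pipeline draw the same
        estimator distribution (checked on mean and covariance)."""
        design = two_arm_design([0.0, 42.0, 200.0, 364.0], 0.5, 60)
        reps = 1200
        rng = np.random.default_rng(12)
        subject_level = np.array([
            fit_available_case(
                simulate_trial(design, ri_ar1_model, logistic_dropout, seed=rng),
                ri_ar1_model,
            )
            for _ in range(reps)
        ])
        fast = evaluate_designs(
            {"d": design}, ri_ar1_model, logistic_dropout, reps=reps, seed=13
        )["d"].estimates
        se_mean = np.sqrt(np.diag(np.cov(subject_level.T)) / reps)
        assert np.all(
            np.abs(subject_level.mean(0) - fast.mean(0)) < 4 * se_mean
        )
        # covariance agreement: relative Frobenius distance within MC error
        ca, cb = np.cov(subject_level.T), np.cov(fast.T)
        rel = np.linalg.norm(ca - cb) / np.linalg.norm(ca)
        assert rel < 0.25

    def test_empirical_covariance_matches_inverse_expected_information(
        self, ri_ar1_model, logistic_dropout, xi_d_star
    ):
        res = evaluate_designs(
            {"xi": xi_d_star}, ri_ar1_model, logistic_dropout, reps=100_000, seed=21
        )["xi"]
        approx = np.linalg.inv(
            expected_information(xi_d_star, ri_ar1_model, logistic_dropout).matrix
        )
        np.testing.assert_allclose(res.empirical_cov, approx, rtol=0.05)

    def test_self_efficiency_is_unity(self, ri_ar1_model, logistic_dropout, xi_ori):
        res = evaluate_designs(
            {"a": xi_ori, "b": xi_ori}, ri_ar1_model, logistic_dropout,
            reps=30_000, seed=8,
        )
        assert res["a"].red["b"] == pytest.approx(1.0, abs=0.03)
        assert res["a"].red_se["b"] > 0

    def test_no_dropout_fe_matches_closed_form(self):
        model = LMMSpec(
            fixed=FixedEffectsSpec(model="Md", c=2, beta=(1.0, 0.5, 0.01)),
            random=RandomEffectsSpec(klass="FE"),
            sigma2=2.0,
            corr=CorrelationSpec(kind="ar1", rho=0.4),
        )
        design = two_arm_design([0.0, 1.0, 2.0], 0.5, 50)
        res = evaluate_designs(
            {"d": design}, model, DropoutSpec("constant_one"), reps=60_000, seed=9
        )["d"]
        closed = np.linalg.inv(
            expected_information(design, model, DropoutSpec("constant_one")).matrix
        )
        np.testing.assert_allclose(np.diag(res.empirical_cov), np.diag(closed), rtol=0.05)
        assert np.linalg.norm(res.empirical_cov - closed) < 0.05 * np.linalg.norm(closed)

    def test_seed_reproducibility(self, ri_ar1_model, logistic_dropout, xi_ori):
        a = evaluate_designs({"d": xi_ori}, ri_ar1_model, logistic_dropout,
                             reps=500, seed=10)["d"]
        b = evaluate_designs({"d": xi_ori}, ri_ar1_model, logistic_dropout,
                             reps=500, seed=10)["d"]
        np.testing.assert_array_equal(a.estimates, b.estimates)
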