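import numpy as np
import pytest

import ttnorm as tn
from ttnorm.harmonize import make_dataset
from ttnorm.validation import DECADE_BANDS, degrees_for_params


class TestDegreeAllocation:
    @pytest.mark.parametrize(
        "n_params,expected",
        [(3, (1, 1)), (4, (2, 1)), (7, (3, 3)), (8, (4, 3)), (11, (5, 5))],
    )
    def test_allocation(self, n_params, expected):
        assert degrees_for_params(n_params) == expected

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            degrees_for_params(1)


class TestKFold:
    def test_five_folds_of_two(self):
        data = make_dataset(np.arange(10.0), np.arange(10.0) + 1)
        folds = tn.kfold_split(data, k=5, seed=0)
        assert [len(f) for f in folds] == [2] * 5

    def test_partition_property(self):
        data = make_dataset(np.arange(23.0) + 3, np.ones(23))
        folds = tn.kfold_split(data, k=5, seed=1)
        ages = np.concatenate([f["age_years"].to_numpy() for f in folds])
        assert sorted(ages) == sorted(data["age_years"])
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_same_seed_same_split(self):
        data = make_dataset(np.arange(20.0), np.ones(20))
        a = tn.kfold_split(data, k=4, seed=7)
        b = tn.kfold_split(data, k=4, seed=7)
        for fa, fb in zip(a, b):
            assert (fa["age_years"].to_numpy() == fb["age_years"].to_numpy()).all()

    def test_small_k_rejected(self):
        data = make_dataset(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            tn.kfold_split(data, k=1)


@pytest.fixture(scope="module")
def simple_truth_data():
    # 3-parameter rational truth, zero noise
    truth_model = tn.RationalPolynomialModel((0.1, 0.02), (0.01,))
    rng = np.random.default_rng(0)
    ages = rng.uniform(3, 88, 600)
    return make_dataset(ages, truth_model.predict_tt(ages)), truth_model


class TestCrossValidate:
    def test_zero_noise_nested_family(self, simple_truth_data):
        data, _ = simple_truth_data
        results = tn.cross_validate(data, param_counts=(3, 4, 5), k=5, seed=0)
        for r in results:
            assert r.test_mse == pytest.approx(0.0, abs=1e-12)

    def test_training_error_monotone_in_complexity(self, uniform_noisy):
        results = tn.cross_validate(uniform_noisy, param_counts=(3, 7, 11), k=5, seed=2)
        by_p = {r.n_params: r.train_mse for r in results}
        assert by_p[11] <= by_p[3] + 1e-12
        assert by_p[7] <= by_p[3] + 1e-12

    def test_selection_consistency_over_replicates(self):
        """The modal selected complexity over repeated draws from the
        7-parameter truth is 7 (pooled study design, sigma = 0.15)."""
        selections = []
        for seed in range(10):
            truth = tn.GroundTruth(sd_profile=0.15, seed=seed)
            pooled = tn.harmonize(
                tn.generate_dataset(tn.default_study_profiles(), truth)
            )
            cv = tn.cross_validate(pooled, seed=seed)
            selections.append(tn.select_optimal(cv))
        values, counts = np.unique(selections, return_counts=True)
        assert values[np.argmax(counts)] == 7

    def test_test_mse_near_irreducible_error(self, pooled_seed0):
        cv = tn.cross_validate(pooled_seed0, param_counts=(7,), k=5, seed=0)
        assert cv[0].test_mse == pytest.approx(0.15**2, rel=0.05)


class TestSelectOptimal:
    def test_single_candidate(self):
        assert tn.select_optimal([tn.CVResult(5, 0.1, 0.2)]) == 5

    def test_tie_breaks_to_fewer_params(self):
        cv = [tn.CVResult(9, 0.1, 0.2), tn.CVResult(7, 0.1, 0.2)]
        assert tn.select_optimal(cv) == 7

    def test_minimal_test_mse_wins(self):
        cv = [tn.CVResult(3, 0.3, 0.3), tn.CVResult(5, 0.1, 0.15)]
        assert tn.select_optimal(cv) == 5

    def test_incomplete_rows_ignored_when_complete_exist(self):
        cv = [
            tn.CVResult(7, 0.1, 0.2),
            tn.CVResult(9, 0.1, 0.1, failures=["fold 2: pole"]),
        ]
        assert tn.select_optimal(cv) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tn.select_optimal([])


class TestResidualAnalysis:
    def test_gaussian_proportions_at_large_n(self, pub_model):
        rng = np.random.default_rng(99)
        n = 1_000_000
        # adult ages keep the zero-clip from truncating the Gaussian tail
        ages = rng.uniform(20, 80, n)
        tt = np.clip(
            tn.inverse_log_adjust(rng.normal(pub_model.evaluate(ages), 0.15)), 0, None
        )
        summary = tn.residual_analysis(pub_model, make_dataset(ages, tt))
        # within 3 binomial SDs of the Gaussian ideal
        for prop, ideal in [
            (summary.within_1sd, 0.6827),
            (summary.within_2sd, 0.9545),
            (summary.within_3sd, 0.9973),
        ]:
            se = np.sqrt(ideal * (1 - ideal) / n)
            assert abs(prop - ideal) < 3 * se + 1e-3
        assert summary.gaussian_fit_r2 >= 0.99
        assert not summary.degenerate

    def test_proportions_weakly_increasing(self, pooled_seed0, pub_model):
        s = tn.residual_analysis(pub_model, pooled_seed0)
        assert 0 <= s.within_1sd <= s.within_2sd <= s.within_3sd <= 1

    def test_degenerate_zero_residuals(self, pub_model):
        ages = np.linspace(3, 88, 100)
        data = make_dataset(ages, pub_model.predict_tt(ages))
        s = tn.residual_analysis(pub_model, data)
        assert s.degenerate
        assert (s.within_1sd, s.within_2sd, s.within_3sd) == (1.0, 1.0, 1.0)

    def test_empty_rejected(self, pub_model):
        with pytest.raises(ValueError):
            tn.residual_analysis(pub_model, make_dataset([], []))


class TestResidualsByDecade:
    def test_band_layout(self):
        assert DECADE_BANDS[0] == (3, 11)
        assert DECADE_BANDS[-1] == (80, 89)

    def test_uniform_ages_fill_every_band(self, pub_model):
        rng = np.random.default_rng(5)
        ages = rng.uniform(3, 89, 5000)
        tt = np.clip(
            tn.inverse_log_adjust(rng.normal(pub_model.evaluate(ages), 0.1)), 0, None
        )
        bands = tn.residuals_by_decade(pub_model, make_dataset(ages, tt))
        assert all(s is not None for _, s in bands)

    def test_empty_band_reported_not_failed(self, pub_model):
        data = make_dataset([25.0, 26.0, 27.0], [13.0, 14.0, 12.0])
        bands = dict(tn.residuals_by_decade(pub_model, data))
        assert bands[(3, 11)] is None
        assert bands[(20, 29)] is not None

    def test_homoscedastic_bands_share_sd(self, pub_model):
        # ages >= 12 keep the zero-clip from truncating residuals at the
        # childhood bands
        rng = np.random.default_rng(17)
        ages = rng.uniform(12, 89, 60000)
        tt = np.clip(
            tn.inverse_log_adjust(rng.normal(pub_model.evaluate(ages), 0.15)), 0, None
        )
        bands = tn.residuals_by_decade(pub_model, make_dataset(ages, tt))
        sds = [s.sd for _, s in bands if s is not None]
        assert len(sds) >= 8
        assert max(sds) / min(sds) < 1.1


class TestLoess:
    def test_noiseless_linear_data(self):
        ages = np.linspace(3, 88, 400)
        tt = tn.inverse_log_adjust(0.2 + 0.01 * ages)  # linear on the log scale
        assert tn.loess_r2(make_dataset(ages, tt), span=0.3, degree=1) > 0.999

    def test_r2_bounded_by_one(self, uniform_noisy):
        for span in (0.2, 0.75):
            assert tn.loess_r2(uniform_noisy, span=span, degree=2) <= 1.0

    @pytest.mark.parametrize("span", [0.0, -0.1, 1.5])
    def test_invalid_span_rejected(self, uniform_noisy, span):
        with pytest.raises(ValueError):
            tn.loess_r2(uniform_noisy, span=span)

    def test_invalid_degree_rejected(self, uniform_noisy):
        with pytest.raises(ValueError):
            tn.loess_r2(uniform_noisy, degree=3)

    def test_agrees_with_statsmodels_lowess(self, uniform_noisy):
        """Independent cross-check of the degree-1 smoother against the
        statsmodels LOWESS implementation."""
        from statsmodels.nonparametric.smoothers_lowess import lowess
        from ttnorm.harmonize import log_adjust

        obs = uniform_noisy
        x = obs["age_years"].to_numpy()
        y = log_adjust(obs["tt_value"].to_numpy())
        sm_fit = lowess(y, x, frac=0.5, return_sorted=True)
        pred = np.interp(x, sm_fit[:, 0], sm_fit[:, 1])
        sm_r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        # the two smoothers differ in weighting details (tricube window
        # vs robustified lowess), so agreement is approximate
        ours = tn.loess_r2(obs, span=0.5, degree=1)
        assert ours == pytest.approx(sm_r2, abs=0.05)

    def test_global_fit_beats_best_loess(self, pooled_seed0):
        summary = tn.fit(pooled_seed0, 3, 3)
        best, _ = tn.best_loess_r2(pooled_seed0)
        assert summary.r2 >= best
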