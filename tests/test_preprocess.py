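"""Scaling, trend features and the three-stage selection."""

import numpy as np
import pytest

from yieldcast import (
    FeatureInfo,
    PanelMinMaxScaler,
    SyntheticConfig,
    TrendFeaturizer,
    correlation_filter,
    expert_filter,
    generate_panel,
    permutation_select,
    split_by_year,
)
from conftest import make_tiny_panel


class TestMinMax:
    def test_endpoints_and_midpoint(self):
        p = make_tiny_panel({"f": np.array([2.0, 4.0, 6.0])},
                            {"f": FeatureInfo("soil")})
        scaled = PanelMinMaxScaler().fit(p).transform(p)
        assert np.allclose(scaled.frame["f"], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        p = make_tiny_panel({"f": np.array([5.0, 5.0, 5.0])},
                            {"f": FeatureInfo("soil")})
        scaled = PanelMinMaxScaler().fit(p).transform(p)
        assert np.allclose(scaled.frame["f"], 0.0)

    def test_test_values_may_leave_unit_interval(self):
        train = make_tiny_panel({"f": np.array([2.0, 6.0])}, {"f": FeatureInfo("soil")})
        test = make_tiny_panel({"f": np.array([8.0, 0.0])}, {"f": FeatureInfo("soil")})
        scaler = PanelMinMaxScaler().fit(train)
        out = scaler.transform(test)
        assert np.allclose(out.frame["f"], [1.5, -0.5])

    def test_train_transform_lies_in_unit_interval(self, small_panel):
        train, _ = split_by_year(small_panel, 2016)
        scaled = PanelMinMaxScaler().fit(train).transform(train)
        X = scaled.X.to_numpy()
        assert X.min() >= -1e-12 and X.max() <= 1 + 1e-12


class TestTrendFeatures:
    def test_perfect_linear_fit_recovers_slope(self):
        years = np.arange(2000, 2010)
        p = make_tiny_panel({}, {}, response=100.0 + 50.0 * (years - 2000), years=years)
        model = TrendFeaturizer().fit(p)
        b0, b1 = model.coef_["L0"]
        assert b1 == pytest.approx(50.0, abs=1e-8)
        assert b0 == pytest.approx(100.0 - 50.0 * 2000, rel=1e-12)

    def test_mean_relative_increment(self):
        p = make_tiny_panel({}, {}, response=np.array([100.0, 110.0]),
                            years=np.array([2000, 2001]))
        model = TrendFeaturizer().fit(p)
        assert model.growth_["S0"] == pytest.approx(0.10)
        assert model.baseline_["S0"] == pytest.approx(110.0)

    def test_compound_extrapolation_one_year_out(self):
        # baseline state mean 9421 with mean increment 0.02 -> 9609.42 next year
        prev = 9421.0 / 1.02
        p = make_tiny_panel({}, {}, response=np.array([prev, 9421.0]),
                            years=np.array([2014, 2015]))
        model = TrendFeaturizer().fit(p)
        test = make_tiny_panel({}, {}, response=np.array([0.0]),
                               years=np.array([2016]))
        out = model.transform(test)
        assert out.frame["yield_avg"].iloc[0] == pytest.approx(9421.0 * 1.02)

    def test_zero_growth_extrapolation_is_fixed_point(self):
        p = make_tiny_panel({}, {}, response=np.array([9000.0, 9000.0, 9000.0]),
                            years=np.array([2013, 2014, 2015]))
        model = TrendFeaturizer().fit(p)
        test = make_tiny_panel({}, {}, response=np.array([0.0]), years=np.array([2018]))
        out = model.transform(test)
        assert out.frame["yield_avg"].iloc[0] == pytest.approx(9000.0)

    def test_training_rows_use_state_year_mean(self, small_panel):
        train, _ = split_by_year(small_panel, 2016)
        model = TrendFeaturizer().fit(train)
        out = model.transform(train)
        means = train.frame.groupby(["state", "year"])["response"].mean()
        for _, row in out.frame.sample(20, random_state=0).iterrows():
            assert row["yield_avg"] == pytest.approx(means[(row["state"], row["year"])])

    def test_noise_free_trend_equals_truth(self, noiseless_panel):
        train, test = split_by_year(noiseless_panel, 2016)
        model = TrendFeaturizer().fit(train)
        for part in (model.transform(train), model.transform(test)):
            err = np.abs(part.frame["yield_trend"] - part.frame["response"])
            assert err.max() < 1e-6

    def test_single_training_year_is_error(self):
        p = make_tiny_panel({}, {}, response=np.array([1.0]), years=np.array([2000]))
        with pytest.raises(ValueError, match="single training year"):
            TrendFeaturizer().fit(p)

    def test_unseen_location_is_error(self, small_panel):
        train, _ = split_by_year(small_panel, 2016)
        model = TrendFeaturizer().fit(train)
        alien = make_tiny_panel({f: np.zeros(2) for f in small_panel.features},
                                dict(small_panel.feature_meta),
                                response=np.zeros(2), years=np.array([2016, 2017]),
                                location="L9999")
        with pytest.raises(ValueError, match="never seen"):
            model.transform(alien)

    def test_trend_columns_are_tagged_trend(self, small_panel):
        train, _ = split_by_year(small_panel, 2016)
        out = TrendFeaturizer().fit(train).transform(train)
        assert out.feature_meta["yield_trend"].group == "trend"
        assert out.feature_meta["yield_avg"].group == "trend"


@pytest.fixture(scope="module")
def full_year_panel():
    return generate_panel(
        SyntheticConfig(n_locations=4, n_weather_vars=1, weather_weeks=(1, 52),
                        n_soil_features=3, planting_weeks=(10, 25), seed=2)
    )


class TestExpertFilter:

    def test_weather_outside_season_removed(self, full_year_panel):
        out, report = expert_filter(full_year_panel, growing_season=(14, 44),
                                    planting_window_start=14)
        weeks = {m.week for m in out.feature_meta.values() if m.group == "weather"}
        assert weeks == set(range(14, 45))
        # 21 weekly blocks of one weather variable removed (weeks 1-13, 45-52)
        removed_weather = [f for f in report.stages[0].removed
                           if full_year_panel.feature_meta[f].group == "weather"]
        assert len(removed_weather) == 21

    def test_pre_window_planting_progress_removed(self, full_year_panel):
        out, report = expert_filter(full_year_panel, growing_season=(14, 44),
                                    planting_window_start=14)
        prog_weeks = {
            m.week for f, m in out.feature_meta.items()
            if m.group == "management" and m.week is not None
        }
        assert prog_weeks == set(range(14, 26))

    def test_soil_untouched(self, full_year_panel):
        out, _ = expert_filter(full_year_panel, (14, 44), 14)
        assert out.features_in_group("soil") == full_year_panel.features_in_group("soil")


@pytest.fixture(scope="module")
def causal_panel():
    # response driven by a single weather feature, zero noise
    cfg = SyntheticConfig(
        n_locations=8, n_weather_vars=1, weather_weeks=(14, 19),
        n_soil_features=2, planting_weeks=(14, 15), noise_sd=0.0,
        trend_slope_range=(0.0, 0.0),
        effect_spec={"tmin_w16": 500.0}, seed=9,
    )
    return generate_panel(cfg)


class TestPermutationSelect:

    def test_sole_causal_feature_ranks_first(self, causal_panel):
        out, report = permutation_select(causal_panel, n_keep=1, n_repeats=3, seed=0)
        scores = report.stages[0].details["scores"]
        assert max(scores, key=scores.get) == "tmin_w16"
        assert "tmin_w16" in out.features

    def test_pure_noise_feature_scores_near_zero(self, causal_panel):
        _, report = permutation_select(causal_panel, n_keep=3, n_repeats=5, seed=0)
        scores = report.stages[0].details["scores"]
        assert abs(scores["soil_00"]) < 0.05 * scores["tmin_w16"]

    def test_keep_all_is_identity(self, causal_panel):
        out, _ = permutation_select(causal_panel, n_keep=len(causal_panel.features),
                                    n_repeats=2, seed=0)
        assert out.features == causal_panel.features

    def test_n_keep_too_large_is_error(self, causal_panel):
        with pytest.raises(ValueError):
            permutation_select(causal_panel, n_keep=len(causal_panel.features) + 1)

    def test_trend_features_do_not_consume_slots(self, small_panel):
        train, _ = split_by_year(small_panel, 2016)
        from yieldcast import TrendFeaturizer

        train = TrendFeaturizer().fit(train).transform(train)
        out, _ = permutation_select(train, n_keep=3, n_repeats=2, seed=0)
        assert {"yield_trend", "yield_avg"} <= set(out.features)
        assert len(out.features) == 5  # 3 kept + 2 forced trend columns


class TestCorrelationFilter:
    def test_duplicate_column_dropped(self):
        x = np.arange(10.0)
        p = make_tiny_panel({"a": x, "b": x.copy(), "c": np.cos(x)},
                            {"a": FeatureInfo("soil"), "b": FeatureInfo("soil"),
                             "c": FeatureInfo("soil")})
        out, report = correlation_filter(p, threshold=0.9)
        assert out.features == ["a", "c"]
        assert report.stages[0].details["pairs"][0]["kept"] == "a"

    def test_independent_noise_columns_both_retained(self, rng):
        p = make_tiny_panel(
            {"a": rng.normal(size=1000), "b": rng.normal(size=1000)},
            {"a": FeatureInfo("soil"), "b": FeatureInfo("soil")},
        )
        out, _ = correlation_filter(p, threshold=0.9)
        assert out.features == ["a", "b"]

    def test_threshold_one_without_duplicates_is_identity(self, small_panel):
        out, _ = correlation_filter(small_panel, threshold=1.0)
        assert out.features == small_panel.features

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_bad_threshold_is_error(self, small_panel, bad):
        with pytest.raises(ValueError):
            correlation_filter(small_panel, threshold=bad)

    def test_retained_set_verified_by_bruteforce_oracle(self):
        panel = generate_panel(
            SyntheticConfig(n_locations=10, n_weather_vars=2, weather_weeks=(14, 24),
                            n_soil_features=4, n_redundant_pairs=4, seed=13)
        )
        out, _ = correlation_filter(panel, threshold=0.9)
        X = out.X.to_numpy()
        corr = np.corrcoef(X, rowvar=False)
        sd = X.std(axis=0)
        offdiag = np.abs(corr[np.triu_indices_from(corr, k=1)])
        nonconst = np.outer(sd > 0, sd > 0)[np.triu_indices_from(corr, k=1)]
        assert (offdiag[nonconst] <= 0.9 + 1e-12).all()

    def test_constant_feature_retained_and_flagged(self):
        p = make_tiny_panel({"a": np.arange(5.0), "k": np.ones(5)},
                            {"a": FeatureInfo("soil"), "k": FeatureInfo("soil")})
        out, report = correlation_filter(p, threshold=0.9)
        assert "k" in out.features
        assert report.stages[0].details["constant_features"] == ["k"]


def test_selection_stages_nest(small_panel):
    """final set <= stage2 <= stage1 <= original, as sets of features."""
    from yieldcast import TrendFeaturizer

    train, _ = split_by_year(small_panel, 2016)
    train = TrendFeaturizer().fit(train).transform(train)
    s1, _ = expert_filter(train, growing_season=(15, 19), planting_window_start=15)
    s2, _ = permutation_select(s1, n_keep=4, n_repeats=2, seed=0)
    s3, _ = correlation_filter(s2, threshold=0.9)
    f0, f1, f2, f3 = map(lambda p: set(p.features), (train, s1, s2, s3))
    assert f3 <= f2 <= f1 <= f0
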