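import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmbm.covariates import (
    AmbiguousDensityError,
    CovariateError,
    DietarySourceEstimate,
    bioclim_annual_mean_temp,
    bioclim_annual_precip,
    classify_mammal_density,
    gendered_division,
    normalize_diet,
    prop_non_foraged,
    select_climate_window,
    zscore,
)


def est(source, intake=None, lo=None, hi=None, score=3.0):
    return DietarySourceEstimate(
        source=source, division_score=score, mean_pct=intake, min_pct=lo, max_pct=hi
    )


class TestDiet:
    def test_min_max_collapse_to_midpoint(self):
        assert est("honey", lo=10, hi=20).intake == pytest.approx(15.0)

    def test_equal_intakes_normalize_to_half(self):
        props = normalize_diet([est("wild_plants", 50), est("domesticated", 50)])
        assert props == {"wild_plants": 0.5, "domesticated": 0.5}

    def test_hand_normalization(self):
        props = normalize_diet(
            [est("wild_plants", 30), est("fish_seafood", 30), est("domesticated", 60)]
        )
        assert props["wild_plants"] == pytest.approx(0.25)
        assert props["fish_seafood"] == pytest.approx(0.25)
        assert props["domesticated"] == pytest.approx(0.5)

    def test_all_zero_and_negative_rejected(self):
        with pytest.raises(CovariateError):
            normalize_diet([est("honey", 0.0)])
        with pytest.raises(CovariateError):
            normalize_diet([est("honey", -5.0)])

    def test_mean_and_range_are_mutually_exclusive(self):
        with pytest.raises(CovariateError):
            DietarySourceEstimate("honey", 3.0, mean_pct=10, min_pct=5, max_pct=15)

    @settings(max_examples=30, deadline=None)
    @given(
        raw=st.lists(st.floats(0.01, 100), min_size=1, max_size=8),
        scale=st.floats(0.01, 50),
    )
    def test_normalization_sums_to_one_and_is_scale_invariant(self, raw, scale):
        base = normalize_diet([est(f"s{i}", v) for i, v in enumerate(raw)])
        scaled = normalize_diet([est(f"s{i}", v * scale) for i, v in enumerate(raw)])
        assert sum(base.values()) == pytest.approx(1.0, abs=1e-12)
        for s in base:
            assert scaled[s] == pytest.approx(base[s], rel=1e-9)

    def test_prop_non_foraged(self):
        assert prop_non_foraged({"domesticated": 0.3, "traded_purchased": 0.2}) == 0.5
        assert prop_non_foraged({"wild_plants": 1.0}) == 0.0
        assert prop_non_foraged({"domesticated": 1.0}) == 1.0


class TestGenderedDivision:
    def test_endpoints(self):
        assert gendered_division({"a": 1.0}, {"a": 5.0}) == pytest.approx(2.0)
        assert gendered_division({"a": 1.0}, {"a": 1.0}) == pytest.approx(-2.0)

    def test_equal_contribution_is_zero(self):
        assert gendered_division(
            {"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 5.0}
        ) == pytest.approx(0.0)

    def test_hand_computation(self):
        assert gendered_division(
            {"a": 0.75, "b": 0.25}, {"a": 5.0, "b": 1.0}
        ) == pytest.approx(1.0)

    def test_score_outside_scale_rejected(self):
        with pytest.raises(CovariateError):
            gendered_division({"a": 1.0}, {"a": 6.0})

    @settings(max_examples=40, deadline=None)
    @given(
        weights=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
        scores=st.lists(st.floats(1, 5), min_size=6, max_size=6),
        bump=st.floats(0, 1),
        idx=st.integers(0, 5),
    )
    def test_monotone_in_scores_and_bounded(self, weights, scores, bump, idx):
        weights = weights + [0.01] * (6 - len(weights)) if len(weights) < 6 else weights[:6]
        total = sum(weights)
        props = {f"s{i}": w / total for i, w in enumerate(weights)}
        d0 = {f"s{i}": s for i, s in enumerate(scores)}
        v0 = gendered_division(props, d0)
        d1 = dict(d0)
        d1[f"s{idx}"] = min(5.0, d0[f"s{idx}"] + bump)
        v1 = gendered_division(props, d1)
        assert v1 >= v0 - 1e-12
        assert -2.0 - 1e-9 <= v0 <= 2.0 + 1e-9


class TestMammalDensity:
    def test_low(self):
        assert classify_mammal_density([0.2, 0.3]) == ("low", pytest.approx(0.5))

    def test_high(self):
        assert classify_mammal_density([12.0, 4.0]) == ("high", pytest.approx(16.0))

    def test_middle_band_requires_manual_class(self):
        with pytest.raises(AmbiguousDensityError):
            classify_mammal_density([3.0])

    def test_empty_list_is_low_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            cls, total = classify_mammal_density([])
        assert (cls, total) == ("low", 0.0)
        assert any("empty" in r.message for r in caplog.records)

    def test_negative_density_rejected(self):
        with pytest.raises(CovariateError):
            classify_mammal_density([-1.0])


def _series(years, tmax, tmin, precip):
    rows = []
    for y in years:
        for m in range(1, 13):
            rows.append((y, m, tmax(y, m), tmin(y, m), precip(y, m)))
    return pd.DataFrame(rows, columns=["year", "month", "tmax_c", "tmin_c", "precip_mm"])


class TestBioclim:
    def test_constant_temperature(self):
        s = _series(range(1990, 1993), lambda y, m: 10, lambda y, m: 10, lambda y, m: 0)
        assert bioclim_annual_mean_temp(s) == pytest.approx(10.0)

    def test_midpoint_of_tmax_tmin(self):
        s = _series(range(1990, 1993), lambda y, m: 20, lambda y, m: 10, lambda y, m: 0)
        assert bioclim_annual_mean_temp(s) == pytest.approx(15.0)

    def test_constant_precip_sums_over_months(self):
        s = _series(range(1990, 1993), lambda y, m: 0, lambda y, m: 0, lambda y, m: 100)
        assert bioclim_annual_precip(s) == pytest.approx(1200.0)
        z = _series(range(1990, 1993), lambda y, m: 0, lambda y, m: 0, lambda y, m: 0)
        assert bioclim_annual_precip(z) == pytest.approx(0.0)

    def test_seasonal_toy_series_matches_hand_average(self):
        # tmax = m + y-offset, tmin = m - 2; hand-computed climatology
        years = [2000, 2001]
        s = _series(
            years,
            lambda y, m: m + (1 if y == 2001 else 0),
            lambda y, m: m - 2.0,
            lambda y, m: 10 * m + (5 if y == 2001 else 0),
        )
        # climatological tmax_m = m + 0.5, tmin_m = m - 2 -> mid = m - 0.75
        expected_t = np.mean([m - 0.75 for m in range(1, 13)])
        assert bioclim_annual_mean_temp(s) == pytest.approx(expected_t)
        expected_p = sum(10 * m + 2.5 for m in range(1, 13))
        assert bioclim_annual_precip(s) == pytest.approx(expected_p)

    def test_missing_months_error_lists_gaps(self):
        s = _series(range(1990, 1992), lambda y, m: 1, lambda y, m: 0, lambda y, m: 1)
        s = s[~((s.year == 1991) & (s.month == 7))]
        with pytest.raises(CovariateError, match="7"):
            bioclim_annual_mean_temp(s)

    def test_linearity(self):
        s = _series(range(1990, 1993), lambda y, m: m, lambda y, m: 0.0,
                    lambda y, m: 7.0 * m)
        p = bioclim_annual_precip(s)
        s2 = s.assign(precip_mm=2 * s.precip_mm)
        assert bioclim_annual_precip(s2) == pytest.approx(2 * p)
        # affine temperature transform shifts BIO1 accordingly
        t = bioclim_annual_mean_temp(s)
        s3 = s.assign(tmax_c=2 * s.tmax_c + 1, tmin_c=2 * s.tmin_c + 1)
        assert bioclim_annual_mean_temp(s3) == pytest.approx(2 * t + 1)

    def test_window_selection(self):
        s = _series(range(1980, 2011), lambda y, m: y - 1980, lambda y, m: y - 1980,
                    lambda y, m: 0)
        w = select_climate_window(s, end_year=2010, window_years=30)
        assert w["year"].min() == 1981 and w["year"].max() == 2010


class TestZscore:
    def test_sample_sd_convention(self):
        assert np.allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(CovariateError):
            zscore(np.array([2.0, 2.0, 2.0]))

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        z = zscore(x)
        assert np.allclose(zscore(z), z, atol=1e-12)

    def test_output_standardized(self):
        rng = np.random.default_rng(1)
        z = zscore(rng.normal(3.0, 7.0, size=12))
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10


class TestProfileAssembly:
    def _inputs(self):
        diet = pd.DataFrame(
            [
                ("s1", "wild_plants", np.nan, np.nan, 40.0, 2.0),
                ("s1", "large_game", 10.0, 30.0, np.nan, 5.0),
                ("s1", "domesticated", np.nan, np.nan, 30.0, 3.0),
                ("s1", "traded_purchased", np.nan, np.nan, 10.0, 3.0),
                ("s2", "wild_plants", np.nan, np.nan, 90.0, 1.0),
                ("s2", "domesticated", np.nan, np.nan, 10.0, 5.0),
            ],
            columns=["society_id", "source", "min_pct", "max_pct", "mean_pct",
                     "division_score"],
        )
        mammals = pd.DataFrame(
            [("s1", "elephant", 11.0), ("s1", "lion", 1.5), ("s2", "jaguar", 0.4)],
            columns=["society_id", "species", "density_n_per_km2"],
        )
        static = pd.DataFrame(
            [("s1", 900.0, 1), ("s2", 1500.0, 2)],
            columns=["society_id", "npp_gc_m2_yr", "water_rating"],
        )
        rows = []
        for sid, t0 in (("s1", 20.0), ("s2", 25.0)):
            for y in (2009, 2010):
                for m in range(1, 13):
                    rows.append((sid, y, m, t0 + 5, t0 - 5, 100.0))
        climate = pd.DataFrame(
            rows, columns=["society_id", "year", "month", "tmax_c", "tmin_c",
                           "precip_mm"],
        )
        return diet, mammals, static, climate

    def test_assembles_all_fields_with_zscores(self):
        from mmbm.covariates import build_society_profiles

        diet, mammals, static, climate = self._inputs()
        out = build_society_profiles(diet, mammals, static, climate).set_index(
            "society_id"
        )
        # s1 diet: 40 + midpoint(10,30)=20 + 30 + 10 = 100
        assert out.loc["s1", "prop_non_foraged"] == pytest.approx(0.4)
        assert out.loc["s2", "prop_non_foraged"] == pytest.approx(0.1)
        # s1 division: .4*2 + .2*5 + .3*3 + .1*3 - 3 = 0.0
        assert out.loc["s1", "gendered_division"] == pytest.approx(0.0)
        assert out.loc["s2", "gendered_division"] == pytest.approx(-1.6)
        assert out.loc["s1", "mammal_density_class"] == "high"
        assert out.loc["s2", "mammal_density_class"] == "low"
        assert out.loc["s1", "annual_mean_temp"] == pytest.approx(20.0)
        assert out.loc["s2", "annual_precip"] == pytest.approx(1200.0)
        for col in ("prop_non_foraged_z", "npp_z", "annual_mean_temp_z",
                    "annual_precip_z"):
            assert abs(out[col].mean()) < 1e-10

    def test_middle_band_density_needs_manual_class(self):
        from mmbm.covariates import build_society_profiles

        diet, mammals, static, climate = self._inputs()
        mammals.loc[0, "density_n_per_km2"] = 2.0  # s1 total now 3.5
        with pytest.raises(AmbiguousDensityError):
            build_society_profiles(diet, mammals, static, climate)
        out = build_society_profiles(
            diet, mammals, static, climate, manual_mammal_class={"s1": "high"}
        )
        assert out.set_index("society_id").loc["s1", "mammal_density_class"] == "high"

    def test_round_trip_through_csv(self, tmp_path):
        from mmbm.covariates import build_society_profiles, load_society_profiles

        diet, mammals, static, climate = self._inputs()
        out = build_society_profiles(diet, mammals, static, climate)
        path = tmp_path / "society_profiles.csv"
        out.to_csv(path, index=False)
        back = load_society_profiles(path)
        assert np.allclose(
            back["prop_non_foraged_z"], out["prop_non_foraged_z"], atol=1e-12
        )
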