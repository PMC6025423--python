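"""Descriptive summaries, accumulation ratios, EF/CF indices and the
contamination category scale."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mossmetal.indices import (
    CATEGORY_LABELS,
    accumulation_ratios,
    cf_site_summary,
    classify_contamination,
    contamination_factor,
    enrichment_factor,
    ratio_extremes,
    summarize,
)
from mossmetal.reference import CF_SURVEY, MEAN_CONCENTRATIONS, cf_survey_index
from mossmetal.synth import make_fixture

from .conftest import mktable


class TestSummarize:
    def test_constant_values(self):
        t = mktable([("S1", "moss", "", r, "Cu", 5.0) for r in (1, 2, 3)])
        s = summarize(t, "moss").iloc[0]
        assert (s["minimum"], s["maximum"], s["mean"], s["sd"]) == (5, 5, 5, 0)

    def test_sample_sd_uses_n_minus_1(self):
        t = mktable([("S1", "moss", "", r, "Cu", v) for r, v in [(1, 1.0), (2, 2.0), (3, 3.0)]])
        s = summarize(t, "moss").iloc[0]
        assert (s["minimum"], s["maximum"], s["mean"]) == (1, 3, 2)
        assert s["sd"] == pytest.approx(1.0)

    def test_medium_absent_raises(self):
        t = mktable([("S1", "moss", "", 1, "Cu", 5.0)])
        with pytest.raises(KeyError):
            summarize(t, "soil")

    def test_lognormal_mean_matches_closed_form(self):
        # draws 10**N(mu, sigma): analytic mean exp(mu ln10 + (sigma ln10)^2 / 2)
        mu, sigma, n = 0.5, 0.3, 500
        rng = np.random.default_rng(42)
        vals = 10.0 ** rng.normal(mu, sigma, n)
        t = mktable([("S1", "moss", "", i + 1, "Cu", v) for i, v in enumerate(vals)])
        s = summarize(t, "moss").iloc[0]
        analytic = math.exp(mu * math.log(10) + (sigma * math.log(10)) ** 2 / 2)
        se = s["sd"] / math.sqrt(n)
        assert abs(s["mean"] - analytic) < 3 * se


class TestAccumulationRatios:
    def test_identical_media_give_unit_ratio(self):
        rows = [("S%d" % i, m, "", 1, "Cu", 2.0 * i) for i in (1, 2, 3) for m in ("moss", "leaf_a")]
        out = accumulation_ratios(mktable(rows), "moss", "leaf_a").iloc[0]
        assert out["mean_ratio"] == 1 and out["sd_ratio"] == 0 and out["n_sites"] == 3

    def test_two_site_hand_computation(self):
        rows = [
            ("S1", "moss", "", 1, "Cu", 4.0), ("S1", "leaf_a", "", 1, "Cu", 2.0),
            ("S2", "moss", "", 1, "Cu", 8.0), ("S2", "leaf_a", "", 1, "Cu", 2.0),
        ]
        out = accumulation_ratios(mktable(rows), "moss", "leaf_a").iloc[0]
        assert out["mean_ratio"] == pytest.approx(3.0)
        assert out["sd_ratio"] == pytest.approx(math.sqrt(2))

    def test_mean_of_ratios_not_ratio_of_means(self):
        # with heterogeneous sites the two conventions must diverge; the
        # published survey's ratio table (Ag 19.8) cannot be reproduced from
        # the ratio of published means (0.127/0.008 ≈ 15.9)
        ratio_of_means = MEAN_CONCENTRATIONS.loc["Ag", "moss"] / MEAN_CONCENTRATIONS.loc["Ag", "leaf_a"]
        assert abs(ratio_of_means - 19.8) > 1
        rows = [
            ("S1", "moss", "", 1, "Ag", 10.0), ("S1", "leaf_a", "", 1, "Ag", 1.0),
            ("S2", "moss", "", 1, "Ag", 10.0), ("S2", "leaf_a", "", 1, "Ag", 10.0),
        ]
        out = accumulation_ratios(mktable(rows), "moss", "leaf_a").iloc[0]
        assert out["mean_ratio"] == pytest.approx(5.5)  # (10 + 1) / 2, not 20/11

    def test_no_shared_site_raises(self):
        rows = [("S1", "moss", "", 1, "Cu", 1.0), ("S2", "leaf_a", "", 1, "Cu", 1.0)]
        with pytest.raises(KeyError):
            accumulation_ratios(mktable(rows), "moss", "leaf_a")

    def test_noise_free_generator_recovers_multipliers_exactly(self, default_profile):
        from mossmetal.synth import generate_survey

        design, model = default_profile
        table = generate_survey(design, model.noise_free(), seed=0)
        out = accumulation_ratios(table, "moss", "leaf_a")
        for _, row in out.iterrows():
            assert row["mean_ratio"] == pytest.approx(model.moss_multiplier[row["element"]])
            assert row["sd_ratio"] == pytest.approx(0.0, abs=1e-9)


class TestEnrichmentFactor:
    def test_hand_computation(self):
        rows = [
            ("S1", "moss", "", 1, "Cu", 2.0), ("S1", "moss", "", 1, "Al", 50.0),
            ("S1", "soil", "", 1, "Cu", 8.0), ("S1", "soil", "", 1, "Al", 400.0),
        ]
        ef = enrichment_factor(mktable(rows), "moss")
        assert ef.df["value"].iloc[0] == pytest.approx(2.0)
        assert list(ef.df["element"]) == ["Cu"]  # reference excluded

    def test_plant_equal_soil_gives_unit_ef(self, lownoise):
        soil = lownoise.df[lownoise.df["medium"] == "soil"]
        mirrored = pd.concat([soil, soil.assign(medium="moss")])
        ef = enrichment_factor(mktable(mirrored.values.tolist()), "moss")
        assert np.allclose(ef.df["value"], 1.0)

    def test_homogeneity_in_reference_element(self):
        rows = [
            ("S1", "moss", "", 1, "Cu", 2.0), ("S1", "moss", "", 1, "Al", 50.0),
            ("S1", "soil", "", 1, "Cu", 8.0), ("S1", "soil", "", 1, "Al", 400.0),
        ]
        base = enrichment_factor(mktable(rows), "moss").df["value"].iloc[0]
        rows[1] = ("S1", "moss", "", 1, "Al", 100.0)  # double plant Al
        halved = enrichment_factor(mktable(rows), "moss").df["value"].iloc[0]
        assert halved == pytest.approx(base / 2)

    def test_rescaling_one_medium_at_one_site_is_invariant(self, lownoise):
        base = enrichment_factor(lownoise, "moss").df
        df = lownoise.df.copy()
        mask = (df["site"] == "GS") & (df["medium"] == "moss")
        df.loc[mask, "concentration_ug_per_g"] *= 1000.0  # e.g. unit change
        scaled = enrichment_factor(mktable(df.values.tolist()), "moss").df
        merged = base.merge(scaled, on=["site", "medium", "element"])
        assert np.allclose(merged["value_x"], merged["value_y"])

    def test_missing_reference_names_site(self):
        rows = [
            ("S1", "moss", "", 1, "Cu", 2.0),
            ("S1", "soil", "", 1, "Cu", 8.0), ("S1", "soil", "", 1, "Al", 400.0),
        ]
        with pytest.raises(ValueError, match="S1"):
            enrichment_factor(mktable(rows), "moss")

    def test_missing_soil_names_site(self):
        rows = [
            ("S1", "moss", "", 1, "Cu", 2.0), ("S1", "moss", "", 1, "Al", 50.0),
            ("S1", "soil", "", 1, "Cu", 8.0), ("S1", "soil", "", 1, "Al", 400.0),
            ("S2", "moss", "", 1, "Cu", 2.0), ("S2", "moss", "", 1, "Al", 50.0),
        ]
        with pytest.raises(ValueError, match="S2"):
            enrichment_factor(mktable(rows), "moss")


class TestContaminationFactor:
    def test_background_site_is_identically_one(self, lownoise):
        cf = contamination_factor(lownoise, "moss", "HZ")
        at_bg = cf.df[cf.df["site"] == "HZ"]["value"]
        assert (at_bg == 1.0).all()

    def test_simple_ratio(self):
        rows = [("BG", "moss", "", 1, "Cu", 10.0), ("S1", "moss", "", 1, "Cu", 35.0)]
        cf = contamination_factor(mktable(rows), "moss", "BG")
        assert cf.df.set_index("site").loc["S1", "value"] == pytest.approx(3.5)

    def test_monotone_in_site_and_background(self):
        mk = lambda c_site, c_bg: contamination_factor(  # noqa: E731
            mktable([("BG", "moss", "", 1, "Cu", c_bg), ("S1", "moss", "", 1, "Cu", c_site)]),
            "moss", "BG",
        ).df.set_index("site").loc["S1", "value"]
        assert mk(20, 10) < mk(30, 10)          # increasing in site concentration
        assert mk(20, 10) > mk(20, 15)          # decreasing in background

    def test_background_missing_element_named(self):
        rows = [("BG", "moss", "", 1, "Cu", 10.0),
                ("S1", "moss", "", 1, "Cu", 35.0), ("S1", "moss", "", 1, "Pb", 1.0)]
        with pytest.raises(ValueError, match="Pb"):
            contamination_factor(mktable(rows), "moss", "BG")

    def test_printed_cr_column_max_is_at_wb(self):
        # the printed per-site Cr CFs, fed as concentrations over a unit
        # background, put the maximum at the boiler-works site above the
        # moderate-contamination threshold of 3.5
        cf = contamination_factor(make_fixture("cf-survey"), "moss", "HZ")
        cr = cf.df[cf.df["element"] == "Cr"].set_index("site")["value"]
        assert cr.idxmax() == "WB" and cr.max() > 3.5
        assert cr.max() == pytest.approx(4.24)


class TestClassifyContamination:
    @pytest.mark.parametrize(
        "cf,cat",
        [(0.0, "C1"), (0.5, "C1"), (1.0, "C2"), (1.99, "C2"), (2.0, "C3"),
         (3.49, "C3"), (3.5, "C4"), (4.24, "C4"), (8.0, "C5"), (26.9, "C5"),
         (27.0, "C6"), (30.0, "C6"), (1e9, "C6")],
    )
    def test_left_closed_bins(self, cf, cat):
        assert classify_contamination(cf) == cat

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_contamination(-0.1)

    @given(st.floats(min_value=0, max_value=1e12, allow_nan=False))
    def test_partition_of_nonnegative_axis(self, cf):
        cat = classify_contamination(cf)
        assert cat in CATEGORY_LABELS

    @given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_contamination(lo) <= classify_contamination(hi)

    def test_vectorized_matches_scalar(self):
        vals = np.array([0.5, 1.0, 2.0, 3.5, 8.0, 27.0])
        assert list(classify_contamination(vals)) == [classify_contamination(v) for v in vals]


class TestCfSiteSummary:
    def test_constant_column_at_bin_boundary(self):
        rows = [(f"S{i}", "moss", "", 1, "Cu", 1.0) for i in range(9)]
        idx = contamination_factor(mktable(rows), "moss", "S0")
        s = cf_site_summary(idx).iloc[0]
        assert s["mean_cf"] == 1.0 and s["max_cf"] == 1.0 and s["category_of_mean"] == "C2"

    def test_printed_cd_column_is_c1(self):
        s = cf_site_summary(cf_survey_index()).set_index("element")
        assert s.loc["Cd", "mean_cf"] < 1
        assert s.loc["Cd", "mean_cf"] == pytest.approx(CF_SURVEY["Cd"].mean())
        assert s.loc["Cd", "category_of_mean"] == "C1"

    def test_printed_ag_column_mean_c2_max_347(self):
        s = cf_site_summary(cf_survey_index()).set_index("element")
        assert s.loc["Ag", "category_of_mean"] == "C2"
        assert s.loc["Ag", "max_cf"] == pytest.approx(3.47)

    def test_requires_cf_kind(self, lownoise):
        ef = enrichment_factor(lownoise, "moss")
        with pytest.raises(ValueError):
            cf_site_summary(ef)


def test_ratio_extremes_reports_max_and_min_per_pair():
    df = pd.DataFrame(
        {
            "element": ["Cu", "Pb", "Cu", "Pb"],
            "numerator_medium": ["moss"] * 4,
            "denominator_medium": ["leaf_a", "leaf_a", "leaf_b", "leaf_b"],
            "mean_ratio": [5.0, 12.0, 7.0, 2.0],
            "sd_ratio": [1, 1, 1, 1],
            "n_sites": [9] * 4,
        }
    )
    out = ratio_extremes(df).set_index(["denominator_medium", "which"])
    assert out.loc[("leaf_a", "max"), "element"] == "Pb"
    assert out.loc[("leaf_b", "min"), "mean_ratio"] == 2.0
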