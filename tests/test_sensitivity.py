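"""Sensitivity readouts: GR50/ED20 extraction, AOC, classification, bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grscreen.design import OXALIPLATIN, SN38
from grscreen.dose_response import DoseResponseFit, fit_ll3u, infer_curve, ll3u
from grscreen.sensitivity import (
    absolute_ed,
    add_library_calls,
    allocate_treatment,
    aoc,
    classify,
    format_report,
    gr50_aoc_correlation,
    sensitivity_profiles,
    summarize_library,
)


def make_fit(gr_inf, gec50, h, c_min=0.012, c_max=120.0, **kw):
    return DoseResponseFit(
        sample_id=kw.get("sample_id", "s"), drug=kw.get("drug", "oxaliplatin"),
        response="gr", gr_inf=gr_inf, gec50=gec50, h=h, rse=0.0,
        converged=True, n_points=20, c_min=c_min, c_max=c_max,
    )


def ed_closed_form(gr_inf, gec50, h, level):
    return gec50 * ((1 - gr_inf) / (level - gr_inf) - 1) ** (1 / h)


class TestAbsoluteED:
    def test_gr50_at_gec50_when_grinf_zero(self):
        # response at GEC50 is (1+GR_inf)/2 = 0.5 when GR_inf = 0
        fit = make_fit(0.0, 4.44, 2.0)
        assert absolute_ed(fit, 0.5) == pytest.approx(4.44, rel=1e-9)

    def test_not_reached_when_asymptote_above_level(self):
        fit = make_fit(0.6, 1.0, 1.0)
        assert np.isnan(absolute_ed(fit, 0.5))

    def test_closed_form_example(self):
        # solve -0.5 + 1.5/(1 + c/2) = 0.5 -> c = 1
        fit = make_fit(-0.5, 2.0, 1.0)
        assert absolute_ed(fit, 0.5) == pytest.approx(1.0, rel=1e-9)

    @given(
        gr_inf=st.floats(-1.0, 0.4),
        log_gec50=st.floats(np.log10(0.05), np.log10(30.0)),
        h=st.floats(0.5, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_root_finding_matches_closed_form(self, gr_inf, log_gec50, h):
        gec50 = 10.0**log_gec50
        expected = ed_closed_form(gr_inf, gec50, h, 0.5)
        if not 0.012 <= expected <= 120.0:
            return  # crossing outside the tested range
        fit = make_fit(gr_inf, gec50, h)
        assert absolute_ed(fit, 0.5) == pytest.approx(expected, rel=1e-6)

    def test_crossing_below_range_clamped_to_c_min(self):
        fit = make_fit(-0.9, 0.001, 2.0)  # level crossed below c_min
        assert absolute_ed(fit, 0.5) == pytest.approx(0.012)

    def test_non_converged_fit_rejected(self):
        bad = dataclasses.replace(make_fit(0.0, 1.0, 1.0), converged=False)
        with pytest.raises(ValueError):
            absolute_ed(bad, 0.5)


class TestAOC:
    @pytest.mark.parametrize(
        "y_const, grid, expected",
        [
            (1.0, OXALIPLATIN, 0.0),
            (0.0, OXALIPLATIN, 119.988),
            (0.0, SN38, 319.968),
            (-1.0, SN38, 639.936),  # 2x range width: the AOC upper bound
        ],
    )
    def test_constant_response_limits(self, y_const, grid, expected):
        x = np.linspace(grid.c_min, grid.c_max, 1000)
        assert aoc((x, np.full_like(x, y_const))) == pytest.approx(expected, rel=1e-12)

    def test_antitone_in_response(self):
        x = np.linspace(0.012, 120.0, 1000)
        y = ll3u(x, 0.0, 1.0, 1.0)
        assert aoc((x, y - 0.1)) > aoc((x, y))

    def test_unordered_grid_rejected(self):
        with pytest.raises(ValueError):
            aoc(([1.0, 0.5, 2.0], [0.1, 0.2, 0.3]))


class TestClassification:
    def test_gr50_below_median_is_sensitive(self):
        assert classify(2.22, 4.44, "gr50") == "sensitive"
        assert classify(8.88, 4.44, "gr50") == "resistant"

    def test_aoc_above_median_is_sensitive(self):
        assert classify(210.0, 105.0, "aoc") == "sensitive"
        assert classify(50.0, 105.0, "aoc") == "resistant"

    def test_not_reached_is_resistant(self):
        assert classify(float("nan"), 4.44, "gr50") == "resistant"

    def test_tie_is_resistant(self):
        assert classify(4.44, 4.44, "gr50") == "resistant"
        assert classify(105.0, 105.0, "aoc") == "resistant"


class TestAllocation:
    def test_discordant_calls_pick_sensitive_drug(self):
        res = allocate_treatment(
            {"A": 150.0, "B": 50.0}, {"A": 100.0, "B": 100.0}
        )
        assert res["recommended_drug"] == "A"
        assert "discordant" in res["rule"]

    def test_both_sensitive_largest_relative_distance(self):
        res = allocate_treatment(
            {"A": 160.0, "B": 110.0}, {"A": 100.0, "B": 100.0}
        )
        assert res["recommended_drug"] == "A"

    def test_both_resistant_smallest_relative_distance(self):
        res = allocate_treatment(
            {"A": 60.0, "B": 95.0}, {"A": 100.0, "B": 100.0}
        )
        assert res["recommended_drug"] == "B"

    def test_missing_aoc_rejected(self):
        with pytest.raises(ValueError):
            allocate_treatment({"A": float("nan"), "B": 50.0}, {"A": 100.0, "B": 100.0})


class TestLibrarySummary:
    def test_hand_computed_median_and_mad(self):
        s = summarize_library([1, 2, 3, 4, 5], n_boot=200)
        assert s["median"] == 3.0
        assert s["mad_unscaled"] == 1.0
        assert s["iqr"] == (2.0, 4.0)

    def test_identical_values_degenerate_ci(self):
        s = summarize_library([7.0] * 6, n_boot=200)
        assert s["ci"] == (7.0, 7.0)

    def test_bootstrap_deterministic_under_seed(self):
        vals = [1.2, 3.4, 2.2, 8.1, 0.4, 5.5]
        assert summarize_library(vals)["ci"] == summarize_library(vals)["ci"]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            summarize_library([1.0])


class TestCorrelation:
    def test_collinear_profiles_give_r_minus_one(self):
        a = np.linspace(50, 300, 8)
        g = 2.0 ** (-0.02 * a + 5)  # log2(GR50) exactly linear in AOC
        res = gr50_aoc_correlation(g, a)
        assert res["r"] == pytest.approx(-1.0, abs=1e-12)
        assert res["slope"] == pytest.approx(-0.02)

    def test_constant_aoc_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = gr50_aoc_correlation([1.0, 2.0, 4.0], [5.0, 5.0, 5.0])
        assert np.isnan(res["r"]) and res["flag"] == "zero_variance"

    def test_not_reached_excluded_and_counted(self):
        res = gr50_aoc_correlation([1, 2, 4, np.nan], [100, 80, 60, 40])
        assert res["n"] == 3 and res["n_excluded"] == 1

    def test_one_parameter_family_strongly_correlated(self):
        # shared (GR_inf, h), GEC50 varying: both metrics are monotone
        # functionals of one parameter, so |r| must be high
        gr50s, aocs = [], []
        for gec50 in np.logspace(np.log10(1.0), np.log10(40), 10):
            fit = make_fit(-0.3, gec50, 1.4)
            gr50s.append(absolute_ed(fit, 0.5))
            aocs.append(aoc(infer_curve(fit)))
        res = gr50_aoc_correlation(gr50s, aocs)
        assert res["r"] < -0.9


class TestProfiles:
    def test_profiles_and_calls_roundtrip(self, noiseless_fits):
        gr_fits, area_fits, specs = noiseless_fits
        profiles = sensitivity_profiles(gr_fits, area_fits)
        assert len(profiles) == len(specs) * 2
        profiles, cutoffs = add_library_calls(profiles)
        for drug, grp in profiles.groupby("drug"):
            med = cutoffs[drug]["median_aoc"]
            # boundary behavior: sensitive-by-AOC iff strictly above median
            for _, row in grp.iterrows():
                assert (row["call_aoc"] == "sensitive") == (row["aoc"] > med)

    def test_calls_invariant_to_sample_relabeling(self, noiseless_fits):
        gr_fits, area_fits, _ = noiseless_fits
        profiles, _ = add_library_calls(sensitivity_profiles(gr_fits, area_fits))
        renamed = [dataclasses.replace(f, sample_id="Z" + f.sample_id) for f in gr_fits]
        renamed_area = [dataclasses.replace(f, sample_id="Z" + f.sample_id) for f in area_fits]
        p2, _ = add_library_calls(sensitivity_profiles(renamed, renamed_area))
        p2["sample_id"] = p2["sample_id"].str.removeprefix("Z")
        merged = profiles.merge(p2, on=["sample_id", "drug"], suffixes=("", "_r"))
        assert (merged["call_aoc"] == merged["call_aoc_r"]).all()
        assert (merged["call_gr50"] == merged["call_gr50_r"]).all()

    def test_report_text(self, noiseless_fits):
        gr_fits, area_fits, specs = noiseless_fits
        profiles, cutoffs = add_library_calls(sensitivity_profiles(gr_fits, area_fits))
        text = format_report(specs[0].sample_id, profiles, cutoffs)
        assert "Drug sensitivity report" in text
        assert "Recommended agent" in text
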