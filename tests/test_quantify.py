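"""Contribution arithmetic, AA/Ret ratios, group summaries and filters."""

import numpy as np
import pandas as pd
import pytest

from serumaf.fitting import FitResult
from serumaf.quantify import (
    ContributionRecord,
    aa_ret_ratio,
    absolute_contributions,
    compare_total_areas,
    contribution_record,
    percent_contributions,
    render_table,
    reporting_filter,
    summarize_groups,
)
from serumaf.simulate import default_profiles, generate_truth_cohort
from serumaf.spectra import ANALYSIS_WINDOW


def make_fit(areas, total=1000.0, converged=True):
    return FitResult(
        sample_id="s", group="sham", excitation=366, stage="reference",
        params={}, residuals=np.zeros(4), sse=0.0, r_squared=1.0,
        component_areas=dict(areas), converged=converged, n_iterations=1,
        window=ANALYSIS_WINDOW, seed=0, total_measured_area=total,
    )


def make_record(sample_id, group, percent, total=1000.0):
    return ContributionRecord(
        sample_id=sample_id, group=group, excitation=366,
        percent=dict(percent),
        absolute={k: v / 100.0 * total for k, v in percent.items()},
        total_measured_area=total,
        aa_ret_ratio=percent.get("arachidonic_acid", 0.0)
        / max(percent.get("retinol", 1e-12), 1e-12),
    )


class TestPercentContributions:
    def test_two_equal_bands_split_50_50(self):
        pct = percent_contributions(make_fit({"retinol": 30.0,
                                              "arachidonic_acid": 30.0}))
        assert pct == {"retinol": 50.0, "arachidonic_acid": 50.0}

    def test_single_band_is_100(self):
        assert percent_contributions(make_fit({"retinol": 7.0})) == \
            {"retinol": 100.0}

    def test_negative_band_excluded_from_denominator(self):
        pct = percent_contributions(make_fit(
            {"retinol": 60.0, "proteins": 40.0, "hemoglobin_neg": -10.0}))
        assert pct["retinol"] == pytest.approx(60.0)
        assert pct["proteins"] == pytest.approx(40.0)
        assert pct["hemoglobin_neg"] == pytest.approx(-10.0)
        positive = [v for v in pct.values() if v > 0]
        assert sum(positive) == pytest.approx(100.0, abs=0.5)

    def test_requires_convergence_and_positive_area(self):
        with pytest.raises(ValueError):
            percent_contributions(make_fit({"retinol": 1.0}, converged=False))
        with pytest.raises(ValueError):
            percent_contributions(make_fit({"hemoglobin_neg": -1.0}))


class TestAbsoluteContributions:
    def test_half_of_1000_is_500(self):
        out = absolute_contributions({"retinol": 50.0}, 1000.0)
        assert out["retinol"] == 500.0

    def test_extremes(self):
        out = absolute_contributions({"a": 0.0, "b": 100.0}, 123.4)
        assert out == {"a": 0.0, "b": 123.4}

    def test_consistency_with_percent_is_exact(self):
        rng = np.random.default_rng(0)
        pct = {f"c{i}": float(v) for i, v in
               enumerate(rng.uniform(1, 40, 6))}
        total = 5321.7
        out = absolute_contributions(pct, total)
        for k in pct:
            assert out[k] / total * 100.0 == pytest.approx(pct[k], rel=1e-12)

    def test_scale_invariance(self):
        """Scaling a spectrum's intensities by k leaves percents unchanged
        and multiplies absolutes by k."""
        areas = {"retinol": 40.0, "arachidonic_acid": 25.0}
        for k in (0.5, 3.0, 117.0):
            base = make_fit(areas, total=1000.0)
            scaled = make_fit({n: a * k for n, a in areas.items()},
                              total=1000.0 * k)
            p0, p1 = percent_contributions(base), percent_contributions(scaled)
            assert p0 == pytest.approx(p1, rel=1e-12)
            a0 = absolute_contributions(p0, base.total_measured_area)
            a1 = absolute_contributions(p1, scaled.total_measured_area)
            for n in areas:
                assert a1[n] == pytest.approx(k * a0[n], rel=1e-12)


class TestAARetRatio:
    @pytest.mark.parametrize("aa,ret,expected", [
        (20.22, 33.43, 0.60),   # sham group means, 366 nm
        (26.50, 24.03, 1.10),   # I/R 60/60
        (27.17, 23.76, 1.14),   # I/R 60/120
        (25.0, 25.0, 1.00),
    ])
    def test_ratio_of_means_to_2_decimals(self, aa, ret, expected):
        pct = {"arachidonic_acid": aa, "retinol": ret}
        assert aa_ret_ratio(pct, decimals=2) == expected

    def test_zero_retinol_rejected(self):
        with pytest.raises(ZeroDivisionError):
            aa_ret_ratio({"arachidonic_acid": 10.0, "retinol": 0.0})

    def test_ratio_of_truth_cohort_means_matches_printed_values(self):
        """Cohorts drawn from the default 366 nm composition profiles
        reproduce the printed AA/Ret ratios within ±0.05 (averaged over
        seeds, n=7 per group)."""
        profiles = default_profiles(366)
        expected = {"sham": 0.60, "ir_60_60": 1.10, "ir_60_120": 1.14}
        ratios = {g: [] for g in expected}
        for seed in range(10):
            df = generate_truth_cohort(profiles, 7, seed)
            for g in expected:
                sub = df[df.group == g]
                ratios[g].append(sub["drawn_percent_arachidonic_acid"].mean()
                                 / sub["drawn_percent_retinol"].mean())
        for g, target in expected.items():
            assert np.mean(ratios[g]) == pytest.approx(target, abs=0.05)


class TestSummaries:
    def _records(self, shift=0.0, n=5, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for group, delta in (("sham", 0.0), ("ir_60_60", shift)):
            for i in range(n):
                recs.append(make_record(
                    f"{group}_{i}", group,
                    {"retinol": 40.0 + rng.normal(0, sd),
                     "arachidonic_acid": 25.0 + delta + rng.normal(0, sd)}))
        return recs

    def test_identical_groups_not_flagged(self):
        table = summarize_groups(self._records(shift=0.0), "sham")
        assert (table.tests["p_value"] > 0.05).all()
        assert (table.tests["flag"] == "").all()

    def test_extreme_separation_double_starred(self):
        table = summarize_groups(self._records(shift=10.0), "sham")
        row = table.tests[table.tests.component == "arachidonic_acid"].iloc[0]
        assert row["p_value"] <= 0.01
        assert row["flag"] == "**"

    def test_standard_error_definition(self):
        recs = self._records()
        table = summarize_groups(recs, "sham")
        vals = np.array([r.percent["retinol"] for r in recs
                         if r.group == "sham"])
        row = table.summaries[(table.summaries.group == "sham")
                              & (table.summaries.component == "retinol")].iloc[0]
        assert row["se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_ranksum_option(self):
        table = summarize_groups(self._records(shift=10.0), "sham",
                                 test="ranksum")
        row = table.tests[table.tests.component == "arachidonic_acid"].iloc[0]
        assert row["p_value"] <= 0.05

    def test_small_group_flagged_not_tested(self):
        recs = self._records()[:6] + [make_record("solo", "ir_60_120",
                                                  {"retinol": 40.0,
                                                   "arachidonic_acid": 25.0})]
        table = summarize_groups(recs, "sham")
        solo = table.tests[table.tests.group == "ir_60_120"]
        assert (solo["flag"] == "n/a").all()


class TestReportingFilter:
    def _table(self, minor_percent):
        recs = []
        for group in ("sham", "ir_60_60"):
            for i in range(3):
                recs.append(make_record(f"{group}_{i}", group, {
                    "retinol": 60.0 - minor_percent,
                    "arachidonic_acid": 40.0,
                    "linoleic_acid": minor_percent,
                }))
        return summarize_groups(recs, "sham")

    def test_component_below_threshold_everywhere_dropped(self):
        out = reporting_filter(self._table(4.0), threshold=5.0)
        assert "linoleic_acid" not in set(out.summaries["component"])
        # raw records keep it
        assert all("linoleic_acid" in r.percent for r in out.records)

    def test_boundary_component_kept(self):
        out = reporting_filter(self._table(5.1), threshold=5.0)
        assert "linoleic_acid" in set(out.summaries["component"])


def test_compare_total_areas_flags_shift():
    rng = np.random.default_rng(1)
    recs = []
    for group, mean in (("sham", 1000.0), ("ir_60_60", 2000.0)):
        for i in range(6):
            recs.append(make_record(f"{group}_{i}", group,
                                    {"retinol": 100.0},
                                    total=mean + rng.normal(0, 50)))
    out = compare_total_areas(recs, "sham")
    row = out[out.group == "ir_60_60"].iloc[0]
    assert row["flag"] in ("*", "**")
    assert row["mean"] > out[out.group == "sham"]["mean"].iloc[0]


def test_render_table_layout():
    recs = []
    for group in ("sham", "ir_60_60"):
        for i in range(3):
            recs.append(make_record(f"{group}_{i}", group,
                                    {"retinol": 40.0 + i,
                                     "arachidonic_acid": 24.0 + i}))
    text = render_table(summarize_groups(recs, "sham"))
    lines = text.strip().split("\n")
    assert lines[0].split("\t") == ["group", "retinol", "arachidonic_acid",
                                    "AA/Ret"]
    assert lines[1].startswith("sham")
    assert "±" in lines[1]
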