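import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpcentiles import tables
from bpcentiles.tables import (
    REFERENCE_FAMILY_MAP,
    check_row_consistency,
    height_percentiles,
    load_reference_thresholds,
    round_half_up,
    tabulate,
    validate_printed_table,
)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(106.60) == 107
        assert round_half_up(106.5) == 107
        assert round_half_up(106.49) == 106
        assert round_half_up(0.09345, 4) == 0.0935


class TestHeightPercentiles:
    def test_type7_convention_on_toy_heights(self):
        # 20 children aged 7 with heights 100..119: median 109.5 -> 110 cm
        df = pd.DataFrame(dict(sex=["M"] * 20, age=[7.3] * 20,
                               height_cm=np.arange(100.0, 120.0)))
        grid = height_percentiles(df, "M", ages=[7])
        med = grid.df[grid.df.height_pct == "50th"].height_cm.iloc[0]
        assert med == 110
        # brute-force oracle for the 25th label: sorted order statistics
        h = np.sort(df.height_cm.to_numpy())
        pos = 0.25 * (len(h) - 1)
        oracle = h[int(pos)] + (pos - int(pos)) * (h[int(pos) + 1] - h[int(pos)])
        got = grid.df[grid.df.height_pct == "25th"].height_cm.iloc[0]
        assert got == int(round_half_up(oracle))

    def test_constant_heights_collapse(self):
        df = pd.DataFrame(dict(sex=["F"] * 25, age=[9.5] * 25, height_cm=[130.0] * 25))
        grid = height_percentiles(df, "F", ages=[9])
        assert set(grid.df.height_cm) == {130}

    def test_sparse_cells_flagged(self):
        df = pd.DataFrame(dict(sex=["M"] * 5, age=[11.2] * 5,
                               height_cm=np.linspace(140, 150, 5)))
        grid = height_percentiles(df, "M", ages=[11])
        assert grid.sparse_cells == [(11, 5)]

    def test_grid_monotone_within_age(self, analysis_small):
        grid = height_percentiles(analysis_small, "F")
        for _, g in grid.df.groupby("age"):
            assert g.height_cm.is_monotonic_increasing


class TestRowConsistency:
    def test_published_boys_sbp_row(self):
        res = check_row_consistency(91, 0.0983, 103)
        assert res.ok
        assert res.implied_nu == pytest.approx(0.27, abs=0.01)
        assert res.implied_p95 == pytest.approx(106.6, abs=0.05)
        assert res.implied_p95_rounded == 107  # printed value

    def test_published_girls_dbp_row(self):
        res = check_row_consistency(60, 0.1313, 70)
        assert res.ok
        assert res.implied_p95 == pytest.approx(72.8, abs=0.05)
        assert res.implied_p95_rounded == 73  # printed value

    def test_normal_row_reproduces_closed_form(self):
        # a nu=1 (pure normal) row: P95 must equal the normal quantile exactly
        mu, sigma = 100.0, 0.1
        p90 = mu * (1 + sigma * stats.norm.ppf(0.9))
        res = check_row_consistency(mu, sigma, p90)
        assert res.implied_nu == pytest.approx(1.0, abs=1e-6)
        assert res.implied_p95 == pytest.approx(mu * (1 + sigma * stats.norm.ppf(0.95)),
                                                abs=1e-6)

    def test_row_without_root_flagged(self):
        # spread too wide for any BCCG nu in [-5, 5] at this S
        res = check_row_consistency(60, 0.07, 70)
        assert not res.ok and "no root" in res.reason

    def test_malformed_row_flagged(self):
        assert not check_row_consistency(100, 0.1, 90).ok


class TestValidatePrintedTable:
    def test_reference_fixture_is_internally_consistent(self):
        report = validate_printed_table(load_reference_thresholds())
        s = report["summary"]
        assert s["n_checked"] == 225   # SBP both sexes + girls' DBP
        assert s["frac_within_tolerance"] >= 0.95
        assert s["n_skipped"] == 75    # boys' DBP rows are BCPE

    def test_bcpe_rows_skipped_with_reason(self):
        report = validate_printed_table(load_reference_thresholds())
        reasons = {d["reason"] for d in report["skipped"]}
        assert reasons == {"underdetermined: two shape unknowns"}

    def test_corrupted_p95_flagged(self):
        ref = load_reference_thresholds().copy()
        i = ref[(ref.sex == "M") & (ref.measure == "SBP")].index[0]
        ref.loc[i, "P95"] += 5
        report = validate_printed_table(ref)
        row = [r for r in report["rows"] if r["index"] == i][0]
        assert row["abs_discrepancy"] >= 4


class TestTabulate:
    def test_table_shape_and_ordering(self, analysis_small, fit_small_sbp, fit_small_dbp):
        grid = height_percentiles(analysis_small, "M")
        ct = tabulate(fit_small_sbp, fit_small_dbp, grid)
        assert len(ct.df) == 15 * 5 * 2
        assert ct.checks["prerounding_order_ok"]
        assert ct.checks["rounded_order_ok"]
        assert np.all((ct.df.P50 <= ct.df.P90) & (ct.df.P90 <= ct.df.P95))

    def test_median_height_p50_nondecreasing(self, analysis_small, fit_small_sbp,
                                             fit_small_dbp):
        grid = height_percentiles(analysis_small, "M")
        ct = tabulate(fit_small_sbp, fit_small_dbp, grid)
        assert ct.checks["median_height_p50_nondecreasing"]["SBP"]

    def test_own_bccg_rows_self_consistent(self, analysis_small, fit_small_sbp,
                                           fit_small_dbp):
        grid = height_percentiles(analysis_small, "M")
        ct = tabulate(fit_small_sbp, fit_small_dbp, grid)
        report = validate_printed_table(ct.df)
        assert report["summary"]["max_abs_discrepancy"] <= 1.0

    def test_regeneration_is_bit_identical(self, analysis_small, fit_small_sbp,
                                           fit_small_dbp, tmp_path):
        from bpcentiles.gamlss import FitResult
        grid = height_percentiles(analysis_small, "M")
        ct = tabulate(fit_small_sbp, fit_small_dbp, grid)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ct.to_csv(p1)
        clone_s = FitResult.from_json(fit_small_sbp.to_json())
        clone_d = FitResult.from_json(fit_small_dbp.to_json())
        tabulate(clone_s, clone_d, grid).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mid_year_age_eval_option(self, analysis_small, fit_small_sbp, fit_small_dbp):
        grid = height_percentiles(analysis_small, "M")
        exact = tabulate(fit_small_sbp, fit_small_dbp, grid, age_eval="exact")
        mid = tabulate(fit_small_sbp, fit_small_dbp, grid, age_eval="mid-year")
        # mid-year evaluation shifts thresholds upward for a rising surface
        assert mid.df.P50.mean() >= exact.df.P50.mean()


class TestReferenceFixture:
    def test_shape_and_family_map(self):
        ref = load_reference_thresholds()
        assert len(ref) == 300  # 15 ages x 5 height labels x 2 measures x 2 sexes
        assert set(REFERENCE_FAMILY_MAP.values()) == {"BCCG", "BCPE"}

    def test_rows_ordered_and_monotone(self):
        ref = load_reference_thresholds()
        for (_, _, _), g in ref.groupby(["sex", "measure", "age"]):
            assert (g.P50 < g.P90).all() and (g.P90 <= g.P95).all()

    def test_age17_median_height_medians(self):
        # narrative anchors: at median height, age 17, SBP 115 / DBP 68 both sexes
        ref = load_reference_thresholds()
        for sex in ("M", "F"):
            row = ref[(ref.sex == sex) & (ref.age == 17) & (ref.height_pct == "50th")]
            assert row[row.measure == "SBP"].P50.iloc[0] == 115
            assert row[row.measure == "DBP"].P50.iloc[0] == 68
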