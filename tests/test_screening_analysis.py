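"""NFU readout, day matching, binning, optima, ratio and t-test utilities."""

import numpy as np
import pandas as pd
import pytest

from dropscreen.gradient_design import design_1d_program, droplet_schedule
from dropscreen.presets import nitrate_1d_plan
from dropscreen.screening_analysis import (
    assign_concentrations,
    bin_1d,
    compare_endpoints,
    find_optimum,
    grid_2d,
    growth_curves,
    match_days,
    nfu,
    nfu_table,
    np_ratio,
)


class TestNfu:
    @pytest.mark.parametrize(
        "i_t,i_t0,expected",
        [(1.3, 1.3, 0.0), (2.6, 1.3, 1.0), (0.5, 1.0, -0.5)],
    )
    def test_definition(self, i_t, i_t0, expected):
        assert nfu(i_t, i_t0) == pytest.approx(expected)

    def test_zero_initial_intensity_is_undefined(self):
        assert np.isnan(nfu(1.0, 0.0))

    def test_day_zero_identity_for_every_droplet(self, rng):
        intensities = rng.uniform(0.1, 5.0, size=1000)
        assert (nfu(intensities, intensities) == 0.0).all()


def fake_records(n, value=1.0, channel="f405_425"):
    return pd.DataFrame({channel: np.full(n, float(value))})


class TestMatchDays:
    def test_equal_counts_pair_in_order(self):
        d0, dt, warned = match_days(fake_records(440), fake_records(440))
        assert len(d0) == len(dt) == 440 and not warned

    def test_small_mismatch_truncates_with_warning(self):
        d0, dt, warned = match_days(fake_records(440), fake_records(438))
        assert len(d0) == len(dt) == 438 and warned

    def test_large_mismatch_is_error(self):
        with pytest.raises(ValueError, match="coalescence or loss"):
            match_days(fake_records(440), fake_records(300))

    def test_excluded_droplets_counted(self):
        d0 = fake_records(10)
        d0.loc[3, "f405_425"] = 0.0
        d0.loc[7, "f405_425"] = -0.2
        table, n_excluded = nfu_table(d0, fake_records(10, 2.0))
        assert n_excluded == 2
        assert table["nfu"].notna().sum() == 8


class TestAssignConcentrations:
    def test_1d_annotations(self, plan_1d, program_1d):
        records = fake_records(440)
        ann = assign_concentrations(records, program_1d, plan_1d)
        assert ann["conc_NaNO3_mM"].iloc[0] == pytest.approx(0.0, abs=0.1)
        # sequence midpoint of a 0-50 mM ramp sits at ~25 mM
        assert ann["conc_NaNO3_mM"].iloc[220] == pytest.approx(25.0, abs=0.15)
        assert ann["conc_NaNO3_mM"].is_monotonic_increasing

    def test_2d_annotations_on_grid(self, plan_2d, program_2d):
        records = fake_records(plan_2d.total_droplets())
        ann = assign_concentrations(records, program_2d, plan_2d)
        combos = set(
            zip(ann["pct_NaNO3"].round(6), ann["pct_K2HPO4"].round(6))
        )
        assert len(combos) == 121

    def test_excess_records_rejected(self, plan_1d, program_1d):
        with pytest.raises(ValueError, match="exceed"):
            assign_concentrations(fake_records(441), program_1d, plan_1d)


class TestBin1D:
    def annotated(self, plan, program, n=440, rng=None):
        sched = droplet_schedule(program, plan)
        df = sched.copy()
        values = (
            rng.normal(1.0, 0.1, len(df)) if rng is not None else np.ones(len(df))
        )
        df["nfu"] = values
        return df

    def test_default_resolution_is_3_1_percent(self, plan_1d, program_1d):
        curve = bin_1d(self.annotated(plan_1d, program_1d), plan_1d, n_bins=32)
        widths = curve["bin_hi_pct"] - curve["bin_lo_pct"]
        assert np.allclose(widths, 3.125)
        assert round(float(widths.iloc[0]), 1) == 3.1

    def test_counts_conserved_and_balanced(self, plan_1d, program_1d):
        curve = bin_1d(self.annotated(plan_1d, program_1d), plan_1d, n_bins=32)
        assert curve["n"].sum() == 440
        assert set(curve["n"]) <= {13, 14}  # 440/32 = 13.75 droplets per bin

    def test_single_bin_matches_grand_statistics(self, plan_1d, program_1d, rng):
        ann = self.annotated(plan_1d, program_1d, rng=rng)
        curve = bin_1d(ann, plan_1d, n_bins=1)
        assert len(curve) == 1
        assert curve["mean_nfu"].iloc[0] == pytest.approx(ann["nfu"].mean())
        assert curve["sd_nfu"].iloc[0] == pytest.approx(ann["nfu"].std(ddof=1))

    def test_order_invariance(self, plan_1d, program_1d, rng):
        ann = self.annotated(plan_1d, program_1d, rng=rng)
        shuffled = ann.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = bin_1d(ann, plan_1d)
        b = bin_1d(shuffled, plan_1d)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self, plan_1d, program_1d):
        with pytest.raises(ValueError):
            bin_1d(self.annotated(plan_1d, program_1d).iloc[:0], plan_1d)


class TestGrid2D:
    def annotated(self, plan, program, value=1.0):
        df = droplet_schedule(program, plan).copy()
        df["nfu"] = value
        return df

    def test_all_cells_have_scheduled_count(self, plan_2d, program_2d):
        m = grid_2d(self.annotated(plan_2d, program_2d), plan_2d)
        assert len(m) == 121
        assert (m["n"] == plan_2d.droplets_per_step).all()

    def test_missing_cells_reported_empty_not_zero(self, plan_2d, program_2d):
        ann = self.annotated(plan_2d, program_2d)
        ann = ann[ann["pct_NaNO3"] > 1e-9]  # drop the whole first row of cells
        m = grid_2d(ann, plan_2d)
        empty = m[m["n"] == 0]
        assert len(empty) == 11
        assert empty["mean_nfu"].isna().all()

    def test_off_grid_annotation_rejected(self, plan_2d, program_2d):
        ann = self.annotated(plan_2d, program_2d)
        ann.loc[0, "pct_NaNO3"] = 3.3
        with pytest.raises(ValueError, match="off the program grid"):
            grid_2d(ann, plan_2d)


class TestGrowthCurves:
    def simulated_days(self, rates, days=tuple(range(8)), n=50):
        # capacity-limited growth: intensity ~ cell number, K/N0 = 100
        out = {}
        for day in days:
            out[day] = pd.DataFrame(
                {
                    "f405_425": [
                        0.1 * 100 / (1 + 99 * np.exp(-r * day)) for r in rates[:n]
                    ]
                }
            )
        return out

    def test_day_zero_mean_and_sd_are_zero(self):
        curves = growth_curves(self.simulated_days(np.full(50, 0.5)))
        day0 = curves[curves["day"] == 0]
        assert day0["mean_nfu"].iloc[0] == 0.0
        assert day0["sd_nfu"].iloc[0] == 0.0

    def test_fast_strain_reaches_half_max_earlier(self):
        fast = growth_curves(self.simulated_days(np.full(50, 0.9)))
        slow = growth_curves(self.simulated_days(np.full(50, 0.3)))
        half = fast["mean_nfu"].max() / 2  # common reference level

        def reach_day(c):
            hit = c[c["mean_nfu"] >= half]["day"]
            return hit.iloc[0] if len(hit) else np.inf

        assert reach_day(fast) < reach_day(slow)

    def test_no_growth_gives_flat_zero_curve(self):
        curves = growth_curves(self.simulated_days(np.zeros(50)))
        assert (curves["mean_nfu"] == 0.0).all()

    def test_requires_two_days(self):
        with pytest.raises(ValueError):
            growth_curves({0: fake_records(10)})


class TestFindOptimum:
    def curve(self, means, plan):
        n = len(means)
        edges = np.linspace(0, 100, n + 1)
        eff = plan.effectors[0]
        return pd.DataFrame(
            {
                "bin_lo_pct": edges[:-1],
                "bin_hi_pct": edges[1:],
                "conc_lo_mM": edges[:-1] / 100 * eff.max_final_mM,
                "conc_hi_mM": edges[1:] / 100 * eff.max_final_mM,
                "mean_nfu": means,
                "sd_nfu": np.zeros(n),
                "n": np.full(n, 10),
            }
        )

    def test_unimodal_curve_contains_peak_bin(self, plan_1d):
        means = np.exp(-0.5 * ((np.arange(32) - 11) / 3.0) ** 2)
        opt = find_optimum(self.curve(means, plan_1d), plan_1d)
        peak_conc = 11.5 / 32 * 50.0  # center of bin 11
        assert opt.conc_lo_mM <= peak_conc <= opt.conc_hi_mM
        assert not opt.at_upper_boundary

    def test_monotone_curve_flags_upper_boundary(self, plan_1d):
        means = np.linspace(0, 5, 32)
        opt = find_optimum(self.curve(means, plan_1d), plan_1d)
        assert opt.at_upper_boundary
        assert opt.conc_hi_mM == pytest.approx(50.0)

    def test_flat_curve_returns_whole_range(self, plan_1d):
        opt = find_optimum(self.curve(np.ones(32), plan_1d), plan_1d)
        assert opt.conc_lo_mM == 0.0
        assert opt.conc_hi_mM == pytest.approx(50.0)
        assert opt.at_lower_boundary and opt.at_upper_boundary

    def test_all_empty_bins_rejected(self, plan_1d):
        with pytest.raises(ValueError, match="empty"):
            find_optimum(self.curve(np.full(32, np.nan), plan_1d), plan_1d)


class TestNpRatio:
    @pytest.mark.parametrize(
        "n,p,expected_r,expected_text",
        [
            (17.6, 0.175, 100.0, "100:1"),  # BG-11
            (12.0, 0.37, 32.0, "32:1"),     # AD7
            (16.0, 1.0, 16.0, "16:1"),      # Redfield N:P
        ],
    )
    def test_reference_media(self, n, p, expected_r, expected_text):
        r, text = np_ratio(n, p)
        assert r == expected_r
        assert text == expected_text

    def test_zero_phosphate_rejected(self):
        with pytest.raises(ValueError):
            np_ratio(10.0, 0.0)


class TestCompareEndpoints:
    def test_identical_groups(self):
        inc, p = compare_endpoints([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert inc == 0.0 and p == 1.0

    def test_constructed_effect_size(self, rng):
        a = 1.0 + rng.normal(0, 1e-4, 30)
        b = 1.157 + rng.normal(0, 1e-4, 30)
        inc, p = compare_endpoints(a, b)
        assert inc == pytest.approx(15.7, abs=0.1)
        assert p < 0.05

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            _, p = compare_endpoints(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_endpoints([1.0], [1.0, 2.0])
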