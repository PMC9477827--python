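"""Simulator: Poisson loading, dose-dependent growth, optics, trace I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropscreen.gradient_design import design_1d_program
from dropscreen.presets import nitrate_1d_plan, nitrate_growth_params
from dropscreen.synthetic_trace import (
    CHANNELS,
    EffectorResponse,
    GrowthParams,
    OpticsModel,
    SensorTrace,
    TraceSchemaError,
    TruthDroplet,
    TruthSet,
    grow,
    read_trace,
    render_trace,
    sample_initial_cells,
    simulate_run,
    write_trace,
)


class TestInitialCells:
    def test_mean_load_matches_poisson_expectation(self, rng):
        draws = [sample_initial_cells(500.0, 10.0, rng) for _ in range(10_000)]
        # mean 5000, SE = sqrt(5000/1e4) ~ 0.71; allow 3 SE
        assert np.mean(draws) == pytest.approx(5000.0, abs=3 * np.sqrt(5000 / 1e4))

    def test_zero_density_yields_zero(self, rng):
        assert sample_initial_cells(500.0, 0.0, rng) == 0

    def test_deterministic_under_seed(self):
        a = [sample_initial_cells(500, 10, np.random.default_rng(7)) for _ in range(5)]
        b = [sample_initial_cells(500, 10, np.random.default_rng(7)) for _ in range(5)]
        assert a == b

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            sample_initial_cells(0.0, 10.0, rng)
        with pytest.raises(ValueError):
            sample_initial_cells(500.0, -1.0, rng)


class TestGrowth:
    def make_params(self, **kw):
        defaults = dict(
            max_rate_per_day=1.0,
            carrying_capacity_per_nl=1e12,  # effectively exponential
            lag_days=0.0,
            responses={"X": EffectorResponse(2.0, 40.0, 0.25)},
        )
        defaults.update(kw)
        return GrowthParams(**defaults)

    def test_monod_midpoint_halves_rate(self):
        # at c = K the Monod term is 1/2 and inhibition ~1 (threshold >> K)
        params_sat = self.make_params(
            responses={"X": EffectorResponse(2.0, 1e9, 1e-6)}
        )
        full = grow(100, {"X": 1e6}, 1, params_sat)
        half = grow(100, {"X": 2.0}, 1, params_sat)
        assert np.log(half / 100) == pytest.approx(0.5 * np.log(full / 100), rel=0.01)

    def test_strong_inhibition_suppresses_growth(self):
        params = self.make_params()
        assert grow(5000, {"X": 400.0}, 7, params) == pytest.approx(5000, rel=1e-3)

    def test_response_is_unimodal_between_K_and_threshold(self):
        params = self.make_params(carrying_capacity_per_nl=2000.0)
        cs = np.linspace(0.01, 80, 400)
        y = [grow(5000, {"X": c}, 7, params) for c in cs]
        c_star = cs[int(np.argmax(y))]
        assert 2.0 < c_star < 40.0  # between half-saturation and threshold

    @settings(max_examples=40, deadline=None)
    @given(
        day=st.floats(0, 7),
        c=st.floats(0, 100),
        cells0=st.integers(1, 10_000),
    )
    def test_monotone_in_time_and_bounded(self, day, c, cells0):
        params = self.make_params(carrying_capacity_per_nl=500.0)
        earlier = grow(cells0, {"X": c}, day * 0.5, params)
        later = grow(cells0, {"X": c}, day, params)
        assert later >= earlier - 1e-9
        assert later <= 500.0 * 500.0 + 1e-6

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            grow(100, {"X": -1.0}, 1, self.make_params())

    def test_effector_response_validation(self):
        with pytest.raises(ValueError, match="exceed half_saturation"):
            EffectorResponse(10.0, 5.0, 1.0)


def make_truth(cells_by_droplet, volume_nl=500.0, period_min=1 / 128):
    droplets = [
        TruthDroplet(
            index=i,
            volume_nl=volume_nl,
            concentrations_mM={},
            percent_of_max={},
            cells_t=np.full(8, float(c)),
            generation_time_min=(i + 0.5) * period_min,
        )
        for i, c in enumerate(cells_by_droplet)
    ]
    return TruthSet(droplets=droplets)


class TestRenderTrace:
    def test_pulse_width_matches_plug_geometry(self, plan_1d, optics_clean):
        # 500 nL in a 1.0 mm tube at 200 uL/min -> ~0.15 s -> ~37.5 samples
        assert optics_clean.passage_time_s(500.0, 200.0) == pytest.approx(0.15, rel=0.01)
        truth = make_truth([0, 0, 0])
        trace = render_trace(truth, 0, optics_clean, plan_1d)
        above = trace.channels["a750"] > optics_clean.carrier_level["a750"] + 1e-9
        widths = np.diff(np.flatnonzero(np.diff(above.astype(int))))[::2]
        assert all(abs(w - 37.5) <= 1 for w in widths)

    def test_blank_droplet_height_is_offset_exactly(self, plan_1d, optics_clean):
        truth = make_truth([0])
        trace = render_trace(truth, 0, optics_clean, plan_1d)
        for ch in CHANNELS:
            peak = trace.channels[ch].max()
            expected = optics_clean.carrier_level[ch] + optics_clean.droplet_offset[ch]
            assert peak == pytest.approx(expected, abs=1e-12)

    def test_height_linear_in_cell_density(self, plan_1d, optics_clean):
        t1 = render_trace(make_truth([1000]), 0, optics_clean, plan_1d)
        t2 = render_trace(make_truth([2000]), 0, optics_clean, plan_1d)
        for ch in CHANNELS:
            base = optics_clean.carrier_level[ch] + optics_clean.droplet_offset[ch]
            h1 = t1.channels[ch].max() - base
            h2 = t2.channels[ch].max() - base
            assert h2 == pytest.approx(2 * h1, rel=1e-9)

    def test_overlapping_droplets_rejected(self, plan_1d, optics_clean):
        truth = make_truth([0, 0], period_min=0.15 / 60 / 2)  # closer than a pulse
        with pytest.raises(ValueError, match="overlap"):
            render_trace(truth, 0, optics_clean, plan_1d)


class TestSimulateRun:
    def test_truth_and_pulse_counts_conserved_across_days(
        self, plan_1d, program_1d, growth_1d, optics_clean
    ):
        truth, traces = simulate_run(
            plan_1d, program_1d, growth_1d, optics_clean,
            seed=3, measure_days=(0, 3, 7), noise_free=True,
        )
        assert len(truth) == 440
        for day, trace in traces.items():
            above = trace.channels["a750"] > optics_clean.carrier_level["a750"] + 1e-9
            n_pulses = int((np.diff(above.astype(int)) == 1).sum())
            assert n_pulses == 440

    def test_daily_measurement_yields_eight_traces(
        self, plan_1d, program_1d, growth_1d, optics_clean
    ):
        plan = nitrate_1d_plan(n_droplets=16)
        program = design_1d_program(plan)
        _, traces = simulate_run(
            plan, program, growth_1d, optics_clean, seed=4, noise_free=True
        )
        assert sorted(traces) == list(range(8))

    def test_deterministic_under_seed(self, plan_1d, growth_1d, optics_default):
        plan = nitrate_1d_plan(n_droplets=32)
        program = design_1d_program(plan)
        runs = [
            simulate_run(plan, program, growth_1d, optics_default, seed=5,
                         measure_days=(0, 7))
            for _ in range(2)
        ]
        for ch in CHANNELS:
            assert np.array_equal(
                runs[0][1][7].channels[ch], runs[1][1][7].channels[ch]
            )
        assert np.array_equal(
            runs[0][0].to_frame().to_numpy(), runs[1][0].to_frame().to_numpy()
        )

    def test_invalid_measure_days(self, plan_1d, program_1d, growth_1d, optics_clean):
        with pytest.raises(ValueError):
            simulate_run(plan_1d, program_1d, growth_1d, optics_clean,
                         seed=1, measure_days=(0, 9))


class TestTraceIO:
    def test_write_read_roundtrip_is_lossless(self, tmp_path, rng):
        n = 500
        trace = SensorTrace(
            sampling_rate_hz=250.0,
            channels={ch: rng.normal(size=n) for ch in CHANNELS},
            metadata={"day": 3, "coil": "A"},
        )
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert back.sampling_rate_hz == 250.0
        assert back.metadata["day"] == 3
        for ch in CHANNELS:
            np.testing.assert_array_equal(back.channels[ch], trace.channels[ch])

    def test_missing_channel_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,a470,a505,a615,a750\n0.0,1,1,1,1\n")
        (tmp_path / "bad.csv.meta.json").write_text('{"sampling_rate_hz": 250}')
        with pytest.raises(TraceSchemaError, match="f405_425"):
            read_trace(path)

    def test_missing_sidecar_is_schema_error(self, tmp_path):
        path = tmp_path / "orphan.csv"
        path.write_text("time_s,a470,a505,a615,a750,f405_425\n0.0,1,1,1,1,1\n")
        with pytest.raises(TraceSchemaError, match="sidecar"):
            read_trace(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text(
            "time_s,a470,a505,a615,a750,f405_425\n0.0,1,1,1,1,1\n0.004,1,1\n"
        )
        (tmp_path / "ragged.csv.meta.json").write_text('{"sampling_rate_hz": 250}')
        with pytest.raises(TraceSchemaError):
            read_trace(path)
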