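"""Protocol bookkeeping, replicate aggregation, phantom check, significance."""

import numpy as np
import pytest

from biospeckle.ba import BACurve, ba_curve
from biospeckle.errors import (
    ConfigError,
    DataError,
    GroupingError,
    NormalizationError,
    SampleSizeError,
)
from biospeckle.protocol import (
    ProtocolSchedule,
    aggregate_curves,
    average_curves_by_plant,
    compare_to_control,
    expand_schedule,
    normalize_ba,
    phantom_noise_floor,
)
from biospeckle.synthetic import (
    DecorrelationModel,
    derive_seed,
    render_dark_frames,
    simulate_ba_matrix,
    simulate_sequence,
)


class TestExpandSchedule:
    def test_fifteen_records_per_plant_per_condition(self):
        sched = ProtocolSchedule(conditions=("control",))
        records = expand_schedule(sched, n_plants=1)
        assert len(records) == 15
        assert sched.records_per_plant_condition == 15

    def test_count_conservation(self):
        sched = ProtocolSchedule()  # 4 conditions
        records = expand_schedule(sched, n_plants=6)
        assert len(records) == 6 * 4 * 15

    def test_timestamps_strictly_increasing_within_plant(self):
        records = expand_schedule(ProtocolSchedule(), n_plants=2)
        for plant in (1, 2):
            ts = [r.start_s for r in records if r.plant_id == plant]
            assert np.all(np.diff(ts) > 0)

    def test_first_record_after_blank(self):
        records = expand_schedule(ProtocolSchedule(), n_plants=1)
        assert records[0].start_s == 600.0

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolSchedule(blank_s=0)


def _curve(ba_values, fps=15.0, **meta):
    lags = np.arange(1, len(ba_values) + 1)
    return BACurve(lags=lags, times=lags / fps, ba=np.asarray(ba_values, float), meta=meta)


class TestAggregateCurves:
    def test_identical_replicates_zero_sem(self):
        curves = [_curve(np.full(30, 0.5), condition="c", age_dap=30) for _ in range(4)]
        agg = aggregate_curves(curves)[("c", 30)]
        assert np.allclose(agg.mean_ba, 0.5)
        assert np.allclose(agg.sem, 0.0)
        assert agg.n == 4

    def test_hand_arithmetic_two_replicates(self):
        curves = [_curve([0.4], condition="c", age_dap=30),
                  _curve([0.6], condition="c", age_dap=30)]
        agg = aggregate_curves(curves)[("c", 30)]
        assert agg.mean_ba[0] == pytest.approx(0.5)
        assert agg.sem[0] == pytest.approx(0.1)

    def test_mixed_time_axes_rejected(self):
        curves = [_curve(np.zeros(10) + 0.1, fps=15, condition="c", age_dap=30),
                  _curve(np.zeros(10) + 0.1, fps=10, condition="c", age_dap=30)]
        with pytest.raises(GroupingError):
            aggregate_curves(curves)

    def test_simulated_replicates_within_three_sem_of_closed_form(self):
        rho = 0.95
        mat = simulate_ba_matrix(12, rho, 16, shape=(64, 64),
                                 speckle_size_px=3.0, seed=31)
        curves = [_curve(mat[i], condition="control", age_dap=30, plant_id=i)
                  for i in range(12)]
        agg = aggregate_curves(curves)[("control", 30)]
        k = np.arange(1, 16)
        expected = 1 - rho ** (2 * k)
        assert np.all(np.abs(agg.mean_ba - expected) <= 3 * agg.sem + 0.01)

    def test_average_by_plant_collapses_records(self):
        curves = [
            _curve(np.full(10, 0.2 + 0.1 * rec), condition="c", age_dap=30,
                   plant_id=p, acquisition=rec)
            for p in (1, 2) for rec in (0, 1, 2)
        ]
        plant_curves = average_curves_by_plant(curves)
        assert len(plant_curves) == 2
        assert np.allclose(plant_curves[0].ba, 0.3)
        assert plant_curves[0].meta["n_records"] == 3


class TestPhantomNoiseFloor:
    @pytest.fixture(scope="class")
    @staticmethod
    def phantom_setup(geometry, camera):
        seqs = [
            simulate_sequence(geometry, camera, DecorrelationModel(1.0, "phantom"),
                              fps=15, duration_s=3.0, seed=derive_seed(5, "ph", i),
                              shape=(64, 64))
            for i in range(6)
        ]
        dark = render_dark_frames(camera, (64, 64), 50, seed=derive_seed(5, "dark"))
        return dark, seqs

    def test_simulated_phantom_within_noise(self, phantom_setup):
        dark, seqs = phantom_setup
        curves = [ba_curve(s) for s in seqs]
        verdict = phantom_noise_floor(dark, seqs[0], curves, seed=1)
        assert verdict.within_noise
        assert verdict.max_phantom_ba < 0.01

    def test_active_leaf_exceeds_noise(self, phantom_setup, geometry, camera):
        dark, seqs = phantom_setup
        leaf = simulate_sequence(geometry, camera, DecorrelationModel(0.98, "leaf"),
                                 fps=15, duration_s=3.0, seed=77, shape=(64, 64))
        verdict = phantom_noise_floor(dark, seqs[0], [ba_curve(leaf)], seed=1)
        assert not verdict.within_noise

    def test_zero_noise_static_phantom_within_noise(self, geometry):
        from biospeckle.synthetic import CameraModel

        quiet = CameraModel(bit_depth=16, readout_noise_e=0.0)
        seq = simulate_sequence(geometry, quiet, DecorrelationModel(1.0, "phantom"),
                                fps=15, duration_s=1.0, seed=3, shape=(64, 64))
        dark = render_dark_frames(quiet, (64, 64), 10, seed=4)
        verdict = phantom_noise_floor(dark, seq, seed=1)
        assert verdict.within_noise
        assert verdict.max_phantom_ba == pytest.approx(0.0, abs=1e-12)

    def test_missing_dark_frames_rejected(self, phantom_setup):
        _, seqs = phantom_setup
        with pytest.raises(DataError):
            phantom_noise_floor(None, seqs[0])


class TestCompareToControl:
    def test_identical_groups(self):
        res = compare_to_control([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_textbook_pooled_formula(self):
        """Pooled-variance t computed from the explicit formula."""
        x = np.array([0.9, 0.85, 0.88])
        y = np.array([0.5, 0.55, 0.52])
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        res = compare_to_control(x, y)
        assert res.t == pytest.approx(t_expected, rel=1e-12)
        assert res.p < 0.05 and res.significant

    def test_welch_variant_differs_with_unequal_variances(self):
        x = [1.0, 1.1, 0.9, 1.05]
        y = [0.2, 0.9, 1.6, 0.1]
        pooled = compare_to_control(x, y)
        welch = compare_to_control(x, y, equal_var=False)
        assert pooled.df != welch.df

    def test_too_small_group_rejected(self):
        with pytest.raises(SampleSizeError):
            compare_to_control([1.0], [1.0, 2.0])


class TestNormalizeBA:
    def test_condition_equal_control_gives_one(self):
        vals = {1: 0.8, 2: 0.7, 3: 0.9}
        nb = normalize_ba(vals, vals, condition="x", age_dap=30)
        assert nb.value == pytest.approx(1.0)
        assert not nb.ttest.significant

    def test_half_control(self):
        cond = {1: 0.38, 2: 0.40, 3: 0.42}
        ctrl = {1: 0.76, 2: 0.80, 3: 0.84}
        assert normalize_ba(cond, ctrl).value == pytest.approx(0.5)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_ba({1: 0.4, 2: 0.4}, {1: 0.0, 2: 0.8})

    def test_disjoint_plants_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_ba({1: 0.4}, {2: 0.8})

    def test_aggregate_then_normalize_commutes_approximately(self):
        """Mean of per-plant ratios vs ratio of means: equal within
        Monte-Carlo tolerance when plant-to-plant spread is modest."""
        rng = np.random.default_rng(8)
        ctrl = {p: 0.27 * (1 + 0.05 * rng.standard_normal()) for p in range(6)}
        cond = {p: 0.10 * (1 + 0.05 * rng.standard_normal()) for p in range(6)}
        per_plant = normalize_ba(cond, ctrl).value
        pooled = np.mean(list(cond.values())) / np.mean(list(ctrl.values()))
        assert per_plant == pytest.approx(pooled, abs=0.02)
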