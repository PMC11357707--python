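"""Thermometry sampling, extent measurement, and validation statistics."""

import numpy as np
import pytest

import dmwasim as d
from dmwasim import refdata
from dmwasim.verification import uniform_block

from conftest import make_static_field


def _pose_through_center():
    return d.ApplicatorPose(
        tip_position=(0.0105, 0.0205, 0.0205),
        axis_direction=(-1.0, 0.0, 0.0),
        radiation_direction=(0.0, 1.0, 0.0),
        active_length=0.010,
        shaft_length=0.030,
    )


class TestSampleProbe:
    def test_voxel_center_returns_nodal_value(self):
        grid = uniform_block("muscle", (8, 8, 8))
        vals = np.arange(512, dtype=float).reshape(8, 8, 8)
        field = make_static_field(grid, vals)
        pos = tuple(np.asarray(grid.origin) + (np.array([3, 4, 5]) + 0.5) * grid.spacing)
        log = d.sample_probe(field, d.ProbeSpec("p", pos, 0.0))
        assert log.temperatures[-1] == vals[3, 4, 5]

    def test_midpoint_is_arithmetic_mean(self):
        grid = uniform_block("muscle", (8, 8, 8))
        vals = np.arange(512, dtype=float).reshape(8, 8, 8)
        field = make_static_field(grid, vals)
        pos = tuple(np.asarray(grid.origin) + (np.array([3.5, 4, 5]) + 0.5) * grid.spacing)
        log = d.sample_probe(field, d.ProbeSpec("p", pos, 0.0))
        assert log.temperatures[-1] == pytest.approx(
            (vals[3, 4, 5] + vals[4, 4, 5]) / 2
        )

    def test_affine_field_reproduced_exactly(self):
        grid = uniform_block("muscle", (10, 10, 10))
        x, y, z = grid.centers()
        vals = np.broadcast_to(5.0 + 300.0 * y, grid.shape)
        field = make_static_field(grid, vals)
        pos = (0.0047, 0.0061, 0.0032)
        log = d.sample_probe(field, d.ProbeSpec("p", pos, 0.0))
        assert log.temperatures[-1] == pytest.approx(5.0 + 300.0 * pos[1], abs=1e-12)

    def test_outside_domain_rejected(self):
        grid = uniform_block("muscle", (8, 8, 8))
        field = make_static_field(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError, match="outside"):
            d.sample_probe(field, d.ProbeSpec("p", (1.0, 0.0, 0.0), 0.0))


class TestDeltaT:
    @pytest.mark.parametrize(
        "t_i,t_f,expected",
        [(20.0, 81.4, 61.4), (37.0, 43.8, 6.8), (30.0, 39.6, 9.6)],
    )
    def test_reference_rows(self, t_i, t_f, expected):
        log = d.SensorLog("T1", (0, 0, 0), [0.0, 210.0], [t_i, t_f])
        assert d.delta_T(log) == pytest.approx((t_i, t_f, expected))

    def test_constant_log(self):
        log = d.SensorLog("T1", (0, 0, 0), [0.0, 1.0, 2.0], [25.0, 25.0, 25.0])
        assert d.delta_T(log)[2] == 0.0


class TestPercentDiff:
    @pytest.mark.parametrize(
        "exp,sim,expected",
        [(33.6, 31.3, -7), (33.5, 31.9, -5), (63.2, 61.4, -3),
         (15.0, 13.4, -11), (10.8, 6.8, -37), (32.3, 21.8, -33)],
    )
    def test_reference_table(self, exp, sim, expected):
        assert d.percent_diff(exp, sim) == expected

    def test_identity_and_half_rounding(self):
        assert d.percent_diff(42.0, 42.0) == 0
        assert d.percent_diff(10.0, 10.25) == 3   # +2.5 -> away from zero
        assert d.percent_diff(10.0, 9.75) == -3   # -2.5 -> away from zero

    def test_zero_experiment_rejected(self):
        with pytest.raises(ValueError):
            d.percent_diff(0.0, 1.0)


class TestAblationExtent:
    def _radial_field(self, peak, iso, radius):
        grid = uniform_block("cancellous bone", (41, 41, 41))
        pose = _pose_through_center()
        x, y, z = grid.centers()
        c = pose.active_center
        dist = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        vals = iso + (peak - iso) * (1.0 - dist / radius)  # == iso at r = radius
        return grid, pose, make_static_field(grid, vals)

    def test_uniform_cold_field_gives_zero_extent(self):
        grid = uniform_block("cancellous bone", (16, 16, 16))
        field = make_static_field(grid, np.full(grid.shape, 30.0))
        ext = d.ablation_extent(field, 55.0, _pose_through_center())
        assert ext.depth_D == 0.0 and ext.length_L == 0.0

    def test_spherical_region_dimensions(self):
        a = 6e-3
        grid, pose, field = self._radial_field(peak=90.0, iso=60.0, radius=a)
        ext = d.ablation_extent(field, 60.0, pose)
        assert ext.depth_D == pytest.approx(a, abs=grid.spacing / 2)
        assert ext.length_L == pytest.approx(2 * a, abs=grid.spacing)

    def test_extent_nested_in_iso_temperature(self):
        _, pose, field = self._radial_field(peak=90.0, iso=55.0, radius=7e-3)
        e55 = d.ablation_extent(field, 55.0, pose)
        e60 = d.ablation_extent(field, 60.0, pose)
        assert e55.depth_D >= e60.depth_D
        assert e55.length_L >= e60.length_L


class TestSummaries:
    def _record(self, final, cond=(80.0, 3.5, 20.0)):
        log = d.SensorLog("T1", (0, 0, 0), [0.0, 210.0], [20.0, final])
        return d.ReplicateRecord(condition=cond, logs={"T1": log})

    def test_identical_replicates_have_zero_std(self):
        out = d.summarize_replicates([self._record(50.0), self._record(50.0)])
        assert out["T1_final_C_std"].iloc[0] == 0.0

    def test_three_value_mean_and_sample_std(self):
        out = d.summarize_replicates(
            [self._record(v) for v in (10.0, 12.0, 14.0)]
        )
        assert out["T1_final_C_mean"].iloc[0] == pytest.approx(12.0)
        assert out["T1_final_C_std"].iloc[0] == pytest.approx(2.0)  # n-1

    def test_single_replicate_flags_std_unavailable(self):
        out = d.summarize_replicates([self._record(50.0)])
        assert not out["std_available"].iloc[0]
        assert np.isnan(out["T1_final_C_std"].iloc[0])

    def test_permutation_invariance(self):
        vals = [11.0, 17.0, 23.0, 29.0]
        a = d.summarize_replicates([self._record(v) for v in vals])
        b = d.summarize_replicates([self._record(v) for v in reversed(vals)])
        for col in ("T1_final_C_mean", "T1_final_C_std"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0])


class TestComparisonTable:
    def test_reference_inputs_reproduce_published_percentages(self):
        rows = d.build_comparison_table(
            refdata.COMPARISON_EXPERIMENT_DT, refdata.COMPARISON_SIMULATION_DT
        )
        assert len(rows) == 6
        for row in rows:
            expected = refdata.COMPARISON_PERCENT_DIFF[row.condition][row.channel]
            assert row.percent_diff == expected

    def test_forward_channel_agreement_band(self):
        rows = d.build_comparison_table(
            refdata.COMPARISON_EXPERIMENT_DT, refdata.COMPARISON_SIMULATION_DT
        )
        t1 = [abs(r.percent_diff) for r in rows if r.channel == "T1"]
        assert all(3 <= v <= 7 for v in t1)

    def test_equal_inputs_give_zero_differences(self):
        rows = d.build_comparison_table(
            refdata.COMPARISON_EXPERIMENT_DT, refdata.COMPARISON_EXPERIMENT_DT
        )
        assert all(r.percent_diff == 0 for r in rows)

    def test_unmatched_condition_skipped_with_warning(self):
        exp = {(80.0, 3.5, 20.0): {"T1": 33.6}, (999.0, 1.0, 20.0): {"T1": 10.0}}
        sim = {(80.0, 3.5, 20.0): {"T1": 31.3}}
        with pytest.warns(UserWarning, match="missing"):
            rows = d.build_comparison_table(exp, sim)
        assert len(rows) == 1


def test_sensor_log_csv_round_trip(tmp_path):
    logs = [
        d.SensorLog("T1", (0, 0, 0), [0.0, 1.0, 2.0], [20.0, 30.0, 40.0]),
        d.SensorLog("T2", (0, 0, 0), [0.0, 1.0, 2.0], [20.0, 22.0, 24.0]),
    ]
    path = tmp_path / "logs.csv"
    d.write_sensor_logs(path, logs)
    loaded = d.read_sensor_logs(path)
    assert set(loaded) == {"T1", "T2"}
    np.testing.assert_allclose(loaded["T1"].temperatures, [20.0, 30.0, 40.0])
    assert loaded["T1"].provenance == "measured"


def test_sensor_log_validation():
    with pytest.raises(ValueError):
        d.SensorLog("T1", (0, 0, 0), [1.0, 2.0], [20.0, 21.0])  # no t=0
    with pytest.raises(ValueError):
        d.SensorLog("T1", (0, 0, 0), [0.0, 0.0], [20.0, 21.0])  # not increasing
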