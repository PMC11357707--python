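"""Virtual thermometry, ablation-extent measurement, and validation statistics.

This module turns temperature fields into the quantities reported for the
ex vivo study: per-channel sensor logs (T1 forward, T2 backward), initial /
final / delta temperatures, the isothermal-contour ablation extent (radial
depth D and axial length L), per-condition replicate summaries (mean +/- SD,
n-1 denominator), and the signed integer percent difference between
experimental and simulated temperature changes,

    percent_diff = round_half_away( 100 * (dT_sim - dT_exp) / dT_exp ).

A simulation that under-predicts the measured change is negative by this
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .bioheat import TemperatureField
from .phantom import ApplicatorPose, ProbeSpec

__all__ = [
    "SensorLog",
    "AblationExtent",
    "ComparisonRow",
    "ReplicateRecord",
    "sample_probe",
    "delta_T",
    "percent_diff",
    "ablation_extent",
    "summarize_replicates",
    "build_comparison_table",
    "write_sensor_logs",
    "read_sensor_logs",
]

Condition = Tuple[float, float, float]  # (power W, duration min, T_i degC)


@dataclass
class SensorLog:
    """One thermometry channel: (time s, temperature degC) series."""

    channel: str
    nominal_position: Tuple[float, float, float]
    times: np.ndarray
    temperatures: np.ndarray
    provenance: str = "simulated"  # simulated | synthetic | measured

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.temperatures = np.asarray(self.temperatures, float)
        if self.times.shape != self.temperatures.shape or self.times.ndim != 1:
            raise ValueError("times and temperatures must be equal-length 1-D")
        if len(self.times) == 0:
            raise ValueError("empty sensor log")
        if self.times[0] != 0.0:
            raise ValueError("sensor log must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.provenance not in ("simulated", "synthetic", "measured"):
            raise ValueError("provenance must be simulated|synthetic|measured")

    @property
    def final_temperature(self) -> float:
        return float(self.temperatures[-1])


@dataclass(frozen=True)
class AblationExtent:
    """Extent of the iso-temperature region: radial depth D along the
    forward direction and axial length L along the shaft."""

    depth_D: float
    length_L: float
    iso_temperature: float

    def __post_init__(self) -> None:
        if self.depth_D < 0 or self.length_L < 0:
            raise ValueError("extents must be >= 0")


@dataclass(frozen=True)
class ComparisonRow:
    """One condition/channel entry of the experiment-vs-simulation table."""

    condition: Condition
    channel: str
    experiment_dT: float
    simulation_dT: float

    @property
    def percent_diff(self) -> int:
        return percent_diff(self.experiment_dT, self.simulation_dT)


def sample_probe(field: TemperatureField, probe: ProbeSpec) -> SensorLog:
    """Trilinear interpolation of the field at the probe position for every
    stored time.  Rejects positions outside the voxel-center hull."""
    grid = field.grid
    p = np.asarray(probe.position, float)
    f = (p - np.asarray(grid.origin)) / grid.spacing - 0.5
    if np.any(f < 0) or np.any(f > np.asarray(grid.shape) - 1):
        raise ValueError(
            f"probe {probe.name!r} at {probe.position} outside the "
            "interpolation domain"
        )
    i0 = np.minimum(np.floor(f).astype(int), np.asarray(grid.shape) - 2)
    w = f - i0
    vals = np.zeros(len(field.times))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                weight = (
                    (w[0] if dx else 1 - w[0])
                    * (w[1] if dy else 1 - w[1])
                    * (w[2] if dz else 1 - w[2])
                )
                vals += weight * field.values[:, i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return SensorLog(
        channel=probe.name,
        nominal_position=tuple(p),
        times=field.times.copy(),
        temperatures=vals,
        provenance="simulated",
    )


def delta_T(log: SensorLog) -> Tuple[float, float, float]:
    """(T_initial, T_final, dT): first sample, last sample, difference."""
    t_i = float(log.temperatures[0])
    t_f = float(log.temperatures[-1])
    return t_i, t_f, t_f - t_i


def percent_diff(experiment_dT: float, simulation_dT: float) -> int:
    """Signed integer percent difference of simulated vs experimental dT.

    ``100 * (sim - exp) / exp`` rounded half away from zero.  Negative when
    the simulation under-predicts the experiment.
    """
    if experiment_dT == 0:
        raise ValueError("experiment dT must be nonzero")
    x = 100.0 * (simulation_dT - experiment_dT) / experiment_dT
    return int(math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5))


def _require_axis_aligned(v: np.ndarray) -> Tuple[int, float]:
    axis = int(np.argmax(np.abs(v)))
    sign = math.copysign(1.0, v[axis])
    if not np.isclose(abs(v[axis]), 1.0):
        raise NotImplementedError(
            "ablation_extent supports grid-axis-aligned applicator poses only"
        )
    return axis, sign


def ablation_extent(
    field: TemperatureField,
    iso_temperature: float,
    pose: ApplicatorPose,
) -> AblationExtent:
    """Measure the final-time iso-temperature region.

    ``depth_D``: maximum distance from the shaft axis along the forward
    direction, within the cross-sectional plane through the center of the
    radiating zone, of the region with ``T >= iso_temperature``.
    ``length_L``: extent of that region along the shaft axis (anywhere in the
    grid).  Both refined to sub-voxel precision by linear interpolation
    across the crossing face; an empty region gives zeros.
    """
    grid = field.grid
    T = field.final()
    ax_axis, _ = _require_axis_aligned(pose.axis)
    f_axis, f_sign = _require_axis_aligned(pose.forward)

    axes = grid.axes()
    hot = T >= iso_temperature
    if not hot.any():
        return AblationExtent(0.0, 0.0, iso_temperature)

    c = pose.active_center
    # central cross-sectional plane: voxel layer nearest the active center
    i_plane = int(np.clip(
        round((c[ax_axis] - grid.origin[ax_axis]) / grid.spacing - 0.5),
        0, grid.shape[ax_axis] - 1,
    ))
    plane = np.take(hot, i_plane, axis=ax_axis)
    T_plane = np.take(T, i_plane, axis=ax_axis)

    depth = 0.0
    if plane.any():
        # signed distance of each in-plane voxel center along +forward
        rem_axes = [d for d in range(3) if d != ax_axis]
        coords = np.meshgrid(*(axes[d] for d in rem_axes), indexing="ij")
        f_pos = rem_axes.index(f_axis)
        dist = f_sign * (coords[f_pos] - c[f_axis])
        dist_hot = np.where(plane, dist, -np.inf)
        flat = int(np.argmax(dist_hot))
        ij = np.unravel_index(flat, plane.shape)
        depth = float(dist_hot[ij])
        # sub-voxel refinement toward the next voxel along +forward
        nxt = list(ij)
        step = 1 if f_sign > 0 else -1
        nxt[f_pos] += step
        if 0 <= nxt[f_pos] < plane.shape[f_pos]:
            t_here = float(T_plane[ij])
            t_next = float(T_plane[tuple(nxt)])
            if t_next < iso_temperature and t_here > t_next:
                frac = (t_here - iso_temperature) / (t_here - t_next)
                depth += frac * grid.spacing
        depth = max(depth, 0.0)

    # axial length: extent of the hot region along the shaft axis
    proj = hot.any(axis=tuple(d for d in range(3) if d != ax_axis))
    idx = np.nonzero(proj)[0]
    lo_i, hi_i = int(idx[0]), int(idx[-1])
    length = (hi_i - lo_i) * grid.spacing
    # refine each end using the hottest voxel of the end layer
    T_ax_max = np.max(T, axis=tuple(d for d in range(3) if d != ax_axis))
    for end_i, out_i in ((lo_i, lo_i - 1), (hi_i, hi_i + 1)):
        if 0 <= out_i < grid.shape[ax_axis]:
            t_here, t_next = float(T_ax_max[end_i]), float(T_ax_max[out_i])
            if t_next < iso_temperature and t_here > t_next:
                length += grid.spacing * (t_here - iso_temperature) / (t_here - t_next)
    return AblationExtent(depth, length, iso_temperature)


@dataclass
class ReplicateRecord:
    """One experimental or synthetic replicate of one condition."""

    condition: Condition
    logs: Mapping[str, SensorLog]
    extent: Optional[AblationExtent] = None
    placements: Mapping[str, float] = field(default_factory=dict)  # channel -> m


def summarize_replicates(records: Sequence[ReplicateRecord]) -> pd.DataFrame:
    """Per-condition mean +/- sample SD (n-1) of extents, per-channel initial
    / final / delta temperatures, and placement distances.

    Single-replicate conditions report the mean with SD flagged unavailable
    (NaN, ``std_available = False``).
    """
    if len(records) == 0:
        raise ValueError("no replicates to summarize")
    rows = []
    for rec in records:
        row: Dict[str, float] = {"condition": rec.condition}
        if rec.extent is not None:
            row["D_mm"] = rec.extent.depth_D * 1e3
            row["L_mm"] = rec.extent.length_L * 1e3
        for ch, logx in rec.logs.items():
            t_i, t_f, dt = delta_T(logx)
            row[f"{ch}_initial_C"] = t_i
            row[f"{ch}_final_C"] = t_f
            row[f"{ch}_delta_C"] = dt
        for ch, dist in rec.placements.items():
            row[f"{ch}_distance_mm"] = dist * 1e3
        rows.append(row)
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("condition")
    mean = grouped.mean()
    std = grouped.std(ddof=1)  # sample SD; NaN for single replicates
    out = mean.join(std, lsuffix="_mean", rsuffix="_std")
    out["n"] = grouped.size()
    out["std_available"] = out["n"] >= 2
    return out


def build_comparison_table(
    experiment: Mapping[Condition, Mapping[str, float]],
    simulation: Mapping[Condition, Mapping[str, float]],
) -> List[ComparisonRow]:
    """Pair experimental and simulated temperature changes per condition and
    channel.  Conditions or channels present on only one side are reported
    (via warning) and skipped."""
    import warnings

    rows: List[ComparisonRow] = []
    for cond, exp_channels in experiment.items():
        if cond not in simulation:
            warnings.warn(f"condition {cond} missing from simulation; skipped",
                          stacklevel=2)
            continue
        for ch, exp_dt in exp_channels.items():
            if ch not in simulation[cond]:
                warnings.warn(
                    f"channel {ch!r} of condition {cond} missing from "
                    "simulation; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(ComparisonRow(cond, ch, exp_dt, simulation[cond][ch]))
    return rows


def write_sensor_logs(path: Union[str, Path], logs: Iterable[SensorLog]) -> None:
    """CSV with columns time_s, channel, temperature_C."""
    frames = [
        pd.DataFrame(
            {"time_s": lg.times, "channel": lg.channel,
             "temperature_C": lg.temperatures}
        )
        for lg in logs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensor_logs(path: Union[str, Path],
                     provenance: str = "measured") -> Dict[str, SensorLog]:
    frame = pd.read_csv(path)
    out: Dict[str, SensorLog] = {}
    for ch, sub in frame.groupby("channel"):
        sub = sub.sort_values("time_s")
        out[str(ch)] = SensorLog(
            channel=str(ch),
            nominal_position=(math.nan, math.nan, math.nan),
            times=sub["time_s"].to_numpy(),
            temperatures=sub["temperature_C"].to_numpy(),
            provenance=provenance,
        )
    return out
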