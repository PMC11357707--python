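"""Solver verification suite: closed-form and brute-force oracles.

Each function runs the production bioheat solver on a purpose-built problem
with an independent reference solution and returns the measured relative
error (dimensionless), so both the test suite and the reproduction script
can report them:

* :func:`adiabatic_heating_error` — uniform volumetric source, insulated
  homogeneous block: ``T(t) = T0 + q t / (rho c)`` exactly.
* :func:`slab_erfc_error` — semi-infinite homogeneous slab with a step
  surface temperature: ``T = T0 + (Ts - T0) erfc(x / (2 sqrt(kappa t)))``.
* :func:`energy_balance_error` — insulated block with a heterogeneous
  source: enthalpy rise must equal deposited energy.
* :func:`explicit_oracle_error` — implicit solve vs a brute-force explicit
  forward-Euler reference at dt = 1 ms on a small grid.
* :func:`probe_convergence_delta` — change in probe final temperatures when
  grid spacing and time step are halved in the full pipeline.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.special import erfc

from .bioheat import (
    AblationProtocol,
    BoundaryConditions,
    TemperatureField,
    simulate_protocol,
    solve_bioheat,
    standard_protocols,
)
from .em_source import DirectionalSourceParams, SARField
from .materials import load_default_library
from .phantom import AIR, APPLICATOR, LabelGrid

__all__ = [
    "uniform_block",
    "adiabatic_heating_error",
    "slab_erfc_error",
    "energy_balance_error",
    "explicit_oracle_error",
    "probe_convergence_delta",
]

_INSULATED = BoundaryConditions(convective_h=0.0, external_temperature=20.0,
                                applicator_temperature=30.0)


def uniform_block(tissue: str = "muscle", shape: Tuple[int, int, int] = (16, 16, 16),
                  spacing: float = 1e-3) -> LabelGrid:
    """Homogeneous block of one tissue class (no applicator placed)."""
    class_names = [AIR, APPLICATOR]
    if tissue in class_names:
        tid = class_names.index(tissue)
    else:
        class_names = class_names + [tissue]
        tid = 2
    ids = np.full(shape, tid, dtype=np.int8)
    return LabelGrid(origin=(0.0, 0.0, 0.0), spacing=spacing,
                     label_ids=ids, class_names=class_names)


def adiabatic_heating_error(duration: float = 100.0, q_w_per_m3: float = 5e5) -> float:
    """Max relative error vs the closed-form adiabatic linear rise."""
    lib = load_default_library()
    grid = uniform_block("muscle", (8, 8, 8))
    props = lib.lookup("muscle")
    sar = SARField(grid, np.full(grid.shape, q_w_per_m3 / props.density),
                   applied_power=float("nan"), absorbed_fraction=1.0)
    protocol = AblationProtocol(1.0, 1.0, duration, 20.0)
    field = solve_bioheat(grid, lib, sar, _INSULATED, protocol, max_dt=10.0)
    expected = 20.0 + q_w_per_m3 * duration / props.volumetric_heat_capacity
    return float(np.abs(field.final() - expected).max() / abs(expected - 20.0))


def slab_erfc_error(
    t_surface: float = 60.0,
    duration: float = 60.0,
    spacing: float = 0.5e-3,
    max_dt: float = 0.25,
    min_depth_voxels: int = 3,
) -> float:
    """Max relative error (on the temperature rise) vs the erfc solution.

    A 1-D slab is emulated by a long homogeneous bar, insulated laterally,
    with the first voxel layer labeled as applicator: its Dirichlet face sets
    the step surface temperature at x = 0.  Errors are evaluated at depths of
    at least ``min_depth_voxels`` voxels and within the region where the rise
    exceeds 1 % of the step (beyond that the reference itself is ~zero).
    """
    lib = load_default_library()
    nx = 64
    grid = uniform_block("muscle", (nx, 4, 4), spacing=spacing)
    grid.label_ids[0, :, :] = grid.class_names.index(APPLICATOR)
    grid.applicator_mask[0, :, :] = True

    props = lib.lookup("muscle")
    kappa = props.thermal_conductivity / props.volumetric_heat_capacity
    t0 = 20.0
    bc = BoundaryConditions(convective_h=0.0, external_temperature=t0,
                            applicator_temperature=t_surface)
    sar = SARField(grid, np.zeros(grid.shape), float("nan"), 1.0)
    protocol = AblationProtocol(1.0, 1.0, duration, t0)
    field = solve_bioheat(grid, lib, sar, bc, protocol, max_dt=max_dt)

    # the Dirichlet surface lies at the face between voxel 0 and voxel 1;
    # voxel i's center is (i - 1/2) * spacing deep from that face
    depth = (np.arange(1, nx) - 0.5) * spacing
    sim = field.final()[1:, 2, 2]
    ref = t0 + (t_surface - t0) * erfc(depth / (2.0 * math.sqrt(kappa * duration)))
    rise_ref = ref - t0
    mask = (np.arange(1, nx) >= 1 + min_depth_voxels - 1) & (
        rise_ref > 0.01 * (t_surface - t0)
    )
    rel = np.abs(sim - ref)[mask] / (t_surface - t0)
    return float(rel.max())


def energy_balance_error(duration: float = 120.0, seed: int = 0) -> float:
    """Relative enthalpy-vs-deposited-energy mismatch, insulated block."""
    lib = load_default_library()
    grid = uniform_block("cancellous bone", (12, 12, 12))
    rng = np.random.default_rng(seed)
    sar_vals = rng.uniform(0.0, 3e3, size=grid.shape)  # W/kg, heterogeneous
    sar = SARField(grid, sar_vals, float("nan"), 1.0)
    protocol = AblationProtocol(1.0, 1.0, duration, 25.0)
    field = solve_bioheat(grid, lib, sar, _INSULATED, protocol, max_dt=10.0)

    props = lib.lookup("cancellous bone")
    dv = grid.voxel_volume
    enthalpy = (props.volumetric_heat_capacity * (field.final() - 25.0) * dv).sum()
    deposited = (props.density * sar_vals * dv).sum() * duration
    return float(abs(enthalpy - deposited) / deposited)


def explicit_oracle_error(duration: float = 30.0, dt_explicit: float = 1e-3) -> float:
    """Implicit solver vs brute-force explicit reference on an 8x8x8 grid.

    The reference integrates the identical spatial operator with forward
    Euler at ``dt_explicit`` (far below the stability limit); returns the max
    relative difference of the final temperature rise.
    """
    from .bioheat import _build_system

    lib = load_default_library()
    grid = uniform_block("cancellous bone", (8, 8, 8))
    # mixed boundary: one applicator voxel layer + convection, to exercise
    # every term of the operator
    grid.label_ids[0, 0:2, 0:2] = grid.class_names.index(APPLICATOR)
    bc = BoundaryConditions(convective_h=10.0, external_temperature=20.0,
                            applicator_temperature=30.0)
    rng = np.random.default_rng(1)
    sar_vals = rng.uniform(0.0, 5e3, size=grid.shape)
    sar = SARField(grid, sar_vals, float("nan"), 1.0)
    t0 = 20.0
    protocol = AblationProtocol(1.0, 1.0, duration, t0)
    implicit = solve_bioheat(grid, lib, sar, bc, protocol, max_dt=1.0)

    solved, index, K, b, m = _build_system(grid, lib, bc)
    from .em_source import _per_voxel

    rho = _per_voxel(grid, lib, "density")[solved]
    q = rho * sar_vals[solved] * grid.voxel_volume
    n_steps = int(round(duration / dt_explicit))
    T = np.full(int(solved.sum()), t0)
    Kc = K.tocsr()
    for _ in range(n_steps):
        T = T + dt_explicit / m * (q + b - Kc @ T)
    ref = np.full(grid.shape, t0)
    ref[solved] = T
    rise_ref = np.abs(ref[solved] - t0).max()
    diff = np.abs(implicit.final()[solved] - ref[solved]).max()
    return float(diff / rise_ref)


def probe_convergence_delta(
    coarse_spacing: float = 1e-3,
    fine_spacing: float = 0.5e-3,
    params: DirectionalSourceParams = DirectionalSourceParams(),
) -> Dict[str, float]:
    """Relative change of T1/T2 final temperature rises when the grid spacing
    and the time step are halved in the full ablation pipeline."""
    protocol = standard_protocols()["80W_3.5min_20C"]
    out: Dict[str, float] = {}
    finals: Dict[float, Dict[str, float]] = {}
    for spacing, max_dt in ((coarse_spacing, 10.0), (fine_spacing, 5.0)):
        _, logs = simulate_protocol(
            params=params, protocol=protocol, spacing=spacing, max_dt=max_dt
        )
        finals[spacing] = {ch: lg.final_temperature for ch, lg in logs.items()}
    for ch in ("T1", "T2"):
        coarse = finals[coarse_spacing][ch] - protocol.initial_temperature
        fine = finals[fine_spacing][ch] - protocol.initial_temperature
        out[ch] = abs(fine - coarse) / abs(fine)
    return out
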