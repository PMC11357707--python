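"""Transient bioheat (heat-conduction) solver on the voxel phantom.

Solves the ex vivo form of the bioheat equation (no perfusion),

    rho * c * dT/dt = div( k * grad T ) + rho * SAR,

by a 7-point finite-volume discretization on the uniform voxel grid with

* harmonic-mean face conductivities across tissue interfaces,
* a Robin (convective) condition ``h * (T - T_ext)`` on every face between a
  tissue voxel and an air voxel and on tissue faces at the domain boundary
  (this realizes the ambient losses at the specimen surface),
* an isothermal Dirichlet condition on the water-cooled applicator shaft,
* backward-Euler (implicit, unconditionally stable) time stepping with a
  uniform step <= ``max_dt`` (default 10 s).

Air voxels are not part of the conduction solve: air acts on the tissue only
through the convective boundary, and its stored temperature stays at the
initial value.  A perfusion term exists in the interface
(``perfusion_w_per_m3K``) but is fixed at zero for every shipped protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .em_source import DirectionalSourceParams, SARField, synthesize_sar, _per_voxel
from .materials import MaterialLibrary, load_default_library
from .phantom import (
    AIR,
    APPLICATOR,
    ApplicatorPose,
    LabelGrid,
    PhantomSpec,
    ProbeSpec,
    build_phantom,
    default_pose,
    default_probes,
    place_applicator,
)

__all__ = [
    "BoundaryConditions",
    "AblationProtocol",
    "TemperatureField",
    "solve_bioheat",
    "simulate_protocol",
    "standard_protocols",
]

#: Direct sparse factorization is used up to this many unknowns, conjugate
#: gradients (Jacobi-preconditioned) beyond it.
_DIRECT_SOLVER_LIMIT = 120_000


@dataclass(frozen=True)
class BoundaryConditions:
    """Thermal boundary conditions of the ex vivo setup."""

    convective_h: float = 10.0          # W/m^2/degC at tissue-air faces
    external_temperature: float = 20.0  # degC ambient
    applicator_temperature: float = 30.0  # degC Dirichlet on the cooled shaft

    def __post_init__(self) -> None:
        if self.convective_h < 0:
            raise ValueError("convective_h must be >= 0")


@dataclass(frozen=True)
class AblationProtocol:
    """One ablation run: console power, nominal antenna power, duration,
    initial specimen temperature."""

    generator_setpoint: float
    nominal_applied_power: float
    duration: float             # s
    initial_temperature: float  # degC

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.generator_setpoint <= 0 or self.nominal_applied_power <= 0:
            raise ValueError("powers must be > 0")


def standard_protocols() -> Dict[str, AblationProtocol]:
    """The four ex vivo study conditions (nominal applied powers 40/60 W for
    80/120 W setpoints; durations 3.5 and 5 min; initial 20/30/37 degC)."""
    return {
        "80W_3.5min_20C": AblationProtocol(80.0, 40.0, 210.0, 20.0),
        "80W_3.5min_30C": AblationProtocol(80.0, 40.0, 210.0, 30.0),
        "80W_3.5min_37C": AblationProtocol(80.0, 40.0, 210.0, 37.0),
        "120W_5min_20C": AblationProtocol(120.0, 60.0, 300.0, 20.0),
    }


@dataclass
class TemperatureField:
    """Time-indexed per-voxel temperature (degC).

    ``values`` has shape ``(len(times),) + grid.shape``; ``times`` includes 0
    and the final time.  Applicator voxels are held at the Dirichlet
    temperature, air voxels at the initial temperature.
    """

    grid: LabelGrid
    times: np.ndarray
    values: np.ndarray

    def final(self) -> np.ndarray:
        return self.values[-1]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times),) + self.grid.shape:
            raise ValueError("values shape inconsistent with times/grid")


def _build_system(
    grid: LabelGrid,
    library: MaterialLibrary,
    bc: BoundaryConditions,
    perfusion_w_per_m3K: float = 0.0,
):
    """Assemble conduction matrix K (W/degC), boundary source b (W), lumped
    capacity m (J/degC) over the solved (tissue) voxels."""
    air_id = grid.class_names.index(AIR) if AIR in grid.class_names else -1
    app_id = grid.class_names.index(APPLICATOR) if APPLICATOR in grid.class_names else -1
    solved = (grid.label_ids != air_id) & (grid.label_ids != app_id)
    n = int(solved.sum())
    if n == 0:
        raise ValueError("no tissue voxels to solve")
    index = -np.ones(grid.shape, dtype=np.int64)
    index[solved] = np.arange(n)

    k = _per_voxel(grid, library, "thermal_conductivity")
    rho = _per_voxel(grid, library, "density")
    cp = _per_voxel(grid, library, "specific_heat")
    if not (np.isfinite(k[solved]).all() and np.isfinite(rho[solved]).all()
            and np.isfinite(cp[solved]).all()):
        raise ValueError("non-finite material properties on the grid")

    h = grid.spacing
    face_area = h * h
    vol = h**3
    m = rho[solved] * cp[solved] * vol  # J/degC per voxel

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    diag = np.zeros(n)
    b = np.zeros(n)

    is_air = grid.label_ids == air_id
    is_app = grid.label_ids == app_id

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)

        a_solved, b_solved = solved[sl_lo], solved[sl_hi]
        # interior tissue-tissue faces: harmonic-mean conductance
        both = a_solved & b_solved
        ka, kb = k[sl_lo][both], k[sl_hi][both]
        g = face_area * (2.0 * ka * kb / (ka + kb)) / h
        ia, ib = index[sl_lo][both], index[sl_hi][both]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-g, -g]
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)

        # tissue next to applicator: Dirichlet at the face (half-cell path)
        for t_sl, o_sl in ((sl_lo, sl_hi), (sl_hi, sl_lo)):
            t_mask = solved[t_sl] & is_app[o_sl]
            if t_mask.any():
                gi = face_area * k[t_sl][t_mask] / (h / 2.0)
                ii = index[t_sl][t_mask]
                np.add.at(diag, ii, gi)
                np.add.at(b, ii, gi * bc.applicator_temperature)
            # tissue next to air: Robin with film coefficient h
            a_mask = solved[t_sl] & is_air[o_sl]
            if a_mask.any() and bc.convective_h > 0:
                gr = face_area * bc.convective_h
                ii = index[t_sl][a_mask]
                np.add.at(diag, ii, np.full(ii.size, gr))
                np.add.at(b, ii, np.full(ii.size, gr * bc.external_temperature))

        # domain-boundary faces of tissue voxels: same Robin condition
        if bc.convective_h > 0:
            for edge_idx in (0, grid.shape[axis] - 1):
                sl = [slice(None)] * 3
                sl[axis] = edge_idx
                e_mask = solved[tuple(sl)]
                if e_mask.any():
                    gr = face_area * bc.convective_h
                    ii = index[tuple(sl)][e_mask]
                    np.add.at(diag, ii, np.full(ii.size, gr))
                    np.add.at(b, ii, np.full(ii.size, gr * bc.external_temperature))

    if perfusion_w_per_m3K:
        diag += perfusion_w_per_m3K * vol
        b += perfusion_w_per_m3K * vol * bc.external_temperature

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return solved, index, K, b, m


def solve_bioheat(
    grid: LabelGrid,
    library: MaterialLibrary,
    sar: SARField,
    bc: BoundaryConditions,
    protocol: AblationProtocol,
    max_dt: float = 10.0,
    perfusion_w_per_m3K: float = 0.0,
) -> TemperatureField:
    """Backward-Euler solve of the bioheat equation over ``protocol.duration``.

    Snapshots are stored at every time step (uniform step
    ``duration / ceil(duration / max_dt) <= max_dt``), so at least every
    ``max_dt`` and at the final time.  Deterministic.
    """
    if max_dt <= 0:
        raise ValueError("max_dt must be > 0")
    if sar.grid is not grid and sar.values.shape != grid.shape:
        raise ValueError("SAR field not defined on this grid")
    if not np.isfinite(sar.values).all():
        raise ValueError("non-finite SAR values")

    solved, index, K, b, m = _build_system(grid, library, bc, perfusion_w_per_m3K)
    n = int(solved.sum())
    rho = _per_voxel(grid, library, "density")[solved]
    q = rho * sar.values[solved] * grid.voxel_volume  # W per voxel

    n_steps = max(1, int(math.ceil(protocol.duration / max_dt)))
    dt = protocol.duration / n_steps

    A = sp.diags(m / dt) + K
    A = A.tocsc()
    if n <= _DIRECT_SOLVER_LIMIT:
        lu = spla.splu(A)
        def step(rhs: np.ndarray, x0: np.ndarray) -> np.ndarray:
            return lu.solve(rhs)
    else:
        M_inv = sp.diags(1.0 / A.diagonal())
        def step(rhs: np.ndarray, x0: np.ndarray) -> np.ndarray:
            x, info = spla.cg(A, rhs, x0=x0, rtol=1e-10, atol=0.0, M=M_inv,
                              maxiter=5000)
            if info != 0:
                res = float(np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs))
                raise RuntimeError(
                    f"bioheat CG failed to converge (info={info}, "
                    f"relative residual {res:.2e})"
                )
            return x

    has_app = APPLICATOR in grid.class_names and (
        grid.label_ids == grid.class_names.index(APPLICATOR)
    ).any()
    app_mask = (
        grid.label_ids == grid.class_names.index(APPLICATOR)
        if has_app else np.zeros(grid.shape, bool)
    )

    T = np.full(n, protocol.initial_temperature)
    times = np.empty(n_steps + 1)
    values = np.empty((n_steps + 1,) + grid.shape)

    def snapshot(i: int, t: float, Tvec: np.ndarray) -> None:
        frame = np.full(grid.shape, protocol.initial_temperature)
        frame[app_mask] = bc.applicator_temperature
        frame[solved] = Tvec
        times[i] = t
        values[i] = frame

    snapshot(0, 0.0, T)
    for i in range(1, n_steps + 1):
        rhs = m / dt * T + q + b
        T = step(rhs, T)
        snapshot(i, i * dt, T)

    field = TemperatureField(grid=grid, times=times, values=values)
    if not np.isfinite(field.values).all():
        raise RuntimeError("bioheat solve produced non-finite temperatures")
    return field


def simulate_protocol(
    spec: PhantomSpec = PhantomSpec(),
    pose: Optional[ApplicatorPose] = None,
    params: DirectionalSourceParams = DirectionalSourceParams(),
    protocol: AblationProtocol = None,  # type: ignore[assignment]
    library: Optional[MaterialLibrary] = None,
    bc: BoundaryConditions = BoundaryConditions(),
    spacing: float = 1e-3,
    max_dt: float = 10.0,
    probes: Optional[Sequence[ProbeSpec]] = None,
):
    """End-to-end pipeline: phantom -> applicator -> SAR -> bioheat -> probes.

    Returns ``(TemperatureField, {channel: SensorLog})``.  Deterministic for
    a fixed configuration.
    """
    from .metrics import sample_probe  # local import to avoid a cycle

    if protocol is None:
        protocol = standard_protocols()["80W_3.5min_20C"]
    library = library or load_default_library()
    pose = pose or default_pose(spec)
    grid = place_applicator(build_phantom(spec, spacing), pose)
    sar = synthesize_sar(grid, pose, params, library,
                         protocol.nominal_applied_power)
    field = solve_bioheat(grid, library, sar, bc, protocol, max_dt=max_dt)
    probes = list(probes) if probes is not None else default_probes(pose)
    logs = {p.name: sample_probe(field, p) for p in probes}
    return field, logs
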