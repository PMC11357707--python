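# Methods

## Scope and intent

`dmwasim` models one specific, well-characterized setting: directional
microwave ablation of an excised porcine vertebral body suspended in air,
observed through two point temperature probes. It is a probe-level model:
its calibrated output is the temperature history at specified points, not a
full replication of a commercial finite-element solution. Everything below
is stated so a user can judge what the package's agreement with reference
data does and does not demonstrate.

## Phantom geometry

The phantom is an elliptical-cross-section prism (latero-lateral width
25 mm × dorsoventral depth 20 mm, extruded 25 mm craniocaudally) of
cancellous bone inside a 2 mm cortical shell, with 2 mm cortical endplates
cranially and caudally. A straight 10 mm-diameter cylinder with spinal-cord
properties runs craniocaudally, tangent to the dorsal body surface
(the real canal widens toward mid-body; a straight cylinder is a deliberate
simplification). Cartilage disks, 7.5 mm thick with the same cross-section,
sit cranial and caudal. The surrounding 8 × 4 × 4 cm domain is air,
emulating the stripped ex vivo specimen.

Coordinates: `x` latero-lateral (shaft axis), `+y` ventral (radiation
direction), `z` craniocaudal; voxel centers at `origin + (i + ½)·spacing`.
Voxelization assigns each voxel the class containing its center, painted
surround → body → disks → canal → applicator; it is deterministic and, with
boundaries on voxel centers at 1 mm, carries a known half-voxel alignment
artifact on the disk faces (volume convergence is therefore verified
between 0.5 and 0.25 mm).

The 14-gauge applicator is modeled as a 2.11 mm-diameter cylinder (standard
gauge table; only "14-gauge" is specified upstream) entering through the
lateral cortical wall aimed ventrally, its dorsal surface 2 mm from the
canal boundary. Probe distances are measured from the shaft **axis** — the
upstream description does not fix axis vs surface; this is a documented,
configurable convention. Default probes: T1 at 9.5 mm forward (the mean
experimental placement), T2 at 2.5 mm backward, plus a `T2_histology`
channel at the histology-derived 2.4 mm.

## Source model

No full-wave solution is attempted: the antenna's internal geometry is
unpublished, so any full-wave model would be guesswork. The model of record
is a parametric directional line source (module docstring of
`em_source.py` gives the formula) with five parameters:

| parameter | meaning | default |
|---|---|---|
| `front_to_back_ratio` | forward/backward power density at equal radius | 5 |
| `beam_exponent` β | angular concentration of the forward lobe | 2 |
| `axial_sigma` σ_a | Gaussian axial extent of the radiating zone | 5 mm |
| `sidelobe_level` s | backward/lateral floor (defaults to 1/front-to-back) | 0.2 |
| `absorbed_fraction` η | fraction of applied power deposited in tissue | 0.9 → calibrated |

Geometric spreading is 1/r (line source), clamped at the shaft radius;
the axial Gaussian confines the zone (measured ablation zones are elongated
along the shaft, favoring a line over a point source). Attenuation uses the
plane-wave constant of each traversed tissue, ray-marched from the axis at
steps ≤ spacing/2. The field is normalized so deposited power equals
`η · P_applied` exactly, which makes SAR exactly linear in applied power.

**Calibration.** The bioheat problem is linear in the source at fixed
boundary conditions, so any probe endpoint is affine in η. `calibrate_source`
exploits this: two forward runs identify the affine map, a third verifies
the solution; only if η leaves its bounds (0.05–1.0] does the front-to-back
ratio move, via a bounded secant. The anchor is the 80 W / 3.5 min / 20 °C
protocol's forward-probe endpoint, 51.3 °C, matched within ±1 °C. The
calibrated η ≈ 0.09 should be read as an *effective tissue-coupling
fraction* of the parametric source — the surrogate deposits all normalized
power in resolvable tissue, whereas the physical device loses most input
power to cable heating, reflection, and deposition inside the cooled
near-field that the 30 °C shaft boundary immediately removes. It is not a
statement that 91 % of antenna power is reflected.

## Thermal solver

Finite-volume, 7-point stencil on the voxel grid; harmonic-mean face
conductivities; air voxels are excluded from the solve (air acts only
through the Robin boundary and is reported frozen at the initial
temperature); applicator voxels are held at the 30 °C Dirichlet value, with
half-cell conductance `k·A/(Δ/2)` to the adjacent tissue so the isothermal
surface sits on the voxel face. The Robin condition (h = 10 W/m²K,
T_ext = 20 °C) applies on every tissue–air face and on tissue faces at the
domain boundary. Time integration is backward Euler with a uniform step
`duration / ceil(duration / max_dt)`, `max_dt` = 10 s; the system matrix is
factorized once (sparse LU; Jacobi-preconditioned CG with rtol 1e-10 beyond
120k unknowns, as in the 0.5 mm refinement run). Snapshots are stored at
every step, so probe logs resolve every internal step. A perfusion term
exists in the interface but is zero in every shipped protocol (ex vivo).

Protocols use the **nominal** applied powers (40 W for the 80 W setpoint,
60 W for 120 W) rather than the exact chain values (41.6/62.4 W via the
−2.84 dB budget); the exact values are computed and reported alongside.
Upstream descriptions of the reference model state both static properties
and per-step property updates; this package implements static properties,
matching the explicit statement and the absence of published
temperature-dependent bone data.

### Verification

Five oracles in `verification.py`, all run by the test suite and the
reproduction script: adiabatic uniform-source rise (closed form, observed
error ~1e-12 %); semi-infinite-slab step response vs the erfc solution at
depths ≥ 3 voxels (~0.16 %); discrete energy balance under insulation
(~1e-13 %, exact for backward Euler up to solver roundoff); agreement with
a brute-force explicit integrator at dt = 1 ms on an 8³ grid (~0.35 %); and
probe-endpoint shifts under halving of spacing and time step
(1 mm → 0.5 mm, 10 s → 5 s: < 0.25 %).

## Problem sizes and runtime

Defaults were chosen so a full calibrated four-protocol study runs in well
under a minute on one core: 1 mm spacing gives an 80×40×40 grid with
~19k solved tissue unknowns; one protocol solve takes ~2 s. The
verification oracles use 8³–12³ blocks and a 64×4×4 bar; the refinement
check runs one 0.5 mm (~150k unknowns) pipeline.

## Synthetic thermometry

The generator emulates the three dominant nuisance processes of the
experiments: truncated-normal radial placement (forward: mean 10.1 mm,
truncated at 8.3–12.7 mm; backward: mean 2.4 mm, truncated at 1.4–3.6 mm —
the histology-derived value, judged more representative than the externally
recorded 4.8 mm, which remains available as a scenario), a Normal(0, 1 mm)
axial off-plane offset per channel, a per-replicate initial-temperature
shift (warmed profile: 30.2 ± 3.7 °C; room profile: 19.9 ± 0.8 °C), and
additive i.i.d. Gaussian sensor noise (SD 0.2 °C). The published data give
means and ranges but no distribution family; truncated normals with
SD = range/4 are this package's documented choice. One `numpy` Generator
seeded per batch; no global state.

What it does **not** emulate: sensor response time and self-heating,
specimen-to-specimen geometry variation, bandsaw/handling artifacts in
extent measurements, and the true (unreconstructable) placement-error
distribution. Passing recovery tests therefore demonstrates that the
statistics pipeline is consistent and sensitive, not that real experimental
error is fully captured.

## Statistics conventions

ΔT is final minus first sample of a log. The comparison statistic is
`100·(ΔT_sim − ΔT_exp)/ΔT_exp`, rounded half-away-from-zero to an integer
percent (this rounding reproduces all six published values exactly;
simulation below experiment is negative). Replicate summaries use the
sample SD (n−1); a single replicate reports its mean with SD flagged
unavailable. Extent measurement interpolates the final-time 55/60 °C
contour sub-voxel: depth is the maximum forward distance from the shaft
axis within the central cross-sectional plane, length the axial extent of
the iso-region; the maximum-over-time envelope is deliberately not used.

## Known limitations

- The angular pattern of the real applicator cannot be validated beyond
  two probe angles; front-to-back ratio and beam exponent are effective
  parameters, not antenna measurements.
- Absolute temperatures very near the shaft are unreliable (1/r clamp and
  normalization concentrate power there); conclusions should be drawn at
  probe-like distances (≥ a few mm).
- Static tissue properties: any temperature dependence of bone dielectrics
  is unmodeled (none is published).
- The visible ablation zone in bone does not track the 55–60 °C contour;
  the package measures contours and makes no discoloration prediction.
- Straight canal, elliptical body: individual vertebra geometry (e.g. from
  CT) is out of scope.
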