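# dmwasim

A desk-scale simulator of **directional microwave ablation (dMWA) in
vertebral bone**, built around the ex vivo porcine vertebral-body validation
setting: a voxelized vertebra phantom suspended in air, a water-cooled
2.45 GHz 14-gauge directional applicator entering through the lateral
cortical wall, fiber-optic temperature probes forward (T1, ventral) and
backward (T2, toward the spinal canal) of the shaft, and the statistics used
to compare simulated against measured probe temperature changes.

It is intended for researchers studying thermal therapy in bone who need a
lightweight, fully scriptable alternative to a commercial FEM model for
probe-level temperature questions: parameter sweeps, placement-uncertainty
studies, and validation-statistics pipelines.

## Model

Heat transfer is the ex vivo (perfusion-free) bioheat equation

```
rho c  dT/dt  =  div( k grad T )  +  rho * SAR
```

solved by a 7-point finite-volume discretization on a uniform voxel grid
(default 1 mm) with harmonic-mean face conductivities, a convective (Robin)
condition `h (T - T_ext)` with `h = 10 W/m^2/K`, `T_ext = 20 °C` on every
tissue–air face, a 30 °C isothermal (Dirichlet) condition on the
water-cooled shaft surface, and unconditionally stable backward-Euler
stepping with steps ≤ 10 s. Tissue dielectric and thermal properties are
static (temperature-independent) at 2.45 GHz.

Because the applicator's internal antenna geometry is proprietary, the SAR
source is a **parametric directional line source**,

```
q(r, θ, u) ∝ D(θ) · exp(-u²/2σ_a²) · exp(-2 ∫ α ds) / max(r, r_min)
D(θ) = s + (1 - s) ((1 + cos θ)/2)^β
```

with tissue-dependent plane-wave attenuation `α` integrated along each ray,
normalized so the deposited power equals `η ·` applied power. The absorbed
fraction `η` is calibrated so one anchor protocol (80 W setpoint / 3.5 min /
20 °C start) reproduces its reference forward-probe endpoint of 51.3 °C;
all other protocols are then pure predictions.

The validation statistic is the signed integer percent difference
`round(100 (ΔT_sim - ΔT_exp) / ΔT_exp)` per channel and protocol, with
ΔT = final − initial probe temperature.

## Worked example

`python examples/04_simulate_ablation.py` calibrates the source on the
anchor protocol and reruns the four study protocols (~20 s):

```
calibrated: absorbed_fraction=0.090, front_to_back_ratio=5.0

protocol           T1_f    dT1   T2_f    dT2  D60 mm  L60 mm
80W_3.5min_20C     51.3   31.3   36.6   16.6     6.9     8.6
80W_3.5min_30C     59.8   29.8   40.2   10.2     8.9    12.7
80W_3.5min_37C     65.7   28.7   42.7    5.7    10.5    15.7
120W_5min_20C      78.0   58.0   44.9   24.9    13.7    20.0
```

The anchor row reproduces its 51.3 °C target by construction; the other
rows are predictions. The forward rise ΔT1 is nearly independent of the
starting temperature for the 80 W runs (29–31 °C, reference values
31.3–32.5 °C), and the backward rise ΔT2 decreases monotonically as the
starting temperature approaches the 30 °C shaft coolant (16.6 → 10.2 → 5.7 °C;
reference 13.4 → 9.6 → 6.8 °C). `D60`/`L60` are the radial depth and axial
length of the final 60 °C contour — deliberately *not* a prediction of the
grossly visible ablation zone, which in bone is smaller than the 55–60 °C
contour.

The other examples cover tissue properties and penetration depths (`01`),
the −2.84 dB transmission-chain budget (`02`), phantom geometry (`03`), the
comparison-table statistics (`05`), and synthetic thermometry with
placement/drift/noise recovery (`06`).

## Layout

- `src/dmwasim/materials.py` — tissue property table, plane-wave attenuation
- `src/dmwasim/power_chain.py` — dB loss budget, setpoint → applied power
- `src/dmwasim/phantom.py` — voxel phantom, applicator pose, probes
- `src/dmwasim/em_source.py` — directional SAR synthesis and calibration
- `src/dmwasim/bioheat.py` — transient finite-volume bioheat solver
- `src/dmwasim/metrics.py` — probe sampling, ΔT/percent-diff, extents, summaries
- `src/dmwasim/synthetic_data.py` — experiment-like synthetic thermometry
- `src/dmwasim/verification.py` — solver oracles (closed-form, brute-force)
- `src/dmwasim/refdata.py` — published reference values used for validation
- `src/dmwasim/vtkio.py` — legacy-VTK export for ParaView inspection

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices, and limitations.
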