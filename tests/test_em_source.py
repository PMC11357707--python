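"""Directional SAR synthesis and source calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

import dmwasim as d
from dmwasim.em_source import CalibrationError
from dmwasim.verification import uniform_block


def _center_pose(active_length=0.010):
    """Shaft along x through the center of a 41 mm cube (origin at 0)."""
    return d.ApplicatorPose(
        tip_position=(0.0105, 0.0205, 0.0205),
        axis_direction=(-1.0, 0.0, 0.0),
        radiation_direction=(0.0, 1.0, 0.0),
        active_length=active_length,
        shaft_length=0.030,
    )


@pytest.fixture()
def block41():
    """Homogeneous cancellous cube, axis on a voxel-center row."""
    return uniform_block("cancellous bone", (41, 41, 41))


def test_isotropic_limit_is_fore_aft_symmetric(block41, library):
    pose = _center_pose()
    params = d.DirectionalSourceParams(front_to_back_ratio=5.0, beam_exponent=0.0)
    sar = d.synthesize_sar(block41, pose, params, library, 40.0)
    j = 20  # axis row (y index); forward is +y
    for k in (3, 7, 12):
        fwd = sar.values[15, j + k, 20]
        back = sar.values[15, j - k, 20]
        assert fwd == pytest.approx(back, rel=1e-6)


def test_deposited_power_matches_absorbed_fraction(phantom_1mm, library):
    _, pose, grid = phantom_1mm
    params = d.DirectionalSourceParams(absorbed_fraction=0.9)
    sar = d.synthesize_sar(grid, pose, params, library, 40.0)
    assert sar.deposited_power(library) == pytest.approx(0.9 * 40.0, rel=1e-3)
    assert (sar.values >= 0).all()
    assert sar.values[grid.mask("air")].max() == 0.0
    assert sar.values[grid.mask("applicator")].max() == 0.0


def test_radial_decay_follows_line_source_attenuation(block41, library):
    """Forward-ray SAR ratio equals (1/2) * exp(-2 alpha r) exactly in a
    homogeneous medium."""
    pose = _center_pose()
    params = d.DirectionalSourceParams()
    sar = d.synthesize_sar(block41, pose, params, library, 40.0)
    alpha, _ = d.plane_wave_attenuation(library.lookup("cancellous bone"),
                                        library.frequency)
    r0 = 4e-3
    j = 20
    s_r = sar.values[15, j + 4, 20]    # r = 4 mm on the forward ray
    s_2r = sar.values[15, j + 8, 20]   # r = 8 mm
    expected = 0.5 * math.exp(-2.0 * alpha * r0)
    assert s_2r / s_r == pytest.approx(expected, rel=1e-9)


def test_sar_linear_in_applied_power(block41, library):
    pose = _center_pose()
    params = d.DirectionalSourceParams()
    s1 = d.synthesize_sar(block41, pose, params, library, 10.0)
    s2 = d.synthesize_sar(block41, pose, params, library, 25.0)
    np.testing.assert_allclose(s2.values, 2.5 * s1.values, rtol=1e-12)


def test_zero_power_gives_zero_field(block41, library):
    pose = _center_pose()
    sar = d.synthesize_sar(block41, pose, d.DirectionalSourceParams(), library, 0.0)
    assert np.all(sar.values == 0.0)


def test_directionality_and_beam_concentration(block41, library):
    """Forward/backward SAR ratio stays >= 1; a larger beam exponent
    concentrates deposition toward the forward lobe (forward/lateral ratio
    strictly increases; the exact-backward floor is set by the sidelobe
    level alone)."""
    pose = _center_pose()
    j = 20
    fb, fl = [], []
    for beta in (1.0, 2.0, 4.0):
        params = d.DirectionalSourceParams(front_to_back_ratio=5.0,
                                           beam_exponent=beta)
        sar = d.synthesize_sar(block41, pose, params, library, 40.0)
        fb.append(sar.values[15, j + 5, 20] / sar.values[15, j - 5, 20])
        fl.append(sar.values[15, j + 5, 20] / sar.values[15, j, 20 + 5])
    assert all(r >= 1.0 for r in fb)
    assert fl[0] < fl[1] < fl[2]


def test_all_air_phantom_rejected(library):
    grid = uniform_block("air", (8, 8, 8))
    with pytest.raises(ValueError, match="absorbing"):
        d.synthesize_sar(grid, _center_pose(), d.DirectionalSourceParams(),
                         library, 40.0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        d.DirectionalSourceParams(front_to_back_ratio=0.5)
    with pytest.raises(ValueError):
        d.DirectionalSourceParams(absorbed_fraction=0.0)
    with pytest.raises(ValueError):
        d.DirectionalSourceParams(axial_sigma=-1.0)


# ---- calibration against a cheap affine surrogate -------------------------

def _affine_simulator(base=20.0, gain=300.0):
    """Probe temperature affine in absorbed_fraction, increasing in the
    front-to-back ratio — the structure of the real forward model."""

    def evaluate(params):
        ftb_boost = 1.0 - 1.0 / (1.0 + params.front_to_back_ratio)
        return base + gain * params.absorbed_fraction * ftb_boost

    return evaluate


def test_calibration_returns_params_unchanged_when_anchor_met():
    evaluate = _affine_simulator()
    p0 = d.DirectionalSourceParams(absorbed_fraction=0.2)
    target = evaluate(p0) + 0.5  # within the 1 degC tolerance
    assert d.calibrate_source(p0, target, evaluate, tolerance=1.0) is p0


def test_calibration_hits_target_via_absorbed_fraction():
    evaluate = _affine_simulator()
    p0 = d.DirectionalSourceParams(absorbed_fraction=0.9)
    cal = d.calibrate_source(p0, 51.3, evaluate, tolerance=0.1)
    assert evaluate(cal) == pytest.approx(51.3, abs=0.1)
    assert cal.front_to_back_ratio == p0.front_to_back_ratio


def test_calibration_monotone_in_target():
    """A hotter anchor requires strictly more absorbed power."""
    evaluate = _affine_simulator()
    p0 = d.DirectionalSourceParams(absorbed_fraction=0.5)
    lo = d.calibrate_source(p0, 60.0, evaluate, tolerance=0.01)
    hi = d.calibrate_source(p0, 120.0, evaluate, tolerance=0.01)
    assert hi.absorbed_fraction > lo.absorbed_fraction


def test_calibration_falls_back_to_front_to_back_ratio():
    """Targets unreachable within absorbed-fraction bounds move the
    front-to-back ratio instead."""
    evaluate = _affine_simulator(gain=300.0)
    p0 = d.DirectionalSourceParams(front_to_back_ratio=2.0,
                                   absorbed_fraction=0.9)
    # max reachable at ftb=2 is 20 + 300 * (2/3) = 220; ask for more
    cal = d.calibrate_source(p0, 250.0, evaluate, tolerance=0.5)
    assert evaluate(cal) == pytest.approx(250.0, abs=0.5)
    assert cal.front_to_back_ratio > p0.front_to_back_ratio


def test_calibration_reports_best_residual_when_unreachable():
    evaluate = _affine_simulator(gain=300.0)
    p0 = d.DirectionalSourceParams(absorbed_fraction=0.5)
    with pytest.raises(CalibrationError) as err:
        d.calibrate_source(p0, 1000.0, evaluate, tolerance=0.5)
    assert err.value.best_params is not None
    assert abs(err.value.residual) > 0.5
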