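"""Tissue property table and lossy-dielectric plane-wave quantities.

The simulator treats every tissue class as a homogeneous, isotropic,
non-magnetic medium with *static* (temperature-independent) dielectric and
thermal properties at the operating frequency of 2.45 GHz.  The bundled
default library carries the five tissue classes used for porcine vertebral
body modelling (cortical bone, cancellous bone, cartilage, muscle, spinal
cord) plus handbook values for the surrounding air and a placeholder for the
water-cooled applicator shaft, which enters the thermal problem only through
an isothermal boundary condition.

The electromagnetic side of the source model needs only the plane-wave
attenuation constant of each tissue,

    alpha = omega * sqrt( (mu0*eps0*eps_r / 2) *
                          ( sqrt(1 + (sigma/(omega*eps0*eps_r))**2) - 1 ) )

in Np/m, and the field-amplitude penetration depth ``delta = 1/alpha``.
Power density along a ray decays as ``exp(-2*alpha*distance)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple, Union

import yaml
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

__all__ = [
    "TissueProperties",
    "MaterialLibrary",
    "load_default_library",
    "plane_wave_attenuation",
    "DEFAULT_FREQUENCY_HZ",
]

#: Operating frequency of the water-cooled 14-gauge directional applicator.
DEFAULT_FREQUENCY_HZ = 2.45e9


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric and thermal constants for one tissue class.

    Parameters
    ----------
    name:
        Tissue-class label (e.g. ``"cancellous bone"``).
    relative_permittivity:
        Dimensionless real relative permittivity ``eps_r``.
    electrical_conductivity:
        Effective conductivity ``sigma`` in S/m (>= 0).
    thermal_conductivity:
        ``k`` in W/m/degC.
    density:
        ``rho`` in kg/m^3.
    specific_heat:
        ``c`` in J/kg/degC.
    """

    name: str
    relative_permittivity: float
    electrical_conductivity: float
    thermal_conductivity: float
    density: float
    specific_heat: float

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise ValueError(f"{self.name}: relative_permittivity must be > 0")
        if self.electrical_conductivity < 0:
            raise ValueError(f"{self.name}: electrical_conductivity must be >= 0")
        for attr in ("thermal_conductivity", "density", "specific_heat"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c in J/m^3/degC."""
        return self.density * self.specific_heat


# Porcine vertebral-body tissue constants at 2.45 GHz used throughout the
# simulator.  Order of the tuple: (eps_r, sigma S/m, k W/m/degC, rho kg/m^3,
# c J/kg/degC).
_CANONICAL_TISSUES: Dict[str, Tuple[float, float, float, float, float]] = {
    "cortical bone": (11.4, 0.39, 0.32, 1908.0, 1313.0),
    "cancellous bone": (18.5, 0.81, 0.31, 1178.0, 2274.0),
    "cartilage": (38.8, 1.76, 0.49, 1100.0, 3568.0),
    "muscle": (52.7, 1.74, 0.49, 1090.0, 3421.0),
    "spinal cord": (30.1, 1.09, 0.51, 1075.0, 3630.0),
}

# Standard handbook values for dry air near room temperature.  The air domain
# matters only through the convective boundary condition, so these affect no
# result; they keep the library total (every label resolvable).
_AIR = (1.0, 0.0, 0.026, 1.2, 1005.0)

# Placeholder for the applicator shaft.  The shaft is excluded from both the
# electromagnetic deposition and the conduction solve (its outer surface is an
# isothermal Dirichlet boundary), so only the label needs to resolve.
_APPLICATOR = (1.0, 0.0, 16.0, 7900.0, 500.0)


@dataclass
class MaterialLibrary:
    """Mapping from tissue-class label to :class:`TissueProperties`.

    A hook for temperature-dependent property callables exists
    (``temperature_dependence``) but ships disabled (``None``): the model of
    record uses static properties.
    """

    entries: Dict[str, TissueProperties] = field(default_factory=dict)
    frequency: float = DEFAULT_FREQUENCY_HZ
    temperature_dependence: Optional[Dict[str, Callable[[float], TissueProperties]]] = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.temperature_dependence is not None:
            raise NotImplementedError(
                "temperature-dependent properties are a documented extension "
                "and are not enabled in this release"
            )

    def lookup(self, name: str) -> TissueProperties:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(
                f"tissue class {name!r} not in material library "
                f"(have: {sorted(self.entries)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def attenuation(self, name: str) -> float:
        """Plane-wave attenuation constant (Np/m) of one tissue class."""
        return plane_wave_attenuation(self.lookup(name), self.frequency)[0]

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: Union[str, Path]) -> None:
        """Write the library as a structured key-value file.

        Floats are stored via ``repr`` so a round trip is bit-exact.
        """
        doc = {
            "frequency_hz": self.frequency,
            "tissues": {
                name: {
                    "relative_permittivity": p.relative_permittivity,
                    "electrical_conductivity": p.electrical_conductivity,
                    "thermal_conductivity": p.thermal_conductivity,
                    "density": p.density,
                    "specific_heat": p.specific_heat,
                }
                for name, p in self.entries.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "MaterialLibrary":
        doc = yaml.safe_load(Path(path).read_text())
        entries = {
            name: TissueProperties(name=name, **vals)
            for name, vals in doc["tissues"].items()
        }
        return cls(entries=entries, frequency=float(doc["frequency_hz"]))


def load_default_library(frequency: float = DEFAULT_FREQUENCY_HZ) -> MaterialLibrary:
    """Return the bundled porcine vertebral-body material library.

    Contains the five canonical tissue classes plus ``"air"`` and an
    ``"applicator"`` placeholder.
    """
    entries = {
        name: TissueProperties(name, *vals) for name, vals in _CANONICAL_TISSUES.items()
    }
    entries["air"] = TissueProperties("air", *_AIR)
    entries["applicator"] = TissueProperties("applicator", *_APPLICATOR)
    return MaterialLibrary(entries=entries, frequency=frequency)


def plane_wave_attenuation(
    props: TissueProperties, frequency: float
) -> Tuple[float, float]:
    """Attenuation constant and penetration depth of a lossy dielectric.

    Parameters
    ----------
    props:
        Tissue whose ``relative_permittivity`` and ``electrical_conductivity``
        are used.
    frequency:
        Wave frequency in Hz (> 0).

    Returns
    -------
    (alpha, delta):
        Field attenuation constant in Np/m and the 1/e field-amplitude
        penetration depth ``1/alpha`` in m.  A lossless medium
        (``sigma == 0``) gives ``(0.0, inf)``.

    Notes
    -----
    Power density decays as ``exp(-2 * alpha * distance)``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    eps_r = props.relative_permittivity
    sigma = props.electrical_conductivity
    if sigma == 0.0:
        return 0.0, math.inf
    loss_tangent = sigma / (omega * EPS0 * eps_r)
    alpha = omega * math.sqrt(
        (MU0 * EPS0 * eps_r / 2.0) * (math.sqrt(1.0 + loss_tangent**2) - 1.0)
    )
    return alpha, 1.0 / alpha
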