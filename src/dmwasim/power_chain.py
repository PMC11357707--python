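"""Generator-to-antenna power budget.

The microwave generator setpoint is attenuated by a cascade of passive
components (cables, adapters, connectors) before reaching the antenna.  The
budget is carried in power dB (10*log10); for the measured/estimated chain of
the 2.45 GHz water-cooled applicator the component losses sum to -2.84 dB,
i.e. roughly half the console power reaches the antenna (80 W setpoint ->
~41.6 W, 120 W -> ~62.4 W).  Simulation protocols use the nominal applied
powers 40 W and 60 W; :func:`applied_power` reports the exact chain value for
transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

__all__ = [
    "LossComponent",
    "PowerChain",
    "total_chain_loss",
    "applied_power",
    "default_loss_components",
]


@dataclass(frozen=True)
class LossComponent:
    """One passive element of the transmission chain.

    ``loss`` is in power dB; negative for attenuation.  Passive components
    must not have gain.
    """

    label: str
    loss: float

    def __post_init__(self) -> None:
        if self.loss > 0:
            raise ValueError(
                f"passive component {self.label!r} cannot have positive gain "
                f"({self.loss} dB)"
            )


def default_loss_components() -> List[LossComponent]:
    """The measured/estimated loss budget of the experimental setup."""
    return [
        LossComponent("2.5 m Succoform-141 cable (measured)", -1.54),
        LossComponent("QMA-to-SMA adapter (datasheet)", -0.17),
        LossComponent("0.25 m UT-034 (extrapolated from datasheet)", -0.73),
        LossComponent("applicator SMA connector (estimated)", -0.20),
        LossComponent("generator connector (estimated)", -0.20),
    ]


def total_chain_loss(components: Sequence[LossComponent]) -> float:
    """Sum of component losses in dB (0.0 for an empty chain)."""
    return float(sum(c.loss for c in components))


def applied_power(setpoint: float, loss: float) -> float:
    """Power reaching the antenna for a generator ``setpoint`` (W).

    ``applied = setpoint * 10**(loss/10)`` with ``loss`` in power dB.  A
    positive loss (gain) is physically implausible for this passive chain; a
    warning is emitted but the value is still computed.
    """
    if setpoint <= 0:
        raise ValueError("generator setpoint must be > 0 W")
    if loss > 0:
        warnings.warn(
            f"positive chain loss {loss:+.2f} dB implies gain in a passive "
            "chain; computing anyway",
            stacklevel=2,
        )
    return setpoint * 10.0 ** (loss / 10.0)


@dataclass
class PowerChain:
    """A generator setpoint together with its loss budget."""

    generator_setpoint: float
    components: List[LossComponent] = field(default_factory=default_loss_components)

    def __post_init__(self) -> None:
        if self.generator_setpoint <= 0:
            raise ValueError("generator_setpoint must be > 0 W")

    @property
    def total_loss(self) -> float:
        return total_chain_loss(self.components)

    @property
    def applied_power(self) -> float:
        return applied_power(self.generator_setpoint, self.total_loss)
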