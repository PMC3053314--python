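"""Canonical Hodgkin-Huxley fixtures and protocol defaults.

The sodium channel is composed of three identical activation gates (m) and
one inactivation gate (h) — an 8-state scheme when aggregated — and the
potassium channel of four identical activation gates (n), a 5-state ladder.
Rate laws are the canonical squid-axon set in the modern voltage convention
(rest near -65 mV).

Channel densities default to 60 um^-2 (Na) and 18 um^-2 (K) with a
single-channel conductance of 10 pS for both; the maximal specific
conductances follow as g = gamma N / area (60 and 18 mS/cm^2), keeping the
deterministic and stochastic descriptions exactly consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError
from .kinetics import ChannelScheme, SubunitSpec
from .membrane import Geometry, MembraneParams
from .microscopic import ChannelPopulation
from .rates import HH_RATES

__all__ = ["HHFixture", "build_hh_fixture", "sodium_scheme", "potassium_scheme"]

DEFAULTS = {
    "gamma_ps": 10.0,
    "na_density_per_um2": 60.0,
    "k_density_per_um2": 18.0,
    "e_na_mv": 50.0,
    "e_k_mv": -77.0,
    "c_m_uf_cm2": 1.0,
    "g_leak_ms_cm2": 0.3,
    "e_leak_mv": -54.4,
    "length_um": 30.0,
    "diameter_um": 30.0,
}


def sodium_scheme() -> ChannelScheme:
    """Fast-inactivating sodium: m^3 h (8 aggregated states, 7 noise terms)."""
    return ChannelScheme.from_subunits(
        "na",
        [SubunitSpec("m", 3, HH_RATES["m"]), SubunitSpec("h", 1, HH_RATES["h"])],
    )


def potassium_scheme() -> ChannelScheme:
    """Delayed-rectifier potassium: n^4 (5-state ladder, 4 noise terms)."""
    return ChannelScheme.from_subunits("k", [SubunitSpec("n", 4, HH_RATES["n"])])


@dataclass(frozen=True)
class HHFixture:
    """The standard two-current model: schemes, membrane constants, geometry."""

    sodium: ChannelScheme
    potassium: ChannelScheme
    membrane: MembraneParams
    geometry: Geometry
    gamma_ps: float
    na_density: float
    k_density: float
    e_na: float
    e_k: float

    def populations(self, geometry: Optional[Geometry] = None) -> list:
        """Na and K populations sized from densities and the geometry area."""
        area = (geometry or self.geometry).area_um2
        return [
            ChannelPopulation.from_density(self.sodium, self.na_density, area,
                                           gamma=self.gamma_ps, e_rev=self.e_na),
            ChannelPopulation.from_density(self.potassium, self.k_density, area,
                                           gamma=self.gamma_ps, e_rev=self.e_k),
        ]


def build_hh_fixture(**overrides) -> HHFixture:
    """Build the canonical fixture; keyword overrides use the unit-suffixed
    names of :data:`DEFAULTS` (e.g. ``diameter_um=10``)."""
    cfg = dict(DEFAULTS)
    for k, v in overrides.items():
        if k not in cfg:
            raise ConfigError(
                f"unknown fixture override {k!r}; valid keys: {sorted(cfg)}"
            )
        cfg[k] = float(v)
    return HHFixture(
        sodium=sodium_scheme(),
        potassium=potassium_scheme(),
        membrane=MembraneParams(c_m=cfg["c_m_uf_cm2"], g_leak=cfg["g_leak_ms_cm2"],
                                e_leak=cfg["e_leak_mv"]),
        geometry=Geometry(length=cfg["length_um"], diameter=cfg["diameter_um"]),
        gamma_ps=cfg["gamma_ps"],
        na_density=cfg["na_density_per_um2"],
        k_density=cfg["k_density_per_um2"],
        e_na=cfg["e_na_mv"],
        e_k=cfg["e_k_mv"],
    )
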