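"""Self-dose S-values for unit-density liquid-water spheres.

Each organ is modeled as a sphere of water (ρ = 1 g/cm³) of the organ's
mass, receiving only self-dose.  The S-value in mGy/(MBq·s) is

    S = 10³ · Σ_classes Δ_class [MeV] · 1.602176634e−13 [J/MeV] · φ_class
        · 10⁶ [decay/s per MBq] / (m [g] · 10⁻³ [kg/g])

Charged-particle emissions (alpha, mean beta, conversion electrons) are
absorbed locally with fraction ``phi_charged`` (default 1).  Photons are
ignored by default; an ``analytic`` mode applies the crude absorbed
fraction 1 − exp(−μ_en·r) at a representative photon energy, labelled
approximate.  Chain S-values weight each member by its decays per
parent decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .nuclides import (
    CHARGED_CLASSES,
    DecayChainSpec,
    NuclideRecord,
    RadiationClass,
    get_nuclide,
)

__all__ = ["SValueConfig", "SphereSValue", "radius_from_mass", "s_value", "chain_s_value"]

MEV_TO_J = 1.602176634e-13
DECAYS_PER_S_PER_MBQ = 1.0e6
WATER_DENSITY_G_CM3 = 1.0
#: mass energy-absorption coefficient of water near 0.3 MeV, cm²/g —
#: representative value for the crude analytic photon mode only
MU_EN_WATER_CM2_G = 0.0319


@dataclass(frozen=True)
class SValueConfig:
    """Absorbed-fraction model of the sphere.

    ``photon_mode``: "ignore" (φ_photon = 0, default) or "analytic"
    (φ_photon = 1 − exp(−μ_en·ρ·r), a coarse approximation).
    ``phi_charged``: absorbed fraction for alpha/beta/electron, in (0, 1].
    """

    photon_mode: str = "ignore"
    phi_charged: float = 1.0

    def __post_init__(self):
        if self.photon_mode not in ("ignore", "analytic"):
            raise ValueError(f"unknown photon_mode {self.photon_mode!r}")
        if not 0 < self.phi_charged <= 1:
            raise ValueError("phi_charged must be in (0, 1]")


@dataclass(frozen=True)
class SphereSValue:
    """S-value of a sphere with per-class / per-member breakdown.

    ``breakdown`` maps (member symbol, radiation class) to its additive
    contribution in mGy/(MBq·s); contributions sum to the total.
    """

    nuclide_or_chain: str
    mass_g: float
    radius_cm: float
    s_mgy_per_mbq_s: float
    breakdown: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.s_mgy_per_mbq_s < 0:
            raise ValueError("S must be >= 0")
        vol = (4.0 / 3.0) * math.pi * self.radius_cm**3 * WATER_DENSITY_G_CM3
        if not math.isclose(vol, self.mass_g, rel_tol=1e-9):
            raise ValueError("radius inconsistent with mass at density 1 g/cm³")
        total = sum(self.breakdown.values())
        if self.breakdown and not math.isclose(
            total, self.s_mgy_per_mbq_s, rel_tol=1e-9, abs_tol=1e-300
        ):
            raise ValueError("breakdown does not sum to total")


def radius_from_mass(mass_g: float) -> float:
    """Radius in cm of a unit-density water sphere of the given mass."""
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    return (3.0 * mass_g / (4.0 * math.pi * WATER_DENSITY_G_CM3)) ** (1.0 / 3.0)


def _phi(radiation_class: RadiationClass, radius_cm: float, config: SValueConfig) -> float:
    if radiation_class in CHARGED_CLASSES:
        return config.phi_charged
    if config.photon_mode == "ignore":
        return 0.0
    return 1.0 - math.exp(-MU_EN_WATER_CM2_G * WATER_DENSITY_G_CM3 * radius_cm)


def s_value(
    nuclide: NuclideRecord, mass_g: float, config: SValueConfig = SValueConfig()
) -> SphereSValue:
    """Self-dose S-value of one nuclide in a water sphere of ``mass_g``."""
    r = radius_from_mass(mass_g)
    per_decay_to_s = DECAYS_PER_S_PER_MBQ * 1.0e3 / (mass_g * 1.0e-3)  # (J -> mGy/(MBq s))
    breakdown: dict[tuple[str, str], float] = {}
    for em in nuclide.emissions:
        phi = _phi(em.radiation_class, r, config)
        contrib = em.delta * MEV_TO_J * phi * per_decay_to_s
        if contrib != 0.0:
            breakdown[(nuclide.symbol, em.radiation_class.value)] = contrib
    return SphereSValue(
        nuclide_or_chain=nuclide.symbol,
        mass_g=mass_g,
        radius_cm=r,
        s_mgy_per_mbq_s=sum(breakdown.values()),
        breakdown=breakdown,
    )


def chain_s_value(
    chain: DecayChainSpec, mass_g: float, config: SValueConfig = SValueConfig()
) -> SphereSValue:
    """Chain S-value: member S-values weighted by decays per parent decay.

    Assumes progeny decay in place (no redistribution), so each member's
    activity equals the parent's times its cumulative branching.
    """
    breakdown: dict[tuple[str, str], float] = {}
    for sym, cb in chain.members:
        member_s = s_value(get_nuclide(sym), mass_g, config)
        for key, contrib in member_s.breakdown.items():
            breakdown[key] = breakdown.get(key, 0.0) + cb * contrib
    return SphereSValue(
        nuclide_or_chain=f"{chain.parent} chain",
        mass_g=mass_g,
        radius_cm=radius_from_mass(mass_g),
        s_mgy_per_mbq_s=sum(breakdown.values()),
        breakdown=breakdown,
    )
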