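"""Absorbed-dose coefficients, worked doses, and injected-activity planning.

The dose coefficient of an organ is the product of its cumulated
activity Ã (seconds) and the sphere S-value (mGy/(MBq·s)), divided by
1000 to yield Gy per MBq injected.  The planner inverts the coefficient:
required injected activity = prescribed dose / coefficient, reported in
both μCi and MBq (1 μCi = 0.037 MBq exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .svalue import SphereSValue
from .tac import CumulatedActivity

__all__ = [
    "MBQ_PER_UCI",
    "DoseResult",
    "Prescription",
    "PlanTable",
    "organ_dose_coefficient",
    "dose_from_injected",
    "required_injected_activity",
    "plan_table",
    "cross_dose_hook",
    "uci_to_mbq",
    "mbq_to_uci",
]

MBQ_PER_UCI = 0.037  # exact by definition of the curie


def uci_to_mbq(uci: float) -> float:
    return uci * MBQ_PER_UCI


def mbq_to_uci(mbq: float) -> float:
    return mbq / MBQ_PER_UCI


@dataclass(frozen=True)
class DoseResult:
    """Absorbed-dose coefficient (Gy/MBq) with optional delivered dose."""

    organ: str
    dose_coefficient_gy_per_mbq: float
    breakdown: dict[tuple[str, str], float] = field(default_factory=dict)
    injected_activity_mbq: float | None = None

    def __post_init__(self):
        if self.dose_coefficient_gy_per_mbq < 0:
            raise ValueError("dose coefficient must be >= 0")

    @property
    def absorbed_dose_gy(self) -> float | None:
        if self.injected_activity_mbq is None:
            return None
        return self.dose_coefficient_gy_per_mbq * self.injected_activity_mbq


@dataclass(frozen=True)
class Prescription:
    """A target tumor dose: how many Gy into how many mg."""

    target: str
    prescribed_dose_gy: float
    tumor_mass_mg: float

    def __post_init__(self):
        if self.prescribed_dose_gy <= 0:
            raise ValueError("prescribed_dose_gy must be > 0")
        if self.tumor_mass_mg <= 0:
            raise ValueError("tumor_mass_mg must be > 0")


@dataclass(frozen=True)
class PlanTable:
    """Required injected activity on a (tumor mass × prescribed dose) grid."""

    mass_mg: tuple[float, ...]
    dose_gy: tuple[float, ...]
    activity_uci: tuple[tuple[float, ...], ...]  # rows = masses, cols = doses

    def __post_init__(self):
        for row in self.activity_uci:
            if len(row) != len(self.dose_gy):
                raise ValueError("row length mismatch")
            if any(a <= 0 for a in row):
                raise ValueError("all cells must be > 0")
            if not all(b > a for a, b in zip(row, row[1:])):
                raise ValueError("cells must increase along the dose axis")

    @property
    def activity_mbq(self) -> tuple[tuple[float, ...], ...]:
        return tuple(tuple(uci_to_mbq(a) for a in row) for row in self.activity_uci)

    def to_frame(self, unit: str = "uci") -> pd.DataFrame:
        grid = self.activity_uci if unit == "uci" else self.activity_mbq
        return pd.DataFrame(
            [list(r) for r in grid],
            index=pd.Index(self.mass_mg, name="mass_mg"),
            columns=pd.Index(self.dose_gy, name="dose_gy"),
        )


def organ_dose_coefficient(a_tilde: CumulatedActivity, s: SphereSValue) -> DoseResult:
    """D = Ã [s] × S [mGy/(MBq·s)] / 1000, in Gy per MBq injected."""
    breakdown = {
        key: a_tilde.a_tilde_s * contrib / 1000.0 for key, contrib in s.breakdown.items()
    }
    return DoseResult(
        organ=a_tilde.organ,
        dose_coefficient_gy_per_mbq=a_tilde.a_tilde_s * s.s_mgy_per_mbq_s / 1000.0,
        breakdown=breakdown,
    )


def dose_from_injected(dose_coefficient: float, injected: float) -> float:
    """Absorbed dose = coefficient × injected activity (consistent units).

    E.g. a coefficient in Gy/μCi times an injected activity in μCi gives
    Gy; report to 3 significant figures in summaries.
    """
    if dose_coefficient < 0 or injected < 0:
        raise ValueError("coefficient and activity must be >= 0")
    return dose_coefficient * injected


def required_injected_activity(
    prescription: Prescription, dose_coefficient_gy_per_uci: float
) -> tuple[float, float]:
    """Injected activity achieving the prescription, as (μCi, MBq)."""
    if dose_coefficient_gy_per_uci <= 0:
        raise ValueError("target receives no dose: coefficient must be > 0")
    uci = prescription.prescribed_dose_gy / dose_coefficient_gy_per_uci
    return uci, uci_to_mbq(uci)


def plan_table(
    mass_grid_mg: list[float],
    dose_grid_gy: list[float],
    coefficient_model: float | list[tuple[float, float]],
    allow_extrapolation: bool = False,
) -> PlanTable:
    """Build a (tumor mass × prescribed dose) injected-activity table.

    ``coefficient_model`` is either a constant coefficient (Gy/μCi) or a
    list of (mass_mg, coefficient) pairs interpolated linearly between
    supplied masses.  Grid masses outside the supplied range raise unless
    ``allow_extrapolation`` (which then clamps to the nearest endpoint).
    """
    masses = sorted(mass_grid_mg)
    doses = sorted(dose_grid_gy)
    if not masses or not doses:
        raise ValueError("mass and dose grids must be non-empty")

    if isinstance(coefficient_model, (int, float)):
        coeff_of = lambda m: float(coefficient_model)  # noqa: E731
    else:
        pairs = sorted(coefficient_model)
        xs = np.array([p[0] for p in pairs], dtype=float)
        ys = np.array([p[1] for p in pairs], dtype=float)
        lo, hi = xs[0], xs[-1]

        def coeff_of(m: float) -> float:
            if (m < lo or m > hi) and not allow_extrapolation:
                raise ValueError(
                    f"mass {m} mg outside model range [{lo}, {hi}] mg "
                    "(pass allow_extrapolation=True to clamp)"
                )
            return float(np.interp(m, xs, ys))

    rows = []
    for m in masses:
        c = coeff_of(m)
        if c <= 0:
            raise ValueError(f"coefficient at mass {m} mg must be > 0")
        rows.append(tuple(d / c for d in doses))
    return PlanTable(tuple(masses), tuple(doses), tuple(rows))


def cross_dose_hook(
    contributions: dict[str, float] | None,
    a_tilde_by_source: dict[str, CumulatedActivity] | None = None,
) -> float:
    """Additive cross-organ dose term, Gy/MBq.

    ``contributions`` maps source organ to target dose per unit source
    Ã (Gy/MBq per second); each source's cumulated activity is looked up
    in ``a_tilde_by_source``.  No physics is supplied by default: an
    empty table contributes exactly 0.
    """
    if not contributions:
        return 0.0
    if a_tilde_by_source is None:
        raise ValueError("cumulated activities required for cross-dose sources")
    total = 0.0
    for source, per_a_tilde in contributions.items():
        if source not in a_tilde_by_source:
            raise KeyError(f"no cumulated activity for source organ {source!r}")
        total += a_tilde_by_source[source].a_tilde_s * per_a_tilde
    return total
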