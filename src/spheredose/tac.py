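"""Time–activity curves and cumulated activity.

A decay-corrected uptake series (%IA/g) is converted to the actual
whole-organ activity fraction A(t)/A_injected by multiplying by organ
mass and re-applying physical decay.  Cumulated activity Ã (MBq·s per
MBq injected, i.e. seconds) is the trapezoidal integral over the sampled
curve plus an analytic physical-decay-only tail beyond the last
timepoint:

    Ã = Σ trapezoids + f(t_last) / λ_phys
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biodist import UptakeSeries
from .nuclides import NuclideRecord

__all__ = ["TimeActivityCurve", "CumulatedActivity", "build_tac", "cumulated_activity"]

S_PER_H = 3600.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Whole-organ activity per unit injected activity vs time."""

    organ: str
    times_s: tuple[float, ...]
    activity_fraction: tuple[float, ...]

    def __post_init__(self):
        if len(self.times_s) != len(self.activity_fraction):
            raise ValueError("times and activities differ in length")
        if self.times_s and self.times_s[0] < 0:
            raise ValueError("first time must be >= 0")
        if not all(b > a for a, b in zip(self.times_s, self.times_s[1:])):
            raise ValueError("times must be strictly increasing")
        if any(a < 0 for a in self.activity_fraction):
            raise ValueError("activity fractions must be >= 0")


@dataclass(frozen=True)
class CumulatedActivity:
    """Ã split into sampled (trapezoid) and extrapolated (tail) parts, seconds."""

    organ: str
    a_tilde_s: float
    trapezoid_part_s: float
    tail_part_s: float

    def __post_init__(self):
        if self.trapezoid_part_s < 0 or self.tail_part_s < 0:
            raise ValueError("parts must be >= 0")
        if not math.isclose(
            self.a_tilde_s, self.trapezoid_part_s + self.tail_part_s, rel_tol=1e-12, abs_tol=1e-300
        ):
            raise ValueError("a_tilde must equal trapezoid + tail")


def build_tac(
    series: UptakeSeries,
    organ_mass_g: float,
    nuclide: NuclideRecord,
    anchor_mode: str = "zero",
) -> TimeActivityCurve:
    """Actual-activity TAC from a decay-corrected uptake series.

    activity_fraction(t) = mean %IA/g(t)/100 × organ_mass × exp(−λ_phys t).
    ``anchor_mode`` controls the t=0 point when the first measurement is
    later: "zero" prepends (0, 0) (IV agent, organ uptake starts empty);
    "hold_first" holds the first measured per-gram value back to t=0
    (appropriate for blood).
    """
    if organ_mass_g <= 0:
        raise ValueError("organ_mass_g must be > 0")
    if anchor_mode not in ("zero", "hold_first"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    lam = nuclide.decay_constant
    times = [t * S_PER_H for t in series.times_h]
    fracs = [
        (p / 100.0) * organ_mass_g * math.exp(-lam * t)
        for p, t in zip(series.mean_pia_per_g, times)
    ]
    if times and times[0] > 0:
        if anchor_mode == "zero":
            times.insert(0, 0.0)
            fracs.insert(0, 0.0)
        else:
            times.insert(0, 0.0)
            fracs.insert(0, (series.mean_pia_per_g[0] / 100.0) * organ_mass_g)
    return TimeActivityCurve(series.organ, tuple(times), tuple(fracs))


def cumulated_activity(tac: TimeActivityCurve, nuclide: NuclideRecord) -> CumulatedActivity:
    """Trapezoid-plus-physical-tail cumulated activity of a TAC, seconds.

    Beyond the last sample the activity is assumed to follow physical
    decay only, contributing f(t_last)/λ.  A stable nuclide has no
    physical tail and is rejected (infinite integral).
    """
    if not any(t > 0 for t in tac.times_s):
        raise ValueError("need at least one point with positive time")
    if nuclide.stable:
        raise ValueError("infinite tail: stable nuclide has no physical decay")
    lam = nuclide.decay_constant
    t = np.asarray(tac.times_s)
    f = np.asarray(tac.activity_fraction)
    trapezoid = float(np.trapezoid(f, t))
    tail = float(f[-1] / lam)
    return CumulatedActivity(tac.organ, trapezoid + tail, trapezoid, tail)
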