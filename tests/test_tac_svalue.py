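"""TAC construction, cumulated activity, and sphere S-values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spheredose as sd
from spheredose.nuclides import RadiationClass
from spheredose.tac import TimeActivityCurve


def _series(times_h, values, organ="tumor"):
    n = len(times_h)
    return sd.UptakeSeries(
        organ=organ,
        times_h=tuple(times_h),
        mean_pia_per_g=tuple(values),
        sem=(0.0,) * n,
        n=(1,) * n,
    )


# --- build_tac -------------------------------------------------------------


def test_build_tac_applies_physical_decay_and_anchor():
    y90 = sd.get_nuclide("Y-90")
    series = _series([24.0, 48.0], [10.0, 10.0])
    tac = sd.build_tac(series, organ_mass_g=2.0, nuclide=y90)
    assert tac.times_s[0] == 0.0 and tac.activity_fraction[0] == 0.0
    for t_s, f in zip(tac.times_s[1:], tac.activity_fraction[1:]):
        expected = 0.10 * 2.0 * math.exp(-y90.decay_constant * t_s)
        assert f == pytest.approx(expected, rel=1e-12)
    # constant decay-corrected uptake decays with the physical half-life
    ratio = tac.activity_fraction[2] / tac.activity_fraction[1]
    assert ratio == pytest.approx(math.exp(-y90.decay_constant * 24 * 3600), rel=1e-12)


def test_build_tac_hold_first_anchor_for_blood():
    y90 = sd.get_nuclide("Y-90")
    series = _series([3.0], [20.0], organ="blood")
    tac = sd.build_tac(series, 1.46, y90, anchor_mode="hold_first")
    assert tac.activity_fraction[0] == pytest.approx(0.20 * 1.46, rel=1e-12)


def test_build_tac_zero_uptake_gives_zero_curve():
    tac = sd.build_tac(_series([3.0, 24.0], [0.0, 0.0]), 1.0, sd.get_nuclide("Ac-225"))
    assert all(f == 0 for f in tac.activity_fraction)


# --- cumulated activity ----------------------------------------------------


def test_cumulated_activity_zero_curve():
    tac = TimeActivityCurve("t", (0.0, 100.0), (0.0, 0.0))
    a = sd.cumulated_activity(tac, sd.get_nuclide("Y-90"))
    assert a.a_tilde_s == 0.0


def test_cumulated_activity_pure_decay_matches_1_over_lambda():
    """Dense sampling of f(t)=exp(-lam t) + tail reproduces 1/lam to 0.1%."""
    y90 = sd.get_nuclide("Y-90")
    lam = y90.decay_constant
    t = np.linspace(0.0, 10 * y90.half_life_s, 1000)
    tac = TimeActivityCurve("o", tuple(t), tuple(np.exp(-lam * t)))
    a = sd.cumulated_activity(tac, y90)
    assert a.a_tilde_s == pytest.approx(1.0 / lam, rel=1e-3)


def test_cumulated_activity_single_point_rule():
    """One sample (t1, f1) with zero anchor: trapezoid t1*f1/2 plus tail f1/lam."""
    lu = sd.get_nuclide("Lu-177")
    t1, f1 = 7200.0, 0.25
    tac = TimeActivityCurve("o", (0.0, t1), (0.0, f1))
    a = sd.cumulated_activity(tac, lu)
    assert a.trapezoid_part_s == pytest.approx(t1 * f1 / 2, rel=1e-12)
    assert a.tail_part_s == pytest.approx(f1 / lu.decay_constant, rel=1e-12)
    assert a.a_tilde_s == pytest.approx(a.trapezoid_part_s + a.tail_part_s, rel=1e-12)


def test_cumulated_activity_rejects_stable_nuclide():
    tac = TimeActivityCurve("o", (0.0, 10.0), (0.0, 1.0))
    with pytest.raises(ValueError, match="infinite tail"):
        sd.cumulated_activity(tac, sd.get_nuclide("Bi-209"))


@settings(deadline=None, max_examples=40)
@given(
    f=st.lists(st.floats(0, 1), min_size=2, max_size=6),
    bump=st.floats(0.01, 1.0),
    idx=st.integers(0, 5),
)
def test_a_tilde_monotone_in_activity_and_linear(f, bump, idx):
    lu = sd.get_nuclide("Lu-177")
    times = tuple(3600.0 * (i + 1) for i in range(len(f)))
    base = sd.cumulated_activity(TimeActivityCurve("o", times, tuple(f)), lu)
    raised = list(f)
    raised[idx % len(f)] += bump
    up = sd.cumulated_activity(TimeActivityCurve("o", times, tuple(raised)), lu)
    assert up.a_tilde_s >= base.a_tilde_s
    doubled = sd.cumulated_activity(
        TimeActivityCurve("o", times, tuple(2 * x for x in f)), lu
    )
    assert doubled.a_tilde_s == pytest.approx(2 * base.a_tilde_s, rel=1e-9, abs=1e-12)


def test_grid_refinement_converges_to_analytic_biexponential_integral():
    """Trapezoid of a decaying convex curve decreases toward the true integral."""
    ac = sd.get_nuclide("Ac-225")
    lam = ac.decay_constant
    lw, lu_rate = 1e-6, 2e-5  # 1/s biological rates

    def f(t):
        return (np.exp(-lw * t) - np.exp(-lu_rate * t)) * np.exp(-lam * t)

    t_end = 10 * ac.half_life_s
    analytic = 1.0 / (lw + lam) - 1.0 / (lu_rate + lam)
    # monotone decrease of the trapezoid part holds for a convex decaying
    # curve (pure exponential); the biexponential's concave rise breaks it
    prev = None
    for n in (50, 200, 800):
        t = np.linspace(0, t_end, n)
        a = sd.cumulated_activity(
            TimeActivityCurve("o", tuple(t), tuple(np.exp(-lam * t))), ac
        )
        if prev is not None:
            assert a.trapezoid_part_s <= prev + 1e-9
        prev = a.trapezoid_part_s
    # dense biexponential matches its analytic integral
    t = np.linspace(0, t_end, 2000)
    a = sd.cumulated_activity(TimeActivityCurve("o", tuple(t), tuple(f(t))), ac)
    assert a.a_tilde_s == pytest.approx(analytic, rel=5e-3)


# --- sphere S-values -------------------------------------------------------


def test_radius_from_mass_closed_form():
    assert sd.radius_from_mass(4 * math.pi / 3) == pytest.approx(1.0, rel=1e-12)
    assert sd.radius_from_mass(1.0) == pytest.approx(0.6204, rel=1e-3)
    assert sd.radius_from_mass(8.0) == pytest.approx(2 * sd.radius_from_mass(1.0), rel=1e-12)


def test_radius_rejects_non_positive_mass():
    with pytest.raises(ValueError):
        sd.radius_from_mass(0.0)


def test_s_value_unit_alpha_emitter_forced_constant():
    """Delta = 1 MeV/decay in 1 g with phi=1 gives 0.16022 mGy/(MBq s)."""
    rec = sd.NuclideRecord(
        symbol="Test-1",
        half_life_s=1000.0,
        emissions=(sd.EmissionSummary(RadiationClass.ALPHA, 1.0),),
        beta_emax_mev=0.0,
        daughters=(("Bi-209", 1.0, "alpha"),),
        stable=False,
    )
    s = sd.s_value(rec, 1.0)
    assert s.s_mgy_per_mbq_s == pytest.approx(0.16022, rel=1e-4)


def test_s_value_scales_inverse_with_mass_and_ignores_photons_by_default():
    y90 = sd.get_nuclide("Y-90")
    s1 = sd.s_value(y90, 0.1)
    s2 = sd.s_value(y90, 0.2)
    assert s1.s_mgy_per_mbq_s == pytest.approx(2 * s2.s_mgy_per_mbq_s, rel=1e-12)


def test_s_value_matches_independent_hand_sum():
    y90 = sd.get_nuclide("Y-90")
    mass = 0.1
    hand = sum(e.delta for e in y90.emissions if e.radiation_class.value != "photon")
    hand = hand * 1.602176634e-13 * 1e6 / (mass * 1e-3) * 1e3
    assert sd.s_value(y90, mass).s_mgy_per_mbq_s == pytest.approx(hand, rel=1e-9)


def test_photon_analytic_mode_adds_partial_absorption():
    lu = sd.get_nuclide("Lu-177")  # has photon lines
    base = sd.s_value(lu, 1.0, sd.SValueConfig(photon_mode="ignore"))
    withp = sd.s_value(lu, 1.0, sd.SValueConfig(photon_mode="analytic"))
    assert withp.s_mgy_per_mbq_s > base.s_mgy_per_mbq_s
    # photon absorbed fraction is far below 1 in a 1 g sphere
    photon = withp.s_mgy_per_mbq_s - base.s_mgy_per_mbq_s
    full = 0.0334 * 1.602176634e-13 * 1e6 / 1e-3 * 1e3
    assert photon < 0.05 * full


def test_chain_s_value_matches_member_sum_and_dominates_parent():
    chain = sd.build_chain("Ac-225")
    mass = 0.1
    hand = sum(
        cb * sd.s_value(sd.get_nuclide(sym), mass).s_mgy_per_mbq_s
        for sym, cb in chain.members
    )
    s = sd.chain_s_value(chain, mass)
    assert s.s_mgy_per_mbq_s == pytest.approx(hand, rel=1e-9)
    assert s.s_mgy_per_mbq_s > sd.s_value(sd.get_nuclide("Ac-225"), mass).s_mgy_per_mbq_s
    total = sum(s.breakdown.values())
    assert total == pytest.approx(s.s_mgy_per_mbq_s, rel=1e-9)


def test_degenerate_chain_s_equals_parent_s():
    chain = sd.build_chain("Y-90")
    s_chain = sd.chain_s_value(chain, 0.5)
    s_parent = sd.s_value(sd.get_nuclide("Y-90"), 0.5)
    assert s_chain.s_mgy_per_mbq_s == pytest.approx(s_parent.s_mgy_per_mbq_s, rel=1e-12)
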