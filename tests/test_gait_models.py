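"""Idealized gait cycles: construction invariants, steady solutions, works."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitwork.gait_models import (
    GAIT_NAMES,
    BallisticPhase,
    GaitCycle,
    ImpulseEvent,
    _stride_work_batch,
    build_gait,
    solve_steady_cycle,
    stride_work,
)

THETA10 = math.radians(10.0)
speeds = st.floats(min_value=0.2, max_value=6.0)
thetas = st.floats(min_value=0.0, max_value=math.radians(44.0))


@pytest.mark.parametrize("name", GAIT_NAMES)
def test_cycle_invariants(name):
    gait = build_gait(name, THETA10)
    impulses = gait.impulses
    assert sum(e.vertical_share for e in impulses) == pytest.approx(1.0)
    assert sum(
        e.vertical_share * math.tan(e.inclination) for e in impulses
    ) == pytest.approx(0.0, abs=1e-15)
    fracs = [e.fraction for e in gait.events if isinstance(e, BallisticPhase)]
    assert sum(fracs) == pytest.approx(1.0)
    for e in impulses:
        sign = {"hind": 1, "fore": -1, "pair": 0}[e.limb]
        assert e.inclination == pytest.approx(sign * THETA10)


def test_trot_clusters_are_net_vertical_pairs():
    gait = build_gait("trot", THETA10)
    assert [e.limb for e in gait.impulses] == ["pair", "pair"]
    assert all(e.inclination == 0.0 for e in gait.impulses)
    assert [e.vertical_share for e in gait.impulses] == [0.5, 0.5]


def test_canter_weight_split_schemes():
    per_limb = build_gait("canter", THETA10, "per_limb_support")
    assert [e.vertical_share for e in per_limb.impulses] == [0.25, 0.5, 0.25]
    even = build_gait("canter", THETA10, "even_instants")
    assert [e.vertical_share for e in even.impulses] == pytest.approx([1 / 3] * 3)
    assert [e.limb for e in per_limb.impulses] == ["hind", "pair", "fore"]


def test_even_gallop_equals_tolt_at_zero_theta():
    """At theta = 0 the hind/fore ordering of identical vertical impulses is
    immaterial: the two cycles carry the same timing, shares and angles."""
    eg = build_gait("even_gallop", 0.0)
    tolt = build_gait("tolt", 0.0)

    def signature(gait):
        return [
            (e.inclination, e.vertical_share) if isinstance(e, ImpulseEvent)
            else ("ballistic", e.fraction)
            for e in gait.events
        ]

    assert signature(eg) == signature(tolt)
    w_eg = stride_work(eg, 1.0, 1.0).total_positive_work
    w_tolt = stride_work(tolt, 1.0, 1.0).total_positive_work
    assert w_eg == pytest.approx(w_tolt, rel=1e-12)


def test_unknown_gait_and_bad_theta_rejected():
    with pytest.raises(ValueError, match="unknown gait"):
        build_gait("pronk", 0.1)
    with pytest.raises(ValueError):
        build_gait("trot", math.pi / 2)
    with pytest.raises(ValueError):
        build_gait("canter", 0.1, "thirds")


def test_inconsistent_cluster_shares_rejected():
    events = (
        BallisticPhase(0.5),
        ImpulseEvent("pair", 0.0, 0.4),
        BallisticPhase(0.5),
        ImpulseEvent("pair", 0.0, 0.6),
    )
    with pytest.raises(ValueError, match="cluster"):
        GaitCycle("trot", events)


class TestSteadyCycle:
    def test_canter_reference_velocities(self):
        """Landing at -gT/2 then hind, pair, fore bookkeeping at theta = 10 deg."""
        gait = build_gait("canter", THETA10, "per_limb_support")
        states = solve_steady_cycle(gait, 2.0, 1.0, 1.0, 1.0)
        got = [(v.vx, v.vy) for v in states]
        dx = 0.25 * math.tan(THETA10)  # 0.044081
        expect = [
            (2.0, 0.5),            # takeoff
            (2.0, -0.5),           # landing after the full-stride ballistic phase
            (2.0 + dx, -0.25),     # after solo hind
            (2.0 + dx, 0.25),      # after vertical pair
            (2.0, 0.5),            # after solo fore: periodic
        ]
        for (gx, gy), (ex, ey) in zip(got, expect):
            assert gx == pytest.approx(ex, abs=1e-12)
            assert gy == pytest.approx(ey, abs=1e-12)

    def test_trot_and_tolt_vertical_velocities(self):
        trot = solve_steady_cycle(build_gait("trot", THETA10), 3.0, 1.0, 1.0, 1.0)
        assert {round(abs(v.vy), 12) for v in trot} == {0.25}
        assert all(v.vx == pytest.approx(3.0) for v in trot)
        tolt = solve_steady_cycle(build_gait("tolt", 0.0), 3.0, 1.0, 1.0, 1.0)
        assert {round(abs(v.vy), 12) for v in tolt} == {0.125}

    @settings(max_examples=60, deadline=None)
    @given(name=st.sampled_from(GAIT_NAMES), speed=speeds, theta=thetas,
           period=st.floats(min_value=0.2, max_value=3.0))
    def test_periodicity_and_mean_speed(self, name, speed, theta, period):
        gait = build_gait(name, theta)
        states = solve_steady_cycle(gait, speed, period, 1.0, 1.0)
        first, last = states[0], states[-1]
        assert last.vx == pytest.approx(first.vx, abs=1e-12 * max(1, speed))
        assert last.vy == pytest.approx(first.vy, abs=1e-12)
        # duration-weighted mean of vx over ballistic phases equals the mean speed
        mean = sum(
            e.fraction * states[i].vx
            for i, e in enumerate(gait.events)
            if isinstance(e, BallisticPhase)
        )
        assert mean == pytest.approx(speed, rel=1e-12)

    def test_even_gallop_phase_speeds_bracket_the_mean(self):
        """Phases sit at Vbar-d, Vbar, Vbar+d, Vbar with d = gT tan(theta)/4."""
        gait = build_gait("even_gallop", THETA10)
        states = solve_steady_cycle(gait, 2.0, 1.0, 1.0, 1.0)
        d = math.tan(THETA10) / 4.0
        phase_vx = [states[i].vx for i, e in enumerate(gait.events)
                    if isinstance(e, BallisticPhase)]
        assert phase_vx == pytest.approx([2.0 - d, 2.0, 2.0 + d, 2.0], abs=1e-12)

    def test_invalid_parameters_rejected(self):
        gait = build_gait("trot", 0.0)
        with pytest.raises(ValueError):
            solve_steady_cycle(gait, -1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            solve_steady_cycle(gait, 1.0, 0.0, 1.0, 1.0)


class TestStrideWork:
    def test_trot_unit_work(self):
        s = stride_work(build_gait("trot", THETA10), 1.7, 1.0)
        assert s.total_positive_work == pytest.approx(0.0625, rel=1e-12)
        assert s.work_ratio_to_trot == pytest.approx(1.0)

    def test_tolt_unit_work(self):
        s = stride_work(build_gait("tolt", 0.0), 1.0, 1.0)
        assert s.total_positive_work == pytest.approx(0.03125, rel=1e-12)
        assert s.work_ratio_to_trot == pytest.approx(0.5)

    def test_gathered_gallop_vertical_limit(self):
        """At theta = 0 the four clustered impulses act as one big reversal:
        work = g^2 T^2 / 8, twice the trot."""
        s = stride_work(build_gait("gathered_gallop", 0.0), 1.0, 1.0)
        assert s.total_positive_work == pytest.approx(0.125, rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(speed=speeds)
    def test_trot_work_independent_of_speed(self, speed):
        s = stride_work(build_gait("trot", THETA10), speed, 1.0)
        assert s.total_positive_work == pytest.approx(0.0625, rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(name=st.sampled_from(GAIT_NAMES), speed=speeds,
           theta=st.floats(min_value=0.01, max_value=math.radians(40.0)))
    def test_cost_ratio_scale_invariance(self, name, speed, theta):
        """Doubling speed and period together leaves every work ratio fixed:
        only (speed/(gT), theta) matters."""
        gait = build_gait(name, theta)
        a = stride_work(gait, speed, 1.0, n_divisions=None)
        b = stride_work(gait, 2.0 * speed, 2.0, n_divisions=None)
        assert a.work_ratio_to_trot == pytest.approx(b.work_ratio_to_trot, rel=1e-9)

    def test_total_is_sum_of_per_impulse(self):
        s = stride_work(build_gait("canter", THETA10), 2.0, 1.0)
        assert s.total_positive_work == pytest.approx(
            sum(o.positive_work for o in s.per_impulse)
        )

    def test_gathered_gallop_doubled_impulse_equivalence(self):
        """Two identical consecutive limb impulses equal one doubled impulse."""
        gait = build_gait("gathered_gallop", THETA10)
        s = stride_work(gait, 2.0, 1.0, n_divisions=None)
        # doubled-impulse surrogate cycle: one hind(1/2), one fore(1/2)
        surrogate = GaitCycle(
            "gathered_gallop",
            (
                BallisticPhase(1.0),
                ImpulseEvent("hind", THETA10, 0.5),
                ImpulseEvent("fore", -THETA10, 0.5),
            ),
        )
        s2 = stride_work(surrogate, 2.0, 1.0, n_divisions=None)
        assert s.total_positive_work == pytest.approx(s2.total_positive_work, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(speed=speeds)
    def test_even_gallop_converges_to_tolt_as_theta_shrinks(self, speed):
        """The two cost curves approach each other as theta shrinks and
        coincide exactly at zero; they may cross on the way (the two gaits
        are functionally indistinguishable at small inclinations)."""
        rel = {}
        for theta in (0.2, 0.05, 0.0):
            w_eg = stride_work(build_gait("even_gallop", theta), speed, 1.0,
                               n_divisions=None).total_positive_work
            w_to = stride_work(build_gait("tolt", theta), speed, 1.0,
                               n_divisions=None).total_positive_work
            rel[theta] = abs(w_eg - w_to) / w_to
        assert rel[0.0] == pytest.approx(0.0, abs=1e-15)
        assert rel[0.05] < 0.01
        assert rel[0.2] < 0.05

    def test_batch_path_matches_scalar_path(self):
        ratios = np.array([0.5, 1.0, 2.0, 3.5])
        for name in GAIT_NAMES:
            gait = build_gait(name, THETA10)
            batch = _stride_work_batch(gait, ratios, 1.0, 1.0, 1.0, 100)
            scalar = [stride_work(gait, float(r), 1.0).total_positive_work for r in ratios]
            assert batch == pytest.approx(scalar, rel=1e-12)

    def test_summary_serializes_to_json(self):
        import json

        s = stride_work(build_gait("canter", THETA10), 2.0, 1.0)
        d = json.loads(s.to_json())
        assert d["gait"] == "canter" and len(d["per_impulse"]) == 3
        assert d["per_impulse"][1]["pseudoelastic"] is True
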