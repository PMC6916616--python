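"""Idealized zero-pitch impulsive gait cycles and their per-stride work.

With vanishing pitch inertia every impulse (or simultaneous pair) must pass
through the CoM.  Unpaired hind impulses are therefore inclined forward of
vertical by an angle θ and fore impulses backward by the same angle;
synchronous hind-fore pairs are net vertical.  Five footfall patterns are
modelled, each as an ordered cycle of ballistic phases (parabolic flight,
gravity only) and instantaneous impulse clusters:

* trot            — two ballistic phases, two synchronous hind-fore pairs;
* tolt            — four even ballistic phases, alternating hind / fore;
* canter          — one ballistic phase, then hind, hind-fore pair, fore in
                    immediate succession (weight split 1/4, 1/2, 1/4 per limb
                    support, or 1/3 each under the ``even_instants`` scheme);
* gathered gallop — one ballistic phase, then hind, hind, fore, fore;
* even gallop     — four even ballistic phases, order hind, hind, fore, fore.

Each limb's vertical impulse component is its share of the total stride
support impulse ``m g T``; its horizontal component is vertical·tanθ,
signed by limb.  Steady cycles are solved exactly: vertical velocities
follow ballistics (±g·τ/2 around each symmetric arc, so CoM height is equal
at every impulse instant), the horizontal velocity is piecewise constant,
and its time average over the stride is pinned to the mean speed.  The work
of every impulse then comes from :mod:`gaitwork.collision_core`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from gaitwork.collision_core import (
    CollisionOutcome,
    ImpulseVector,
    PlanarVelocity,
    _collision_arrays,
    impulse_work_closed_form,
    impulse_work_numeric,
)

__all__ = [
    "GAIT_NAMES",
    "CANTER_SCHEMES",
    "ImpulseEvent",
    "BallisticPhase",
    "GaitCycle",
    "GaitWorkSummary",
    "build_gait",
    "solve_steady_cycle",
    "stride_work",
]

GAIT_NAMES = ("tolt", "trot", "canter", "gathered_gallop", "even_gallop")
CANTER_SCHEMES = ("per_limb_support", "even_instants")

_SIGN = {"hind": 1.0, "fore": -1.0, "pair": 0.0}


@dataclass(frozen=True)
class ImpulseEvent:
    """One momentary limb impulse within a stride.

    ``limb`` is hind, fore or pair; ``inclination`` is the angle from
    vertical (rad, positive tilts the impulse to accelerate the body
    forward: +θ for hind, -θ for fore, 0 for pairs); ``vertical_share``
    is this impulse's fraction of the total stride vertical impulse mgT.
    """

    limb: str
    inclination: float
    vertical_share: float

    def __post_init__(self) -> None:
        if self.limb not in _SIGN:
            raise ValueError(f"limb must be one of {tuple(_SIGN)}, got {self.limb!r}")
        if not 0.0 < self.vertical_share <= 1.0:
            raise ValueError(f"vertical_share must be in (0, 1], got {self.vertical_share}")
        if self.limb == "pair" and self.inclination != 0.0:
            raise ValueError("paired hind-fore impulses are net vertical (inclination 0)")
        if self.limb != "pair" and self.inclination * _SIGN[self.limb] < 0.0:
            raise ValueError(f"{self.limb} inclination has the wrong sign")


@dataclass(frozen=True)
class BallisticPhase:
    """Airborne interval; ``fraction`` is its duration as a stride fraction."""

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"ballistic fraction must be in (0, 1], got {self.fraction}")


Event = Union[ImpulseEvent, BallisticPhase]


@dataclass(frozen=True)
class GaitCycle:
    """One stride: an ordered alternation of ballistic phases and impulses.

    Consecutive ImpulseEvents form a cluster applied at literally zero
    elapsed time, in order.  Construction checks the steady-cycle
    invariants: vertical shares sum to one (weight support over the
    stride), signed horizontal components cancel, ballistic fractions sum
    to one, and each cluster's vertical impulse matches the ballistic
    landing/takeoff velocities on either side so the motion is periodic
    with equal CoM height at every impulse instant.
    """

    name: str
    events: tuple
    canter_scheme: str | None = None

    def __post_init__(self) -> None:
        impulses = [e for e in self.events if isinstance(e, ImpulseEvent)]
        phases = [e for e in self.events if isinstance(e, BallisticPhase)]
        if len(impulses) + len(phases) != len(self.events):
            raise ValueError("events must be ImpulseEvent or BallisticPhase instances")
        if not impulses or not phases:
            raise ValueError("a gait cycle needs at least one impulse and one ballistic phase")
        share_sum = sum(e.vertical_share for e in impulses)
        if abs(share_sum - 1.0) > 1e-12:
            raise ValueError(f"vertical shares must sum to 1, got {share_sum}")
        horiz = sum(e.vertical_share * math.tan(e.inclination) for e in impulses)
        if abs(horiz) > 1e-12:
            raise ValueError(f"signed horizontal impulse components must cancel, got {horiz}")
        frac_sum = sum(p.fraction for p in phases)
        if abs(frac_sum - 1.0) > 1e-12:
            raise ValueError(f"ballistic fractions must sum to 1, got {frac_sum}")
        # each cluster must reverse the ballistic vertical velocity:
        # -g*tau_prev/2  ->  +g*tau_next/2, i.e. cluster share = (tau_prev+tau_next)/2
        seq = list(self.events)
        n = len(seq)
        for i, e in enumerate(seq):
            if isinstance(e, BallisticPhase):
                continue
            if isinstance(seq[i - 1], ImpulseEvent):
                continue  # interior of a cluster; checked at its head
            cluster = [e]
            k = (i + 1) % n
            while isinstance(seq[k], ImpulseEvent):
                cluster.append(seq[k])
                k = (k + 1) % n
            tau_prev = seq[i - 1].fraction
            tau_next = seq[k].fraction
            need = 0.5 * (tau_prev + tau_next)
            got = sum(c.vertical_share for c in cluster)
            if abs(got - need) > 1e-12:
                raise ValueError(
                    f"impulse cluster at position {i} supplies vertical share {got}, "
                    f"but the surrounding ballistics require {need}"
                )

    @property
    def impulses(self) -> list[ImpulseEvent]:
        return [e for e in self.events if isinstance(e, ImpulseEvent)]


def build_gait(
    name: str,
    theta: float,
    canter_scheme: str = "per_limb_support",
) -> GaitCycle:
    """Construct one of the five idealized zero-pitch gait cycles.

    ``theta`` (rad, 0 <= θ < π/2) inclines every unpaired impulse: hind
    +θ, fore -θ.  ``canter_scheme`` picks the canter's weight split:
    ``per_limb_support`` gives each limb an equal share (so the paired
    middle impulse is double a solo one, shares 1/4, 1/2, 1/4);
    ``even_instants`` splits evenly across the three instants (1/3 each).
    """
    if not 0.0 <= theta < math.pi / 2:
        raise ValueError(f"theta must satisfy 0 <= theta < pi/2, got {theta}")
    if canter_scheme not in CANTER_SCHEMES:
        raise ValueError(f"canter_scheme must be one of {CANTER_SCHEMES}, got {canter_scheme!r}")

    def hind(share: float) -> ImpulseEvent:
        return ImpulseEvent("hind", theta, share)

    def fore(share: float) -> ImpulseEvent:
        return ImpulseEvent("fore", -theta, share)

    def pair(share: float) -> ImpulseEvent:
        return ImpulseEvent("pair", 0.0, share)

    B = BallisticPhase
    if name == "trot":
        events = (B(0.5), pair(0.5), B(0.5), pair(0.5))
    elif name == "tolt":
        events = (B(0.25), hind(0.25), B(0.25), fore(0.25),
                  B(0.25), hind(0.25), B(0.25), fore(0.25))
    elif name == "canter":
        if canter_scheme == "per_limb_support":
            shares = (0.25, 0.5, 0.25)
        else:
            shares = (1 / 3, 1 / 3, 1 / 3)
        events = (B(1.0), hind(shares[0]), pair(shares[1]), fore(shares[2]))
    elif name == "gathered_gallop":
        events = (B(1.0), hind(0.25), hind(0.25), fore(0.25), fore(0.25))
    elif name == "even_gallop":
        events = (B(0.25), hind(0.25), B(0.25), hind(0.25),
                  B(0.25), fore(0.25), B(0.25), fore(0.25))
    else:
        raise ValueError(f"unknown gait {name!r}; expected one of {GAIT_NAMES}")
    return GaitCycle(name=name, events=events,
                     canter_scheme=canter_scheme if name == "canter" else None)


def _boundary_states(gait: GaitCycle, mean_speed, stride_period: float, mass: float, g: float):
    """Velocities at every event boundary; ``mean_speed`` may be an array.

    Returns ``(vx_list, vy_list)`` of length ``len(events) + 1``: entry 0
    is the state at the start of the first event, entry i+1 the state
    after event i.  Vertical velocities are fixed by the ballistic
    timing; the horizontal level is set so the duration-weighted average
    of vx over the ballistic phases equals ``mean_speed``.
    """
    T, m = stride_period, mass
    vbar = np.asarray(mean_speed, dtype=float)

    # horizontal offsets (relative to the first ballistic phase) and
    # vertical velocity at each boundary, walking the cycle once
    first = gait.events[0]
    if isinstance(first, BallisticPhase):
        vy0 = 0.5 * g * first.fraction * T
    else:  # cycle starting mid-cluster is not produced by build_gait
        raise ValueError("gait cycle must start with a ballistic phase")
    offsets = [0.0]
    vys = [vy0]
    for e in gait.events:
        if isinstance(e, BallisticPhase):
            offsets.append(offsets[-1])
            vys.append(vys[-1] - g * e.fraction * T)
        else:
            jy = e.vertical_share * m * g * T
            jx = jy * math.tan(e.inclination)
            offsets.append(offsets[-1] + jx / m)
            vys.append(vys[-1] + jy / m)
    assert abs(vys[-1] - vys[0]) <= 1e-12 * max(1.0, abs(vys[0])), "cycle not periodic"
    assert abs(offsets[-1]) <= 1e-12 * max(1.0, g * T), "horizontal drift over cycle"

    # pin the time-averaged horizontal velocity to mean_speed
    weighted = 0.0
    for i, e in enumerate(gait.events):
        if isinstance(e, BallisticPhase):
            weighted += e.fraction * offsets[i]
    base = vbar - weighted
    vxs = [base + c for c in offsets]
    return vxs, vys


def solve_steady_cycle(
    gait: GaitCycle,
    mean_speed: float,
    stride_period: float,
    mass: float,
    g: float,
) -> list[PlanarVelocity]:
    """Exact periodic CoM velocities at every event boundary of a stride.

    Incoming velocities follow ballistics (takeoff +gτ/2, landing -gτ/2
    over a phase of duration τ) or the state after an immediately
    preceding impulse; the stride's time-averaged horizontal velocity
    equals ``mean_speed``.  Entry 0 is the start-of-cycle (takeoff)
    state; entry i+1 follows event i, so the last entry closes the loop.
    """
    for name, v in (("mean_speed", mean_speed), ("stride_period", stride_period),
                    ("mass", mass), ("g", g)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    vxs, vys = _boundary_states(gait, mean_speed, stride_period, mass, g)
    return [PlanarVelocity(float(vx), float(vy)) for vx, vy in zip(vxs, vys)]


@dataclass(frozen=True)
class GaitWorkSummary:
    """Per-impulse outcomes and per-stride totals for one gait condition."""

    gait: str
    per_impulse: tuple
    total_positive_work: float
    work_ratio_to_trot: float
    mean_speed: float = 1.0
    stride_period: float = 1.0
    mass: float = 1.0
    g: float = 1.0
    theta: float = 0.0

    def to_dict(self) -> dict:
        return {
            "gait": self.gait,
            "theta_deg": math.degrees(self.theta),
            "mean_speed": self.mean_speed,
            "stride_period": self.stride_period,
            "mass": self.mass,
            "g": self.g,
            "total_positive_work": self.total_positive_work,
            "work_ratio_to_trot": self.work_ratio_to_trot,
            "per_impulse": [
                {
                    "positive_work": o.positive_work,
                    "dissipated_energy": o.dissipated_energy,
                    "speed_before": o.speed_before,
                    "speed_after": o.speed_after,
                    "speed_min": o.speed_min,
                    "pseudoelastic": o.pseudoelastic,
                }
                for o in self.per_impulse
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _impulse_outcomes(
    gait: GaitCycle,
    mean_speed: float,
    stride_period: float,
    mass: float,
    g: float,
    n_divisions: int | None,
) -> list[CollisionOutcome]:
    """Collision outcome of every impulse, chained through clusters."""
    states = solve_steady_cycle(gait, mean_speed, stride_period, mass, g)
    outcomes = []
    for i, e in enumerate(gait.events):
        if not isinstance(e, ImpulseEvent):
            continue
        u = states[i]
        jy = e.vertical_share * mass * g * stride_period
        j = ImpulseVector(jy * math.tan(e.inclination), jy)
        if n_divisions is None:
            outcomes.append(impulse_work_closed_form(u, j, mass))
        else:
            outcomes.append(impulse_work_numeric(u, j, mass, n_divisions))
    return outcomes


def stride_work(
    gait: GaitCycle,
    mean_speed: float,
    stride_period: float,
    mass: float = 1.0,
    g: float = 1.0,
    n_divisions: int | None = 100,
) -> GaitWorkSummary:
    """Per-stride positive CoM work of a gait, normalized to trot.

    Every impulse is passed through the collision engine (sub-impulse
    quadrature with ``n_divisions`` pieces, or the exact closed form when
    ``n_divisions`` is None); consecutive impulses chain, the output
    velocity of one feeding the next.  ``work_ratio_to_trot`` compares
    against trot at the same speed, period, mass and gravity — trot's own
    work, m g²T²/16, is independent of speed.
    """
    outcomes = _impulse_outcomes(gait, mean_speed, stride_period, mass, g, n_divisions)
    total = sum(o.positive_work for o in outcomes)
    if gait.name == "trot":
        trot_total = total
    else:
        trot = build_gait("trot", 0.0)
        trot_total = sum(
            o.positive_work
            for o in _impulse_outcomes(trot, mean_speed, stride_period, mass, g, n_divisions)
        )
    theta = max((abs(e.inclination) for e in gait.impulses), default=0.0)
    return GaitWorkSummary(
        gait=gait.name,
        per_impulse=tuple(outcomes),
        total_positive_work=total,
        work_ratio_to_trot=total / trot_total,
        mean_speed=mean_speed,
        stride_period=stride_period,
        mass=mass,
        g=g,
        theta=theta,
    )


def _stride_work_batch(
    gait: GaitCycle,
    mean_speeds: np.ndarray,
    stride_period: float,
    mass: float,
    g: float,
    n_divisions: int | None,
) -> np.ndarray:
    """Total positive stride work for a vector of mean speeds.

    Vectorized twin of :func:`stride_work` used by the map sweeps; agrees
    with the scalar path elementwise (same engine, same chaining).
    """
    vxs, vys = _boundary_states(gait, mean_speeds, stride_period, mass, g)
    total = np.zeros_like(np.asarray(mean_speeds, dtype=float))
    for i, e in enumerate(gait.events):
        if not isinstance(e, ImpulseEvent):
            continue
        jy = e.vertical_share * mass * g * stride_period
        jx = jy * math.tan(e.inclination)
        if n_divisions is None:
            pos = _closed_form_positive(vxs[i], vys[i], jx, jy, mass)
        else:
            pos, _, _ = _collision_arrays(vxs[i], vys[i], jx, jy, mass, n_divisions)
        total = total + pos
    return total


def _closed_form_positive(ux, uy, jx, jy, mass):
    ux = np.asarray(ux, dtype=float)
    uy = np.asarray(uy, dtype=float)
    dx, dy = jx / mass, jy / mass
    vx, vy = ux + dx, uy + dy
    den = dx * dx + dy * dy
    if den == 0.0:
        return np.zeros_like(ux)
    t = np.clip(-(ux * dx + uy * dy) / den, 0.0, 1.0)
    mx, my = ux + t * dx, uy + t * dy
    return np.maximum(0.0, 0.5 * mass * (vx * vx + vy * vy - mx * mx - my * my))
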