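"""Work of a momentary impulse acting on a point-mass centre of mass.

A limb contact is reduced to an impulse ``J`` that carries the CoM velocity
from ``U`` (pre-impulse) to ``V = U + J/m`` along a straight segment in
velocity space.  While the speed decreases along that traversal kinetic
energy is dissipated; while it increases, positive muscle work must be
supplied.  Only and all the positive work is counted as costly.  The speed
minimum ``V_min`` is the point of the segment closest to zero velocity,
clamped to an endpoint when the perpendicular foot falls outside the
segment (then the impulse is purely generating or purely dissipating).
A collision with ``V_min`` strictly interior — speed falls, then rises —
is "pseudoelastic": the low-work way to redirect a trajectory.

Two evaluation routes are provided: a sub-impulse quadrature that splits
the impulse into ``n`` equal pieces and accumulates kinetic-energy
increments, and the exact closed form of that limit.  The numeric route is
the workhorse of the gait sweeps; the closed form is its oracle.

Units are SI throughout, but every quantity scales out, so the gait
comparisons elsewhere use the unit system m = g = T_stride = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlanarVelocity",
    "ImpulseVector",
    "CollisionOutcome",
    "DimensionlessState",
    "impulse_work_numeric",
    "impulse_work_closed_form",
    "to_dimensionless",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} components must be finite, got {values}")


@dataclass(frozen=True)
class PlanarVelocity:
    """Planar CoM velocity: ``vx`` along travel (m/s), ``vy`` up (m/s)."""

    vx: float
    vy: float

    def __post_init__(self) -> None:
        _require_finite("velocity", self.vx, self.vy)

    @property
    def speed(self) -> float:
        return math.hypot(self.vx, self.vy)


@dataclass(frozen=True)
class ImpulseVector:
    """Limb impulse components in N·s; ``jy >= 0`` for support impulses."""

    jx: float
    jy: float

    def __post_init__(self) -> None:
        _require_finite("impulse", self.jx, self.jy)

    @property
    def magnitude(self) -> float:
        return math.hypot(self.jx, self.jy)


@dataclass(frozen=True)
class CollisionOutcome:
    """Energy bookkeeping for one impulse.

    ``positive_work - dissipated_energy`` equals the net kinetic-energy
    change; ``speed_min`` is attained at ``V_min`` (possibly an endpoint).
    """

    positive_work: float
    dissipated_energy: float
    speed_before: float
    speed_after: float
    speed_min: float

    @property
    def net_work(self) -> float:
        return self.positive_work - self.dissipated_energy

    @property
    def pseudoelastic(self) -> bool:
        """True when the speed strictly dips below both endpoints."""
        return self.speed_min < self.speed_before and self.speed_min < self.speed_after


@dataclass(frozen=True)
class DimensionlessState:
    """Froude-style normalization of speed and stride period.

    ``v_hat_x = Vx / sqrt(g L_leg)`` (note the non-squared form),
    ``t_hat_stride = T / sqrt(L_leg / g)``; their ratio ``Vx/(g T)`` is
    leg-length free and governs the gait cost landscape.
    """

    v_hat_x: float
    t_hat_stride: float
    ratio: float


def _check_mass(mass: float) -> None:
    if not (mass > 0 and math.isfinite(mass)):
        raise ValueError(f"mass must be positive and finite, got {mass}")


def _collision_arrays(ux, uy, jx, jy, mass: float, n_divisions: int):
    """Sub-impulse traversal, vectorized over any leading array shape.

    Returns ``(positive, dissipated, speed_min)`` with the impulse applied
    in ``n_divisions`` equal pieces; the kinetic-energy increments between
    the n+1 velocity states are accumulated by sign.
    """
    ux, uy, jx, jy = np.broadcast_arrays(
        np.asarray(ux, dtype=float),
        np.asarray(uy, dtype=float),
        np.asarray(jx, dtype=float),
        np.asarray(jy, dtype=float),
    )
    frac = np.linspace(0.0, 1.0, n_divisions + 1)
    vx = ux[..., None] + (jx / mass)[..., None] * frac
    vy = uy[..., None] + (jy / mass)[..., None] * frac
    ke = 0.5 * mass * (vx * vx + vy * vy)
    dke = np.diff(ke, axis=-1)
    positive = np.where(dke > 0.0, dke, 0.0).sum(axis=-1)
    dissipated = np.where(dke < 0.0, -dke, 0.0).sum(axis=-1)
    speed_min = np.sqrt(2.0 * ke.min(axis=-1) / mass)
    return positive, dissipated, speed_min


def impulse_work_numeric(
    u: PlanarVelocity,
    j: ImpulseVector,
    mass: float,
    n_divisions: int = 100,
) -> CollisionOutcome:
    """Positive work and dissipation of one impulse by sub-impulse quadrature.

    The impulse is applied in ``n_divisions`` equal sub-impulses (100 by
    default; results are not sensitive to this) and the kinetic-energy
    increment of each step is accumulated: positive increments sum to
    ``positive_work``, the magnitudes of negative increments to
    ``dissipated_energy``.  ``speed_min`` is the minimum CoM speed over
    the traversal including both endpoints.
    """
    _check_mass(mass)
    if not (isinstance(n_divisions, (int, np.integer)) and n_divisions >= 1):
        raise ValueError(f"n_divisions must be a positive integer, got {n_divisions}")
    pos, dis, smin = _collision_arrays(u.vx, u.vy, j.jx, j.jy, mass, int(n_divisions))
    return CollisionOutcome(
        positive_work=float(pos),
        dissipated_energy=float(dis),
        speed_before=u.speed,
        speed_after=math.hypot(u.vx + j.jx / mass, u.vy + j.jy / mass),
        speed_min=float(smin),
    )


def impulse_work_closed_form(
    u: PlanarVelocity,
    j: ImpulseVector,
    mass: float,
) -> CollisionOutcome:
    """Exact limit of the sub-impulse procedure.

    The velocity traverses the straight segment from ``U`` to
    ``V = U + J/m``; ``V_min`` is the segment point closest to the origin
    (clamped to the nearer endpoint when the perpendicular foot lies
    outside), giving

    ``positive_work = m/2 (|V|^2 - |V_min|^2)``,
    ``dissipated    = m/2 (|U|^2 - |V_min|^2)``.
    """
    _check_mass(mass)
    dx, dy = j.jx / mass, j.jy / mass
    vx, vy = u.vx + dx, u.vy + dy
    den = dx * dx + dy * dy
    if den == 0.0:
        t = 0.0
    else:
        t = min(1.0, max(0.0, -(u.vx * dx + u.vy * dy) / den))
    mx, my = u.vx + t * dx, u.vy + t * dy
    min_sq = mx * mx + my * my
    positive = max(0.0, 0.5 * mass * (vx * vx + vy * vy - min_sq))
    dissipated = max(0.0, 0.5 * mass * (u.vx * u.vx + u.vy * u.vy - min_sq))
    return CollisionOutcome(
        positive_work=positive,
        dissipated_energy=dissipated,
        speed_before=u.speed,
        speed_after=math.hypot(vx, vy),
        speed_min=math.sqrt(min_sq),
    )


def to_dimensionless(
    mean_speed: float,
    stride_period: float,
    leg_length: float,
    g: float = 9.81,
) -> DimensionlessState:
    """Normalize mean horizontal speed and stride period by leg length.

    ``v_hat_x = mean_speed / sqrt(g * leg_length)`` and
    ``t_hat_stride = stride_period / sqrt(leg_length / g)``; the returned
    ratio equals ``mean_speed / (g * stride_period)`` exactly — leg length
    cancels, which is why the gait maps are drawn over the ratio.
    """
    for name, v in (
        ("mean_speed", mean_speed),
        ("stride_period", stride_period),
        ("leg_length", leg_length),
        ("g", g),
    ):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    v_hat = mean_speed / math.sqrt(g * leg_length)
    t_hat = stride_period / math.sqrt(leg_length / g)
    return DimensionlessState(
        v_hat_x=v_hat,
        t_hat_stride=t_hat,
        ratio=mean_speed / (g * stride_period),
    )
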