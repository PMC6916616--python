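"""Analytic condition for good cantering.

The canter redirects the CoM trajectory from α below horizontal to α above
it across three immediately successive impulses inclined at +θ, 0 and -θ.
If weight support is split evenly across the three instants and every
impulse is perfectly pseudoelastic — its speed minimum bisecting incoming
and outgoing velocity — the redirection 2α splits into three equal turns
and the geometry collapses to

    θ = (2/3) · atan( T̂ / (2 V̂x) )        and its inverse
    V̂x = T̂ / ( 2 tan(3θ/2) ),

with T̂ and V̂x the dimensionless stride period and speed.  The landing
vertical velocity after the canter's single ballistic phase is
U_y = -g T / 2.  The curve traced by the inverse lies inside the
canter-optimal region of the numerical gait map.

All angles are in radians; the CLI converts to and from degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CanterGeometry",
    "landing_vertical_velocity",
    "incoming_angle",
    "ideal_canter_theta",
    "ideal_canter_speed",
    "ideal_canter_geometry",
]


@dataclass(frozen=True)
class CanterGeometry:
    """Landing state and ideal inclination for one canter condition.

    ``u_y`` (m/s, <= 0) is the landing vertical velocity, ``alpha`` (rad)
    the CoM path angle below horizontal at landing, ``theta_ideal`` (rad)
    the single-stance inclination that makes all three impulses
    pseudoelastic.
    """

    u_y: float
    alpha: float
    theta_ideal: float

    def __post_init__(self) -> None:
        if self.u_y > 0:
            raise ValueError(f"landing vertical velocity must be <= 0, got {self.u_y}")
        if not 0.0 <= self.alpha < math.pi / 2:
            raise ValueError(f"alpha must be in [0, pi/2), got {self.alpha}")
        if not 0.0 <= self.theta_ideal < math.pi / 3:
            raise ValueError(f"theta_ideal must be in [0, pi/3), got {self.theta_ideal}")


def landing_vertical_velocity(g: float, stride_period: float) -> float:
    """Vertical velocity at the end of the canter's single ballistic phase.

    The whole stride is airborne (the three impulses are instantaneous),
    so a symmetric arc of duration T lands at ``-g T / 2``.
    """
    if g < 0 or stride_period < 0:
        raise ValueError("g and stride_period must be non-negative")
    return -g * stride_period / 2.0


def incoming_angle(u_x: float, u_y: float) -> float:
    """CoM path angle below horizontal at landing: |atan(u_y / u_x)|."""
    if u_x <= 0:
        raise ValueError(f"horizontal landing velocity must be positive, got {u_x}")
    return abs(math.atan(u_y / u_x))


def ideal_canter_theta(v_hat_x: float, t_hat_stride: float) -> float:
    """Single-stance inclination making all three canter impulses pseudoelastic.

    The total 2α redirection, α = atan(T̂ / (2 V̂x)), splits across three
    equal pseudoelastic turns at +θ, 0, -θ, giving θ = (2/3)·atan(T̂/(2V̂x)).
    """
    if v_hat_x <= 0 or t_hat_stride <= 0:
        raise ValueError("v_hat_x and t_hat_stride must be positive")
    return (2.0 / 3.0) * math.atan(t_hat_stride / (2.0 * v_hat_x))


def ideal_canter_speed(theta: float, t_hat_stride: float) -> float:
    """Dimensionless speed at which inclination θ is ideal for cantering.

    Exact inverse of :func:`ideal_canter_theta`:
    V̂x = T̂ / (2 tan(3θ/2)), valid for 0 < θ < π/3.
    """
    if not 0.0 < theta < math.pi / 3:
        raise ValueError(f"theta must be in (0, pi/3), got {theta}")
    if t_hat_stride <= 0:
        raise ValueError("t_hat_stride must be positive")
    return t_hat_stride / (2.0 * math.tan(1.5 * theta))


def ideal_canter_geometry(
    v_hat_x: float,
    t_hat_stride: float,
    g: float = 1.0,
    leg_length: float = 1.0,
) -> CanterGeometry:
    """Full landing geometry for one dimensionless canter condition."""
    if g <= 0 or leg_length <= 0:
        raise ValueError("g and leg_length must be positive")
    stride_period = t_hat_stride * math.sqrt(leg_length / g)
    mean_speed = v_hat_x * math.sqrt(g * leg_length)
    u_y = landing_vertical_velocity(g, stride_period)
    return CanterGeometry(
        u_y=u_y,
        alpha=incoming_angle(mean_speed, u_y),
        theta_ideal=ideal_canter_theta(v_hat_x, t_hat_stride),
    )
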