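"""Trot-versus-tolt energetics with finite pitch moment of inertia.

The two-beat trot pairs a hind and a fore impulse so their net vector is
vertical through the CoM: no pitching, but only two (large) collisions per
stride.  The four-beat tolt spreads four half-size vertical impulses evenly
through the stride — half the vertical work — but each unpaired impulse,
acting at hip or shoulder with lever arm ``L_back/2``, pitches the body and
the pitch kinetic energy must also be paid for.  Summing the vertical and
rotational positive work gives a clean criterion: trotting is cheaper than
tolting exactly when the normalized pitch inertia

    Iˆ = 4 I / (m L_back²)

is below one.  The same threshold emerges from the center-of-percussion
view: a vertical hip impulse leaves the shoulder unmoved at Iˆ = 1,
accelerates it upward for Iˆ > 1 and downward (the costly, trot-favoring,
but passively stable regime) for Iˆ < 1.

The CoM sits midway between hip and shoulder, and ``I`` and ``L_back`` are
treated as constants through the stride.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BodyParams",
    "PitchWorkSummary",
    "takeoff_vertical_speed",
    "trot_vertical_work",
    "tolt_vertical_work",
    "tolt_pitch_rate_change",
    "tolt_rotational_work",
    "normalized_inertia",
    "shoulder_velocity_change",
    "evaluate_pitch_energetics",
    "batch_evaluate",
    "batch_from_csv",
]

#: columns required of a batch parameter table, in canonical order
BATCH_COLUMNS = ("mass", "g", "stride_period", "back_length", "pitch_inertia")


@dataclass(frozen=True)
class BodyParams:
    """Morphology and stride timing of the model quadruped.

    mass (kg), g (m/s²), stride_period (s), back_length (m, hip to
    shoulder, CoM midway) and pitch_inertia (kg·m², about the CoM).
    """

    mass: float
    g: float
    stride_period: float
    back_length: float
    pitch_inertia: float

    def __post_init__(self) -> None:
        for name in ("mass", "g", "stride_period", "back_length", "pitch_inertia"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class PitchWorkSummary:
    """Per-stride positive works (J) and the trot/tolt verdict."""

    trot_vertical_work: float
    tolt_vertical_work: float
    tolt_rotational_work: float
    i_hat: float
    trot_favored: bool

    @property
    def tolt_total_work(self) -> float:
        return self.tolt_vertical_work + self.tolt_rotational_work


def takeoff_vertical_speed(g: float, stride_period: float, cycles_per_stride: int) -> float:
    """Vertical speed just after contact for evenly spaced ballistic cycles.

    With ``cycles_per_stride`` symmetric ballistic arcs per stride the
    takeoff (and landing) vertical speed is ``g T / (2 * cycles)``:
    ``g T / 4`` for the two-cycle trot, ``g T / 8`` for the four-cycle tolt.
    """
    if cycles_per_stride not in (2, 4):
        raise ValueError(f"cycles_per_stride must be 2 (trot) or 4 (tolt), got {cycles_per_stride}")
    if not (g >= 0 and stride_period > 0):
        raise ValueError("g must be non-negative and stride_period positive")
    return g * stride_period / (2 * cycles_per_stride)


def trot_vertical_work(body: BodyParams) -> float:
    """Per-stride positive work of trot's two vertical collisions: m g²T²/16."""
    return body.mass * body.g**2 * body.stride_period**2 / 16.0


def tolt_vertical_work(body: BodyParams) -> float:
    """Per-stride vertical work of tolt's four half-size collisions: m g²T²/32.

    Doubling the number of impulses at half magnitude halves the
    point-mass vertical work relative to trot.
    """
    return body.mass * body.g**2 * body.stride_period**2 / 32.0


def tolt_pitch_rate_change(body: BodyParams) -> float:
    """|Δω| imparted by one unpaired tolt impulse (rad/s).

    Each limb's impulse has magnitude ``m g T / 4`` and lever arm
    ``L_back / 2`` about the CoM, resisted by the pitch inertia ``I``.
    """
    impulse = body.mass * body.g * body.stride_period / 4.0
    return impulse * (body.back_length / 2.0) / body.pitch_inertia


def tolt_rotational_work(body: BodyParams) -> float:
    """Per-stride positive work feeding pitch kinetic energy in tolt.

    Pitching reverses sense each stance and passes through zero angular
    velocity at midstance, so ``ω_max = |Δω| / 2``; four impulses per
    stride give ``4 · ½ I ω_max² = (m g²T²/32) · (m L_back² / 4I)``.
    """
    return tolt_vertical_work(body) * (
        body.mass * body.back_length**2 / (4.0 * body.pitch_inertia)
    )


def normalized_inertia(body: BodyParams) -> float:
    """Normalized pitch moment of inertia ``Iˆ = 4 I / (m L_back²)``.

    Trot is energetically favored over tolt iff the result is below one.
    """
    return 4.0 * body.pitch_inertia / (body.mass * body.back_length**2)


def shoulder_velocity_change(impulse_at_hip: float, body: BodyParams) -> float:
    """Vertical velocity change of the shoulder from a vertical hip impulse.

    The CoM rises by ``p/m`` while the nose-down pitch impulse swings the
    shoulder by ``-p L_back² / (4I)``; the sum vanishes exactly at
    ``Iˆ = 1``, where hip and shoulder sit at each other's center of
    percussion.  Positive (shoulder up) iff ``Iˆ > 1``.
    """
    p = impulse_at_hip
    return p / body.mass - p * body.back_length**2 / (4.0 * body.pitch_inertia)


def evaluate_pitch_energetics(body: BodyParams) -> PitchWorkSummary:
    """All pitch-model outputs for one body."""
    i_hat = normalized_inertia(body)
    return PitchWorkSummary(
        trot_vertical_work=trot_vertical_work(body),
        tolt_vertical_work=tolt_vertical_work(body),
        tolt_rotational_work=tolt_rotational_work(body),
        i_hat=i_hat,
        trot_favored=i_hat < 1.0,
    )


def batch_evaluate(table: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the pitch model for every row of a parameter table.

    ``table`` must carry the columns mass, g, stride_period, back_length,
    pitch_inertia; the result appends i_hat, trot_favored and the three
    per-stride works.
    """
    missing = [c for c in BATCH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            "parameter table is missing required column(s): " + ", ".join(missing)
        )
    out = table.copy()
    summaries = [
        evaluate_pitch_energetics(
            BodyParams(
                mass=row.mass,
                g=row.g,
                stride_period=row.stride_period,
                back_length=row.back_length,
                pitch_inertia=row.pitch_inertia,
            )
        )
        for row in table.itertuples(index=False)
    ]
    out["i_hat"] = [s.i_hat for s in summaries]
    out["trot_favored"] = [s.trot_favored for s in summaries]
    out["trot_vertical_work"] = [s.trot_vertical_work for s in summaries]
    out["tolt_vertical_work"] = [s.tolt_vertical_work for s in summaries]
    out["tolt_rotational_work"] = [s.tolt_rotational_work for s in summaries]
    return out


def batch_from_csv(path, out_path=None) -> pd.DataFrame:
    """Read a CSV of parameter sets, evaluate, optionally write the result."""
    result = batch_evaluate(pd.read_csv(path))
    if out_path is not None:
        result.to_csv(out_path, index=False)
    return result
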