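"""Optimal-gait maps over speed-to-stride-period ratio and impulse inclination.

All five idealized gaits are costed per stride at shared stride period and
mean speed, in the unit system m = g = T = 1 where the mean speed equals
the governing dimensionless ratio V̄x/(g·T).  Costs are reported relative
to trot (whose work, m g²T²/16, is speed independent), and each grid cell
is labelled with the work-minimizing gait.  Along the inclination transect
the map reproduces the predicted gait sequence with increasing speed:
tolt, then trot, then canter over a bounded window, then trot again.

Tolt and even gallop coincide exactly at θ = 0 and stay nearly
indistinguishable at small inclinations, so near-ties are reported
explicitly (a joined label) rather than resolved by floating-point noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaitwork.canter_geometry import ideal_canter_speed
from gaitwork.gait_models import GAIT_NAMES, build_gait, _stride_work_batch

__all__ = [
    "GaitCostMap",
    "compute_map",
    "transect",
    "default_ratio_grid",
    "default_theta_grid",
    "optimal_gait_sequence",
    "plot_map",
    "plot_transect",
]

#: fixed precedence used to order tie labels and break sub-tolerance ties
PRECEDENCE = ("tolt", "trot", "canter", "gathered_gallop", "even_gallop")


def default_ratio_grid() -> np.ndarray:
    """Dimensionless speed/stride-period ratios 0.2 to 4.0, step 0.02."""
    return np.round(np.arange(0.2, 4.0 + 1e-9, 0.02), 10)


def default_theta_grid() -> np.ndarray:
    """Impulse inclinations 0.5 deg to 45 deg, step 0.5 deg, in radians."""
    return np.deg2rad(np.round(np.arange(0.5, 45.0 + 1e-9, 0.5), 10))


@dataclass(frozen=True)
class GaitCostMap:
    """Per-gait relative costs and the work-minimizing gait on a grid.

    ``cost[gait]`` has shape (len(ratio_grid), len(theta_grid)), each
    entry the gait's positive stride work divided by trot's; ``optimal``
    holds the argmin label per cell, with gaits within ``tie_tolerance``
    (relative) of the minimum joined as "a|b" ties.
    """

    ratio_grid: np.ndarray
    theta_grid: np.ndarray
    cost: dict
    optimal: np.ndarray
    tie_tolerance: float
    canter_scheme: str
    n_divisions: int | None

    def theta_column(self, theta: float) -> int:
        """Index of the grid inclination closest to ``theta`` (rad)."""
        return int(np.argmin(np.abs(self.theta_grid - theta)))

    def ratio_row(self, ratio: float) -> int:
        return int(np.argmin(np.abs(self.ratio_grid - ratio)))

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: ratio, theta_deg, gait, work_ratio_to_trot, optimal_flag."""
        rows = []
        theta_deg = np.rad2deg(self.theta_grid)
        for ti in range(len(self.theta_grid)):
            for ri in range(len(self.ratio_grid)):
                best = self.optimal[ri, ti]
                for gait in GAIT_NAMES:
                    rows.append(
                        (
                            self.ratio_grid[ri],
                            theta_deg[ti],
                            gait,
                            self.cost[gait][ri, ti],
                            gait in best.split("|"),
                        )
                    )
        return pd.DataFrame(
            rows, columns=["ratio", "theta_deg", "gait", "work_ratio_to_trot", "optimal_flag"]
        )


def compute_map(
    ratio_grid=None,
    theta_grid=None,
    canter_scheme: str = "per_limb_support",
    n_divisions: int | None = 100,
    tie_tolerance: float = 1e-9,
) -> GaitCostMap:
    """Cost all five gaits over a (ratio, theta) grid and label the argmin.

    Grids must be ascending and positive; ratios are realized as mean
    speeds with m = g = T = 1.  ``n_divisions`` is forwarded to the
    collision engine (None selects the exact closed form).  Ties within
    ``tie_tolerance`` relative of the cell minimum are reported as joined
    labels in the fixed precedence order tolt, trot, canter, gathered
    gallop, even gallop.
    """
    ratio_grid = default_ratio_grid() if ratio_grid is None else np.asarray(ratio_grid, float)
    theta_grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    for name, grid in (("ratio_grid", ratio_grid), ("theta_grid", theta_grid)):
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError(f"{name} must be a non-empty 1-D grid")
        if np.any(grid <= 0) and name == "ratio_grid":
            raise ValueError("ratios must be positive")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be strictly ascending")
    if np.any(theta_grid < 0) or np.any(theta_grid >= math.pi / 2):
        raise ValueError("theta grid must lie in [0, pi/2)")

    trot_work = 1.0 / 16.0  # m g^2 T^2 / 16 with m = g = T = 1
    cost = {}
    for gait_name in GAIT_NAMES:
        col = np.empty((ratio_grid.size, theta_grid.size))
        for ti, theta in enumerate(theta_grid):
            gait = build_gait(gait_name, float(theta), canter_scheme)
            col[:, ti] = _stride_work_batch(gait, ratio_grid, 1.0, 1.0, 1.0, n_divisions)
        cost[gait_name] = col / trot_work
    stacked = np.stack([cost[g] for g in PRECEDENCE])  # (5, R, Th)
    cmin = stacked.min(axis=0)
    within = stacked <= cmin * (1.0 + tie_tolerance)
    optimal = np.empty(cmin.shape, dtype=object)
    for ri in range(cmin.shape[0]):
        for ti in range(cmin.shape[1]):
            names = [g for k, g in enumerate(PRECEDENCE) if within[k, ri, ti]]
            optimal[ri, ti] = "|".join(names)
    return GaitCostMap(
        ratio_grid=ratio_grid,
        theta_grid=theta_grid,
        cost=cost,
        optimal=optimal,
        tie_tolerance=tie_tolerance,
        canter_scheme=canter_scheme,
        n_divisions=n_divisions,
    )


def transect(
    theta: float,
    ratio_grid=None,
    canter_scheme: str = "per_limb_support",
    n_divisions: int | None = 100,
) -> pd.DataFrame:
    """Slice of the cost surface at one inclination.

    Returns a table with one row per ratio and one column per gait
    holding work relative to trot (the trot column is identically 1).
    """
    ratio_grid = default_ratio_grid() if ratio_grid is None else np.asarray(ratio_grid, float)
    cmap = compute_map(ratio_grid, np.array([theta]), canter_scheme, n_divisions)
    data = {"ratio": ratio_grid}
    for gait in GAIT_NAMES:
        data[gait] = cmap.cost[gait][:, 0]
    return pd.DataFrame(data)


def optimal_gait_sequence(cost_map: GaitCostMap, theta: float) -> list[str]:
    """Labels of the work-minimizing gait with increasing ratio at ``theta``,
    consecutive duplicates collapsed."""
    col = cost_map.theta_column(theta)
    labels = cost_map.optimal[:, col]
    seq: list[str] = []
    for lab in labels:
        if not seq or seq[-1] != lab:
            seq.append(lab)
    return seq


def _analytic_canter_curve(theta_grid: np.ndarray) -> np.ndarray:
    """Ratio V̄x/(gT) at which each inclination is ideal for cantering."""
    return np.array([ideal_canter_speed(float(t), 1.0) for t in theta_grid])


def plot_map(cost_map: GaitCostMap, path=None, overlay_analytic: bool = True):
    """Render the optimal-gait map as a heatmap (convenience, needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    base = {g: i for i, g in enumerate(PRECEDENCE)}
    idx = np.vectorize(lambda lab: base[lab.split("|")[0]])(cost_map.optimal)
    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = ListedColormap(["#7fc97f", "#beaed4", "#fdc086", "#ffff99", "#386cb0"])
    theta_deg = np.rad2deg(cost_map.theta_grid)
    ax.pcolormesh(cost_map.ratio_grid, theta_deg, idx.T, cmap=cmap, vmin=0, vmax=4,
                  shading="nearest")
    if overlay_analytic:
        lo, hi = cost_map.ratio_grid[0], cost_map.ratio_grid[-1]
        curve = _analytic_canter_curve(cost_map.theta_grid)
        keep = (curve >= lo) & (curve <= hi)
        ax.plot(curve[keep], theta_deg[keep], "k--", lw=1.5, label="analytic canter")
        ax.legend(loc="upper right")
    ax.set_xlabel(r"$\hat{V}_x / \hat{T}_{stride}$")
    ax.set_ylabel(r"$\theta$ (deg)")
    ax.set_title("Work-minimizing gait")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_transect(table: pd.DataFrame, path=None):
    """Line plot of per-gait relative cost along a transect (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for gait in GAIT_NAMES:
        ax.plot(table["ratio"], table[gait], label=gait)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel(r"$\hat{V}_x / \hat{T}_{stride}$")
    ax.set_ylabel("work relative to trot")
    ax.set_ylim(0, 3)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
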