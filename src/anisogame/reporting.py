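"""Tabular and figure output: CSV rows, ratio curves, trajectory export."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import analytic
from .dynamics import Trajectory
from .params import ModelParams
from .stability import ScanResult


def equilibrium_row(params: ModelParams, eq: analytic.EquilibriumResult) -> dict:
    """Flat CSV/JSON row for one equilibrium."""
    return {
        "alpha": params.alpha,
        "beta": params.beta,
        "k": params.k,
        "regime": eq.regime,
        "x": eq.sizes.x,
        "y": eq.sizes.y,
        "ratio": eq.ratio,
        "source": eq.source,
        "gradient_residual": eq.gradient_residual,
    }


def ratio_curve(beta_over_alpha: Sequence[float]) -> pd.DataFrame:
    """Exact and approximate macro:micro ratio over a grid of beta/alpha.

    The approximate column follows the anisogamous-branch expression from
    the threshold upward, so the table reproduces the onset jump from 1
    to 3 while the exact column rises continuously from 1.
    """
    grid = np.asarray(list(beta_over_alpha), dtype=float)
    if grid.size == 0:
        raise ValueError("beta/alpha grid must be non-empty")
    exact = [analytic.exact_ratio_of(v) for v in grid]
    approx = [analytic.approximate_ratio_of(v) for v in grid]
    return pd.DataFrame(
        {"beta_over_alpha": grid, "exact_ratio": exact, "approximate_ratio": approx}
    )


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": traj.times,
            "x": [p.x for p in traj.points],
            "y": [p.y for p in traj.points],
        }
    )


def scan_frame(scan: ScanResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": scan.parameter_name,
            "value": scan.values,
            "regime": scan.regimes,
        }
    )


def plot_ratio_curve(df: pd.DataFrame, path: str | Path) -> None:
    """Overlaid exact (continuous) vs approximate (discontinuous) ratio curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["beta_over_alpha"], df["exact_ratio"], label="exact", lw=2)
    ax.plot(
        df["beta_over_alpha"],
        df["approximate_ratio"],
        label="approximate",
        lw=2,
        ls="--",
    )
    ax.axvline(4.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel(r"$\beta/\alpha$")
    ax.set_ylabel("macro:micro size ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_trajectory(
    trajectories: Iterable[Trajectory], path: str | Path, params: ModelParams | None = None
) -> None:
    """Phase-plane plot of one or more gradient-dynamics trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for traj in trajectories:
        xs = [p.x for p in traj.points]
        ys = [p.y for p in traj.points]
        ax.plot(xs, ys, lw=1.2)
        ax.plot(xs[-1], ys[-1], "ko", ms=4)
    if params is not None and params.zygote_survival_form == "exponential":
        eq = analytic.stable_equilibrium(params)
        ax.plot([eq.sizes.x, eq.sizes.y], [eq.sizes.y, eq.sizes.x], "r*", ms=10)
    ax.set_xlabel("gamete size x")
    ax.set_ylabel("gamete size y")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
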