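"""Figure builders mirroring the standard presentation of AE experiments:
session-by-session requirement trajectories, indifference points as a
function of the FR requirement, IRE distributions per requirement, and
mean energy per reinforcement (E/RFT) versus the requirement.

Each function returns a matplotlib Figure; callers save or show it.
Open markers denote the ascending series, filled markers the descending
series, following the field's plotting convention.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_requirement_trajectories",
    "plot_indifference_points",
    "plot_ire_distributions",
    "plot_e_per_rft",
]


def _series_style(series_label: str) -> dict:
    if series_label == "descending":
        return {"mfc": "black"}
    return {"mfc": "white"}


def plot_requirement_trajectories(condition_results):
    """Session-mean AE requirement per session, one panel per condition."""
    n = len(condition_results)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), sharey=True, squeeze=False)
    for ax, cond in zip(axes[0], condition_results):
        means = [s.mean_ae_requirement for s in cond.logs]
        ax.plot(
            np.arange(1, len(means) + 1),
            means,
            marker="o",
            ms=4,
            color="black",
            **_series_style(cond.series_label),
        )
        ax.set_title(f"FR {cond.fr_requirement} ({cond.series_label})", fontsize=9)
        ax.set_xlabel("session")
    axes[0][0].set_ylabel("AE requirement (J)")
    fig.tight_layout()
    return fig


def plot_indifference_points(table):
    """Indifference point vs. FR requirement, arrows in condition order."""
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    xs = table["fr_requirement"].to_numpy(dtype=float)
    ys = table["indifference_point"].to_numpy(dtype=float)
    for x, y, series in zip(xs, ys, table["series"]):
        ax.plot(x, y, marker="o", ms=7, color="black", **_series_style(series))
    for i in range(len(xs) - 1):
        ax.annotate(
            "",
            xy=(xs[i + 1], ys[i + 1]),
            xytext=(xs[i], ys[i]),
            arrowprops={"arrowstyle": "->", "color": "gray", "lw": 0.8},
        )
    ax.set_xlabel("FR requirement")
    ax.set_ylabel("indifference point (J)")
    fig.tight_layout()
    return fig


def plot_ire_distributions(summaries, max_points: int = 400, seed: int = 0):
    """IRE samples (small filled dots) and mean IRE (open circles) per
    condition, plotted against the condition's titrated requirement."""
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    rng = np.random.default_rng(seed)
    for s in summaries:
        samples = np.asarray(s.ire_samples, dtype=float)
        if samples.size > max_points:
            samples = rng.choice(samples, size=max_points, replace=False)
        x = np.full(samples.size, s.indifference_point)
        ax.plot(x, samples, ".", color="0.4", ms=2, alpha=0.4)
        ax.plot(s.indifference_point, s.mean_ire, "o", color="black", mfc="white", ms=7)
    ax.set_xlabel("AE requirement (J)")
    ax.set_ylabel("IRE (J)")
    fig.tight_layout()
    return fig


def plot_e_per_rft(table):
    """Mean energy per reinforcement vs. the titrated AE requirement."""
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    for _, row in table.iterrows():
        ax.plot(
            row["indifference_point"],
            row["e_per_rft"],
            marker="o",
            ms=7,
            color="black",
            **_series_style(row["series"]),
        )
    ax.set_xlabel("AE requirement (J)")
    ax.set_ylabel("E/RFT (J)")
    fig.tight_layout()
    return fig
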