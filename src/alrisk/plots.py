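"""Static figures: nomogram axes, calibration plot, RA-CUSUM chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cusum import ChangePointSet, CusumTrace
from .nomogram import NomogramSpec


def plot_nomogram(spec: NomogramSpec, path: str | Path) -> Path:
    """Horizontal point scales, one row per variable, plus the probability axis."""
    n_rows = len(spec.axes) + 2
    fig, ax = plt.subplots(figsize=(9, 0.8 * n_rows + 1))
    ax.set_xlim(-5, 105)
    ax.set_ylim(-0.5, n_rows - 0.5)
    ax.axis("off")
    row = n_rows - 1
    ax.hlines(row, 0, 100, color="k", lw=1)
    for p in range(0, 101, 10):
        ax.vlines(p, row - 0.08, row + 0.08, color="k", lw=0.8)
        ax.text(p, row + 0.18, str(p), ha="center", fontsize=7)
    ax.text(-4, row, "Points", ha="right", va="center", fontsize=9)
    row -= 1
    for axis in spec.axes:
        if axis.kind in ("binary", "categorical"):
            items = sorted(axis.level_points.items(), key=lambda kv: kv[1])
            pts = [kv[1] for kv in items]
            ax.hlines(row, min(pts), max(pts), color="k", lw=1)
            for lv, p in items:
                ax.vlines(p, row - 0.08, row + 0.08, color="k", lw=0.8)
                ax.text(p, row + 0.18, str(lv), ha="center", fontsize=7)
        else:
            ax.hlines(row, axis.breakpoint_points.min(), axis.breakpoint_points.max(), color="k", lw=1)
            for v, p in zip(axis.breakpoints, axis.breakpoint_points):
                ax.vlines(p, row - 0.08, row + 0.08, color="k", lw=0.8)
                ax.text(p, row + 0.18, f"{v:g}", ha="center", fontsize=7)
        ax.text(-4, row, axis.variable, ha="right", va="center", fontsize=9)
        row -= 1
    pa = spec.probability_axis
    scale = 100.0 / max(pa["total_points"].max(), 1.0)
    ax.hlines(row, 0, 100, color="k", lw=1)
    for _, r in pa.iterrows():
        x = r["total_points"] * scale
        ax.vlines(x, row - 0.08, row + 0.08, color="k", lw=0.8)
        ax.text(x, row - 0.35, f"{r['probability']:.3f}", ha="center", fontsize=6, rotation=45)
    ax.text(-4, row, "Total points → P(leak)", ha="right", va="center", fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_calibration(calibration, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(calibration["predicted_mean"].max(), calibration["observed_fraction"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="ideal")
    ax.plot(calibration["predicted_mean"], calibration["observed_fraction"], "o-", label="observed")
    ax.set_xlabel("Predicted probability of leak")
    ax.set_ylabel("Observed leak fraction")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_cusum(trace: CusumTrace, path: str | Path, changepoints: ChangePointSet | None = None,
               era_starts=(), era_labels=()) -> Path:
    fig, ax = plt.subplots(figsize=(9, 4))
    seq = trace.frame["seq"]
    ax.plot(seq, trace.s, lw=1.2)
    ax.axhline(0, color="k", lw=0.6)
    if changepoints is not None:
        for cp in changepoints.indices:
            ax.axvline(cp, color="r", ls="--", lw=1)
            ax.text(cp, ax.get_ylim()[1], f"{cp}", color="r", ha="center", va="bottom", fontsize=8)
    for s, lab in zip(era_starts, era_labels):
        ax.axvline(s, color="g", ls=":", lw=0.8)
        ax.text(s, ax.get_ylim()[0], lab, color="g", ha="center", va="top", fontsize=8)
    ax.set_xlabel("Consecutive operation")
    ax.set_ylabel("Cumulative observed − expected leaks")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
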