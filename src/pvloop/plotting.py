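"""Figures: PV loop with energy shading, Kaplan-Meier tertile curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import PVLoop, emax_point

__all__ = ["plot_pv_loop", "plot_km_curves"]


def plot_pv_loop(loop: PVLoop, path: str | Path | None = None, title: str = "PV loop"):
    """Render one PV loop, shading stroke work and potential energy.

    The loop interior (stroke work) is shaded light gray; the triangle
    between the ESPVR, the volume axis, and the end-systolic point
    (potential energy) dark gray.
    """
    esv, esp, _ = emax_point(loop)
    fig, ax = plt.subplots(figsize=(5, 4))
    v = np.append(loop.volumes, loop.volumes[0])
    p = np.append(loop.pressures, loop.pressures[0])
    ax.fill(v, p, color="0.85", label="stroke work")
    ax.fill(
        [loop.v0, esv, esv],
        [0.0, 0.0, esp],
        color="0.55",
        alpha=0.8,
        label="potential energy",
    )
    ax.plot(v, p, color="k", lw=1.5)
    ax.plot([loop.v0, esv], [0.0, esp], "k--", lw=1, label="ESPVR")
    ax.plot([esv, loop.edv], [esp, 0.0], "k:", lw=1, label="Ea")
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_xlim(left=min(0.0, loop.v0))
    ax.set_ylim(bottom=0.0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_km_curves(curves: dict, path: str | Path | None = None, title: str = "Event-free survival"):
    """Step plots of per-tertile product-limit curves with CI bands."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, frame in curves.items():
        ax.step(frame.index, frame["survival"], where="post", label=group)
        ax.fill_between(
            frame.index,
            frame["ci_lower"],
            frame["ci_upper"],
            step="post",
            alpha=0.2,
        )
    ax.set_xlabel("Years")
    ax.set_ylabel("Event-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
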