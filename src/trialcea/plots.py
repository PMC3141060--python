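"""Cost-effectiveness plane and acceptability-curve figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cea import CEACurve, Ellipse, PSACloud


def plot_ce_plane(cloud: PSACloud, ellipse: Ellipse, path: str | Path,
                  wtp_lines: tuple[float, ...] = (50.0, 100.0)) -> None:
    """Scatter of the incremental cloud with the confidence ellipse and
    willingness-to-pay rays through the origin."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(cloud.delta_effect, cloud.delta_cost, s=4, alpha=0.25,
               color="steelblue", linewidths=0)
    theta = np.linspace(0, 2 * np.pi, 200)
    a, b = ellipse.semi_axes
    u = a * np.cos(theta)
    v = b * np.sin(theta)
    c, s = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    ax.plot(ellipse.center[0] + c * u - s * v,
            ellipse.center[1] + s * u + c * v,
            color="firebrick", lw=1.5,
            label=f"{ellipse.level:.0%} confidence ellipse")
    xlim = np.array(ax.get_xlim())
    for lam in wtp_lines:
        ax.plot(xlim, lam * xlim, ls="--", lw=0.8, color="gray")
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("Incremental effect (QALYs)")
    ax.set_ylabel("Incremental cost ($k, 2010)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, color="steelblue")
    ax.set_xlabel("Willingness-to-pay ($k per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
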