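"""Basic diagnostic plots: reference trajectory with ellipses, rank contours."""

from __future__ import annotations

from typing import List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .model_free import EllipseTestResult, RankOrderResult, ReferenceTrajectory

__all__ = ["plot_trajectory", "plot_rank_contours"]


def plot_trajectory(traj: ReferenceTrajectory,
                    ellipse_tests: Optional[List[EllipseTestResult]] = None,
                    out: Optional[str] = None):
    """Reference trajectory with its 95% band and, optionally, the observed /
    projected points and confidence ellipses of the distance test."""
    fig, ax = plt.subplots(figsize=(5, 5))
    y = np.linspace(1e-4, 1 - 1e-4, 400)
    lo, hi = traj.band(y)
    ax.plot(y, traj.curve(y), color="0.4", lw=2, label="reference trajectory")
    ax.fill_between(y, lo, hi, color="0.8", alpha=0.6, label="95% band")
    if ellipse_tests:
        t = np.linspace(0, 2 * np.pi, 200)
        for i, res in enumerate(ellipse_tests):
            color = f"C{i % 10}"
            ox, oy = res.ellipse_obs.boundary(t)
            px, py = res.ellipse_proj.boundary(t)
            ax.plot(ox, oy, color=color, lw=0.8)
            ax.plot(px, py, color=color, lw=0.8, ls="--")
            ax.plot(*res.projection.observed, "o", ms=4, color=color,
                    label=f"{res.ligand_id}{' *' if res.flagged else ''}")
            ax.plot(*res.projection.projected, "s", ms=3, color=color)
    ax.set_xlabel("intrinsic activity, assay A")
    ax.set_ylabel("intrinsic activity, assay B")
    ax.set_xlim(-0.05, 1.15)
    ax.set_ylim(-0.05, 1.15)
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_rank_contours(result: RankOrderResult, out: Optional[str] = None):
    """Pooled joint rank density with observed rank pairs overlaid."""
    fig, ax = plt.subplots(figsize=(5, 5))
    pooled = result.joint_density.sum(axis=0)
    n = pooled.shape[0]
    ax.imshow(pooled.T, origin="lower", extent=(0.5, n + 0.5, 0.5, n + 0.5),
              cmap="viridis", aspect="equal")
    for lig, (ra, rb) in result.observed_ranks.items():
        flagged = lig in result.flagged
        ax.plot(ra, rb, "o", mfc="white" if not flagged else "red", mec="black", ms=5)
    ax.set_xlabel("IA rank, assay A")
    ax.set_ylabel("IA rank, assay B")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
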