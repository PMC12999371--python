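"""Cost-effectiveness plane rendering.

Everything in this toolkit is summarised on one canvas: per-study bubbles
at (deltaE_j, deltaC_j) with area proportional to the study size, the
pooled point marked with an X, a rectangle spanning the two univariate
CIs, a ray from the origin with the pooled ICER slope, optionally the
bootstrap cloud with its shaded wedge arc, a dashed willingness-to-pay
line, and an optional normal-approximation confidence ellipse fitted to
the bootstrap cloud (an extra overlay, not part of the core method).
Axes always include the origin so the quadrant boundaries stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import

import matplotlib.pyplot as plt
import numpy as np

from .data import MetaDataset
from .ratio import PooledDifference
from .wedge import BootstrapCloud, ICEREstimate, WedgeInterval

__all__ = ["PlaneSpec", "plot_ce_plane"]


@dataclass(frozen=True)
class PlaneSpec:
    """Presentation options for the CE plane."""

    bubble_scale: float = 1.0  # marker area (pt^2) per patient
    wtp_line: float | None = None  # slope of the dashed threshold line
    show_box: bool = True
    show_wedge: bool = True
    show_ellipse: bool = False  # extra overlay from the cloud's mean/cov

    def __post_init__(self) -> None:
        if self.bubble_scale <= 0:
            raise ValueError("bubble_scale must be positive")


def _limits(values: np.ndarray, margin: float = 0.10) -> tuple[float, float]:
    """Data range plus a margin, always including the origin."""
    lo = min(float(np.min(values)), 0.0)
    hi = max(float(np.max(values)), 0.0)
    span = hi - lo or 1.0
    return lo - margin * span, hi + margin * span


def _ray_end(angle: float, xlim, ylim) -> tuple[float, float]:
    """Point where a ray from the origin at `angle` exits the axes box."""
    dx, dy = np.cos(angle), np.sin(angle)
    ts = []
    if dx > 0:
        ts.append(xlim[1] / dx)
    elif dx < 0:
        ts.append(xlim[0] / dx)
    if dy > 0:
        ts.append(ylim[1] / dy)
    elif dy < 0:
        ts.append(ylim[0] / dy)
    t = min(t for t in ts if t > 0) if ts else 1.0
    return t * dx, t * dy


def plot_ce_plane(
    dataset: MetaDataset,
    icer: ICEREstimate,
    ci_cost: PooledDifference | None = None,
    ci_effect: PooledDifference | None = None,
    cloud: BootstrapCloud | None = None,
    wedge: WedgeInterval | None = None,
    spec: PlaneSpec | None = None,
    path=None,
):
    """Render the meta-analysis on the CE plane.

    Writes an image when ``path`` is given (format from the extension:
    svg/png/pdf); otherwise returns the matplotlib Figure for further
    inspection.  SVG output is deterministic for identical inputs (the
    embedded date and hash salt are pinned).
    """
    if wedge is not None and cloud is None:
        raise ValueError("a wedge arc cannot be drawn without its bootstrap cloud")
    spec = spec or PlaneSpec()

    fig, ax = plt.subplots(figsize=(7.0, 6.0))
    de, dc, n = dataset.delta_e, dataset.delta_c, dataset.n

    xs = [de, [icer.delta_e_pooled]]
    ys = [dc, [icer.delta_c_pooled]]
    if cloud is not None:
        xs.append(cloud.delta_e)
        ys.append(cloud.delta_c)
    if ci_effect is not None:
        xs.append([ci_effect.ci_lower, ci_effect.ci_upper])
    if ci_cost is not None:
        ys.append([ci_cost.ci_lower, ci_cost.ci_upper])
    xlim = _limits(np.concatenate([np.atleast_1d(v) for v in xs]))
    ylim = _limits(np.concatenate([np.atleast_1d(v) for v in ys]))
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)

    # quadrant boundaries
    ax.axhline(0.0, color="0.6", lw=0.8, zorder=1)
    ax.axvline(0.0, color="0.6", lw=0.8, zorder=1)

    # shaded wedge between CB and CCB (counterclockwise), behind the data
    if wedge is not None and spec.show_wedge:
        a0, a1 = wedge.cb_angle, wedge.ccb_angle
        if a1 <= a0:
            a1 += 2.0 * np.pi
        arc = np.linspace(a0, a1, 120)
        pts = [(0.0, 0.0)] + [_ray_end(a, xlim, ylim) for a in arc]
        ax.add_patch(
            plt.Polygon(pts, closed=True, facecolor="tab:orange", alpha=0.18, edgecolor="none",
                        zorder=1.5, label=f"{wedge.level:.0%} wedge arc")
        )
        for a in (wedge.cb_angle, wedge.ccb_angle):
            ex, ey = _ray_end(a, xlim, ylim)
            ax.plot([0, ex], [0, ey], color="tab:orange", lw=1.0, zorder=2)

    if cloud is not None:
        ax.scatter(cloud.delta_e, cloud.delta_c, s=4, color="tab:gray", alpha=0.35,
                   linewidths=0, zorder=2, label=f"{cloud.B} bootstrap replicates")

    # CI box spanning the two univariate intervals
    if spec.show_box and ci_cost is not None and ci_effect is not None:
        ax.add_patch(
            plt.Rectangle(
                (ci_effect.ci_lower, ci_cost.ci_lower),
                ci_effect.ci_upper - ci_effect.ci_lower,
                ci_cost.ci_upper - ci_cost.ci_lower,
                fill=False, edgecolor="tab:blue", lw=1.2, zorder=3,
                label="95% CI box",
            )
        )

    # study bubbles, area proportional to sample size
    ax.scatter(de, dc, s=spec.bubble_scale * n, facecolor="tab:blue", alpha=0.45,
               edgecolor="navy", linewidths=0.6, zorder=4, label="studies (area ∝ N)")

    # ICER ray through the origin
    angle = float(np.arctan2(icer.delta_c_pooled, icer.delta_e_pooled))
    ex, ey = _ray_end(angle, xlim, ylim)
    ax.plot([0, ex], [0, ey], color="black", lw=1.6, zorder=5,
            label=f"pooled ICER = {icer.slope:,.0f}")

    ax.scatter([icer.delta_e_pooled], [icer.delta_c_pooled], marker="x", s=90,
               color="crimson", linewidths=2.0, zorder=6, label="pooled point")

    if spec.wtp_line is not None:
        xx = np.array(xlim)
        ax.plot(xx, spec.wtp_line * xx, ls="--", color="tab:green", lw=1.2, zorder=2,
                label=f"WTP = {spec.wtp_line:,.0f}")
        ax.set_ylim(*ylim)  # WTP line must not widen the view

    if spec.show_ellipse and cloud is not None:
        # 95% normal contour of the cloud: extra overlay, not a core output
        pts = np.column_stack([cloud.delta_e, cloud.delta_c])
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T)
        vals, vecs = np.linalg.eigh(cov)
        r = np.sqrt(5.991)  # chi2(2) 95% quantile
        t = np.linspace(0, 2 * np.pi, 200)
        circ = np.column_stack([np.cos(t), np.sin(t)]) * np.sqrt(np.maximum(vals, 0)) * r
        ell = circ @ vecs.T + mean
        ax.plot(ell[:, 0], ell[:, 1], color="purple", lw=1.0, ls=":",
                label="95% ellipse (cloud)")

    ax.set_xlabel(f"Incremental effectiveness ({dataset.effect_label})")
    ax.set_ylabel(f"Incremental cost ({dataset.cost_label})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()

    if path is None:
        return fig
    path = str(path)
    try:
        if path.endswith(".svg"):
            with matplotlib.rc_context({"svg.hashsalt": "cemeta"}):
                fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)
    finally:
        plt.close(fig)
    return None
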