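"""Treatment-group statistics and figure rendering.

Per-chip network metrics are compared across conditions day by day with a
one-way ANOVA followed by pairwise two-sample Student's (pooled-variance)
t-tests, flagged at alpha = 0.05. No multiple-comparison correction is
applied by default (Holm is selectable). Boxplot summaries use the
1.5 x IQR whisker convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatsResult",
    "one_way_anova",
    "pairwise_t_test",
    "summarize",
    "render_thickness_figure",
    "render_branch_overlay",
]

ALPHA = 0.05


@dataclass
class StatsResult:
    """Per-metric-per-day ANOVA, pairwise t-tests, and boxplot summaries."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    summaries: pd.DataFrame
    alpha: float = ALPHA
    meta: dict = field(default_factory=dict)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA across k groups: returns (F, p).

    p comes from the F distribution with (k-1, N-k) degrees of freedom. All
    values identical is an error (F undefined); zero within-group variance
    with unequal means yields (inf, 0.0).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ValueError("all values identical: F undefined")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def pairwise_t_test(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance, two-sided): (t, p).

    Welch's variant is selectable via ``equal_var=False``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if equal_var and np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            raise ValueError("zero pooled variance with equal means: t undefined")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _box_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()) if inside.size else float(med),
        "whisker_hi": float(inside.max()) if inside.size else float(med),
    }


def summarize(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    correction: str | None = None,
    equal_var: bool = True,
) -> StatsResult:
    """Aggregate a tidy metrics table and run the group comparisons.

    ``table`` has columns (chip, condition, day, metric, value). Per metric
    and day: one-way ANOVA across conditions (skipped with a warning for
    days with fewer than two conditions), then all pairwise t-tests
    (optionally Holm-corrected), plus boxplot-ready summaries.
    """
    required = {"chip", "condition", "day", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    table = table.sort_values(["metric", "day", "condition", "chip"]).reset_index(drop=True)

    anova_rows, pair_rows, summary_rows = [], [], []
    for (metric, day), sub in table.groupby(["metric", "day"], sort=True):
        by_cond = {c: g["value"].to_numpy() for c, g in sub.groupby("condition", sort=True)}
        for cond, vals in by_cond.items():
            summary_rows.append({"metric": metric, "day": day, "condition": cond, **_box_summary(vals)})
        conds = sorted(by_cond)
        if len(conds) < 2:
            warnings.warn(f"day {day} / {metric}: fewer than two conditions, ANOVA skipped", stacklevel=2)
            continue
        try:
            f, p = one_way_anova([by_cond[c] for c in conds])
        except ValueError as exc:
            warnings.warn(f"day {day} / {metric}: ANOVA failed ({exc})", stacklevel=2)
            f, p = float("nan"), float("nan")
        anova_rows.append({"metric": metric, "day": day, "F": f, "p": p, "significant": bool(p < alpha)})
        pvals, keys = [], []
        for i, ca in enumerate(conds):
            for cb in conds[i + 1 :]:
                try:
                    t, pt = pairwise_t_test(by_cond[ca], by_cond[cb], equal_var=equal_var)
                except ValueError:
                    t, pt = float("nan"), float("nan")
                keys.append((ca, cb, t))
                pvals.append(pt)
        if correction == "holm":
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * pvals[idx])
                adj[idx] = min(1.0, running)
            pvals = list(adj)
        elif correction not in (None, "none"):
            raise ValueError(f"unknown correction {correction!r}")
        for (ca, cb, t), pt in zip(keys, pvals):
            pair_rows.append(
                {
                    "metric": metric, "day": day, "group_a": ca, "group_b": cb,
                    "t": t, "p": pt, "significant": bool(pt < alpha),
                }
            )
    return StatsResult(
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
        summaries=pd.DataFrame(summary_rows),
        alpha=alpha,
        meta={"correction": correction or "none", "equal_var": equal_var},
    )


def render_thickness_figure(tmap, voxel_spacing=None, ax=None, cmap: str = "inferno"):
    """Color-coded local-thickness map with a calibrated um color bar and a
    scale bar. Returns the matplotlib Figure."""
    values = tmap.values if hasattr(tmap, "values") else np.asarray(tmap)
    spacing = getattr(tmap, "voxel_spacing", voxel_spacing) or (1.0, 1.0)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    vmax = float(values.max()) if values.max() > 0 else 1.0
    im = ax.imshow(values.T, origin="lower", cmap=cmap, vmin=0.0, vmax=vmax,
                   extent=[0, values.shape[0] * spacing[0], 0, values.shape[1] * spacing[1]])
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("vessel thickness (μm)")
    _add_scale_bar(ax, values.shape[0] * spacing[0])
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    return fig


def _add_scale_bar(ax, width_um: float) -> None:
    bar = 500.0 if width_um > 1000 else max(10.0, round(width_um / 5, -1))
    x0 = 0.05 * width_um
    y0 = 0.05 * ax.get_ylim()[1]
    ax.plot([x0, x0 + bar], [y0, y0], color="white", lw=3)
    ax.text(x0, y0 * 1.3, f"{bar:.0f} μm", color="white", fontsize=8)


def branch_overlay_rgb(graph, shape=None) -> np.ndarray:
    """Hue-luminance encoding of the projected skeleton.

    Hue encodes the local number of confluent paths (2 for a plain path, 3+
    at junctions); luminance (value) encodes the voxel's z-depth within the
    band. Returns an (nx, ny, 3) RGB array on a black background.
    """
    skel = graph.skeleton
    if skel.ndim != 3:
        raise ValueError("branch overlay needs a 3D skeleton")
    if shape is None:
        shape = skel.shape[:2]
    rgb = np.zeros(shape + (3,), dtype=float)
    if not skel.any():
        return rgb
    from .metrics import _neighbor_counts

    counts = _neighbor_counts(skel)
    nz = skel.shape[2]
    voxels = np.argwhere(skel)
    degree = counts[skel]
    # degree 1..5+ mapped over a fixed hue wheel segment
    hue = np.clip((np.minimum(degree, 5) - 1) / 4.0, 0, 1) * 0.75
    val = 0.25 + 0.75 * (voxels[:, 2] / max(nz - 1, 1))
    hsv = np.stack([hue, np.ones_like(hue, dtype=float), val], axis=1)
    colors = hsv_to_rgb(hsv)
    # z-order: later (deeper) voxels drawn last per column
    order = np.argsort(voxels[:, 2])
    for i in order:
        x, y = voxels[i, 0], voxels[i, 1]
        rgb[x, y] = colors[i]
    return rgb


def render_branch_overlay(graph, ax=None):
    """Render the hue-luminance branch/depth overlay with a legend.

    Empty graphs produce a blank canvas (legend only). Returns the Figure.
    """
    rgb = branch_overlay_rgb(graph)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    ax.imshow(np.transpose(rgb, (1, 0, 2)), origin="lower")
    ax.set_title("hue: confluent paths (2–5+) — luminance: depth in band")
    ax.set_xticks([])
    ax.set_yticks([])
    return fig
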