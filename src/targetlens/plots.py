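"""Radar ("spider") profile plot of the eight area scores.

Wedge height encodes how much evidence exists in each area; the four
quality-bearing axes (druggability, chemistry, genetics, safety) are filled
on a red-to-green ramp encoding how *good* that evidence is, the remaining
axes in a neutral blue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .scoring import AreaScores, quality_color

__all__ = ["SPIDER_AXIS_ORDER", "render_spider_plot", "spider_plot_figure"]

#: Fixed axis order, clockwise from the top.
SPIDER_AXIS_ORDER = (
    "structure",
    "druggability",
    "chemistry",
    "biology",
    "diseases",
    "genetics",
    "information",
    "safety",
)

_QUALITY_AXES = ("druggability", "chemistry", "genetics", "safety")
_NEUTRAL = (0.35, 0.55, 0.85)


def spider_plot_figure(
    scores: AreaScores,
    qualities: Mapping[str, float] | None = None,
    title: str = "",
):
    """Build the radar figure; callers own closing it."""
    qualities = dict(qualities or {})
    values = [getattr(scores, name) for name in SPIDER_AXIS_ORDER]
    n = len(SPIDER_AXIS_ORDER)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + np.pi / 2.0

    fig = plt.figure(figsize=(4.6, 4.6))
    ax = fig.add_subplot(111, polar=True)
    ax.set_theta_direction(-1)
    width = 2.0 * np.pi / n * 0.92
    colors = []
    for name in SPIDER_AXIS_ORDER:
        if name in _QUALITY_AXES:
            q = float(np.clip(qualities.get(name, 0.5), 0.0, 1.0))
            colors.append(quality_color(q))
        else:
            colors.append(_NEUTRAL)
    ax.bar(angles, values, width=width, color=colors, edgecolor="white", alpha=0.9)
    ax.set_xticks(angles)
    ax.set_xticklabels([name.capitalize() for name in SPIDER_AXIS_ORDER], fontsize=8)
    ax.set_ylim(0.0, 1.0)
    ax.set_yticks([0.25, 0.5, 0.75, 1.0])
    ax.set_yticklabels(["", "0.5", "", "1"], fontsize=7)
    if title:
        ax.set_title(title, fontsize=11)
    fig.subplots_adjust(left=0.08, right=0.92, top=0.88, bottom=0.08)
    # stash the rendered geometry for downstream assertions
    fig.targetlens_axes = {
        name: {"score": v, "color": c}
        for name, v, c in zip(SPIDER_AXIS_ORDER, values, colors)
    }
    return fig


def render_spider_plot(
    scores: AreaScores,
    qualities: Mapping[str, float] | None = None,
    path: str | Path = "spider.png",
    title: str = "",
) -> Path:
    """Write the radar profile to ``path`` (format from the extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig = spider_plot_figure(scores, qualities, title=title)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
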