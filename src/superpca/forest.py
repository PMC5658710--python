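"""Forest plots of hazard/odds ratios with confidence intervals.

The module plots user-supplied summary rows verbatim — no pooling, no CI
recomputation. One row per estimate in input order, a point at the estimate,
a whisker spanning the interval, and a reference line at 1.0 on a log-scaled
axis by default (ratio-scale measures are symmetric around 1 in log space).
SVG output is deterministic: identical inputs give byte-identical files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_clinical import ForestRow, ValidationError

__all__ = ["ForestStyle", "render_forest"]

_SUPPORTED = (".png", ".svg", ".pdf")


@dataclass
class ForestStyle:
    """Visual options for a forest plot."""

    title: str = ""
    axis_label: str = "hazard ratio"
    font_size: float = 10.0
    point_color: str = "#1f4e79"
    ci_color: str = "#555555"
    log_scale: bool = True
    reference_line: float = 1.0

    def __post_init__(self) -> None:
        if self.font_size <= 0:
            raise ValidationError("font_size must be positive")
        if self.log_scale and self.reference_line <= 0:
            raise ValidationError("reference_line must be positive on a log scale")


def render_forest(rows: list[ForestRow], style: ForestStyle,
                  out_path: str | Path) -> Path:
    """Render one row per estimate, top to bottom in input order."""
    out_path = Path(out_path)
    if out_path.suffix.lower() not in _SUPPORTED:
        raise ValidationError(
            f"unsupported output format {out_path.suffix!r}; "
            f"supported: {', '.join(_SUPPORTED)}"
        )
    if not rows:
        raise ValidationError("need at least one row to plot")
    for r in rows:
        if not isinstance(r, ForestRow):
            r = ForestRow(r.label, r.estimate, r.lower, r.upper)  # re-validates

    est = np.array([r.estimate for r in rows])
    lo = np.array([r.lower for r in rows])
    hi = np.array([r.upper for r in rows])
    ypos = np.arange(len(rows), 0, -1)  # first row on top

    plt.rcParams["svg.hashsalt"] = "superpca"
    plt.rcParams["svg.fonttype"] = "none"  # labels stay text, and files stay deterministic
    fig, ax = plt.subplots(figsize=(6, 1.0 + 0.45 * len(rows)))
    ax.errorbar(est, ypos, xerr=[est - lo, hi - est], fmt="s",
                color=style.point_color, ecolor=style.ci_color,
                elinewidth=1.4, capsize=3, markersize=6, linestyle="none")
    ax.axvline(style.reference_line, color="#999999", linestyle="--", linewidth=1)
    if style.log_scale:
        ax.set_xscale("log")
    ax.set_yticks(ypos, [r.label for r in rows], fontsize=style.font_size)
    ax.set_ylim(0.3, len(rows) + 0.7)
    ax.set_xlabel(style.axis_label, fontsize=style.font_size)
    if style.title:
        ax.set_title(style.title, fontsize=style.font_size + 2)
    fig.tight_layout()
    meta = {"Date": None} if out_path.suffix.lower() == ".svg" else None
    fig.savefig(out_path, metadata=meta)
    plt.close(fig)
    return out_path
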