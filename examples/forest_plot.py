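"""Forest plot of user-supplied hazard ratios with confidence intervals.

Each row is drawn verbatim (no pooling): a point at the estimate, a whisker
over the CI, and a dashed reference line at 1 on a log-scaled axis, so
symmetric ratios like (0.5, 2.0) sit symmetrically around no-effect.
"""
from pathlib import Path

from superpca import ForestRow, ForestStyle, render_forest

Path("scratch").mkdir(exist_ok=True)
rows = [
    ForestRow("signature A", 2.10, 1.32, 3.34),
    ForestRow("signature B", 0.71, 0.52, 0.97),
    ForestRow("signature C", 1.05, 0.66, 1.67),
    ForestRow("stage III vs I", 3.40, 1.90, 6.08),
]
style = ForestStyle(title="Survival associations", axis_label="hazard ratio",
                    font_size=10, point_color="#1f4e79")
out = render_forest(rows, style, "scratch/example_forest.svg")
print(f"wrote {out}: {len(rows)} rows, log-scaled axis, reference line at HR = 1")
print("rows whose whisker crosses the line (C here) have CIs that do not")
print("exclude no effect; A and B do, in opposite directions")
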