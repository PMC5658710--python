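"""Association between the predicted principal component and the test outcome.

Pairings of outcome type and summary style:

==========  ============  ==========================================
outcome     style         test / display
==========  ============  ==========================================
survival    dichotomized  Kaplan-Meier curves + two-group log-rank
continuous  continuous    scatter + Pearson correlation
continuous  dichotomized  boxplot + Welch t-test on the outcome
binary      continuous    boxplot of PC by class + Welch t-test
binary      dichotomized  bar plot + Pearson chi-square on the 2x2
==========  ============  ==========================================

Dichotomization is always at the median of the PC scores, with scores <= median
labelled "low" and the rest "high".
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from .io_clinical import ClinicalOutcome, ValidationError

__all__ = ["AssociationSummary", "dichotomize_at_median", "km_logrank",
           "pearson_summary", "ttest_summary", "chisq_summary", "summarize",
           "render_summary_plots"]

_VALID_PAIRINGS = {("survival", "dichotomized"), ("continuous", "continuous"),
                   ("continuous", "dichotomized"), ("binary", "continuous"),
                   ("binary", "dichotomized")}


@dataclass
class AssociationSummary:
    """A named two-sided test of the PC/outcome association."""

    test_name: str  # logrank | pearson | t_test | chi_square
    statistic: float
    p_value: float
    effect: float | None = None  # Pearson r, mean difference, or odds ratio
    group_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"test_name": self.test_name, "statistic": self.statistic,
                "p_value": self.p_value, "effect": self.effect,
                "group_sizes": self.group_sizes}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def dichotomize_at_median(pc_scores: np.ndarray) -> np.ndarray:
    """Labels: "low" for scores <= median, "high" above it."""
    z = np.asarray(pc_scores, dtype=float)
    if len(z) < 2:
        raise ValidationError("need at least 2 samples to dichotomize")
    if np.all(z == z[0]):
        raise ValidationError("cannot dichotomize constant scores")
    med = float(np.median(z))
    labels = np.where(z <= med, "low", "high")
    if (labels == "high").sum() == 0:
        # median ties can swallow the upper half; split strictly above the
        # largest value below the max instead so both groups stay non-empty
        cut = z[z < z.max()].max()
        labels = np.where(z <= cut, "low", "high")
    return labels


def km_logrank(outcome_test: ClinicalOutcome, groups: np.ndarray) -> AssociationSummary:
    """Two-group log-rank test (1 df) on dichotomized PC scores."""
    if outcome_test.outcome_type != "survival":
        raise ValidationError("km_logrank needs a survival outcome")
    groups = np.asarray(groups)
    low, high = groups == "low", groups == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ValidationError("both groups must be non-empty")
    if outcome_test.event.sum() == 0:
        raise ValidationError("no events observed in the test set")
    from lifelines.statistics import logrank_test
    res = logrank_test(outcome_test.time[low], outcome_test.time[high],
                       event_observed_A=outcome_test.event[low],
                       event_observed_B=outcome_test.event[high])
    return AssociationSummary("logrank", float(res.test_statistic), float(res.p_value),
                              effect=None,
                              group_sizes={"low": int(low.sum()), "high": int(high.sum())})


def pearson_summary(outcome_test: ClinicalOutcome, pc_scores: np.ndarray) -> AssociationSummary:
    """Pearson correlation of outcome value and PC score, with its t test."""
    if outcome_test.outcome_type != "continuous":
        raise ValidationError("pearson_summary needs a continuous outcome")
    y = outcome_test.value
    z = np.asarray(pc_scores, dtype=float)
    n = len(y)
    if n < 3:
        raise ValidationError("need at least 3 samples for a correlation test")
    if np.std(y) == 0 or np.std(z) == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = sps.pearsonr(z, y)
    if abs(r) < 1.0:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    else:
        t = np.sign(r) * np.finfo(float).max
    return AssociationSummary("pearson", float(t), float(p), effect=float(r),
                              group_sizes=None)


def ttest_summary(values: np.ndarray, groups: np.ndarray,
                  flavor: str = "welch") -> AssociationSummary:
    """Two-sample t test of ``values`` between the two groups.

    Welch's unequal-variance form by default; ``flavor="pooled"`` for the
    classic equal-variance test. Effect is mean(high) - mean(low) (or
    mean(class 1) - mean(class 0) when groups are 0/1 labels).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(levels)}")
    # order so the effect is high-minus-low / class1-minus-class0
    if set(map(str, levels)) == {"low", "high"}:
        lo, hi = values[groups == "low"], values[groups == "high"]
    else:
        lo, hi = values[groups == levels[0]], values[groups == levels[1]]
    if len(lo) < 2 or len(hi) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if flavor not in ("welch", "pooled"):
        raise ValidationError(f"unknown t-test flavor {flavor!r}")
    t, p = sps.ttest_ind(hi, lo, equal_var=(flavor == "pooled"))
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return AssociationSummary("t_test", float(t), float(p),
                              effect=float(hi.mean() - lo.mean()),
                              group_sizes={"low": len(lo), "high": len(hi)})


def chisq_summary(groups_predicted: np.ndarray, outcome_binary: np.ndarray,
                  correction: bool = False) -> AssociationSummary:
    """Pearson chi-square (1 df) of predicted low/high group vs observed class.

    Continuity correction is off by default. The odds ratio uses the raw 2x2
    counts; 0.5 is added to every cell only when a zero cell exists (logged).
    """
    groups_predicted = np.asarray(groups_predicted)
    y = np.asarray(outcome_binary).astype(int)
    table = np.array([
        [int(((groups_predicted == g) & (y == c)).sum()) for c in (0, 1)]
        for g in ("low", "high")
    ], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("2x2 table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    t = table
    if np.any(t == 0):
        warnings.warn("zero cell in 2x2 table: adding 0.5 to all cells for the odds ratio")
        t = t + 0.5
    oratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    sizes = {"low": int(table[0].sum()), "high": int(table[1].sum())}
    return AssociationSummary("chi_square", float(chi2), float(p),
                              effect=float(oratio), group_sizes=sizes)


def summarize(outcome_test: ClinicalOutcome, pc_scores: np.ndarray, style: str,
              t_test_flavor: str = "welch", chisq_correction: bool = False):
    """Dispatch to the test matching the outcome type / style pairing.

    Returns (AssociationSummary, group labels or None).
    """
    pair = (outcome_test.outcome_type, style)
    if pair not in _VALID_PAIRINGS:
        raise ValidationError(
            f"unsupported pairing {pair}; valid: {sorted(_VALID_PAIRINGS)}"
        )
    if pair == ("continuous", "continuous"):
        return pearson_summary(outcome_test, pc_scores), None
    if pair == ("binary", "continuous"):
        groups = np.where(outcome_test.label == 1, "high", "low")
        return ttest_summary(pc_scores, outcome_test.label, t_test_flavor), groups
    groups = dichotomize_at_median(pc_scores)
    if pair == ("survival", "dichotomized"):
        return km_logrank(outcome_test, groups), groups
    if pair == ("continuous", "dichotomized"):
        return ttest_summary(outcome_test.value, groups, t_test_flavor), groups
    return chisq_summary(groups, outcome_test.label, chisq_correction), groups


# ---------------------------------------------------------------------------
# Plots


def _annotate(ax, summary: AssociationSummary) -> None:
    txt = f"{summary.test_name}: stat={summary.statistic:.3g}, p={summary.p_value:.3g}"
    if summary.effect is not None:
        txt += f", effect={summary.effect:.3g}"
    ax.set_title(txt, fontsize=9)


def _save(fig, out_dir: Path, stem: str) -> list[Path]:
    plt.rcParams["svg.hashsalt"] = "superpca"
    plt.rcParams["svg.fonttype"] = "none"  # keep labels as searchable text
    paths = []
    for ext in ("png", "svg"):
        p = out_dir / f"{stem}.{ext}"
        fig.savefig(p, metadata={"Date": None} if ext == "svg" else None)
        paths.append(p)
    plt.close(fig)
    return paths


def render_summary_plots(outcome_test: ClinicalOutcome, pc_scores: np.ndarray,
                         groups: np.ndarray | None, summary: AssociationSummary,
                         style: str, out_dir: str | Path) -> list[Path]:
    """Write the figure matching the outcome/style pairing as PNG and SVG."""
    pair = (outcome_test.outcome_type, style)
    if pair not in _VALID_PAIRINGS:
        raise ValidationError(
            f"unsupported pairing {pair}; valid: {sorted(_VALID_PAIRINGS)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z = np.asarray(pc_scores, dtype=float)

    if pair == ("survival", "dichotomized"):
        from lifelines import KaplanMeierFitter
        fig, ax = plt.subplots(figsize=(5, 4))
        for name in ("low", "high"):
            m = np.asarray(groups) == name
            km = KaplanMeierFitter()
            km.fit(outcome_test.time[m], outcome_test.event[m], label=f"PC {name}")
            km.plot_survival_function(ax=ax, show_censors=True)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        _annotate(ax, summary)
        return _save(fig, out_dir, "km")

    if pair == ("continuous", "continuous"):
        y = outcome_test.value
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(z, y, s=18)
        b, a = np.polyfit(z, y, 1)
        xs = np.linspace(z.min(), z.max(), 50)
        ax.plot(xs, a + b * xs, color="C3")
        ax.set_xlabel("predicted PC score")
        ax.set_ylabel("outcome")
        ax.text(0.02, 0.95, f"r = {summary.effect:.3f}", transform=ax.transAxes)
        _annotate(ax, summary)
        return _save(fig, out_dir, "scatter")

    if pair in (("continuous", "dichotomized"), ("binary", "continuous")):
        if pair[0] == "continuous":
            vals, lab = outcome_test.value, "outcome"
        else:
            vals, lab = z, "predicted PC score"
        g = np.asarray(groups)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.boxplot([vals[g == "low"], vals[g == "high"]], tick_labels=["low", "high"])
        ax.set_ylabel(lab)
        ax.set_xlabel("PC group" if pair[0] == "continuous" else "observed class")
        _annotate(ax, summary)
        return _save(fig, out_dir, "boxplot")

    # binary + dichotomized: two bars per observed class
    g = np.asarray(groups)
    y = outcome_test.label
    counts = np.array([[((g == grp) & (y == c)).sum() for c in (0, 1)]
                       for grp in ("low", "high")], dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = np.arange(2)
    ax.bar(x - 0.18, counts[0], width=0.36, label="PC low")
    ax.bar(x + 0.18, counts[1], width=0.36, label="PC high")
    ax.set_xticks(x, ["class 0", "class 1"])
    ax.set_ylabel("count")
    ax.legend()
    _annotate(ax, summary)
    return _save(fig, out_dir, "barplot")
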