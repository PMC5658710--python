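"""Per-feature univariate association scores for feature screening.

The screening statistic s_j is a signed z-like quantity computed in closed form
at the null, so screening is deterministic and requires no iterative fitting:

* survival   — Cox partial-likelihood score test at beta=0 with Breslow handling
               of tied event times: z_j = U_j / sqrt(I_j), where U_j sums, over
               observed events, the difference between the subject's expression
               and the risk-set mean, and I_j sums the risk-set variances.
* continuous — t statistic of the univariate least-squares slope,
               t_j = r_j * sqrt(n-2) / sqrt(1 - r_j^2).
* binary     — logistic score test at slope 0 with the intercept fixed at
               logit(ybar): U_j = sum_i x_ij (y_i - ybar),
               I_j = ybar (1-ybar) sum_i (x_ij - xbar_j)^2, z_j = U_j/sqrt(I_j).
               A Wald variant (z from a fitted univariate logistic model) is
               available via ``stat="wald"``.

Signs are oriented so a positive score means higher expression goes with higher
hazard / larger outcome / class 1. Constant features score 0 with a warning so
that thresholding silently drops them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_clinical import ClinicalOutcome, ExpressionMatrix, ValidationError, _sep_for, _fmt

__all__ = ["ScoreTable", "score_survival", "score_continuous", "score_binary",
           "compute_scores", "write_scores", "read_scores"]


@dataclass
class ScoreTable:
    """Per-feature univariate statistics, in input feature order."""

    feature_ids: list[str]
    score: np.ndarray
    numerator: np.ndarray | None = None    # U_j where the statistic is a score test
    information: np.ndarray | None = None  # I_j where the statistic is a score test

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.feature_ids),):
            raise ValidationError("one score per feature required")
        if not np.all(np.isfinite(self.score)):
            raise ValidationError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids, "score": self.score,
                             "abs_score": np.abs(self.score)})


def write_scores(table: ScoreTable, path: str | Path) -> None:
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"feature_id{sep}score{sep}abs_score\n")
        for fid, s in zip(table.feature_ids, table.score):
            fh.write(f"{fid}{sep}{_fmt(s)}{sep}{_fmt(abs(s))}\n")


def read_scores(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    return ScoreTable([str(f) for f in df["feature_id"]], df["score"].to_numpy())


def _warn_constant(feature_ids, const_mask) -> None:
    if np.any(const_mask):
        names = [f for f, c in zip(feature_ids, const_mask) if c]
        warnings.warn(
            f"{len(names)} constant feature(s) scored 0: {', '.join(names[:10])}"
            + ("..." if len(names) > 10 else ""),
            stacklevel=3,
        )


def _check_aligned(X: ExpressionMatrix, outcome: ClinicalOutcome, expected_type: str) -> None:
    if outcome.outcome_type != expected_type:
        raise ValidationError(
            f"expected a {expected_type} outcome, got {outcome.outcome_type}"
        )
    if outcome.sample_ids != X.sample_ids:
        raise ValidationError("outcome samples are not aligned with the expression matrix")


def score_survival(X: ExpressionMatrix, outcome: ClinicalOutcome) -> ScoreTable:
    """Cox score-test z statistic per feature (Breslow ties), vectorized."""
    _check_aligned(X, outcome, "survival")
    time, event = outcome.time, outcome.event
    if event.sum() == 0:
        raise ValidationError("no events observed")
    order = np.argsort(time, kind="stable")
    t = time[order]
    ev = event[order].astype(bool)
    xs = X.values[:, order]
    n = xs.shape[1]
    # suffix sums over the sorted samples: risk set at time t = samples with time >= t
    s1 = np.cumsum(xs[:, ::-1], axis=1)[:, ::-1]
    s2 = np.cumsum((xs * xs)[:, ::-1], axis=1)[:, ::-1]
    nrisk = n - np.arange(n)
    first = np.searchsorted(t, t, side="left")  # tied event times share one risk set
    ev_idx = np.flatnonzero(ev)
    fi = first[ev_idx]
    mean_r = s1[:, fi] / nrisk[fi]
    var_r = np.maximum(s2[:, fi] / nrisk[fi] - mean_r**2, 0.0)
    U = xs[:, ev_idx].sum(axis=1) - mean_r.sum(axis=1)
    I = var_r.sum(axis=1)
    const = X.values.std(axis=1) == 0
    _warn_constant(X.feature_ids, const)
    z = np.zeros(X.n_features)
    ok = I > 0
    z[ok] = U[ok] / np.sqrt(I[ok])
    return ScoreTable(list(X.feature_ids), z, numerator=U, information=I)


def score_continuous(X: ExpressionMatrix, outcome: ClinicalOutcome) -> ScoreTable:
    """Slope t statistic per feature, r*sqrt(n-2)/sqrt(1-r^2)."""
    _check_aligned(X, outcome, "continuous")
    y = outcome.value
    n = len(y)
    if n < 3:
        raise ValidationError("need at least 3 samples for the slope t statistic")
    yc = y - y.mean()
    sy = np.sqrt((yc * yc).sum())
    if sy == 0:
        raise ValidationError("constant outcome: slope t statistic undefined")
    xc = X.values - X.values.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    const = sx == 0
    _warn_constant(X.feature_ids, const)
    r = np.zeros(X.n_features)
    np.divide(xc @ yc, sx * sy, out=r, where=~const)
    r = np.clip(r, -1.0, 1.0)
    t = np.zeros(X.n_features)
    collinear = (1.0 - r * r < 1e-12) & ~const
    ok = ~const & ~collinear
    t[ok] = r[ok] * np.sqrt(n - 2) / np.sqrt(1.0 - r[ok] ** 2)
    if np.any(collinear):
        names = [f for f, c in zip(X.feature_ids, collinear) if c]
        warnings.warn(
            "perfectly collinear feature(s) assigned the maximum representable "
            f"score: {', '.join(names[:10])}",
            stacklevel=2,
        )
        t[collinear] = np.sign(r[collinear]) * np.finfo(float).max
    return ScoreTable(list(X.feature_ids), t)


def score_binary(X: ExpressionMatrix, outcome: ClinicalOutcome, stat: str = "score") -> ScoreTable:
    """Logistic score-test z per feature (or Wald z with ``stat="wald"``)."""
    _check_aligned(X, outcome, "binary")
    y = outcome.label.astype(float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValidationError("binary outcome must contain both classes")
    if min(n0, n1) < 2:
        raise ValidationError("each class needs at least 2 samples")
    if stat not in ("score", "wald"):
        raise ValidationError(f"unknown binary statistic {stat!r}")
    const = X.values.std(axis=1) == 0
    _warn_constant(X.feature_ids, const)
    if stat == "wald":
        z = np.array([_wald_logistic(x, y) if not c else 0.0
                      for x, c in zip(X.values, const)])
        return ScoreTable(list(X.feature_ids), z)
    ybar = y.mean()
    U = X.values @ (y - ybar)
    xc = X.values - X.values.mean(axis=1, keepdims=True)
    I = ybar * (1.0 - ybar) * (xc * xc).sum(axis=1)
    z = np.zeros(X.n_features)
    ok = I > 0
    z[ok] = U[ok] / np.sqrt(I[ok])
    return ScoreTable(list(X.feature_ids), z, numerator=U, information=I)


def _wald_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 50) -> float:
    """Wald z from a Newton-fitted univariate logistic model (intercept + slope)."""
    xs = (x - x.mean()) / x.std()
    beta = np.zeros(2)
    Xd = np.column_stack([np.ones_like(xs), xs])
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        g = Xd.T @ (y - p)
        H = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = np.clip(beta + step, -30, 30)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(Xd @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    H = Xd.T @ (Xd * (p * (1 - p))[:, None])
    cov = np.linalg.pinv(H)
    se = np.sqrt(cov[1, 1])
    return float(beta[1] / se) if se > 0 else 0.0


def compute_scores(X: ExpressionMatrix, outcome: ClinicalOutcome, **opts) -> ScoreTable:
    """Dispatch to the scoring function matching ``outcome.outcome_type``."""
    if outcome.outcome_type == "survival":
        return score_survival(X, outcome)
    if outcome.outcome_type == "continuous":
        return score_continuous(X, outcome)
    return score_binary(X, outcome, **opts)
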