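"""The supervised principal components engine.

The workflow: split samples into training and test sets; compute a univariate
association score per feature on training data; build a grid of candidate
screening thresholds on |score|; pick the threshold by K-fold cross-validation
(maximizing the mean held-out likelihood-ratio statistic of the outcome on the
projected first principal component); refit on all training data at the chosen
threshold; project the test samples and summarize the association.

Features are centered by their training means before the PC fit; no per-feature
variance scaling is applied, so the screening statistic's implicit weighting is
preserved (pre-standardize the matrix if unit-variance features are wanted).
Only the first principal component is used; the loading vector has unit norm
and its largest-magnitude entry is made positive so the sign is reproducible
across linear-algebra backends.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_clinical import (ClinicalOutcome, ExpressionMatrix, FoldAssignment,
                          ValidationError, _fmt)
from .scores import ScoreTable, compute_scores, write_scores

logger = logging.getLogger("superpca")

__all__ = ["SplitSpec", "SuperPCModel", "CVResult", "SuperPCRun",
           "split_train_test", "make_folds", "make_threshold_grid",
           "screen_features", "fit_pc", "project",
           "cross_validate_threshold", "run_superpc"]

GRID_UPPER_QUANTILE = 0.95  # caps the grid so the top threshold cannot empty the selection


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Train/test split and fold generation


@dataclass
class SplitSpec:
    """How to split samples into training and test sets."""

    train_proportion: float = 0.67
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_proportion < 1.0:
            raise ValidationError("train_proportion must be in (0, 1)")


def _strata(outcome: ClinicalOutcome) -> np.ndarray:
    """Stratification labels: event indicator, class label, or a single stratum."""
    if outcome.outcome_type == "survival":
        return outcome.event
    if outcome.outcome_type == "binary":
        return outcome.label
    return np.zeros(outcome.n_samples, dtype=int)


def _allocate(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` draws across strata."""
    quota = sizes * total / sizes.sum()
    take = np.floor(quota).astype(int)
    remainder = quota - take
    for i in np.argsort(-remainder, kind="stable")[: total - take.sum()]:
        take[i] += 1
    return take


def split_train_test(sample_ids: list[str], outcome: ClinicalOutcome,
                     spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Deterministic (optionally stratified) train/test split.

    The training size is ``round(p * n)``; under stratification each stratum's
    share is preserved to within one sample via largest-remainder rounding.
    """
    n = len(sample_ids)
    if n < 4:
        raise ValidationError("need at least 4 samples to split")
    n_train = int(round(spec.train_proportion * n))
    if n_train < 1 or n_train >= n:
        raise ValidationError(
            f"train_proportion {spec.train_proportion} yields an empty "
            f"{'training' if n_train < 1 else 'test'} set for n={n}"
        )
    out = outcome.subset(sample_ids)
    strata = _strata(out) if spec.stratify else np.zeros(n, dtype=int)
    levels, inverse = np.unique(strata, return_inverse=True)
    if spec.stratify and np.any(np.bincount(inverse) < 2):
        raise ValidationError("each stratum needs at least 2 samples to stratify")
    rng = np.random.default_rng(spec.seed)
    sizes = np.bincount(inverse)
    takes = _allocate(sizes, n_train)
    train_mask = np.zeros(n, dtype=bool)
    for lev in range(len(levels)):
        members = np.flatnonzero(inverse == lev)
        chosen = rng.permutation(members)[: takes[lev]]
        train_mask[chosen] = True
    train = [s for s, m in zip(sample_ids, train_mask) if m]
    test = [s for s, m in zip(sample_ids, train_mask) if not m]
    return train, test


def make_folds(sample_ids: list[str], outcome: ClinicalOutcome, n_folds: int,
               seed: int) -> FoldAssignment:
    """Seeded fold assignment, stratified by event indicator or class label.

    Within each stratum samples are shuffled and dealt cyclically to folds
    1..K, so events (or classes) are spread as evenly as possible.
    """
    n = len(sample_ids)
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    if n_folds > n:
        raise ValidationError(f"more folds ({n_folds}) than training samples ({n})")
    out = outcome.subset(sample_ids)
    strata = _strata(out)
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    offset = 0
    for lev in np.unique(strata):
        members = np.flatnonzero(strata == lev)
        perm = rng.permutation(members)
        fold_of[perm] = (offset + np.arange(len(perm))) % n_folds + 1
        offset += len(perm)
    return FoldAssignment({s: int(f) for s, f in zip(sample_ids, fold_of)})


# ---------------------------------------------------------------------------
# Threshold grid and screening


def make_threshold_grid(scores: ScoreTable, n_thresholds: int) -> np.ndarray:
    """Candidate thresholds: |score| quantiles, equally spaced on [0, 0.95].

    Linear-interpolation quantiles of the training |s_j| between the 0 and
    0.95 quantiles; the upper cap keeps the strictest threshold from emptying
    the selection. Duplicates collapse, so fewer than ``n_thresholds`` values
    may return when scores tie.
    """
    if n_thresholds < 2:
        raise ValidationError("need at least 2 thresholds")
    a = np.abs(scores.score)
    if np.unique(a).size < 2:
        raise ValidationError("all |score| values equal: no threshold grid possible")
    qs = np.linspace(0.0, GRID_UPPER_QUANTILE, n_thresholds)
    grid = np.unique(np.quantile(a, qs, method="linear"))
    return grid


def screen_features(scores: ScoreTable, threshold: float) -> list[str]:
    """Features with |s_j| strictly above the threshold, in input order."""
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    kept = [f for f, s in zip(scores.feature_ids, scores.score) if abs(s) > threshold]
    if not kept:
        raise ValidationError(f"threshold {threshold} removes all features")
    return kept


# ---------------------------------------------------------------------------
# Principal-component fit and projection


@dataclass
class SuperPCModel:
    """A fitted supervised-PC predictor.

    ``loadings`` is the unit-norm leading principal direction over the selected
    features of the training-mean-centered matrix; ``center`` holds those
    training means. A new sample's risk score is loadings . (x - center).
    """

    outcome_type: str
    threshold: float
    feature_ids: list[str]
    center: np.ndarray
    loadings: np.ndarray
    sign_convention: str = "largest-abs-loading-positive"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        k = len(self.feature_ids)
        if not k:
            raise ValidationError("model must retain at least one feature")
        if self.center.shape != (k,) or self.loadings.shape != (k,):
            raise ValidationError("center/loadings length must match feature_ids")
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-8:
            raise ValidationError("loadings must have unit norm")

    def to_json(self, path: str | Path) -> None:
        obj = {"outcome_type": self.outcome_type, "threshold": self.threshold,
               "selected_features": self.feature_ids,
               "center": self.center.tolist(), "loadings": self.loadings.tolist(),
               "sign_convention": self.sign_convention, "n_components": 1}
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SuperPCModel":
        obj = json.loads(Path(path).read_text())
        return cls(obj["outcome_type"], obj["threshold"], obj["selected_features"],
                   np.array(obj["center"]), np.array(obj["loadings"]),
                   obj.get("sign_convention", "largest-abs-loading-positive"))


def fit_pc(X_train: ExpressionMatrix, threshold: float = 0.0,
           outcome_type: str = "continuous") -> SuperPCModel:
    """Fit the first principal component of the (screened) training matrix.

    Rows are centered by their training means; the leading singular direction
    over features becomes the loading vector, sign-fixed so its largest-
    magnitude entry is positive.
    """
    if X_train.n_samples < 2:
        raise ValidationError("need at least 2 training samples to fit a PC")
    center = X_train.values.mean(axis=1)
    Xc = X_train.values - center[:, None]
    if X_train.n_features == 1:
        w = np.ones(1)
    else:
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        w = u[:, 0]
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
    return SuperPCModel(outcome_type, float(threshold), list(X_train.feature_ids),
                        center, w)


def project(model: SuperPCModel, X_new: ExpressionMatrix) -> np.ndarray:
    """Per-sample PC score: loadings . (x - center), in ``X_new`` sample order."""
    sub = X_new.subset_features(model.feature_ids)  # errors name any missing feature
    return model.loadings @ (sub.values - model.center[:, None])


# ---------------------------------------------------------------------------
# Held-out likelihood-ratio objectives (univariate models on the projected PC)
#
# Small in-package Newton solvers keep cross-validation deterministic and
# warning-free at tiny fold sizes; tests cross-check them against lifelines
# and statsmodels fits.


def _cox_pll_parts(beta: float, t: np.ndarray, ev: np.ndarray, z: np.ndarray):
    """Breslow partial log-likelihood, gradient, Hessian for one covariate."""
    order = np.argsort(t, kind="stable")
    ts, evs, zs = t[order], ev[order].astype(bool), z[order]
    w = np.exp(beta * zs)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * zs)[::-1])[::-1]
    s2 = np.cumsum((w * zs * zs)[::-1])[::-1]
    first = np.searchsorted(ts, ts, side="left")
    fi = first[np.flatnonzero(evs)]
    m1 = s1[fi] / s0[fi]
    ll = float(beta * zs[evs].sum() - np.log(s0[fi]).sum())
    g = float(zs[evs].sum() - m1.sum())
    h = float(-(s2[fi] / s0[fi] - m1 * m1).sum())
    return ll, g, h


def cox_lr_statistic(time: np.ndarray, event: np.ndarray, z: np.ndarray) -> float:
    """LR chi-square of a univariate proportional-hazards fit on ``z``."""
    event = np.asarray(event)
    if event.sum() == 0 or np.std(z) == 0:
        return 0.0
    zs = (z - z.mean()) / z.std()
    ll0, _, _ = _cox_pll_parts(0.0, time, event, zs)
    beta, ll = 0.0, ll0
    for _ in range(100):
        _, g, h = _cox_pll_parts(beta, time, event, zs)
        if h >= 0 or abs(g) < 1e-10:
            break
        step = -g / h
        new = float(np.clip(beta + step, -50.0, 50.0))
        ll_new, _, _ = _cox_pll_parts(new, time, event, zs)
        halvings = 0
        while ll_new < ll and halvings < 30:
            new = (beta + new) / 2.0
            ll_new, _, _ = _cox_pll_parts(new, time, event, zs)
            halvings += 1
        if abs(new - beta) < 1e-12:
            break
        beta, ll = new, ll_new
    return max(0.0, 2.0 * (ll - ll0))


def logistic_lr_statistic(y: np.ndarray, z: np.ndarray) -> float:
    """LR chi-square of a univariate logistic fit (intercept + slope) on ``z``."""
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0) or np.std(z) == 0:
        return 0.0
    zs = (z - z.mean()) / z.std()
    Xd = np.column_stack([np.ones_like(zs), zs])

    def ll_of(b):
        eta = np.clip(Xd @ b, -30, 30)
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll0 = float(len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))
    b = np.array([np.log(ybar / (1 - ybar)), 0.0])
    ll = ll_of(b)
    for _ in range(100):
        eta = np.clip(Xd @ b, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        g = Xd.T @ (y - p)
        H = Xd.T @ (Xd * (p * (1 - p))[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        new = np.clip(b + step, -30.0, 30.0)
        ll_new = ll_of(new)
        halvings = 0
        while ll_new < ll and halvings < 30:
            new = (b + new) / 2.0
            ll_new = ll_of(new)
            halvings += 1
        if np.max(np.abs(new - b)) < 1e-12:
            break
        b, ll = new, ll_new
    return max(0.0, 2.0 * (ll - ll0))


def linear_lr_statistic(y: np.ndarray, z: np.ndarray) -> float:
    """Gaussian LR chi-square of a univariate linear fit: -n log(1 - r^2)."""
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0 or np.std(z) == 0:
        return 0.0
    r = float(np.corrcoef(y, z)[0, 1])
    r2 = min(r * r, 1.0 - 1e-12)
    return float(-len(y) * np.log1p(-r2))


def heldout_lr_statistic(outcome: ClinicalOutcome, pc_scores: np.ndarray) -> float:
    """The CV objective for the outcome type on held-out projected PC scores."""
    if outcome.outcome_type == "survival":
        return cox_lr_statistic(outcome.time, outcome.event, pc_scores)
    if outcome.outcome_type == "binary":
        return logistic_lr_statistic(outcome.label, pc_scores)
    return linear_lr_statistic(outcome.value, pc_scores)


# ---------------------------------------------------------------------------
# Cross-validated threshold selection


@dataclass
class CVResult:
    """Cross-validation curve over the threshold grid.

    ``statistics[f, t]`` is fold f+1's held-out LR statistic at threshold t;
    ``fold_scores[f]`` are the per-feature screening scores computed with fold
    f held out (stored so leakage is checkable). Ties in the mean are broken
    toward the larger threshold (fewer features).
    """

    thresholds: np.ndarray
    statistics: np.ndarray
    fold_assignment: FoldAssignment
    objective: str = "heldout_likelihood_ratio"
    fold_scores: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return self.fold_assignment.n_folds

    @property
    def mean_statistic(self) -> np.ndarray:
        return self.statistics.mean(axis=0)

    @property
    def optimal_threshold(self) -> float:
        m = self.mean_statistic
        best = np.flatnonzero(m == m.max())[-1]
        return float(self.thresholds[best])


def _validate_cv_folds(outcome: ClinicalOutcome, folds: FoldAssignment) -> None:
    ids = outcome.sample_ids
    if set(folds.assignments) != set(ids):
        raise ValidationError("fold assignment does not cover the training samples")
    n = len(ids)
    for f in range(1, folds.n_folds + 1):
        held = folds.samples_in(f)
        if len(held) < 2 or n - len(held) < 2:
            raise ValidationError(
                f"fold {f} must leave at least 2 samples both in and out"
            )
        if outcome.outcome_type == "survival":
            held_ev = outcome.subset(held).event.sum()
            rest = [s for s in ids if folds.assignments[s] != f]
            rest_ev = outcome.subset(rest).event.sum()
            if held_ev == 0 or rest_ev == 0:
                raise ValidationError(
                    f"fold {f} has zero events in its "
                    f"{'held-out' if held_ev == 0 else 'training'} portion; "
                    "use stratified folds or fewer folds"
                )


def cross_validate_threshold(X_train: ExpressionMatrix, outcome_train: ClinicalOutcome,
                             grid: np.ndarray, folds: FoldAssignment,
                             score_options: dict | None = None) -> CVResult:
    """K-fold CV of the screening threshold.

    For each fold, scores, screening, centering and the PC fit use only the
    out-of-fold samples; the held-out fold is projected and its LR statistic
    computed. A threshold that empties the screened set contributes 0 for that
    fold (logged) so the curve stays total across the grid.
    """
    _validate_cv_folds(outcome_train, folds)
    grid = np.asarray(grid, dtype=float)
    K = folds.n_folds
    stats = np.zeros((K, len(grid)))
    fold_scores: dict[int, np.ndarray] = {}
    opts = score_options or {}
    for f in range(1, K + 1):
        held = [s for s in X_train.sample_ids if folds.assignments[s] == f]
        rest = [s for s in X_train.sample_ids if folds.assignments[s] != f]
        X_out = X_train.subset_samples(rest)
        y_out = outcome_train.subset(rest)
        table = compute_scores(X_out, y_out, **opts)
        fold_scores[f] = table.score.copy()
        X_held = X_train.subset_samples(held)
        y_held = outcome_train.subset(held)
        keep_mask = np.abs(table.score)
        for t_idx, theta in enumerate(grid):
            kept = [fid for fid, a in zip(table.feature_ids, keep_mask) if a > theta]
            if not kept:
                logger.info("fold %d, threshold %.6g: empty selection, statistic 0", f, theta)
                stats[f - 1, t_idx] = 0.0
                continue
            model = fit_pc(X_out.subset_features(kept), theta, outcome_train.outcome_type)
            z = project(model, X_held)
            stats[f - 1, t_idx] = heldout_lr_statistic(y_held, z)
    return CVResult(grid, stats, folds, fold_scores=fold_scores)


# ---------------------------------------------------------------------------
# End-to-end run


@dataclass
class SuperPCRun:
    """Everything a full pipeline run produced."""

    model: SuperPCModel
    cv: CVResult
    scores: ScoreTable
    train_ids: list[str]
    test_ids: list[str]
    test_pc_scores: np.ndarray
    test_groups: np.ndarray | None
    summary: "object"  # AssociationSummary; typed loosely to avoid an import cycle
    summary_style: str


def _stage(name):
    """Re-raise stage failures with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (ValidationError, ValueError)):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_superpc(X: ExpressionMatrix, outcome: ClinicalOutcome, *,
                split: SplitSpec | None = None,
                n_thresholds: int = 20, n_folds: int = 10,
                folds: FoldAssignment | None = None,
                summary_style: str | None = None,
                score_options: dict | None = None,
                test_options: dict | None = None,
                out_dir: str | Path | None = None,
                make_plots: bool = True) -> SuperPCRun:
    """Run the full supervised-PC pipeline.

    Either ``split`` (seeded train/test split + seeded stratified folds) or an
    explicit ``folds`` assignment is used. With ``folds``, the training set is
    the fold file's sample domain and the test set the remaining samples, so a
    run is replayed exactly without a seed. All chosen parameters, scores, the
    CV curve, the realized folds, the fitted model, test predictions and the
    association summary are written to ``out_dir`` when given.
    """
    from . import association  # late import: association uses no core symbols

    if (split is None) == (folds is None):
        raise ValidationError("provide exactly one of split= or folds=")
    if outcome.sample_ids != X.sample_ids:
        outcome = outcome.subset(X.sample_ids)

    with _stage("split"):
        if folds is not None:
            train_ids = [s for s in X.sample_ids if s in folds.assignments]
            test_ids = [s for s in X.sample_ids if s not in folds.assignments]
            if not test_ids:
                raise ValidationError("fold file covers every sample: empty test set")
        else:
            train_ids, test_ids = split_train_test(X.sample_ids, outcome, split)
    X_train, X_test = X.subset_samples(train_ids), X.subset_samples(test_ids)
    y_train, y_test = outcome.subset(train_ids), outcome.subset(test_ids)

    with _stage("folds"):
        if folds is None:
            folds = make_folds(train_ids, y_train, n_folds, split.seed)

    with _stage("scores"):
        table = compute_scores(X_train, y_train, **(score_options or {}))
    with _stage("threshold_grid"):
        grid = make_threshold_grid(table, n_thresholds)
    with _stage("cross_validation"):
        cv = cross_validate_threshold(X_train, y_train, grid, folds, score_options)
    theta = cv.optimal_threshold
    with _stage("final_fit"):
        selected = screen_features(table, theta)
        model = fit_pc(X_train.subset_features(selected), theta, outcome.outcome_type)
    with _stage("project"):
        test_pc = project(model, X_test)

    style = summary_style or ("continuous" if outcome.outcome_type == "continuous"
                              else "dichotomized")
    with _stage("summary"):
        summary, groups = association.summarize(y_test, test_pc, style,
                                                **(test_options or {}))

    run = SuperPCRun(model, cv, table, train_ids, test_ids, test_pc, groups,
                     summary, style)
    if out_dir is not None:
        write_run_outputs(run, Path(out_dir), make_plots=make_plots, outcome_test=y_test)
    return run


def write_cv_curve(cv: CVResult, full_scores: ScoreTable, path: str | Path) -> None:
    """cv_curve.tsv: threshold, #features kept on full training data, fold stats, mean."""
    a = np.abs(full_scores.score)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["threshold", "n_features"] + [f"fold_{f}" for f in range(1, cv.n_folds + 1)] + ["mean"]
        fh.write("\t".join(cols) + "\n")
        for t_idx, theta in enumerate(cv.thresholds):
            row = [_fmt(theta), str(int((a > theta).sum()))]
            row += [_fmt(v) for v in cv.statistics[:, t_idx]]
            row.append(_fmt(cv.statistics[:, t_idx].mean()))
            fh.write("\t".join(row) + "\n")


def write_run_outputs(run: SuperPCRun, out_dir: Path, make_plots: bool = True,
                      outcome_test: ClinicalOutcome | None = None) -> None:
    from . import association

    out_dir.mkdir(parents=True, exist_ok=True)
    write_scores(run.scores, out_dir / "scores.tsv")
    write_cv_curve(run.cv, run.scores, out_dir / "cv_curve.tsv")
    run.cv.fold_assignment.write(out_dir / "folds.tsv")
    run.model.to_json(out_dir / "model.json")
    with open(out_dir / "predictions.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpc_score\tgroup\n")
        groups = run.test_groups if run.test_groups is not None else [""] * len(run.test_ids)
        for s, z, g in zip(run.test_ids, run.test_pc_scores, groups):
            fh.write(f"{s}\t{_fmt(z)}\t{g}\n")
    run.summary.to_json(out_dir / "summary.json")
    if make_plots and outcome_test is not None:
        association.render_summary_plots(outcome_test, run.test_pc_scores,
                                         run.test_groups, run.summary,
                                         run.summary_style, out_dir)
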