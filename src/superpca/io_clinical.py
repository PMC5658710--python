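"""Tabular input/output for every artifact the pipeline touches.

All readers are strict: duplicate IDs, non-numeric cells, missing values and
sample mismatches raise :class:`ValidationError` naming the offending record.
Files are plain delimited text (tab for ``.tsv``/anything else, comma for
``.csv``), UTF-8, one header row, first column holding the IDs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("superpca")

OUTCOME_TYPES = ("survival", "continuous", "binary")


class ValidationError(ValueError):
    """An input table violated a structural or domain constraint."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _fmt(x: float) -> str:
    # repr round-trips doubles exactly, so written tables reload bit-identically
    return repr(float(x))


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} IDs: {', '.join(map(str, dups))}")


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of real-valued expression measures."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 1 or len(self.sample_ids) < 2:
            raise ValidationError("need at least 1 feature and 2 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def _sample_index(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in expression matrix: {', '.join(missing)}")
        return np.array([pos[s] for s in ids], dtype=int)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        idx = self._sample_index(ids)
        return ExpressionMatrix(list(self.feature_ids), list(ids), self.values[:, idx])

    def subset_features(self, ids) -> "ExpressionMatrix":
        pos = {f: k for k, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise ValidationError(f"features not in expression matrix: {', '.join(missing)}")
        idx = np.array([pos[f] for f in ids], dtype=int)
        return ExpressionMatrix(list(ids), list(self.sample_ids), self.values[idx, :])

    def write(self, path: str | Path) -> None:
        sep = _sep_for(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature_id" + sep + sep.join(self.sample_ids) + "\n")
            for i, fid in enumerate(self.feature_ids):
                fh.write(fid + sep + sep.join(_fmt(v) for v in self.values[i]) + "\n")


def read_expression(path: str | Path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Read a delimited expression table.

    ``orientation="samples_in_rows"`` transposes the table into the canonical
    features x samples layout.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False, na_values=[""])
    if orientation == "samples_in_rows":
        df = df.T
    _check_unique(list(df.index), "feature")
    _check_unique(list(df.columns), "sample")
    raw = df.to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(numeric))
    if bad.size:
        i, j = bad[0]
        cell = raw[i, j]
        kind = "missing value" if (cell is None or (isinstance(cell, float) and np.isnan(cell))) \
            else f"non-numeric value {cell!r}"
        raise ValidationError(
            f"{kind} at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), numeric)


# ---------------------------------------------------------------------------
# Clinical outcomes


@dataclass
class ClinicalOutcome:
    """Per-sample clinical outcome of one of three types.

    survival   -> ``time`` (strictly positive) and ``event`` (1 = observed)
    continuous -> ``value`` (finite real)
    binary     -> ``label`` in {0, 1}
    """

    outcome_type: str
    sample_ids: list[str]
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    value: np.ndarray | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise ValidationError(f"unknown outcome type {self.outcome_type!r}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.outcome_type == "survival":
            if self.time is None or self.event is None:
                raise ValidationError("survival outcome needs time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event)
            if self.time.shape != (n,) or self.event.shape != (n,):
                raise ValidationError("time/event length does not match sample_ids")
            if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
                bad = self.sample_ids[int(np.argmin(self.time > 0))]
                raise ValidationError(f"non-positive survival time for sample {bad!r}")
            self._check_indicator(self.event, "event")
            self.event = self.event.astype(int)
        elif self.outcome_type == "continuous":
            if self.value is None:
                raise ValidationError("continuous outcome needs a value column")
            self.value = np.asarray(self.value, dtype=float)
            if self.value.shape != (n,):
                raise ValidationError("value length does not match sample_ids")
            if not np.all(np.isfinite(self.value)):
                bad = self.sample_ids[int(np.argmax(~np.isfinite(self.value)))]
                raise ValidationError(f"non-finite outcome value for sample {bad!r}")
        else:
            if self.label is None:
                raise ValidationError("binary outcome needs a label column")
            self.label = np.asarray(self.label)
            if self.label.shape != (n,):
                raise ValidationError("label length does not match sample_ids")
            self._check_indicator(self.label, "label")
            self.label = self.label.astype(int)

    def _check_indicator(self, arr: np.ndarray, what: str) -> None:
        vals = np.asarray(arr, dtype=float)
        bad = ~np.isin(vals, (0.0, 1.0))
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValidationError(
                f"{what} must be 0 or 1; sample {self.sample_ids[k]!r} has {arr[k]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "ClinicalOutcome":
        """Return the outcome restricted (and reordered) to ``ids``."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in outcome table: {', '.join(missing)}")
        idx = np.array([pos[s] for s in ids], dtype=int)
        take = lambda a: None if a is None else a[idx]
        return ClinicalOutcome(self.outcome_type, list(ids), time=take(self.time),
                               event=take(self.event), value=take(self.value),
                               label=take(self.label))

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_ids}
        if self.outcome_type == "survival":
            cols["time"], cols["event"] = self.time, self.event
        elif self.outcome_type == "continuous":
            cols["value"] = self.value
        else:
            cols["label"] = self.label
        return pd.DataFrame(cols)

    def write(self, path: str | Path) -> None:
        sep = _sep_for(path)
        df = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(sep.join(df.columns) + "\n")
            for _, row in df.iterrows():
                out = [str(row["sample_id"])]
                for c in df.columns[1:]:
                    v = row[c]
                    out.append(_fmt(v) if c in ("time", "value") else str(int(v)))
                fh.write(sep.join(out) + "\n")


def read_outcome(path: str | Path, outcome_type: str,
                 sample_order: list[str] | None = None) -> ClinicalOutcome:
    """Read a clinical table; optionally align rows to ``sample_order`` by ID."""
    if outcome_type not in OUTCOME_TYPES:
        raise ValidationError(f"unknown outcome type {outcome_type!r}")
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValidationError("outcome table must have a 'sample_id' column")
    need = {"survival": ["time", "event"], "continuous": ["value"], "binary": ["label"]}[outcome_type]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"outcome table missing column(s): {', '.join(missing)}")
    ids = [str(s) for s in df["sample_id"]]
    kwargs = {c: df[c].to_numpy() for c in need}
    if outcome_type == "survival":
        out = ClinicalOutcome("survival", ids, time=kwargs["time"], event=kwargs["event"])
    elif outcome_type == "continuous":
        out = ClinicalOutcome("continuous", ids, value=kwargs["value"])
    else:
        out = ClinicalOutcome("binary", ids, label=kwargs["label"])
    if sample_order is not None:
        extra = sorted(set(ids) - set(sample_order))
        if extra:
            raise ValidationError(f"outcome samples not in expression data: {', '.join(extra)}")
        out = out.subset(sample_order)
    return out


def align_samples(expression: ExpressionMatrix, outcome: ClinicalOutcome,
                  allow_intersection: bool = False):
    """Return (expression, outcome) on a common sample set, outcome in matrix order.

    By default any mismatch between the two sample sets is an error; with
    ``allow_intersection=True`` the intersection is kept and dropped IDs logged.
    """
    e, o = set(expression.sample_ids), set(outcome.sample_ids)
    if e != o:
        if not allow_intersection:
            only_e = sorted(e - o)
            only_o = sorted(o - e)
            parts = []
            if only_e:
                parts.append(f"expression-only samples: {', '.join(only_e)}")
            if only_o:
                parts.append(f"outcome-only samples: {', '.join(only_o)}")
            raise ValidationError("sample sets differ (" + "; ".join(parts) + ")")
        keep = [s for s in expression.sample_ids if s in o]
        dropped = sorted((e | o) - (e & o))
        logger.warning("keeping %d common samples; dropped: %s", len(keep), ", ".join(dropped))
        expression = expression.subset_samples(keep)
    return expression, outcome.subset(expression.sample_ids)


# ---------------------------------------------------------------------------
# Fold assignments


@dataclass
class FoldAssignment:
    """Explicit sample -> fold map enabling exact replication of a CV run."""

    assignments: dict[str, int]
    n_folds: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("empty fold assignment")
        folds = sorted(set(self.assignments.values()))
        k = max(folds)
        if k < 2:
            raise ValidationError("need at least 2 folds")
        if folds != list(range(1, k + 1)):
            raise ValidationError(
                f"non-contiguous fold indices: found {folds}, expected 1..{k}"
            )
        self.n_folds = k

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def samples_in(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def write(self, path: str | Path) -> None:
        sep = _sep_for(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"sample_id{sep}fold\n")
            for s, f in self.assignments.items():
                fh.write(f"{s}{sep}{f}\n")


def read_fold_ids(path: str | Path, training_sample_ids: list[str] | None = None) -> FoldAssignment:
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"sample_id", "fold"}.issubset(df.columns):
        raise ValidationError("fold table must have columns sample_id, fold")
    ids = [str(s) for s in df["sample_id"]]
    _check_unique(ids, "sample")
    folds = df["fold"].to_numpy()
    if not np.all(folds == folds.astype(int)):
        raise ValidationError("fold indices must be integers")
    fa = FoldAssignment(dict(zip(ids, folds.astype(int).tolist())))
    if training_sample_ids is not None:
        missing = [s for s in training_sample_ids if s not in fa.assignments]
        if missing:
            raise ValidationError(f"fold file omits training sample(s): {', '.join(missing)}")
        extra = [s for s in fa.assignments if s not in set(training_sample_ids)]
        if extra:
            raise ValidationError(f"fold file has unknown sample(s): {', '.join(extra)}")
    return fa


# ---------------------------------------------------------------------------
# Forest-plot input


@dataclass
class ForestRow:
    """One row of a forest plot: a ratio-scale estimate with its CI."""

    label: str
    estimate: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        for name in ("estimate", "lower", "upper"):
            v = float(getattr(self, name))
            setattr(self, name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"row {self.label!r}: ratio-scale values must be positive ({name}={v})"
                )
        if not (self.lower <= self.estimate <= self.upper):
            raise ValidationError(
                f"row {self.label!r}: need lower <= estimate <= upper "
                f"(got {self.lower}, {self.estimate}, {self.upper})"
            )


def read_forest_table(path: str | Path) -> list[ForestRow]:
    df = pd.read_csv(path, sep=_sep_for(path))
    need = ["label", "estimate", "lower", "upper"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"forest table missing column(s): {', '.join(missing)}")
    return [ForestRow(str(r.label), r.estimate, r.lower, r.upper) for r in df.itertuples()]
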