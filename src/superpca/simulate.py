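"""Synthetic expression + outcome datasets with known signal structure.

A single latent factor u_i ~ N(0, 1) drives both a block of "signal" genes and
the clinical outcome:

* signal gene j:  x_ji = b_j u_i + eps,  b_j ~ Uniform(0.5, 1.5),  eps ~ N(0, 1)
* noise gene:     x_ji ~ N(0, 1), independent of u
* survival:       event time ~ Exponential with hazard exp(gamma * u_i);
                  independent Uniform(0, tau) censoring with tau calibrated so
                  the expected censoring fraction equals ``censor_rate``
* continuous:     y_i = gamma * u_i + N(0, 1)
* binary:         y_i ~ Bernoulli(logistic(gamma * u_i))

Everything is reproducible from the seed. The distributions are deliberately
the simplest members of their families; this is a test fixture generator, not
a model of real tumor expression data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_clinical import ClinicalOutcome, ExpressionMatrix, ValidationError

__all__ = ["SyntheticDataset", "simulate_dataset"]


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    expression: ExpressionMatrix
    outcome: ClinicalOutcome
    signal_feature_ids: list[str]
    latent: np.ndarray          # u, one value per sample
    effect: float               # gamma
    loadings: np.ndarray        # b_j for the signal genes

    def write_truth(self, path: str | Path) -> None:
        obj = {"signal_feature_ids": self.signal_feature_ids,
               "latent": self.latent.tolist(), "effect": self.effect,
               "loadings": self.loadings.tolist()}
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _calibrate_censoring(hazard: np.ndarray, censor_rate: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring hitting the target rate.

    With T ~ Exp(lambda_i) and C ~ U(0, tau), P(censored) averaged over
    samples is mean_i (1 - exp(-lambda_i tau)) / (lambda_i tau), monotone
    decreasing in tau; solve by bisection.
    """

    def frac(tau):
        lt = hazard * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt)) - censor_rate

    return brentq(frac, 1e-10, 1e12, xtol=1e-12, rtol=1e-12)


def simulate_dataset(outcome_type: str, n_samples: int, n_genes: int,
                     n_signal: int, effect: float, censor_rate: float = 0.3,
                     seed: int = 0) -> SyntheticDataset:
    """Generate one dataset; see the module docstring for the generative model."""
    if outcome_type not in ("survival", "continuous", "binary"):
        raise ValidationError(f"unknown outcome type {outcome_type!r}")
    if n_signal > n_genes:
        raise ValidationError("n_signal cannot exceed n_genes")
    if n_signal < 1 or n_genes < 1 or n_samples < 2:
        raise ValidationError("need n_samples >= 2, n_genes >= 1, n_signal >= 1")
    if effect < 0:
        raise ValidationError("effect must be non-negative")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_samples)
    b = rng.uniform(0.5, 1.5, size=n_signal)
    X = rng.standard_normal((n_genes, n_samples))
    X[:n_signal] += b[:, None] * u[None, :]

    width = max(4, len(str(n_genes)))
    feature_ids = [f"G{j + 1:0{width}d}" for j in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(feature_ids, sample_ids, X)

    if outcome_type == "survival":
        hazard = np.exp(effect * u)
        t_event = rng.exponential(1.0 / hazard)
        if censor_rate > 0:
            tau = _calibrate_censoring(hazard, censor_rate)
            c = rng.uniform(0.0, tau, size=n_samples)
            time = np.minimum(t_event, c)
            event = (t_event <= c).astype(int)
        else:
            time, event = t_event, np.ones(n_samples, dtype=int)
        time = np.maximum(time, 1e-12)  # guard against exact-zero draws
        outcome = ClinicalOutcome("survival", sample_ids, time=time, event=event)
    elif outcome_type == "continuous":
        y = effect * u + rng.standard_normal(n_samples)
        outcome = ClinicalOutcome("continuous", sample_ids, value=y)
    else:
        y = rng.binomial(1, expit(effect * u))
        outcome = ClinicalOutcome("binary", sample_ids, label=y)

    return SyntheticDataset(expr, outcome, feature_ids[:n_signal], u, float(effect), b)
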