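"""Forward evaluation of the yield model and observed-vs-predicted diagnostics.

A prediction evaluates the linear predictor

    eta = b0 + b_PRI * pri + b_SEC * sec + sum(matched indicator betas)

and returns Y = 10**eta, the C-mol yield.  Coefficients can come from a
fresh fit (:class:`~yeastyield.regress.FitResult`) or from a published
coefficient file; the two differ by rounding, which matters for
interpretation helpers such as :func:`step_loss`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .corpus import ProductionRecord
from .encoder import (CategoryProfile, INDICATOR_TERMS, ModelVariant,
                      build_design, profile_indicators)
from .exceptions import ConfigurationError, DomainError
from .regress import FitResult

__all__ = [
    "PredictionQuery",
    "YieldPrediction",
    "ParityStats",
    "linear_predictor",
    "term_contributions",
    "predict_yield",
    "fold_effect",
    "step_loss",
    "parity_stats",
]


@dataclass(frozen=True)
class PredictionQuery:
    """A user experiment: effective step counts + condition profile."""

    pri: float
    sec: float
    profile: CategoryProfile = field(default_factory=CategoryProfile)
    variant: ModelVariant = ModelVariant.MODEL1_WITH_PRI

    def __post_init__(self):
        if self.pri < 0 or self.sec < 0:
            raise DomainError("step counts must be >= 0")


@dataclass(frozen=True)
class YieldPrediction:
    """Predicted yield with its log-scale predictor and per-term breakdown."""

    yield_c: float
    log10_yield: float
    contributions: dict[str, float]
    extrapolated: bool  # True when the predicted yield exceeds 1


def _coefficients(coefficients) -> Mapping[str, float]:
    if isinstance(coefficients, FitResult):
        return coefficients.coefficients
    return coefficients


def term_contributions(query: PredictionQuery,
                       coefficients) -> dict[str, float]:
    """Per-term additive contributions to the log10-yield predictor."""
    coef = _coefficients(coefficients)
    required = list(query.variant.terms)
    missing = [t for t in required if t not in coef]
    if missing:
        raise ConfigurationError(
            f"coefficient set lacks required terms {missing} for "
            f"{query.variant.name}")
    contrib = {"Intercept": float(coef["Intercept"])}
    if query.variant.includes_pri:
        contrib["PRI"] = float(coef["PRI"]) * query.pri
    contrib["SEC"] = float(coef["SEC"]) * query.sec
    indicators = profile_indicators(query.profile)
    for term, x in zip(INDICATOR_TERMS, indicators):
        contrib[term] = float(coef[term]) * x
    return contrib


def linear_predictor(query: PredictionQuery, coefficients) -> float:
    """The log10-yield linear predictor for a query."""
    return float(sum(term_contributions(query, coefficients).values()))


def predict_yield(query: PredictionQuery, coefficients) -> YieldPrediction:
    """Predicted C-mol yield, 10 raised to the linear predictor.

    Predictions above 1 are physically impossible as carbon yields; they
    are returned with ``extrapolated=True`` rather than clamped, since
    clamping would hide that the query lies outside the model's support.
    """
    contrib = term_contributions(query, coefficients)
    eta = float(sum(contrib.values()))
    y = float(10.0 ** eta)
    return YieldPrediction(yield_c=y, log10_yield=eta, contributions=contrib,
                           extrapolated=y > 1.0)


def fold_effect(beta: float) -> float:
    """Multiplicative yield change for a one-unit predictor change: 10**beta."""
    if not np.isfinite(beta):
        raise DomainError(f"beta must be finite, got {beta}")
    return float(10.0 ** beta)


def step_loss(beta_sec: float) -> float:
    """Percent yield lost per added secondary-pathway step: (1 - 10**b) * 100."""
    if not np.isfinite(beta_sec):
        raise DomainError(f"beta_sec must be finite, got {beta_sec}")
    return float((1.0 - 10.0 ** beta_sec) * 100.0)


@dataclass
class ParityStats:
    """Observed-vs-predicted diagnostics on the log10 scale."""

    r_squared_log: float
    fraction_within_order: float
    residuals: np.ndarray


def parity_stats(records: Iterable[ProductionRecord],
                 fit: FitResult) -> ParityStats:
    """Residual diagnostics of a coefficient set on a corpus.

    Residual = observed log10 yield - predicted; ``fraction_within_order``
    counts records whose absolute log10 residual is at most 1 (the band is
    inclusive).  On the training corpus with a freshly fitted model,
    ``r_squared_log`` equals the fit's R-squared.
    """
    design, response = build_design(records, fit.variant)
    coef = fit.coefficients
    missing = [t for t in design.columns if t not in coef]
    if missing:
        raise ConfigurationError(
            f"coefficient set lacks terms {missing} for {fit.variant.name}")
    beta = np.array([coef[t] for t in design.columns], dtype=float)
    predicted = design.to_numpy(dtype=float) @ beta
    observed = response.to_numpy(dtype=float)
    resid = observed - predicted
    sst = float(((observed - observed.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else float("nan")
    frac = float(np.mean(np.abs(resid) <= 1.0))
    return ParityStats(r_squared_log=r2, fraction_within_order=frac,
                       residuals=resid)
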