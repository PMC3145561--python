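"""OLS fitting of the log-linear yield model and the three-model comparison.

The estimator is plain ordinary least squares on log10 yields with
classical (homoskedastic) standard errors, two-sided t-test p-values and
multiple R-squared about the mean — no weighting, robust errors or
multiple-testing correction.  A term is called significant at the 90%
level when its p-value is below 0.1.

Fitting is delegated to :mod:`statsmodels`; this module owns the variable
system, the variant bookkeeping, serialization of coefficient sets and
the side-by-side comparison table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import ProductionRecord
from .encoder import ModelVariant, build_design
from .exceptions import (ConfigurationError, DomainError,
                         InsufficientDataError, SingularDesignError)

__all__ = [
    "FitResult",
    "fit_ols",
    "fit_variant",
    "fit_all_variants",
    "significant_terms",
    "coefficient_table",
    "format_coefficient_table",
    "published_coefficients",
]

COEFFICIENT_FORMAT = "yeastyield-coefficients/1"


@dataclass
class FitResult:
    """Coefficients and frequentist inference for one model variant.

    ``residuals`` is ``None`` for coefficient sets loaded from a file
    (e.g. the published tables), which carry no per-record information.
    """

    variant: ModelVariant
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n_obs: int | None
    df_resid: int | None
    residuals: np.ndarray | None = None
    source: str = "fit"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "format": COEFFICIENT_FORMAT,
            "variant": self.variant.value,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "t_stats": self.t_stats,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "source": self.source,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        if d.get("format") != COEFFICIENT_FORMAT:
            raise ConfigurationError(
                f"unsupported coefficient file format {d.get('format')!r}")
        return cls(
            variant=ModelVariant.from_name(d["variant"]),
            coefficients=dict(d["coefficients"]),
            std_errors=dict(d.get("std_errors", {})),
            t_stats=dict(d.get("t_stats", {})),
            p_values=dict(d.get("p_values", {})),
            r_squared=float(d["r_squared"]),
            n_obs=d.get("n_obs"),
            df_resid=d.get("df_resid"),
            residuals=None,
            source=d.get("source", "file"),
        )

    @classmethod
    def load(cls, path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    X = design.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(X)
    _, R, piv = qr(X, pivoting=True, mode="economic")
    return sorted(design.columns[i] for i in piv[r:])


def fit_ols(design: pd.DataFrame, response,
            variant: ModelVariant | None = None) -> FitResult:
    """Fit OLS of the response on the design matrix.

    Standard errors come from the unbiased residual variance and the
    inverse Gram matrix; p-values are two-sided from the t distribution
    with ``n - p`` degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    n, p = design.shape
    if n <= p:
        raise InsufficientDataError(
            f"need more observations ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < p:
        raise SingularDesignError(_collinear_columns(design))
    res = sm.OLS(y, design).fit()
    terms = list(design.columns)
    return FitResult(
        variant=variant or _infer_variant(terms),
        coefficients={t: float(res.params[t]) for t in terms},
        std_errors={t: float(res.bse[t]) for t in terms},
        t_stats={t: float(res.tvalues[t]) for t in terms},
        p_values={t: float(res.pvalues[t]) for t in terms},
        r_squared=float(res.rsquared),
        n_obs=int(n),
        df_resid=int(n - p),
        residuals=np.asarray(res.resid, dtype=float),
    )


def _infer_variant(terms: Sequence[str]) -> ModelVariant:
    return (ModelVariant.MODEL1_WITH_PRI if "PRI" in terms
            else ModelVariant.MODEL2_NO_PRI)


def fit_variant(records: Iterable[ProductionRecord],
                variant: ModelVariant) -> FitResult:
    """Encode the corpus for one variant and fit it."""
    design, response = build_design(records, variant)
    return fit_ols(design, response, variant=variant)


def fit_all_variants(records: Iterable[ProductionRecord]) -> list[FitResult]:
    records = list(records)
    return [fit_variant(records, v) for v in ModelVariant]


def significant_terms(fit: FitResult, alpha: float = 0.1,
                      include_intercept: bool = False) -> list[str]:
    """Terms with p < alpha, excluding the intercept by default."""
    if not (0 < alpha < 1) and alpha != 1:
        raise DomainError(f"alpha must lie in (0, 1], got {alpha}")
    out = []
    for term, p in fit.p_values.items():
        if term == "Intercept" and not include_intercept:
            continue
        if p < alpha:
            out.append(term)
    return out


_ALL_TERMS = ("Intercept", "PRI", "SEC", "OVE_C2", "OVE_C3", "KNO_C2",
              "NUT_C2", "INT_C2", "CUL_C2", "OXY_C2")

_MODEL_LABELS = {
    ModelVariant.MODEL1_WITH_PRI: "Model 1",
    ModelVariant.MODEL2_NO_PRI: "Model 2",
    ModelVariant.MODEL3_ETHANOL_PRIMARY: "Model 3",
}


def coefficient_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Side-by-side comparison of fitted variants.

    One row per term plus a ``Multiple R^2`` row; one (coefficient,
    p_value, std_error) column triple per fit.  Terms a variant lacks
    (PRI in Model 2) are NaN.
    """
    if not fits:
        raise DomainError("need at least one fit")
    columns = {}
    for fit in fits:
        label = _MODEL_LABELS.get(fit.variant, fit.variant.value)
        coef, pv, se = {}, {}, {}
        for t in _ALL_TERMS:
            coef[t] = fit.coefficients.get(t, np.nan)
            pv[t] = fit.p_values.get(t, np.nan)
            se[t] = fit.std_errors.get(t, np.nan)
        coef["Multiple R^2"] = fit.r_squared
        pv["Multiple R^2"] = np.nan
        se["Multiple R^2"] = np.nan
        columns[(label, "coefficient")] = coef
        columns[(label, "p_value")] = pv
        columns[(label, "std_error")] = se
    table = pd.DataFrame(columns)
    table = table.loc[list(_ALL_TERMS) + ["Multiple R^2"]]
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["model", "statistic"])
    return table


def format_coefficient_table(table: pd.DataFrame,
                             table_compat: bool = True) -> str:
    """Render the comparison table as text.

    With ``table_compat`` p-values below 0.005 print as ``0.00`` (matching
    the published table's convention of printing tiny p-values as 0);
    full precision is retained in the DataFrame itself.
    """
    def fmt(value, stat):
        if pd.isna(value):
            return "-"
        if stat == "p_value" and table_compat and value < 0.005:
            return "0.00"
        return f"{value:.2f}"

    models = list(dict.fromkeys(c[0] for c in table.columns))
    header = ["Variable"] + [f"{m} {s}" for m in models
                             for s in ("coef", "p", "se")]
    lines = ["\t".join(header)]
    for term, row in table.iterrows():
        cells = [str(term)]
        for m in models:
            for stat in ("coefficient", "p_value", "std_error"):
                cells.append(fmt(row[(m, stat)], stat))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def published_coefficients(variant: ModelVariant) -> FitResult:
    """The published coefficient set for a variant (rounded, as printed)."""
    name = f"coefficients_{variant.value}.json"
    path = resources.files("yeastyield.data") / name
    return FitResult.from_dict(json.loads(path.read_text()))
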