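"""Synthetic production corpora and parameter-recovery experiments.

The generator draws covariates (condition categories and step counts)
from configurable discrete distributions — by default the empirical
frequencies of the packaged training corpus, stored once as a data
artifact — and produces log10 yields as

    log10 Y = linear predictor + Normal(0, noise_sd)

i.e. Gaussian noise in log10 space, the minimal error model consistent
with OLS on log yields.  Records whose sampled yield would exceed 1
(impossible for a C-mol yield) are resampled rather than truncated, which
keeps the conditional mean structure clean; resample counts are reported.

Recovery experiments repeat generate -> fit and summarize per-term bias,
RMSE and the empirical coverage of nominal 90% t-intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy import stats

from .corpus import ProductionRecord
from .encoder import INDICATOR_TERMS, ModelVariant
from .exceptions import ConfigurationError
from .regress import FitResult, fit_variant

__all__ = [
    "CovariateModel",
    "SyntheticConfig",
    "RecoveryReport",
    "default_covariate_model",
    "calibrated_noise_sd",
    "default_config",
    "generate_corpus",
    "recovery_experiment",
]


def _load_artifact() -> dict:
    path = resources.files("yeastyield.data") / "covariate_frequencies.json"
    return json.loads(path.read_text())


@dataclass(frozen=True)
class CovariateModel:
    """Sampling distributions for the model covariates.

    ``ove_freqs`` maps levels C1/C2/C3 to probabilities; ``binary_freqs``
    maps KNO/NUT/INT/CUL/OXY to the probability of level C2; ``pri_dist``
    and ``sec_dist`` map step-count values to (unnormalized) weights.
    """

    ove_freqs: Mapping[str, float]
    binary_freqs: Mapping[str, float]
    pri_dist: Mapping[float, float]
    sec_dist: Mapping[float, float]

    def __post_init__(self):
        total = sum(self.ove_freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError(
                f"OVE frequencies must sum to 1, got {total}")
        for name, p in self.binary_freqs.items():
            if not (0 <= p <= 1):
                raise ConfigurationError(f"frequency for {name} not in [0,1]")
        for name, dist in (("pri_dist", self.pri_dist),
                           ("sec_dist", self.sec_dist)):
            if not dist or sum(dist.values()) <= 0:
                raise ConfigurationError(f"{name} has no probability mass")


def default_covariate_model() -> CovariateModel:
    """Covariate model measured from the packaged corpus (stored artifact)."""
    art = _load_artifact()
    return CovariateModel(
        ove_freqs={k: float(v) for k, v in art["ove_freqs"].items()},
        binary_freqs={k: float(v) for k, v in art["binary_freqs"].items()},
        pri_dist={float(k): float(v) for k, v in art["pri_dist"].items()},
        sec_dist={float(k): float(v) for k, v in art["sec_dist"].items()},
    )


def calibrated_noise_sd() -> float:
    """Residual SD of the full model on the packaged corpus (stored artifact)."""
    return float(_load_artifact()["calibrated_noise_sd"])


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and sampling plan for a synthetic corpus."""

    true_coefficients: Mapping[str, float]
    noise_sd: float
    n_records: int
    covariate_model: CovariateModel
    seed: int

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        required = {"Intercept", "SEC", *INDICATOR_TERMS}
        missing = required - set(self.true_coefficients)
        if missing:
            raise ConfigurationError(
                f"true_coefficients lacks terms {sorted(missing)}")
        n_terms = len(self.true_coefficients)
        if self.n_records < n_terms + 1:
            raise ConfigurationError(
                f"n_records must be >= number of terms + 1 ({n_terms + 1})")

    @property
    def variant(self) -> ModelVariant:
        return (ModelVariant.MODEL1_WITH_PRI
                if "PRI" in self.true_coefficients
                else ModelVariant.MODEL2_NO_PRI)


def default_config(seed: int, n_records: int = 126,
                   noise_sd: float | None = None) -> SyntheticConfig:
    """Study-condition defaults: published full-model coefficients as the
    ground truth, corpus-calibrated noise, corpus-sized sample."""
    from .regress import published_coefficients

    pub = published_coefficients(ModelVariant.MODEL1_WITH_PRI)
    return SyntheticConfig(
        true_coefficients=dict(pub.coefficients),
        noise_sd=calibrated_noise_sd() if noise_sd is None else noise_sd,
        n_records=n_records,
        covariate_model=default_covariate_model(),
        seed=seed,
    )


def _draw_discrete(rng: np.random.Generator, dist: Mapping[float, float]):
    values = np.array(sorted(dist), dtype=float)
    weights = np.array([dist[v] for v in values], dtype=float)
    return float(rng.choice(values, p=weights / weights.sum()))


def generate_corpus(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[ProductionRecord], int]:
    """Draw a synthetic corpus; returns (records, n_resampled).

    ``n_resampled`` counts draws discarded because the sampled yield
    exceeded 1.  Records are written in the raw-corpus schema (category
    levels, separate intermediate-side counts) so they flow through the
    standard pipeline and always pass corpus validation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cm = config.covariate_model
    coef = config.true_coefficients
    records: list[ProductionRecord] = []
    resampled = 0
    ove_levels = sorted(cm.ove_freqs)
    ove_p = np.array([cm.ove_freqs[k] for k in ove_levels], dtype=float)
    ove_p = ove_p / ove_p.sum()
    i = 0
    while len(records) < config.n_records:
        ove = str(rng.choice(ove_levels, p=ove_p))
        levels = {name: ("C2" if rng.random() < cm.binary_freqs[name] else "C1")
                  for name in ("KNO", "NUT", "INT", "CUL", "OXY")}
        pri_sub = _draw_discrete(rng, cm.pri_dist)
        sec_sub = _draw_discrete(rng, cm.sec_dist)
        if levels["INT"] == "C2":
            # intermediate feeding shortcuts the pathway: the
            # intermediate-side count is a uniform draw below the
            # substrate-side count
            pri_int = float(rng.integers(0, int(pri_sub) + 1))
            sec_int = float(rng.integers(0, int(sec_sub) + 1))
            pri_eff = (pri_sub + pri_int) / 2.0
            sec_eff = (sec_sub + sec_int) / 2.0
        else:
            pri_int = sec_int = None
            pri_eff, sec_eff = pri_sub, sec_sub
        eta = (coef["Intercept"]
               + coef.get("PRI", 0.0) * pri_eff
               + coef["SEC"] * sec_eff
               + coef["OVE_C2"] * (ove == "C2")
               + coef["OVE_C3"] * (ove == "C3")
               + sum(coef[f"{name}_C2"] * (levels[name] == "C2")
                     for name in ("KNO", "NUT", "INT", "CUL", "OXY")))
        log_y = eta + (rng.normal(0.0, config.noise_sd)
                       if config.noise_sd > 0 else 0.0)
        y = 10.0 ** log_y
        if y > 1.0:
            resampled += 1
            continue
        i += 1
        records.append(ProductionRecord(
            reference_id="SIM",
            product=f"synthetic-{i:04d}",
            yield_c=y,
            pri_substrate=pri_sub,
            sec_substrate=sec_sub,
            pri_intermediate=pri_int,
            sec_intermediate=sec_int,
            ove=ove,
            kno=levels["KNO"], nut=levels["NUT"], int_add=levels["INT"],
            cul=levels["CUL"], oxy=levels["OXY"],
        ))
    return records, resampled


@dataclass
class RecoveryReport:
    """Summary of a repeated generate -> fit experiment."""

    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]  # empirical coverage of nominal 90% intervals
    replications: int
    resampled_yields: int       # draws discarded for exceeding yield 1
    resampled_designs: int      # replications redrawn for rank deficiency


def recovery_experiment(config: SyntheticConfig,
                        replications: int,
                        ci_level: float = 0.90) -> RecoveryReport:
    """Repeat generate -> fit and measure estimator quality per term.

    Child seeds are spawned deterministically from ``config.seed``.  A
    replication whose design happens to be rank deficient (possible at
    tiny n) is redrawn and counted.
    """
    if replications < 2:
        raise ConfigurationError("need at least 2 replications")
    terms = list(config.true_coefficients)
    truth = np.array([config.true_coefficients[t] for t in terms])
    estimates = np.empty((replications, len(terms)))
    covered = np.zeros((replications, len(terms)), dtype=bool)
    ss = np.random.SeedSequence(config.seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(replications)]
    resampled_yields = 0
    resampled_designs = 0
    for r, rng in enumerate(child_rngs):
        while True:
            records, n_res = generate_corpus(config, rng=rng)
            resampled_yields += n_res
            try:
                fit = fit_variant(records, config.variant)
            except Exception:
                resampled_designs += 1
                continue
            break
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, fit.df_resid)
        for j, t in enumerate(terms):
            b, se = fit.coefficients[t], fit.std_errors[t]
            estimates[r, j] = b
            covered[r, j] = abs(b - truth[j]) <= tcrit * se
    bias = estimates.mean(axis=0) - truth
    rmse = np.sqrt(((estimates - truth) ** 2).mean(axis=0))
    coverage = covered.mean(axis=0)
    return RecoveryReport(
        bias={t: float(b) for t, b in zip(terms, bias)},
        rmse={t: float(v) for t, v in zip(terms, rmse)},
        coverage={t: float(c) for t, c in zip(terms, coverage)},
        replications=replications,
        resampled_yields=resampled_yields,
        resampled_designs=resampled_designs,
    )
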