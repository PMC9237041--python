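"""Synthetic survey generator with a known decanalization signal.

The generator emulates a national risk-factor survey table: one row per adult
respondent with fasting capillary glycemia (mg/dL), age, sex and a battery of
ordinal/continuous socioeconomic and lifestyle covariates.  Ground truth is a
one-dimensional latent disadvantage axis ``d ~ Normal(0, 1)`` that

* drives every covariate through a loading (ordinal covariates are produced by
  thresholding ``loading * d + noise`` at empirical quantiles; household income
  is lognormal with log-location decreasing in ``d``), and
* drives the *variance* of glycemia: the residual standard deviation of
  individual ``i`` is ``sigma_i = sigma0 * exp(gamma * d_i)``.

``gamma = 0`` therefore yields a perfectly homoskedastic (canalized)
population, while ``gamma > 0`` concentrates extreme glycemia values among
the disadvantaged — the decanalization effect every downstream stage is meant
to recover.  The mean structure is a plain linear age trend,
``beta0 + beta1 * age``, with age drawn independently of ``d`` so that
age-residualization and socioeconomic effects remain separable.

Randomness is driven by a single master seed through a fixed
``numpy.random.SeedSequence`` spawning order (latent axis, age, sex, one
stream per covariate, glycemia noise, missingness), so sub-draws are
individually reproducible and identical seeds give bitwise-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_covariate_specs",
    "simulate_survey",
    "truth_variance_profile",
    "write_survey",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One generated covariate.

    kind
        ``"ordinal"``: threshold ``loading*d + noise`` at the empirical
        quantiles implied by ``level_probs`` into codes ``1..n_levels``.
        ``"continuous"``: standardize ``loading*d + noise`` then rescale to
        ``mean``/``sd`` and clip to ``[lower, upper]``.
        ``"income"``: lognormal, ``log(income) = mean + loading*d + noise``
        (``mean``/``sd`` interpreted on the log scale; ``sd`` unused).
    loading
        Weight of the latent disadvantage axis; its sign sets the direction of
        the covariate's association with disadvantage.
    """

    name: str
    loading: float
    noise_sd: float = 1.0
    kind: str = "ordinal"
    n_levels: int | None = None
    level_probs: tuple[float, ...] | None = None
    mean: float = 0.0
    sd: float = 1.0
    lower: float | None = None
    upper: float | None = None

    def validate(self) -> None:
        if self.kind not in ("ordinal", "continuous", "income"):
            raise ConfigError(f"covariate_specs[{self.name}].kind: unknown kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"covariate_specs[{self.name}].noise_sd: must be >= 0")
        if self.kind == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise ConfigError(f"covariate_specs[{self.name}].n_levels: must be >= 2")
            if self.level_probs is not None:
                if len(self.level_probs) != self.n_levels:
                    raise ConfigError(
                        f"covariate_specs[{self.name}].level_probs: length must equal n_levels"
                    )
                if any(p <= 0 for p in self.level_probs):
                    raise ConfigError(
                        f"covariate_specs[{self.name}].level_probs: probabilities must be > 0"
                    )


def default_covariate_specs() -> tuple[CovariateSpec, ...]:
    """Covariate battery emulating the 2018 survey's explanatory variables.

    Marginal level shares and continuous means/SDs follow the survey's
    published summary table; loadings encode the reported component
    structure: education and income load strongly (negatively) on
    disadvantage, working time moderately, household density and utilities
    moderately, and lifestyle covariates (physical activity, sedentarism,
    diet, salt, alcohol) only weakly.
    """
    return (
        CovariateSpec("edu_interviewee", loading=-0.8, noise_sd=0.6, n_levels=3,
                      level_probs=(0.0841, 0.3390, 0.5769)),
        CovariateSpec("edu_head", loading=-0.8, noise_sd=0.6, n_levels=3,
                      level_probs=(0.0928, 0.3536, 0.5536)),
        CovariateSpec("income", kind="income", loading=-0.55, noise_sd=0.42, mean=9.82),
        CovariateSpec("working_hours", loading=-0.5, noise_sd=0.9, n_levels=4,
                      level_probs=(0.385, 0.222, 0.231, 0.162)),
        CovariateSpec("density", kind="continuous", loading=0.45, noise_sd=0.9,
                      mean=1.00, sd=0.70, lower=0.05),
        CovariateSpec("utilities", kind="continuous", loading=-0.45, noise_sd=0.9,
                      mean=0.64, sd=0.17, lower=0.0, upper=1.0),
        CovariateSpec("physical_activity", loading=-0.15, noise_sd=1.0, n_levels=3,
                      level_probs=(0.462, 0.368, 0.170)),
        CovariateSpec("sedentarism", kind="continuous", loading=0.10, noise_sd=1.0,
                      mean=261.4, sd=174.0, lower=0.0),
        CovariateSpec("fruit_veg", kind="continuous", loading=-0.15, noise_sd=1.0,
                      mean=2.03, sd=1.62, lower=0.0),
        CovariateSpec("salt", loading=0.10, noise_sd=1.0, n_levels=4,
                      level_probs=(0.216, 0.508, 0.174, 0.102)),
        CovariateSpec("alcohol", loading=0.10, noise_sd=1.0, n_levels=3,
                      level_probs=(0.829, 0.132, 0.038)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic survey draw.

    Units: ``beta0`` mg/dL, ``beta1`` mg/dL per year, ``sigma0`` mg/dL
    (baseline residual SD), ``gamma`` log-SD per unit latent disadvantage.
    """

    n_individuals: int = 4000
    age_low: float = 18.0
    age_high: float = 82.0
    beta0: float = 77.0
    beta1: float = 0.4
    sigma0: float = 15.0
    gamma: float = 0.3
    covariate_specs: tuple[CovariateSpec, ...] = field(default_factory=default_covariate_specs)
    sex_prob: float = 0.4155  # P(male), coded 1=male 2=female
    missing_rate: float = 0.0
    age_disadvantage_corr: float = 0.0  # optional coupling of age to the latent axis
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals: must be > 0")
        if not self.age_low < self.age_high:
            raise ConfigError("age_low: must satisfy age_low < age_high")
        if self.sigma0 <= 0:
            raise ConfigError("sigma0: must be > 0")
        if not 0.0 <= self.sex_prob <= 1.0:
            raise ConfigError("sex_prob: must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate: must lie in [0, 1]")
        if not -1.0 <= self.age_disadvantage_corr <= 1.0:
            raise ConfigError("age_disadvantage_corr: must lie in [-1, 1]")
        names = [s.name for s in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ConfigError("covariate_specs: duplicate covariate names")
        for s in self.covariate_specs:
            s.validate()


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a simulated table: the quantities estimators chase."""

    d: np.ndarray       # latent disadvantage, standard-normal scale
    sigma: np.ndarray   # true residual SD per individual, mg/dL
    config: SimulationConfig

    def __post_init__(self) -> None:
        if len(self.d) != len(self.sigma):
            raise InputError("GroundTruth: d and sigma must have equal length")


def _ordinal_codes(z: np.ndarray, spec: CovariateSpec) -> np.ndarray:
    """Threshold a latent score at its empirical quantiles into codes 1..K."""
    probs = spec.level_probs or tuple(1.0 / spec.n_levels for _ in range(spec.n_levels))
    cum = np.cumsum(probs)[:-1] / sum(probs)
    cuts = np.quantile(z, cum)
    return (np.searchsorted(cuts, z, side="left") + 1).astype(np.int64)


def simulate_survey(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one survey table and its ground truth.

    Returns a DataFrame with columns ``glycemia``, ``age``, ``sex`` and one
    column per covariate spec, plus a :class:`GroundTruth` carrying the latent
    disadvantage and the true per-individual residual SD.
    """
    config.validate()
    n = config.n_individuals
    master = np.random.SeedSequence(config.seed)
    n_streams = 5 + len(config.covariate_specs)
    children = master.spawn(n_streams)
    rng_latent = np.random.default_rng(children[0])
    rng_age = np.random.default_rng(children[1])
    rng_sex = np.random.default_rng(children[2])
    cov_rngs = [np.random.default_rng(c) for c in children[3:3 + len(config.covariate_specs)]]
    rng_gly = np.random.default_rng(children[-2])
    rng_miss = np.random.default_rng(children[-1])

    d = rng_latent.standard_normal(n)
    age = rng_age.uniform(config.age_low, config.age_high, n)
    if config.age_disadvantage_corr:
        # rank-free Gaussian coupling: replace the uniform with a Gaussian
        # copula mix of d and an independent normal, mapped back to the range
        rho = config.age_disadvantage_corr
        z = rho * d + math.sqrt(1 - rho * rho) * rng_age.standard_normal(n)
        from scipy.stats import norm
        age = config.age_low + (config.age_high - config.age_low) * norm.cdf(z)
    sex = np.where(rng_sex.random(n) < config.sex_prob, 1, 2).astype(np.int64)

    cols: dict[str, np.ndarray] = {}
    for spec, rng in zip(config.covariate_specs, cov_rngs):
        z = spec.loading * d + spec.noise_sd * rng.standard_normal(n)
        if spec.kind == "ordinal":
            cols[spec.name] = _ordinal_codes(z, spec)
        elif spec.kind == "income":
            cols[spec.name] = np.exp(spec.mean + z)
        else:
            scale = math.hypot(spec.loading, spec.noise_sd)
            x = spec.mean + spec.sd * (z / scale if scale > 0 else z)
            lo = -np.inf if spec.lower is None else spec.lower
            hi = np.inf if spec.upper is None else spec.upper
            cols[spec.name] = np.clip(x, lo, hi)

    sigma = config.sigma0 * np.exp(config.gamma * d)
    glycemia = config.beta0 + config.beta1 * age + sigma * rng_gly.standard_normal(n)

    table = pd.DataFrame({"glycemia": glycemia, "age": age, "sex": sex, **cols})
    if config.missing_rate > 0:
        mask = rng_miss.random(table.shape) < config.missing_rate
        table = table.astype({c: "float64" for c in table.columns})
        table[pd.DataFrame(mask, index=table.index, columns=table.columns)] = np.nan
    return table, GroundTruth(d=d, sigma=sigma, config=config)


def truth_variance_profile(truth: GroundTruth, order) -> np.ndarray:
    """Re-index the true per-individual SD to an externally supplied ordering.

    Pure re-indexing: ``order`` is an integer permutation/selection aligned to
    whatever row order downstream estimates use (e.g. after sorting by an
    estimated component score).
    """
    order = np.asarray(order)
    if order.shape[0] != len(truth.sigma):
        raise InputError(
            f"truth_variance_profile: ordering length {order.shape[0]} != "
            f"number of individuals {len(truth.sigma)}"
        )
    return truth.sigma[order]


def write_survey(table: pd.DataFrame, path, truth: GroundTruth | None = None) -> None:
    """Write a survey table as CSV (empty cells for missing values).

    If ground truth is supplied, a ``<stem>.truth.csv`` sidecar with the latent
    disadvantage and true SD is written in the same dialect.
    """
    from pathlib import Path

    path = Path(path)
    table.to_csv(path, index=False)
    if truth is not None:
        sidecar = path.with_suffix(".truth.csv")
        pd.DataFrame({"d": truth.d, "sigma": truth.sigma}).to_csv(sidecar, index=False)
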