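"""Register-style synthetic cohort generation.

The study data this package is designed around — a Finnish total-population
register cohort of children diagnosed with type 1 diabetes (T1D) at school
ages plus matched population controls — are confidential and cannot be
redistributed.  This module therefore generates *synthetic* cohorts that
emulate the published design and descriptive margins:

* 38 baseline covariates (individual, parent, household and postcode level)
  measured the year the child turns 6, with cross-correlations induced by a
  single latent family socioeconomic-status (SES) factor;
* exact-count treatment (T1D) assignment by exponentially tilted sampling,
  reproducing the published mild covariate imbalances (hospital visits,
  household diabetes, sibling count, sex);
* six adult outcomes at ages 28-30: death by 30, antidepressant purchase,
  continuous singlehood, basic-education-only, annualized unemployment
  months, and annual income (rounded to hundreds and top-coded).  All
  non-mortality outcomes are observed only for survivors, and the
  antidepressant and income outcomes are censored for the 1990 birth cohort
  (register follow-up ends before their outcome window closes);
* configurable ground-truth effect heterogeneity injected on the
  probability/level scale: by default a sex-modified antidepressant effect
  and a family-SES-modified partnership effect, the two patterns the design
  is meant to detect.

Intercepts and average effect sizes are *calibrated* so that the implied
group means of a default-size matched design (3048 treated, ~79k matched
controls) equal the published descriptive values; see :func:`calibrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from .config import config_hash, logger

__all__ = [
    "ConfigError",
    "CovariateSpec",
    "OutcomeModel",
    "DGPConfig",
    "COVARIATE_ORDER",
    "OUTCOME_NAMES",
    "EXCLUSION_ORDER",
    "default_config",
    "calibrate",
    "generate_covariates",
    "assign_treatment",
    "generate_outcomes",
    "generate_cohort",
    "true_cate",
    "calibration_report",
    "ses_index",
    "model_feature",
    "write_cohort",
    "read_cohort",
]


class ConfigError(ValueError):
    """Raised when a configuration references unknown covariates or is invalid."""


# ---------------------------------------------------------------------------
# covariate specification
# ---------------------------------------------------------------------------

#: the 38 baseline covariates, in fixed column order
COVARIATE_ORDER = [
    "female",
    "finnish_language",
    "child_hospital_visits",
    "mother_age",
    "mother_education",
    "mother_education_health",
    "mother_employed",
    "mother_hospital_visits",
    "mother_married",
    "father_age",
    "father_education",
    "father_education_health",
    "father_employed",
    "father_hospital_visits",
    "parent_missing",
    "household_diabetes",
    "n_children",
    "household_size",
    "single_parent",
    "household_assets",
    "household_debts",
    "social_assistance",
    "childcare_allowance",
    "unemployment_benefits",
    "household_earnings",
    "business_income",
    "pension_income",
    "social_insurance_benefits",
    "overcrowded",
    "housing_flat",
    "homeowner",
    "postcode_foreign_share",
    "postcode_unemployed_share",
    "postcode_low_education_share",
    "postcode_swedish_share",
    "remoteness",
    "birth_year",
    "region_code",
]

OUTCOME_NAMES = [
    "died_by_30",
    "antidepressant_use",
    "no_partnership",
    "basic_education_only",
    "unemployment_months_annualized",
    "income_annual",
]

#: exclusion reasons, in the precedence order they are counted
EXCLUSION_ORDER = [
    "diagnosis_before_7",
    "missing_covariates",
    "death_before_18",
    "emigration_before_18",
]

#: 17 region population shares (largest region ~30%, roughly Finland-shaped)
REGION_PROBS = (
    0.300, 0.085, 0.040, 0.031, 0.092, 0.036, 0.031, 0.023, 0.026,
    0.045, 0.030, 0.049, 0.035, 0.032, 0.013, 0.074, 0.058,
)


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate plus its latent-SES loading.

    ``kind`` is one of ``bernoulli`` (params: p), ``poisson`` (rate, shift),
    ``normal`` (mean, sd, lo, hi), ``ordinal`` (probs, 1-based codes),
    ``lognormal`` (mean_log, sd_log, zero_p), ``share`` (logistic-normal on
    (0,1): a, noise), ``categorical`` (probs), ``uniform_int`` (lo, hi) and
    ``derived`` (computed from other columns).  Loadings act on a shared
    standard-normal factor ``Z`` (positive loading = higher value in
    higher-SES families); marginal means are preserved exactly for
    bernoulli/poisson/normal/ordinal kinds.
    """

    kind: str
    params: dict = field(default_factory=dict)
    loading: float = 0.0


def _default_covariate_spec() -> dict[str, CovariateSpec]:
    B, P, N, O, L, S = "bernoulli", "poisson", "normal", "ordinal", "lognormal", "share"
    return {
        "female": CovariateSpec(B, {"p": 0.49}),
        "finnish_language": CovariateSpec(B, {"p": 0.94}),
        "child_hospital_visits": CovariateSpec(P, {"rate": 0.51}, -0.10),
        "mother_age": CovariateSpec(N, {"mean": 34.0, "sd": 4.6, "lo": 20, "hi": 55}, 1.8),
        "mother_education": CovariateSpec(O, {"probs": (0.08, 0.18, 0.34, 0.25, 0.15)}, 0.65),
        "mother_education_health": CovariateSpec(B, {"p": 0.12}, 0.10),
        "mother_employed": CovariateSpec(B, {"p": 0.71}, 0.55),
        "mother_hospital_visits": CovariateSpec(P, {"rate": 0.30}, -0.05),
        "mother_married": CovariateSpec(B, {"p": 0.78}, 0.45),
        "father_age": CovariateSpec(N, {"mean": 36.0, "sd": 5.2, "lo": 20, "hi": 60}, 1.8),
        "father_education": CovariateSpec(O, {"probs": (0.10, 0.20, 0.34, 0.22, 0.14)}, 0.65),
        "father_education_health": CovariateSpec(B, {"p": 0.03}, 0.05),
        "father_employed": CovariateSpec(B, {"p": 0.84}, 0.60),
        "father_hospital_visits": CovariateSpec(P, {"rate": 0.25}, -0.05),
        "parent_missing": CovariateSpec(B, {"p": 0.04}, -0.35),
        "household_diabetes": CovariateSpec(B, {"p": 0.05}),
        "n_children": CovariateSpec(P, {"rate": 1.6, "shift": 1}, 0.03),
        "household_size": CovariateSpec("derived"),
        "single_parent": CovariateSpec(B, {"p": 0.11}, -0.50),
        "household_assets": CovariateSpec(L, {"mean_log": 9.806, "sd_log": 0.8, "zero_p": 0.25}, 0.50),
        "household_debts": CovariateSpec(L, {"mean_log": 9.70, "sd_log": 0.9, "zero_p": 0.40}, 0.20),
        "social_assistance": CovariateSpec(B, {"p": 0.11}, -1.00),
        "childcare_allowance": CovariateSpec(B, {"p": 0.35}, -0.20),
        "unemployment_benefits": CovariateSpec(B, {"p": 0.20}, -0.80),
        "household_earnings": CovariateSpec(L, {"mean_log": 9.951, "sd_log": 0.50, "zero_p": 0.0}, 0.45),
        "business_income": CovariateSpec(L, {"mean_log": 9.0, "sd_log": 1.0, "zero_p": 0.88}, 0.10),
        "pension_income": CovariateSpec(B, {"p": 0.08}, -0.30),
        "social_insurance_benefits": CovariateSpec(B, {"p": 0.30}, -0.10),
        "overcrowded": CovariateSpec(B, {"p": 0.15}, -0.60),
        "housing_flat": CovariateSpec(B, {"p": 0.35}, -0.40),
        "homeowner": CovariateSpec(B, {"p": 0.76}, 0.70),
        "postcode_foreign_share": CovariateSpec(S, {"a": -3.4, "noise": 0.45}, 0.05),
        "postcode_unemployed_share": CovariateSpec(S, {"a": -2.0, "noise": 0.35}, -0.25),
        "postcode_low_education_share": CovariateSpec(S, {"a": -0.4, "noise": 0.35}, -0.30),
        "postcode_swedish_share": CovariateSpec(S, {"a": -4.0, "noise": 1.2}),
        "remoteness": CovariateSpec(O, {"probs": (0.38, 0.17, 0.12, 0.10, 0.09, 0.08, 0.06)}, -0.25),
        "birth_year": CovariateSpec("uniform_int", {"lo": 1981, "hi": 1990}),
        "region_code": CovariateSpec("categorical", {"probs": REGION_PROBS}),
    }


# ---------------------------------------------------------------------------
# outcome models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeModel:
    """One outcome's data-generating model.

    ``kind`` is ``binary`` (probability = sigmoid baseline + additive
    treatment effect on the probability scale), ``months_zibeta``
    (zero-inflated scaled Beta on [0, 12]; treatment shifts the positive-
    occupancy probability so the effect is additive in expected months) or
    ``income_lognormal`` (log-normal level; treatment scales the level by
    ``1 + effect_base`` before rounding/top-coding).

    ``control_mean`` / ``treated_mean`` are the calibration targets for the
    matched design; ``intercept`` and ``effect_base`` are solved by
    :func:`calibrate` so the implied group means equal those targets.
    ``effect_mods`` are additive interaction terms of the treatment effect
    with model features (e.g. ``{"female": 0.06}`` adds 6 probability
    points to the effect for women), the configurable ground-truth
    heterogeneity.
    """

    kind: str
    control_mean: float
    treated_mean: float
    coefs: dict[str, float] = field(default_factory=dict)
    effect_mods: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    effect_base: float | None = None
    beta_a: float = 0.9
    beta_b: float = 2.1
    sigma_log: float = 0.55


def _default_outcome_models() -> dict[str, OutcomeModel]:
    return {
        "died_by_30": OutcomeModel(
            "binary", control_mean=0.009, treated_mean=0.023,
            coefs={"ses_index": -0.35, "female": -0.50},
        ),
        "antidepressant_use": OutcomeModel(
            "binary", control_mean=0.131, treated_mean=0.171,
            coefs={"ses_index": -0.15, "female": 0.55, "cohort_c": 0.02},
            effect_mods={"female": 0.06},
        ),
        "no_partnership": OutcomeModel(
            "binary", control_mean=0.318, treated_mean=0.358,
            coefs={"ses_index": -0.10, "female": -0.10},
            effect_mods={"ses_index": -0.02},
        ),
        "basic_education_only": OutcomeModel(
            "binary", control_mean=0.103, treated_mean=0.108,
            coefs={"ses_index": -0.80},
        ),
        "unemployment_months_annualized": OutcomeModel(
            "months_zibeta", control_mean=1.02, treated_mean=1.18,
            coefs={"ses_index": -0.50},
        ),
        "income_annual": OutcomeModel(
            "income_lognormal", control_mean=27453.0, treated_mean=25697.0,
            coefs={"ses_index": 0.30, "female": -0.12},
        ),
    }


@dataclass(frozen=True)
class DGPConfig:
    """Full configuration of the synthetic register cohort generator."""

    n_treated: int = 3048
    # large enough that nearly every stratum saturates its 26-per-case cap,
    # emulating a ~21:1 source-population-to-matched ratio: the matched
    # control count then lands at ~79k as in the design being emulated
    n_control_pool: int = 180_000
    seed: int = 0
    covariate_spec: dict[str, CovariateSpec] = field(default_factory=_default_covariate_spec)
    treatment_model: dict[str, float] = field(default_factory=lambda: {
        "female": -0.24,
        "child_hospital_visits": 0.20,
        "household_diabetes": 0.55,
        "n_children": 0.06,
        "birth_year": 0.035,
    })
    outcome_models: dict[str, OutcomeModel] = field(default_factory=_default_outcome_models)
    income_topcode: float = 150_000.0
    income_rounding: float = 100.0
    censor_cohorts: frozenset = frozenset({1990})
    exclusion_rates: dict[str, float] = field(default_factory=lambda: {
        "diagnosis_before_7": 0.0025,
        "missing_covariates": 0.008,
        "death_before_18": 0.002,
        "emigration_before_18": 0.0115,
    })
    max_controls_per_case: int = 26

    def validate(self) -> None:
        if self.n_treated < 1:
            raise ConfigError("n_treated must be >= 1")
        if self.n_control_pool < 0:
            raise ConfigError("n_control_pool must be >= 0")
        if self.income_topcode <= 0 or self.income_rounding <= 0:
            raise ConfigError("income_topcode and income_rounding must be > 0")
        known_kinds = {"bernoulli", "poisson", "normal", "ordinal", "lognormal",
                       "share", "categorical", "uniform_int", "derived"}
        for name, spec in self.covariate_spec.items():
            if name not in COVARIATE_ORDER:
                raise ConfigError(f"unknown covariate {name!r} in covariate_spec")
            if spec.kind not in known_kinds:
                raise ConfigError(f"unknown covariate kind {spec.kind!r} for {name!r}")
        for name in COVARIATE_ORDER:
            if name not in self.covariate_spec:
                raise ConfigError(f"covariate_spec missing {name!r}")
        for name in self.treatment_model:
            _check_feature_name(name)
        for oname, model in self.outcome_models.items():
            if oname not in OUTCOME_NAMES:
                raise ConfigError(f"unknown outcome {oname!r}")
            for fname in list(model.coefs) + list(model.effect_mods):
                _check_feature_name(fname)


def _check_feature_name(name: str) -> None:
    if name not in COVARIATE_ORDER and name not in ("ses_index", "cohort_c"):
        raise ConfigError(f"unknown covariate or feature {name!r} in model specification")


# ---------------------------------------------------------------------------
# model features
# ---------------------------------------------------------------------------

# fixed standardization constants for the observed family-SES composite
# (population values implied by the default covariate spec)
_SES_SCALE = 0.78


def ses_index(df: pd.DataFrame) -> np.ndarray:
    """Observed family-SES composite (≈ mean 0, sd 1 under the default spec).

    A weighted sum of standardized log household earnings, parental
    education, homeownership and social-assistance receipt.  The outcome
    models express their SES gradients — and the SES-modified partnership
    effect — through this observable index, so forests can recover it.
    """
    z_earn = (np.log(np.maximum(df["household_earnings"].to_numpy(float), 1000.0)) - 9.951) / 0.673
    z_med = (df["mother_education"].to_numpy(float) - 3.21) / 1.13
    z_fed = (df["father_education"].to_numpy(float) - 3.10) / 1.16
    z_home = (df["homeowner"].to_numpy(float) - 0.76) / 0.427
    z_sa = (df["social_assistance"].to_numpy(float) - 0.11) / 0.313
    s = 0.45 * z_earn + 0.22 * z_med + 0.22 * z_fed + 0.20 * z_home - 0.15 * z_sa
    return s / _SES_SCALE


def model_feature(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a treatment/outcome-model feature name to a numeric vector."""
    if name == "ses_index":
        return ses_index(df)
    if name == "cohort_c":
        return df["birth_year"].to_numpy(float) - 1985.5
    if name in COVARIATE_ORDER:
        return df[name].to_numpy(float)
    raise ConfigError(f"unknown covariate or feature {name!r}")


def _linear_term(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    out = np.zeros(len(df))
    for name, c in coefs.items():
        out += c * model_feature(df, name)
    return out


# ---------------------------------------------------------------------------
# covariate generation
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _bernoulli_intercept(target: float, loading: float) -> float:
    """Solve a s.t. E_Z[sigmoid(a + loading Z)] = target (Gauss-Hermite)."""
    if loading == 0.0:
        return float(np.log(target / (1 - target)))

    def f(a: float) -> float:
        return float(np.dot(_GH_WEIGHTS, expit(a + loading * _GH_NODES))) - target

    return brentq(f, -20.0, 20.0, xtol=1e-12)


def generate_covariates(config: DGPConfig, n: int, seed: int | None = None) -> pd.DataFrame:
    """Draw ``n`` rows of baseline covariates (plus exclusion flags).

    Cross-covariate correlation is induced solely through the latent SES
    factor ``Z``; marginal means follow the configured spec.  Exclusion
    flags (pre-age-7 diagnosis, missing covariates, death/emigration before
    18) are also drawn here: they are pre-treatment facts of the register
    design, exercised later by the matching stage.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 101])

    z = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {"person_id": np.arange(n, dtype=np.int64)}
    for name in COVARIATE_ORDER:
        spec = config.covariate_spec[name]
        b = spec.loading
        p = spec.params
        if spec.kind == "bernoulli":
            a = _bernoulli_intercept(p["p"], b)
            cols[name] = (rng.random(n) < expit(a + b * z)).astype(np.int8)
        elif spec.kind == "poisson":
            rate = p["rate"] * np.exp(b * z - b * b / 2.0)
            cols[name] = (rng.poisson(rate) + p.get("shift", 0)).astype(np.int64)
        elif spec.kind == "normal":
            v = p["mean"] + b * z + p["sd"] * rng.standard_normal(n)
            cols[name] = np.clip(v, p["lo"], p["hi"])
        elif spec.kind == "ordinal":
            probs = np.asarray(p["probs"], float)
            bb = min(abs(b), 0.95)
            latent = b * z + np.sqrt(1.0 - bb * bb) * rng.standard_normal(n)
            cuts = ndtri(np.cumsum(probs)[:-1])
            cols[name] = (np.searchsorted(cuts, latent) + 1).astype(np.int64)
        elif spec.kind == "lognormal":
            pos = rng.random(n) >= p["zero_p"]
            v = np.exp(p["mean_log"] + b * z + p["sd_log"] * rng.standard_normal(n))
            cols[name] = np.where(pos, v, 0.0)
        elif spec.kind == "share":
            cols[name] = expit(p["a"] + b * z + p["noise"] * rng.standard_normal(n))
        elif spec.kind == "categorical":
            probs = np.asarray(p["probs"], float)
            cols[name] = rng.choice(len(probs), size=n, p=probs / probs.sum()).astype(np.int64)
        elif spec.kind == "uniform_int":
            cols[name] = rng.integers(p["lo"], p["hi"] + 1, size=n)
        elif spec.kind == "derived":
            cols[name] = np.zeros(n)  # filled below

    # derived: household size = child + children + parents (+ rare extra adult)
    cols["household_size"] = (
        1.0 + (1 - cols["single_parent"]) + (cols["n_children"] - 1)
        + (rng.random(n) < 0.04).astype(np.int8) + 1.0
    )
    df = pd.DataFrame(cols)

    # missing-parent imputation: reference-group values for father covariates
    miss = df["parent_missing"].to_numpy(bool)
    if miss.any():
        df.loc[miss, "father_age"] = 36.0
        df.loc[miss, "father_education"] = 3
        df.loc[miss, "father_education_health"] = 0
        df.loc[miss, "father_employed"] = 1
        df.loc[miss, "father_hospital_visits"] = 0

    # pre-treatment exclusion flags
    for reason in EXCLUSION_ORDER:
        rate = config.exclusion_rates.get(reason, 0.0)
        df[f"excl_{reason}"] = (rng.random(n) < rate).astype(np.int8)
    flags = df[[f"excl_{r}" for r in EXCLUSION_ORDER]].to_numpy(bool)
    df["excluded_flag"] = flags.any(axis=1).astype(np.int8)
    first = np.argmax(flags, axis=1)
    df["exclusion_reason"] = np.where(
        df["excluded_flag"].to_numpy(bool),
        np.asarray(EXCLUSION_ORDER, object)[first],
        "",
    )
    return df


def assign_treatment(cohort: pd.DataFrame, config: DGPConfig, seed: int | None = None) -> pd.DataFrame:
    """Mark exactly ``n_treated`` rows as treated (T1D).

    Selection is weighted sampling without replacement with weights
    ``exp(theta . x)`` (Gumbel top-k), restricted to non-excluded rows so
    the analyzed case count is exact.  An all-zero model reduces to uniform
    sampling.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    eligible = ~cohort["excluded_flag"].to_numpy(bool)
    n_elig = int(eligible.sum())
    if config.n_treated > n_elig:
        raise ConfigError(
            f"n_treated={config.n_treated} exceeds {n_elig} eligible rows")
    rng = np.random.default_rng([int(seed), 202])
    logw = _linear_term(cohort, config.treatment_model)
    logw = logw - logw.max()
    keys = logw + rng.gumbel(size=len(cohort))
    keys[~eligible] = -np.inf
    treated_idx = np.argpartition(-keys, config.n_treated - 1)[: config.n_treated]
    out = cohort.copy()
    w = np.zeros(len(cohort), dtype=np.int8)
    w[treated_idx] = 1
    out["treated"] = w
    return out


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def _require_calibrated(model: OutcomeModel, name: str) -> None:
    if model.intercept is None or model.effect_base is None:
        raise ConfigError(
            f"outcome model {name!r} is not calibrated; use default_config() or calibrate()")


def _binary_p0(df: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    return expit(model.intercept + _linear_term(df, model.coefs))


def _effect(df: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    """Treatment effect tau(x) on the outcome's own scale.

    For ``income_lognormal`` the returned value is the *relative* level
    shift (multiplier - 1); use :func:`true_cate` for the euro-scale effect.
    """
    return model.effect_base + _linear_term(df, model.effect_mods)


_MONTHS_MAX = 12.0


def _months_mu_cond(model: OutcomeModel) -> float:
    return _MONTHS_MAX * model.beta_a / (model.beta_a + model.beta_b)


def _income_mu(df: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    return model.intercept + _linear_term(df, model.coefs)


def _capped_lognormal_mean(mu: np.ndarray, sigma: float, cap: float) -> np.ndarray:
    """E[min(exp(mu + sigma Z), cap)] for standard-normal Z (closed form)."""
    lc = np.log(cap)
    return (
        np.exp(mu + 0.5 * sigma**2) * ndtr((lc - mu - sigma**2) / sigma)
        + cap * (1.0 - ndtr((lc - mu) / sigma))
    )


def generate_outcomes(cohort: pd.DataFrame, config: DGPConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the six outcomes given covariates and the treatment flag.

    Mortality is drawn first; every other outcome is drawn only for
    survivors (missing for the deceased).  Antidepressant use and income
    are additionally censored for the configured birth cohorts.  Treatment
    effects are additive on the probability scale (binary outcomes) and
    months scale (unemployment), and multiplicative on the pre-rounding
    income level.
    """
    config.validate()
    if "treated" not in cohort.columns:
        raise ConfigError("treatment must be assigned before generating outcomes")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 303])
    df = cohort.copy()
    w = df["treated"].to_numpy(float)
    n = len(df)

    models = config.outcome_models
    for name in OUTCOME_NAMES:
        _require_calibrated(models[name], name)

    m = models["died_by_30"]
    p_death = np.clip(_binary_p0(df, m) + w * _effect(df, m), 1e-6, 1 - 1e-6)
    died = (rng.random(n) < p_death).astype(np.int8)
    df["died_by_30"] = died
    alive = ~died.astype(bool)
    censored = df["birth_year"].isin(config.censor_cohorts).to_numpy()

    for name in ("antidepressant_use", "no_partnership", "basic_education_only"):
        m = models[name]
        p = np.clip(_binary_p0(df, m) + w * _effect(df, m), 0.0, 1.0)
        y = (rng.random(n) < p).astype(float)
        y[~alive] = np.nan
        if name == "antidepressant_use":
            y[censored] = np.nan
        df[name] = y

    m = models["unemployment_months_annualized"]
    mu_c = _months_mu_cond(m)
    p_pos = np.clip(expit(m.intercept + _linear_term(df, m.coefs)) + w * _effect(df, m) / mu_c, 0.0, 1.0)
    pos = rng.random(n) < p_pos
    months = np.where(pos, _MONTHS_MAX * rng.beta(m.beta_a, m.beta_b, size=n), 0.0)
    months[~alive] = np.nan
    df["unemployment_months_annualized"] = months

    m = models["income_annual"]
    level = np.exp(_income_mu(df, m) + m.sigma_log * rng.standard_normal(n))
    level *= 1.0 + w * _effect(df, m)
    level = np.minimum(level, config.income_topcode)
    level = np.round(level / config.income_rounding) * config.income_rounding
    level[~alive] = np.nan
    level[censored] = np.nan
    df["income_annual"] = level

    return df


def generate_cohort(config: DGPConfig, seed: int | None = None) -> pd.DataFrame:
    """Covariates + treatment + outcomes for the configured design sizes."""
    if seed is None:
        seed = config.seed
    n = config.n_treated + config.n_control_pool
    df = generate_covariates(config, n, seed=seed)
    df = assign_treatment(df, config, seed=seed)
    df = generate_outcomes(df, config, seed=seed)
    logger.info("generated cohort n=%d (config %s, seed %d)", n, config_hash(config), seed)
    return df


def true_cate(cohort: pd.DataFrame, config: DGPConfig, outcome: str) -> np.ndarray:
    """Ground-truth per-person effect tau(x) = E[Y|W=1,x] - E[Y|W=0,x].

    Computed in closed form from the configured outcome model, on the
    outcome's own scale (probability points, months/year, euros/year).
    Censoring does not apply: the model-implied truth exists for every row.
    """
    if outcome not in config.outcome_models:
        raise ConfigError(f"no outcome model configured for {outcome!r}")
    m = config.outcome_models[outcome]
    _require_calibrated(m, outcome)
    if m.kind == "binary":
        p0 = _binary_p0(cohort, m)
        return np.clip(p0 + _effect(cohort, m), 0.0, 1.0) - p0
    if m.kind == "months_zibeta":
        mu_c = _months_mu_cond(m)
        p0 = expit(m.intercept + _linear_term(cohort, m.coefs))
        p1 = np.clip(p0 + _effect(cohort, m) / mu_c, 0.0, 1.0)
        return (p1 - p0) * mu_c
    if m.kind == "income_lognormal":
        mu = _income_mu(cohort, m)
        cap = config.income_topcode
        e0 = _capped_lognormal_mean(mu, m.sigma_log, cap)
        e1 = _capped_lognormal_mean(mu + np.log1p(_effect(cohort, m)), m.sigma_log, cap)
        return e1 - e0
    raise ConfigError(f"unknown outcome kind {m.kind!r}")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_CALIBRATION_SEED = 734001


def calibrate(config: DGPConfig, calibration_seed: int = _CALIBRATION_SEED) -> DGPConfig:
    """Solve outcome intercepts and mean effects against the design targets.

    A calibration cohort of the configured design size is generated with a
    fixed internal seed, run through exclusions and stratified matching,
    and the control intercept / treated mean effect of every outcome model
    is solved so that the *expected* group means (survival-weighted,
    censoring-aware, over the matched sample's covariate distribution)
    equal ``control_mean`` / ``treated_mean``.  Expectations are taken
    analytically given covariates, so calibration error is limited to the
    covariate Monte-Carlo error of one design-size draw (negligible against
    the per-run outcome sampling noise).
    """
    from .matching import apply_exclusions, match_controls

    config.validate()
    n = config.n_treated + config.n_control_pool
    df = generate_covariates(config, n, seed=calibration_seed)
    df = assign_treatment(df, config, seed=calibration_seed)
    kept, _ = apply_exclusions(df)
    matched = match_controls(kept, config.max_controls_per_case, seed=calibration_seed).data

    is_t = matched["treated"].to_numpy(bool)
    T, C = matched[is_t], matched[~is_t]
    models = dict(config.outcome_models)

    def solve_binary(model: OutcomeModel, w_c: np.ndarray, w_t: np.ndarray) -> OutcomeModel:
        lin_c = _linear_term(C, model.coefs)
        lin_t = _linear_term(T, model.coefs)

        def mean_c(a: float) -> float:
            return float(np.average(expit(a + lin_c), weights=w_c)) - model.control_mean

        a0 = brentq(mean_c, -20.0, 20.0, xtol=1e-12)
        mod_t = _linear_term(T, model.effect_mods)
        base = model.treated_mean - float(np.average(expit(a0 + lin_t) + mod_t, weights=w_t))
        return replace(model, intercept=a0, effect_base=base)

    # mortality first (unweighted); its probabilities weight the rest
    ones_c, ones_t = np.ones(len(C)), np.ones(len(T))
    m_mort = solve_binary(models["died_by_30"], ones_c, ones_t)
    models["died_by_30"] = m_mort
    surv_c = 1.0 - _binary_p0(C, m_mort)
    surv_t = 1.0 - np.clip(_binary_p0(T, m_mort) + _effect(T, m_mort), 0.0, 1.0)

    cens_c = C["birth_year"].isin(config.censor_cohorts).to_numpy()
    cens_t = T["birth_year"].isin(config.censor_cohorts).to_numpy()

    models["antidepressant_use"] = solve_binary(
        models["antidepressant_use"], surv_c * ~cens_c, surv_t * ~cens_t)
    models["no_partnership"] = solve_binary(models["no_partnership"], surv_c, surv_t)
    models["basic_education_only"] = solve_binary(
        models["basic_education_only"], surv_c, surv_t)

    m = models["unemployment_months_annualized"]
    mu_cond = _months_mu_cond(m)
    lin_c, lin_t = _linear_term(C, m.coefs), _linear_term(T, m.coefs)

    def mean_months_c(a: float) -> float:
        return float(np.average(expit(a + lin_c) * mu_cond, weights=surv_c)) - m.control_mean

    a0 = brentq(mean_months_c, -20.0, 20.0, xtol=1e-12)
    base = m.treated_mean - float(np.average(expit(a0 + lin_t) * mu_cond, weights=surv_t))
    models["unemployment_months_annualized"] = replace(m, intercept=a0, effect_base=base)

    m = models["income_annual"]
    lin_c, lin_t = _linear_term(C, m.coefs), _linear_term(T, m.coefs)
    w_c, w_t = surv_c * ~cens_c, surv_t * ~cens_t
    cap = config.income_topcode

    def mean_income_c(a: float) -> float:
        return float(np.average(_capped_lognormal_mean(a + lin_c, m.sigma_log, cap),
                                weights=w_c)) - m.control_mean

    a0 = brentq(mean_income_c, 0.0, 20.0, xtol=1e-10)

    def mean_income_t(rel: float) -> float:
        return float(np.average(
            _capped_lognormal_mean(a0 + lin_t + np.log1p(rel), m.sigma_log, cap),
            weights=w_t)) - m.treated_mean

    rel = brentq(mean_income_t, -0.9, 0.9, xtol=1e-10)
    models["income_annual"] = replace(m, intercept=a0, effect_base=rel)

    out = replace(config, outcome_models=models)
    logger.info("calibrated DGP config %s", config_hash(out))
    return out


_DEFAULT_CONFIG: DGPConfig | None = None


def default_config() -> DGPConfig:
    """The calibrated default configuration (cached per process)."""
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = calibrate(DGPConfig())
    return _DEFAULT_CONFIG


# ---------------------------------------------------------------------------
# reporting and I/O
# ---------------------------------------------------------------------------

_REPORT_COVARIATES = [
    "female", "birth_year", "father_employed", "homeowner",
    "child_hospital_visits", "household_assets", "household_earnings",
    "household_size", "mother_employed", "single_parent", "social_assistance",
    "household_diabetes", "n_children",
]


def calibration_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group means of the six outcomes and headline covariates.

    Rows are outcomes then covariates; columns are the treated group, the
    comparison group (all non-treated rows of the supplied table) and the
    full table, formatted for side-by-side comparison with published
    descriptive tables.  Outcome means ignore missing (deceased/censored)
    values.
    """
    if "treated" not in cohort.columns or int(cohort["treated"].sum()) == 0:
        raise ValueError("no treated observations")
    is_t = cohort["treated"].to_numpy(bool)
    rows = []
    for name in OUTCOME_NAMES + _REPORT_COVARIATES:
        if name not in cohort.columns:
            continue
        col = cohort[name].astype(float)
        rows.append({
            "variable": name,
            "kind": "outcome" if name in OUTCOME_NAMES else "covariate",
            "treated": col[is_t].mean(),
            "comparison": col[~is_t].mean(),
            "full": col.mean(),
        })
    return pd.DataFrame(rows)


def write_cohort(df: pd.DataFrame, path: str) -> None:
    """Write a cohort table as CSV (documented header = column names)."""
    df.to_csv(path, index=False)


def read_cohort(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["person_id", "treated"] if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort file lacks required columns: {missing}")
    return df
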