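"""Synthetic cohort generator with the generative structure the analysis assumes.

Childhood socioeconomic position (father's occupational class) and adulthood
SEP (education) are drawn as correlated ordinals through a Gaussian copula
calibrated to a target rank correlation. Risk factors are drawn on the *raw*
questionnaire scale (frequency bands, drinking days, weight/height, item
flags) from logit models with gradients in both SEP indicators, so the coding
module is exercised end to end. CVD death times follow a proportional-hazards
model with an exponential baseline and a log-linear age effect; other-cause
death, emigration and the administrative end of follow-up censor.

Default sample sizes, SEP marginals, the SEP-indicator correlation (0.345),
smoking and overweight prevalences, and the per-level hazard effects are set
to the values the cohort analysis reports, so the default cohort is
"study-like"; the baseline CVD hazards are calibrated so that roughly 9.7% of
men and 6.2% of women die of CVD over the 16.5-year window.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import coding
from .followup import BASELINE_DATE, DAYS_PER_YEAR, WINDOW_YEARS

LN = math.log


class ConfigError(ValueError):
    pass


# SEP level labels ordered from LOW to HIGH (copula ordering)
ADULT_SEP_ASC = ("1_low", "2_mid_low", "3_mid_high", "4_high")
CHILD_SEP_ASC = ("blue_collar", "white_collar", "professional")


def _norm(v) -> tuple[float, ...]:
    a = np.asarray(v, float)
    return tuple(a / a.sum())


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    n: dict = dc_field(
        default_factory=lambda: {"male": 5395, "female": 6306}
    )
    #: adulthood SEP marginals, ordered low -> high (explanatory-table group sizes)
    sep_marginals: dict = dc_field(
        default_factory=lambda: {
            "male": _norm([1270, 1795, 1088, 1242]),
            "female": _norm([1961, 3079, 774, 492]),
        }
    )
    #: father's occupational class, ordered blue -> white -> professional
    childhood_marginals: tuple = (0.55, 0.30, 0.15)
    #: target Spearman correlation between the two SEP indicators
    sep_correlation: float = 0.345
    age_range: tuple = (40, 75)
    age_log_hr: float = 0.08
    follow_up_years: float = WINDOW_YEARS
    emigration_rate: float = 0.002  # per year
    #: other-cause baseline mortality hazard at age 57.5, per year
    other_mortality_rate: dict = dc_field(
        default_factory=lambda: {"male": 0.011, "female": 0.007}
    )
    other_age_log_hr: float = 0.09
    #: baseline CVD hazard at age 57.5 for the reference covariate pattern,
    #: per year (calibrated to the reported CVD death fractions)
    cvd_baseline_hazard: dict = dc_field(
        default_factory=lambda: {"male": 0.001397, "female": 0.000544}
    )
    #: direct (unmediated) log hazard ratios of adulthood SEP vs 4_high
    direct_sep_log_hr: dict = dc_field(
        default_factory=lambda: {
            "male": {"1_low": LN(1.30), "2_mid_low": LN(1.10), "3_mid_high": LN(1.08)},
            "female": {"1_low": LN(1.30), "2_mid_low": LN(1.10), "3_mid_high": LN(1.10)},
        }
    )
    #: direct log hazard ratios of childhood SEP vs professional
    childhood_log_hr: dict = dc_field(
        default_factory=lambda: {
            "male": {"white_collar": LN(1.09), "blue_collar": LN(1.34)},
            "female": {"white_collar": LN(1.00), "blue_collar": LN(1.10)},
        }
    )
    #: per-level log hazard ratios of the coded risk factors (study estimates)
    covariate_log_hr: dict = dc_field(
        default_factory=lambda: {
            "male": {
                "smoking": {"former": LN(0.97), "current": LN(1.85)},
                "physical_activity": {
                    "moderately_active": LN(1.16),
                    "little_active": LN(1.52),
                    "inactive": LN(1.71),
                },
                "alcohol": {"abstainer": LN(1.12), "moderate": LN(0.98), "heavy": LN(1.36)},
                "bmi_class": {"underweight": LN(0.47), "overweight": LN(1.09), "obese": LN(1.39)},
                "tenure": {"renter": LN(1.31)},
                "car": {"no": LN(1.37)},
                "insurance": {"public": LN(1.19)},
                "financial_problems": {"some": LN(1.08), "big": LN(1.74)},
                "nbhd_adversity": {"one_or_more": LN(0.94)},
                "housing_adversity": {"one_or_more": LN(1.02)},
                "marital": {"single": LN(1.51), "divorced": LN(1.45), "widowed": LN(1.20)},
                "life_events": {"one": LN(1.10), "two_or_more": LN(0.98)},
                "sleep_anxiety_drugs": {"yes": LN(1.51)},
                "depression_nervousness": {"yes": LN(1.20)},
            },
            "female": {
                "smoking": {"former": LN(0.80), "current": LN(1.87)},
                "physical_activity": {
                    "moderately_active": LN(1.31),
                    "little_active": LN(1.40),
                    "inactive": LN(2.09),
                },
                "alcohol": {"abstainer": LN(1.80), "moderate": LN(1.22), "heavy": LN(2.01)},
                "bmi_class": {"underweight": LN(1.93), "overweight": LN(0.92), "obese": LN(1.66)},
                "tenure": {"renter": LN(1.35)},
                "car": {"no": LN(1.27)},
                "insurance": {"public": LN(1.17)},
                "financial_problems": {"some": LN(1.31), "big": LN(1.82)},
                "nbhd_adversity": {"one_or_more": LN(1.02)},
                "housing_adversity": {"one_or_more": LN(1.13)},
                "marital": {"single": LN(1.31), "divorced": LN(1.46), "widowed": LN(1.51)},
                "life_events": {"one": LN(0.98), "two_or_more": LN(1.30)},
                "sleep_anxiety_drugs": {"yes": LN(0.98)},
                "depression_nervousness": {"yes": LN(1.34)},
            },
        }
    )
    #: per-factor logit gradients (b_adult, b_child) on normalized adversity
    #: scores u in [0, 1] (1 = lowest SEP); applied to the factor's
    #: "adverse" linear predictor as described in docs/methods.md
    risk_gradients: dict = dc_field(
        default_factory=lambda: {
            "smoking_current": (0.6, 0.15),
            "activity": (-0.4, -0.15),  # shift of the latent activity propensity
            "alcohol_abstainer": (0.5, 0.1),
            "alcohol_units": (0.2, 0.1),  # log-scale on units per drinking day
            "bmi": (0.6, 0.3),  # kg/m^2 added at the lowest SEP
            "insurance_public": (1.5, 0.3),
            "car_no": (1.0, 0.2),
            "tenure_renter": (1.1, 0.3),
            "financial_problems": (0.8, 0.2),
            "nbhd": (0.5, 0.1),
            "housing": (0.7, 0.2),
            "marital_nonmarried": (0.3, 0.0),
            "life_events": (0.2, 0.0),
            "sleep_drugs": (0.5, 0.1),
            "depression": (0.4, 0.1),
        }
    )
    #: per-column missingness rates injected after hazard generation
    missingness: dict = dc_field(
        default_factory=lambda: {
            "education": 0.02,
            "father_occupation": 0.08,
            "smoking_raw": 0.015,
            "sport_band": 0.02,
            "transport_band": 0.02,
            "leisure_band": 0.02,
            "alcohol_days_per_week": 0.03,
            "alcohol_units_per_day": 0.03,
            "weight": 0.02,
            "height": 0.02,
            "insurance": 0.02,
            "car": 0.01,
            "tenure": 0.01,
            "financial_problems": 0.03,
            "nbhd_item1": 0.02,
            "nbhd_item2": 0.02,
            "nbhd_item3": 0.02,
            "nbhd_item4": 0.02,
            "housing_item1": 0.02,
            "housing_item2": 0.02,
            "housing_item3": 0.02,
            "marital": 0.005,
            "life_events_count": 0.04,
            "sleep_anxiety_drugs": 0.02,
            "depression_nervousness": 0.03,
        }
    )
    prior_cvd_rate: dict = dc_field(
        default_factory=lambda: {"male": 0.03, "female": 0.02}
    )
    under40_rate: float = 0.0  # fraction of under-40 records (exclusion plumbing)
    #: recorded by make_mediation_scenario for recovery tests
    implied_attenuation: dict | None = None
    scenario: str = "default"

    def validate(self) -> None:
        for sex in ("male", "female"):
            m = np.asarray(self.sep_marginals[sex], float)
            if abs(m.sum() - 1.0) > 1e-12 or (m < 0).any():
                raise ConfigError(f"sep_marginals[{sex}] must be a probability vector")
        c = np.asarray(self.childhood_marginals, float)
        if abs(c.sum() - 1.0) > 1e-12 or (c < 0).any():
            raise ConfigError("childhood_marginals must be a probability vector")
        if self.emigration_rate < 0 or self.follow_up_years <= 0:
            raise ConfigError("rates must be >= 0 and follow-up positive")


# ---------------------------------------------------------------------------
# Gaussian copula for the two ordinal SEP indicators


def _thresholds(marginals: np.ndarray) -> np.ndarray:
    """Standard-normal cut points of an ordinal marginal (ascending levels)."""
    cum = np.cumsum(marginals)[:-1]
    return stats.norm.ppf(cum)


def _joint_pmf(rho: float, p_child: np.ndarray, p_adult: np.ndarray) -> np.ndarray:
    """Cell probabilities of the discretized bivariate normal."""
    tc = np.concatenate([[-np.inf], _thresholds(p_child), [np.inf]])
    ta = np.concatenate([[-np.inf], _thresholds(p_adult), [np.inf]])
    mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def F(x, y):
        if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
            return 0.0
        xx = min(x, 8.0)
        yy = min(y, 8.0)
        return float(mvn.cdf([xx, yy]))

    P = np.empty((len(p_child), len(p_adult)))
    for i in range(len(p_child)):
        for j in range(len(p_adult)):
            P[i, j] = (
                F(tc[i + 1], ta[j + 1]) - F(tc[i], ta[j + 1]) - F(tc[i + 1], ta[j]) + F(tc[i], ta[j])
            )
    return np.clip(P, 0.0, 1.0)


def _spearman_of_joint(P: np.ndarray) -> float:
    """Spearman rank correlation (midranks) of a discrete joint pmf."""
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    # fractional midranks on [0, 1]
    r_row = np.cumsum(p_row) - p_row / 2
    r_col = np.cumsum(p_col) - p_col / 2
    mu_r = float(p_row @ r_row)
    mu_c = float(p_col @ r_col)
    var_r = float(p_row @ (r_row - mu_r) ** 2)
    var_c = float(p_col @ (r_col - mu_c) ** 2)
    cov = float(((r_row - mu_r)[:, None] * (r_col - mu_c)[None, :] * P).sum())
    return cov / math.sqrt(var_r * var_c)


def solve_copula_rho(
    target: float, p_child: np.ndarray, p_adult: np.ndarray
) -> float:
    """Latent normal correlation hitting a target ordinal Spearman correlation."""
    if target == 0.0 or (p_child > 1 - 1e-12).any() or (p_adult > 1 - 1e-12).any():
        # independence, or a degenerate marginal for which any rho works
        return 0.0
    bound = _spearman_of_joint(_joint_pmf(0.999, p_child, p_adult))
    if abs(target) > bound:
        raise ConfigError(
            f"correlation target {target} unattainable for these marginals "
            f"(feasible bound {bound:.3f})"
        )

    def f(rho):
        return _spearman_of_joint(_joint_pmf(rho, p_child, p_adult)) - target

    return float(optimize.brentq(f, -0.999, 0.999, xtol=1e-5))


# ---------------------------------------------------------------------------
# raw covariate generation


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _bern(rng, eta: np.ndarray) -> np.ndarray:
    return (rng.random(eta.shape) < 1 / (1 + np.exp(-eta))).astype(int)


def _ordinal_from_latent(latent: np.ndarray, probs) -> np.ndarray:
    """Map a standard-normal latent to ordinal codes with given marginals."""
    cuts = _thresholds(np.asarray(probs, float))
    return np.searchsorted(cuts, latent)


def _draw_sex_block(cfg: SimulationConfig, sex: str, rng: np.random.Generator) -> pd.DataFrame:
    n = int(cfg.n[sex])
    p_adult = np.asarray(cfg.sep_marginals[sex], float)
    p_child = np.asarray(cfg.childhood_marginals, float)
    rho = solve_copula_rho(cfg.sep_correlation, p_child, p_adult)

    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    child_idx = _ordinal_from_latent(z[:, 0], p_child)  # 0=blue .. 2=professional
    adult_idx = _ordinal_from_latent(z[:, 1], p_adult)  # 0=1_low .. 3=4_high

    # normalized adversity scores: 1 at the lowest SEP, 0 at the highest
    u_a = (3 - adult_idx) / 3.0
    u_c = (2 - child_idx) / 2.0
    g = cfg.risk_gradients

    def eta(base_logit, key):
        ba, bc = g[key]
        return base_logit + ba * u_a + bc * u_c

    age = rng.uniform(*cfg.age_range, size=n)
    if cfg.under40_rate > 0:
        young = rng.random(n) < cfg.under40_rate
        age = np.where(young, rng.uniform(25, 40, size=n), age)

    # -- smoking: current via logit with SEP gradient; former among the rest
    base_cur = _logit(0.29) if sex == "male" else _logit(0.185)
    current = _bern(rng, eta(base_cur, "smoking_current"))
    p_former = 0.45 if sex == "male" else 0.28
    former = (rng.random(n) < p_former) & (current == 0)
    smoking_raw = np.where(current == 1, "current", np.where(former, "former", "never"))

    # -- physical activity bands: latent propensity shifted down with low SEP
    ba, bc = g["activity"]
    shift = ba * u_a + bc * u_c
    bands = list(coding.BAND_HOURS)

    def draw_band(marginals):
        # shift is negative at low SEP: lower latent -> lower activity band
        latent = rng.standard_normal(n) + shift
        idx = _ordinal_from_latent(latent, marginals)
        return np.array(bands, dtype=object)[idx]

    sport_band = draw_band([0.45, 0.15, 0.20, 0.20])
    transport_band = draw_band([0.25, 0.20, 0.30, 0.25])
    leisure_band = draw_band([0.20, 0.20, 0.30, 0.30])

    # -- alcohol: abstention probability and intensity both SEP-graded
    base_abst = _logit(0.14) if sex == "male" else _logit(0.30)
    abstainer = _bern(rng, eta(base_abst, "alcohol_abstainer"))
    p_day = 0.38 if sex == "male" else 0.22
    days = rng.binomial(7, p_day, size=n)
    days = np.where(abstainer == 1, 0, np.maximum(days, 1))
    ba_u, bc_u = g["alcohol_units"]
    lam = np.exp(math.log(0.9 if sex == "male" else 0.45) + ba_u * u_a + bc_u * u_c)
    units = 1 + rng.poisson(lam)

    # -- BMI via normal body-mass with additive SEP gradient
    ba_b, bc_b = g["bmi"]
    mu_bmi = (23.9 if sex == "male" else 23.2) + ba_b * u_a + bc_b * u_c
    bmi = rng.normal(mu_bmi, 3.3)
    height = rng.normal(1.77 if sex == "male" else 1.64, 0.07, size=n)
    weight = np.round(bmi * height**2, 1)
    height = np.round(height, 2)

    insurance = np.where(_bern(rng, eta(_logit(0.40), "insurance_public")) == 1, "public", "private")
    car = np.where(_bern(rng, eta(_logit(0.10), "car_no")) == 1, "no", "yes")
    tenure = np.where(_bern(rng, eta(_logit(0.28), "tenure_renter")) == 1, "renter", "owner")

    any_fin = _bern(rng, eta(_logit(0.14), "financial_problems"))
    big = rng.random(n) < 0.20
    financial = np.where(any_fin == 1, np.where(big, "big", "some"), "none")

    nbhd = {
        f"nbhd_item{i}": _bern(rng, eta(_logit(0.12), "nbhd")) for i in range(1, 5)
    }
    housing = {
        f"housing_item{i}": _bern(rng, eta(_logit(0.09), "housing")) for i in range(1, 4)
    }

    base_marital = (
        np.array([0.82, 0.07, 0.05, 0.06])
        if sex == "male"
        else np.array([0.72, 0.07, 0.06, 0.15])
    )
    ba_m, _ = g["marital_nonmarried"]
    marital_levels = np.array(["married", "single", "divorced", "widowed"], dtype=object)
    marital = np.empty(n, dtype=object)
    for k in range(n):
        p = base_marital.copy()
        p[1:] *= math.exp(ba_m * u_a[k])
        p /= p.sum()
        marital[k] = marital_levels[rng.choice(4, p=p)]

    ba_l, _ = g["life_events"]
    life_events = np.minimum(rng.poisson(np.exp(math.log(0.45) + ba_l * u_a)), 9)

    sleep = np.where(_bern(rng, eta(_logit(0.08), "sleep_drugs")) == 1, "yes", "no")
    depression = np.where(_bern(rng, eta(_logit(0.13), "depression")) == 1, "yes", "no")
    prior_cvd = np.where(rng.random(n) < cfg.prior_cvd_rate[sex], "yes", "no")

    df = pd.DataFrame(
        {
            "sex": sex,
            "age_baseline": np.round(age).astype(int),
            "education": (adult_idx + 1),  # 1-low .. 4-high
            "father_occupation": np.array(CHILD_SEP_ASC, dtype=object)[child_idx],
            "smoking_raw": smoking_raw,
            "sport_band": sport_band,
            "transport_band": transport_band,
            "leisure_band": leisure_band,
            "alcohol_days_per_week": days,
            "alcohol_units_per_day": units,
            "weight": weight,
            "height": height,
            "insurance": insurance,
            "car": car,
            "tenure": tenure,
            "financial_problems": financial,
            **nbhd,
            **housing,
            "marital": marital,
            "life_events_count": life_events,
            "sleep_anxiety_drugs": sleep,
            "depression_nervousness": depression,
            "prior_cvd_5yr": prior_cvd,
        }
    )
    return df


def _linear_predictor(cfg: SimulationConfig, sex: str, coded: pd.DataFrame) -> np.ndarray:
    """Log relative hazard (vs reference pattern) from the TRUE coded values."""
    lp = cfg.age_log_hr * (coded["age_baseline"].to_numpy(float) - 57.5)
    sep = coded["adulthood_sep"].astype(str).to_numpy()
    for level, b in cfg.direct_sep_log_hr[sex].items():
        lp = lp + b * (sep == level)
    child = coded["childhood_sep"].astype(str).to_numpy()
    for level, b in cfg.childhood_log_hr[sex].items():
        lp = lp + b * (child == level)
    for cov, levels in cfg.covariate_log_hr[sex].items():
        values = coded[cov].astype(str).to_numpy()
        for level, b in levels.items():
            lp = lp + b * (values == level)
    return lp


def _simulate_events(
    cfg: SimulationConfig, sex: str, coded: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(coded)
    rr = np.exp(_linear_predictor(cfg, sex, coded))
    h_cvd = cfg.cvd_baseline_hazard[sex] * rr
    age = coded["age_baseline"].to_numpy(float)
    h_oth = cfg.other_mortality_rate[sex] * np.exp(cfg.other_age_log_hr * (age - 57.5))

    t_cvd = rng.exponential(1.0 / h_cvd)
    t_oth = (
        rng.exponential(1.0 / h_oth)
        if np.all(h_oth > 0)
        else np.full(n, np.inf)
    )
    if cfg.emigration_rate > 0:
        t_emig = rng.exponential(1.0 / cfg.emigration_rate, size=n)
    else:
        t_emig = np.full(n, np.inf)

    T = cfg.follow_up_years
    t_obs = np.minimum.reduce([t_cvd, t_oth, t_emig, np.full(n, T)])
    cause = np.where(
        t_obs >= T,
        "alive",
        np.where(t_obs == t_cvd, "cvd", np.where(t_obs == t_oth, "other", "emigrated")),
    )

    death_date = []
    icd_code = []
    icd_version = []
    emigration_date = []
    for t, c in zip(t_obs, cause):
        date = BASELINE_DATE + dt.timedelta(days=max(1, round(t * DAYS_PER_YEAR)))
        if c in ("cvd", "other"):
            death_date.append(date.isoformat())
            if date.year < 1996:
                icd_code.append("410" if c == "cvd" else "162")
                icd_version.append(9)
            else:
                icd_code.append("I21" if c == "cvd" else "C34")
                icd_version.append(10)
            emigration_date.append("")
        elif c == "emigrated":
            death_date.append("")
            icd_code.append("")
            icd_version.append("")
            emigration_date.append(date.isoformat())
        else:
            death_date.append("")
            icd_code.append("")
            icd_version.append("")
            emigration_date.append("")
    return pd.DataFrame(
        {
            "death_date": death_date,
            "icd_code": icd_code,
            "icd_version": icd_version,
            "emigration_date": emigration_date,
        }
    )


def _inject_missingness(
    cfg: SimulationConfig, raw: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    out = raw.copy()
    for col, rate in cfg.missingness.items():
        if rate <= 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def generate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a raw two-sex cohort in the schema the coding module consumes.

    Byte-reproducible for a given (config, seed); missingness is injected
    after event generation, so hazards always depend on true exposures.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    blocks = []
    offset = 0
    for sex in ("male", "female"):
        raw = _draw_sex_block(cfg, sex, rng)
        raw.insert(0, "id", np.arange(offset, offset + len(raw)))
        offset += len(raw)
        coded = coding.code_cohort(raw)
        linkage = _simulate_events(cfg, sex, coded, rng)
        raw = pd.concat([raw.reset_index(drop=True), linkage], axis=1)
        raw = _inject_missingness(cfg, raw, rng)
        blocks.append(raw)
    cohort = pd.concat(blocks, ignore_index=True)
    return cohort[coding.RAW_COLUMNS]


# ---------------------------------------------------------------------------
# calibration & scenarios


def calibrate_cvd_baseline(
    cfg: SimulationConfig, sex: str, target_fraction: float, n: int = 40000, seed: int = 12345
) -> float:
    """Baseline CVD hazard giving the target CVD-death fraction.

    Uses the closed-form cause-specific death probability given one large
    draw of covariates (so the solve is deterministic given the seed):
    P(CVD death) = E[ h_c / h_tot * (1 - exp(-h_tot * T)) ].
    """
    big = dataclasses.replace(cfg)
    big.n = {s: (n if s == sex else 10) for s in ("male", "female")}
    rng = np.random.default_rng(seed)
    raw = _draw_sex_block(big, sex, rng)
    raw.insert(0, "id", np.arange(len(raw)))
    coded = coding.code_cohort(raw)
    rr = np.exp(_linear_predictor(cfg, sex, coded))
    age = coded["age_baseline"].to_numpy(float)
    h_oth = cfg.other_mortality_rate[sex] * np.exp(cfg.other_age_log_hr * (age - 57.5))
    T = cfg.follow_up_years
    m = cfg.emigration_rate

    def frac(lam):
        h_c = lam * rr
        h_tot = h_c + h_oth + m
        return float(np.mean(h_c / h_tot * (1 - np.exp(-h_tot * T)))) - target_fraction

    return float(optimize.brentq(frac, 1e-6, 0.2))


def implied_mediated_ratio(
    cfg: SimulationConfig, sex: str, sep_level: str, n_mc: int = 40000, seed: int = 999
) -> float:
    """Rare-event mediated hazard-ratio component of one SEP level vs 4_high.

    Draws covariates with adulthood SEP pinned at the level (childhood SEP
    from its copula conditional), and returns
    E[exp(sum of covariate log-HRs) | level] / E[... | 4_high]. No survival
    data involved: the value comes from the coefficient construction.
    """
    means = {}
    for level in (sep_level, "4_high"):
        sub = dataclasses.replace(cfg)
        marg = [0.0, 0.0, 0.0, 0.0]
        marg[ADULT_SEP_ASC.index(level)] = 1.0
        # degenerate adulthood marginal: childhood then follows its own
        # marginal (the copula conditional is what the generator induces via
        # the joint pmf row); approximate by the conditional from the joint
        P = _joint_pmf(
            solve_copula_rho(
                cfg.sep_correlation,
                np.asarray(cfg.childhood_marginals, float),
                np.asarray(cfg.sep_marginals[sex], float),
            ),
            np.asarray(cfg.childhood_marginals, float),
            np.asarray(cfg.sep_marginals[sex], float),
        )
        j = ADULT_SEP_ASC.index(level)
        child_cond = P[:, j] / P[:, j].sum()
        sub.n = {s: (n_mc if s == sex else 10) for s in ("male", "female")}
        sub.sep_marginals = {s: tuple(marg) for s in ("male", "female")}
        sub.childhood_marginals = tuple(child_cond)
        sub.sep_correlation = 0.0
        rng = np.random.default_rng(seed)
        raw = _draw_sex_block(sub, sex, rng)
        raw.insert(0, "id", np.arange(len(raw)))
        coded = coding.code_cohort(raw)
        lp = np.zeros(len(coded))
        for cov, levels in cfg.covariate_log_hr[sex].items():
            values = coded[cov].astype(str).to_numpy()
            for lvl, b in levels.items():
                lp = lp + b * (values == lvl)
        child = coded["childhood_sep"].astype(str).to_numpy()
        for lvl, b in cfg.childhood_log_hr[sex].items():
            lp = lp + b * (child == lvl)
        means[level] = float(np.mean(np.exp(lp)))
    return means[sep_level] / means["4_high"]


def make_mediation_scenario(
    kind: str, config: SimulationConfig | None = None, n_mc: int = 40000, seed: int = 999
) -> SimulationConfig:
    """Configure a null / partial / full mediation scenario.

    null:    SEP affects the hazard only directly; risk factors carry no SEP
             gradient -> expected attenuation ~ 0.
    full:    no direct SEP effect; strongly SEP-graded risk factors carry the
             whole association -> expected attenuation ~ -100%.
    partial: both channels; the implied attenuation of the lowest SEP level
             is computed from the construction and recorded in
             ``implied_attenuation``.
    """
    cfg = dataclasses.replace(config or SimulationConfig())
    cfg.scenario = kind
    zero_grad = {k: (0.0, 0.0) for k in cfg.risk_gradients}
    cfg.childhood_log_hr = {s: {} for s in ("male", "female")}
    # non-mediator covariates become pure noise in every scenario: strong
    # nuisance effects would otherwise inflate the conditional SEP hazard
    # ratio on adjustment (non-collapsibility) and mask the mediation signal
    mediators = {
        "smoking": {"former": 0.0, "current": LN(1.85)},
        "physical_activity": {
            "moderately_active": LN(1.16),
            "little_active": LN(1.52),
            "inactive": LN(1.71),
        },
        "tenure": {"renter": LN(1.31)},
    }
    cfg.covariate_log_hr = {s: mediators for s in ("male", "female")}
    if kind == "null":
        cfg.risk_gradients = zero_grad
        # covariates are pure noise: no gradients and no hazard effects, so
        # the adjusted SEP hazard ratio is collapsible and attenuation is 0
        cfg.covariate_log_hr = {s: {} for s in ("male", "female")}
        cfg.direct_sep_log_hr = {
            s: {"1_low": LN(1.8), "2_mid_low": LN(1.35), "3_mid_high": LN(1.25)}
            for s in ("male", "female")
        }
        cfg.implied_attenuation = {"1_low": 0.0}
        return cfg
    if kind == "full":
        cfg.direct_sep_log_hr = {s: {} for s in ("male", "female")}
        cfg.risk_gradients = dict(
            zero_grad,
            smoking_current=(2.2, 0.0),
            activity=(-1.5, 0.0),
            tenure_renter=(2.0, 0.0),
        )
        cfg.implied_attenuation = {"1_low": -100.0}
        return cfg
    if kind == "partial":
        cfg.direct_sep_log_hr = {
            s: {"1_low": LN(1.35), "2_mid_low": LN(1.15), "3_mid_high": LN(1.10)}
            for s in ("male", "female")
        }
        cfg.risk_gradients = dict(
            zero_grad,
            smoking_current=(1.8, 0.0),
            activity=(-1.2, 0.0),
            tenure_renter=(1.6, 0.0),
        )
        implied = {}
        for sex in ("male",):
            R = implied_mediated_ratio(cfg, sex, "1_low", n_mc=n_mc, seed=seed)
            d = math.exp(cfg.direct_sep_log_hr[sex]["1_low"])
            implied["1_low"] = 100.0 * (d - d * R) / (d * R - 1.0)
        cfg.implied_attenuation = implied
        return cfg
    raise ConfigError(f"unknown scenario kind: {kind!r}")
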