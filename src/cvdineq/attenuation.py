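"""Hazard-ratio attenuation across nested models, BCa bootstrap intervals,
and the direct / indirect life-course decomposition.

The attenuation percentage quantifies how much of the excess hazard of a SEP
group (relative to the highest group) is removed by adding an explanatory
covariate block to the SEP-only model:

    attenuation% = 100 * (HR_adjusted - HR_base) / (HR_base - 1)

computed on the hazard-ratio scale (not the log scale). Negative values mean
the adjusted HR moved toward 1, i.e. the added block "explains" part of the
inequality. Confidence intervals around the attenuation are bias-corrected
accelerated (BCa) bootstrap intervals obtained by resampling participants and
refitting both models per resample.

The decomposition splits the total explained percentage (model 7, T) using
the childhood-only (model 2, C) and adulthood-only (model 6, A) attenuations:

    direct childhood   = T - A      (independent of adulthood risk factors)
    direct adulthood   = T - C      (independent of childhood conditions)
    indirect childhood = C + A - T  (childhood via adulthood risk factors)

These three components sum to T by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import MISSING
from .hazard_models import EstimationError, FittedModel, ModelSpec, fit_ph_model

#: |HR_base - 1| below which the attenuation denominator is too unstable
DEFAULT_NOT_EVALUABLE_BAND = 0.05


class BootstrapError(RuntimeError):
    pass


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def attenuation_percent(
    hr_base: float,
    hr_adj: float,
    not_evaluable_band: float = DEFAULT_NOT_EVALUABLE_BAND,
) -> float:
    """Percent change in the excess hazard between a base and adjusted model.

    Returns NaN (flagged not evaluable) when the base HR is within
    ``not_evaluable_band`` of 1, where the denominator is unstable.
    """
    if hr_base <= 0 or hr_adj <= 0:
        raise ValueError("hazard ratios must be positive")
    if abs(hr_base - 1.0) < not_evaluable_band:
        return float("nan")
    return 100.0 * (hr_adj - hr_base) / (hr_base - 1.0)


@dataclass(frozen=True)
class Decomposition:
    """Life-course split of the total explained percentage."""

    total_explained: float  # T: model-7 attenuation magnitude
    childhood_alone: float  # C: model-2 attenuation magnitude
    adulthood_alone: float  # A: model-6 attenuation magnitude

    @property
    def direct_childhood(self) -> float:
        return self.total_explained - self.adulthood_alone

    @property
    def direct_adulthood(self) -> float:
        return self.total_explained - self.childhood_alone

    @property
    def indirect_childhood(self) -> float:
        return self.childhood_alone + self.adulthood_alone - self.total_explained


def decompose(att_model2: float, att_model6: float, att_model7: float) -> Decomposition:
    """Build the decomposition from positive percent-explained magnitudes."""
    return Decomposition(
        total_explained=att_model7,
        childhood_alone=att_model2,
        adulthood_alone=att_model6,
    )


def decompose_from_attenuations(att2: float, att6: float, att7: float) -> Decomposition:
    """Same, but from signed attenuations (negative = explained)."""
    to_mag = lambda a: -a if np.isfinite(a) else 0.0
    return decompose(to_mag(att2), to_mag(att6), to_mag(att7))


def bca_interval(
    boot: np.ndarray,
    jack: np.ndarray,
    theta_hat: float,
    level: float = 0.95,
) -> tuple[float, float, list[str]]:
    """Bias-corrected accelerated bootstrap interval (Efron).

    ``boot`` are bootstrap replicates of the statistic, ``jack`` jackknife
    (leave-one-out or grouped leave-k-out) replicates, ``theta_hat`` the
    point estimate on the original data.

    Degenerate cases fall back with a flag: all bootstrap values on one side
    of the estimate -> plain percentile interval; zero jackknife variance ->
    acceleration 0.
    """
    boot = np.asarray(boot, float)
    boot = boot[np.isfinite(boot)]
    if boot.size < 2 or np.unique(boot).size < 2:
        raise BootstrapError("need >= 2 distinct finite bootstrap values")
    flags: list[str] = []
    alpha = (1.0 - level) / 2.0

    prop = np.mean(boot < theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        flags.append("percentile_fallback")
        lo, hi = np.quantile(boot, [alpha, 1 - alpha])
        return float(lo), float(hi), flags
    z0 = stats.norm.ppf(prop)

    jack = np.asarray(jack, float)
    jack = jack[np.isfinite(jack)]
    if jack.size >= 2:
        d = jack.mean() - jack
        denom = np.sum(d**2) ** 1.5
        if denom > 0:
            a = np.sum(d**3) / (6.0 * denom)
        else:
            a = 0.0
            flags.append("zero_jackknife_variance")
    else:
        a = 0.0
        flags.append("zero_jackknife_variance")

    out = []
    for alph in (alpha, 1 - alpha):
        z = stats.norm.ppf(alph)
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(boot, np.clip(stats.norm.cdf(adj), 0.0, 1.0))))
    return out[0], out[1], flags


@dataclass
class AttenuationResult:
    sex: str
    sep_level: str
    model_id: int
    hr_base: float
    hr_adj: float
    attenuation_pct: float
    ci_low_pct: float = float("nan")
    ci_high_pct: float = float("nan")
    n_boot: int = 0
    n_discarded: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def evaluable(self) -> bool:
        return np.isfinite(self.attenuation_pct)


def attenuation_from_fits(
    fit_base: FittedModel,
    fit_adj: FittedModel,
    sep_levels: list[str],
    sex: str = "",
    not_evaluable_band: float = DEFAULT_NOT_EVALUABLE_BAND,
) -> dict[str, AttenuationResult]:
    """Point attenuations per non-reference SEP level from two fitted models."""
    out = {}
    for level in sep_levels:
        hr_b = fit_base.hazard_ratio("adulthood_sep", level)
        hr_a = fit_adj.hazard_ratio("adulthood_sep", level)
        out[level] = AttenuationResult(
            sex=sex,
            sep_level=level,
            model_id=fit_adj.model_id,
            hr_base=hr_b,
            hr_adj=hr_a,
            attenuation_pct=attenuation_percent(hr_b, hr_a, not_evaluable_band),
        )
    return out


def _jackknife_groups(n: int, rng: np.random.Generator, max_groups: int = 200) -> list[np.ndarray]:
    """Leave-one-out below n=2000; otherwise ~200 seeded random groups."""
    if n <= 2000:
        return [np.array([i]) for i in range(n)]
    perm = rng.permutation(n)
    return [g for g in np.array_split(perm, max_groups) if g.size]


def bootstrap_attenuation(
    survival: pd.DataFrame,
    coded: pd.DataFrame,
    spec_base: ModelSpec,
    spec_adj: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    sex: str = "",
    sep_levels: list[str] | None = None,
    ties: str = "breslow",
    level: float = 0.95,
    max_discard_frac: float = 0.10,
) -> dict[str, AttenuationResult]:
    """Attenuation per SEP level with BCa intervals, resampling participants.

    Both models are refit on every resample so that the interval propagates
    the joint sampling noise of base and adjusted hazard ratios. Resamples
    with no events or a non-convergent fit are discarded and redrawn; more
    than ``max_discard_frac * B`` discards aborts.
    """
    if B < 2:
        raise BootstrapError("need B >= 2 resamples")
    if sep_levels is None:
        sep_levels = [
            l
            for l in coded["adulthood_sep"].astype(str).unique()
            if l not in ("4_high", MISSING)
        ]
        sep_levels.sort()
    rng = np.random.default_rng(seed)
    n = len(survival)
    surv = survival.reset_index(drop=True)
    cov = coded.reset_index(drop=True)

    fit_b = fit_ph_model(surv, cov, spec_base, ties=ties)
    fit_a = fit_ph_model(surv, cov, spec_adj, ties=ties)
    point = attenuation_from_fits(fit_b, fit_a, sep_levels, sex=sex)

    def statistic(idx: np.ndarray) -> dict[str, float]:
        s = surv.iloc[idx].reset_index(drop=True)
        c = cov.iloc[idx].reset_index(drop=True)
        fb = fit_ph_model(s, c, spec_base, ties=ties)
        fa = fit_ph_model(s, c, spec_adj, ties=ties)
        return {
            lvl: attenuation_percent(
                fb.hazard_ratio("adulthood_sep", lvl), fa.hazard_ratio("adulthood_sep", lvl)
            )
            for lvl in sep_levels
        }

    boot: dict[str, list[float]] = {lvl: [] for lvl in sep_levels}
    discarded = 0
    max_discards = max(1, int(max_discard_frac * B))
    drawn = 0
    while drawn < B:
        idx = rng.integers(0, n, n)
        try:
            values = statistic(idx)
        except (EstimationError, KeyError):
            discarded += 1
            if discarded > max_discards:
                raise BootstrapError(
                    f"{discarded} discarded resamples out of {drawn + discarded} "
                    f"exceeds {max_discard_frac:.0%} of B={B}"
                )
            continue
        for lvl in sep_levels:
            boot[lvl].append(values[lvl])
        drawn += 1

    groups = _jackknife_groups(n, rng)
    jack: dict[str, list[float]] = {lvl: [] for lvl in sep_levels}
    all_idx = np.arange(n)
    for g in groups:
        keep = np.setdiff1d(all_idx, g, assume_unique=True)
        try:
            values = statistic(keep)
        except EstimationError:
            continue
        for lvl in sep_levels:
            jack[lvl].append(values[lvl])

    out = {}
    for lvl in sep_levels:
        res = point[lvl]
        res.n_boot = B
        res.n_discarded = discarded
        res.seed = seed
        if res.evaluable:
            lo, hi, flags = bca_interval(
                np.array(boot[lvl]), np.array(jack[lvl]), res.attenuation_pct, level
            )
            res.ci_low_pct, res.ci_high_pct = lo, hi
            res.flags = flags
        else:
            res.flags = ["not_evaluable"]
        out[lvl] = res
    return out
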