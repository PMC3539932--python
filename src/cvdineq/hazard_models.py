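"""Sex-stratified age-adjusted proportional-hazards models.

Implements the nested explanatory model sequence

    1: adulthood SEP
    2: 1 + childhood SEP
    3: 1 + material factors
    4: 1 + behavioural factors
    5: 1 + psychosocial factors
    6: 1 + material + behavioural + psychosocial
    7: 6 + childhood SEP

(every model additionally adjusted for continuous age), and the screening
rule that admits a risk factor into the explanatory blocks only when it is
both associated with CVD mortality and unequally distributed across the
adulthood SEP groups.

Estimation is by Cox partial likelihood (Breslow ties by default, Efron
selectable), via the in-package Newton-Raphson solver (``cvdineq._cox``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxError, cox_fit
from .coding import BLOCKS, COVARIATE_LEVELS, MISSING


class EstimationError(RuntimeError):
    pass


class AssociationTestError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Covariate-block composition of one explanatory model.

    ``covariate_list`` overrides the default block membership (used after
    factor screening restricts the material / behavioural / psychosocial
    blocks to the selected factors).
    """

    model_id: int
    blocks: tuple[str, ...]
    covariate_list: tuple[str, ...] | None = None

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.covariate_list is not None:
            return self.covariate_list
        out: list[str] = []
        for block in self.blocks:
            out.extend(BLOCKS[block])
        return tuple(out)


MODEL_SEQUENCE: Mapping[int, ModelSpec] = {
    1: ModelSpec(1, ("adulthood_sep",)),
    2: ModelSpec(2, ("adulthood_sep", "childhood_sep")),
    3: ModelSpec(3, ("adulthood_sep", "material")),
    4: ModelSpec(4, ("adulthood_sep", "behavioural")),
    5: ModelSpec(5, ("adulthood_sep", "psychosocial")),
    6: ModelSpec(6, ("adulthood_sep", "material", "behavioural", "psychosocial")),
    7: ModelSpec(
        7, ("adulthood_sep", "childhood_sep", "material", "behavioural", "psychosocial")
    ),
}


@dataclass
class FittedModel:
    model_id: int
    terms: pd.DataFrame  # covariate, level, coef, se, hr, ci_low, ci_high, p_value
    n: int
    n_events: int
    log_partial_likelihood: float
    ties: str

    def hazard_ratio(self, covariate: str, level: str) -> float:
        sel = (self.terms["covariate"] == covariate) & (self.terms["level"] == level)
        if not sel.any():
            raise KeyError(f"no term {covariate}={level}")
        return float(self.terms.loc[sel, "hr"].iloc[0])


@dataclass
class FactorSelection:
    sex: str
    alpha: float
    evidence: pd.DataFrame  # covariate, block, p_mortality, p_sep, selected
    selected: dict[str, list[str]] = field(default_factory=dict)


def build_design(
    coded: pd.DataFrame,
    covariates: Sequence[str],
    levels: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Dummy-code covariates against their reference (first) level.

    Only levels observed in the data get a column; MISSING levels are coded
    like any substantive level. Returns the design matrix and the
    (covariate, level) label of each column.
    """
    levels = levels or COVARIATE_LEVELS
    cols: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    for cov in covariates:
        values = coded[cov].astype(str).to_numpy()
        cov_levels = levels[cov]
        unknown = set(values) - set(cov_levels)
        if unknown:
            raise EstimationError(f"unknown levels for {cov}: {sorted(unknown)}")
        for level in cov_levels[1:]:
            indicator = (values == level).astype(float)
            if indicator.any():
                cols.append(indicator)
                labels.append((cov, level))
    X = np.column_stack(cols) if cols else np.empty((len(coded), 0))
    return X, labels


def _fit_phreg(
    time: np.ndarray, event: np.ndarray, X: np.ndarray, ties: str
) -> tuple[np.ndarray, np.ndarray, float]:
    try:
        res = cox_fit(time, event, X, ties=ties)
    except CoxError as exc:
        raise EstimationError(f"partial-likelihood maximization failed: {exc}") from exc
    params = res.params
    se = res.bse
    if not res.converged:
        raise EstimationError(
            f"no convergence in {res.n_iter} iterations "
            f"(|g|max = {np.abs(res.score).max():.2e})"
        )
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(se))):
        raise EstimationError("non-finite estimates (possible separation)")
    if np.any(np.abs(params) > 15):
        raise EstimationError(
            f"divergent coefficient (|b|max = {np.abs(params).max():.1f}); "
            "likely complete separation"
        )
    return params, se, float(res.loglik)


def fit_ph_model(
    survival: pd.DataFrame,
    coded: pd.DataFrame,
    spec: ModelSpec,
    ties: str = "breslow",
    extra_covariates: Sequence[str] = (),
) -> FittedModel:
    """Fit one explanatory model on an id-aligned survival + covariate table.

    ``survival`` needs time_years and event; ``coded`` the covariate levels
    plus age_baseline (always entered as a continuous adjustment).
    """
    if len(survival) != len(coded):
        raise EstimationError("survival and covariate tables differ in length")
    time = survival["time_years"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    if event.sum() == 0:
        raise EstimationError("no events in the analytic data")

    covariates = tuple(spec.covariates) + tuple(extra_covariates)
    X_cat, labels = build_design(coded, covariates)
    # a dummy level whose carriers have no events has an infinite ML
    # coefficient; such columns carry no hazard information and are dropped
    keep = [j for j in range(X_cat.shape[1]) if X_cat[event == 1, j].sum() > 0]
    X_cat = X_cat[:, keep]
    labels = [labels[j] for j in keep]
    age = coded["age_baseline"].to_numpy(float)[:, None]
    X = np.hstack([age, X_cat])
    all_labels = [("age", "linear")] + labels

    params, se, llf = _fit_phreg(time, event, X, ties)
    z = 0.975
    crit = stats.norm.ppf(z)
    terms = pd.DataFrame(
        {
            "covariate": [c for c, _ in all_labels],
            "level": [l for _, l in all_labels],
            "coef": params,
            "se": se,
            "hr": np.exp(params),
            "ci_low": np.exp(params - crit * se),
            "ci_high": np.exp(params + crit * se),
            "p_value": 2 * stats.norm.sf(np.abs(params / se)),
        }
    )
    return FittedModel(
        model_id=spec.model_id,
        terms=terms,
        n=len(survival),
        n_events=int(event.sum()),
        log_partial_likelihood=llf,
        ties=ties,
    )


def test_sep_association(coded_covariate: pd.Series, adulthood_sep: pd.Series) -> float:
    """Pearson chi-square p for covariate distribution varying by adulthood SEP.

    MISSING levels of the covariate are excluded from the table; the test is
    on the substantive levels only.
    """
    mask = (coded_covariate.astype(str) != MISSING) & (adulthood_sep.astype(str) != MISSING)
    table = pd.crosstab(coded_covariate[mask], adulthood_sep[mask])
    if table.size == 0 or min(table.shape) < 2:
        raise AssociationTestError(f"degenerate contingency table:\n{table}")
    stat, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected == 0):
        raise AssociationTestError(f"zero expected cell count in table:\n{table}")
    return float(p)


def lr_test_covariate(
    survival: pd.DataFrame,
    coded: pd.DataFrame,
    covariate: str,
    adjust_for: Sequence[str] = ("adulthood_sep", "childhood_sep"),
    ties: str = "breslow",
) -> float:
    """Likelihood-ratio p-value for a covariate's substantive dummy block.

    The full model contains age, the adjustment covariates and all dummies of
    the covariate; the reduced model keeps the MISSING dummy (so incomplete
    respondents stay comparable) and drops only the substantive levels.
    df = number of substantive non-reference levels.
    """
    time = survival["time_years"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    age = coded["age_baseline"].to_numpy(float)[:, None]

    X_adj, _ = build_design(coded, adjust_for)
    X_cov, cov_labels = build_design(coded, [covariate])
    substantive = [i for i, (_, lvl) in enumerate(cov_labels) if lvl != MISSING]
    missing_cols = [i for i, (_, lvl) in enumerate(cov_labels) if lvl == MISSING]
    if not substantive:
        raise EstimationError(f"{covariate} has no substantive non-reference levels")

    X_full = np.hstack([age, X_adj, X_cov])
    X_red = np.hstack([age, X_adj, X_cov[:, missing_cols]])
    _, _, ll_full = _fit_phreg(time, event, X_full, ties)
    _, _, ll_red = _fit_phreg(time, event, X_red, ties)
    lr = max(0.0, 2 * (ll_full - ll_red))
    return float(stats.chi2.sf(lr, df=len(substantive)))


def select_factors(
    survival: pd.DataFrame,
    coded: pd.DataFrame,
    sex: str,
    alpha: float = 0.05,
    candidates: Sequence[str] | None = None,
    ties: str = "breslow",
) -> FactorSelection:
    """Screen candidate risk factors for inclusion in the explanatory blocks.

    A factor is selected iff it is significantly associated with CVD mortality
    (LR test, adjusted for age, childhood SEP and adulthood SEP) AND its
    distribution varies by adulthood SEP (chi-square), both at ``alpha``.
    """
    if candidates is None:
        candidates = [c for b in ("material", "behavioural", "psychosocial") for c in BLOCKS[b]]
    block_of = {c: b for b in BLOCKS for c in BLOCKS[b]}

    rows = []
    for cov in candidates:
        try:
            p_mort = lr_test_covariate(survival, coded, cov, ties=ties)
        except EstimationError as exc:
            rows.append(
                {
                    "covariate": cov,
                    "block": block_of[cov],
                    "p_mortality": np.nan,
                    "p_sep": np.nan,
                    "selected": False,
                    "note": str(exc),
                }
            )
            continue
        p_sep = test_sep_association(coded[cov], coded["adulthood_sep"])
        rows.append(
            {
                "covariate": cov,
                "block": block_of[cov],
                "p_mortality": p_mort,
                "p_sep": p_sep,
                "selected": bool(p_mort < alpha and p_sep < alpha),
                "note": "",
            }
        )
    evidence = pd.DataFrame(rows)
    selected: dict[str, list[str]] = {}
    for _, row in evidence[evidence["selected"]].iterrows():
        selected.setdefault(row["block"], []).append(row["covariate"])
    return FactorSelection(sex=sex, alpha=alpha, evidence=evidence, selected=selected)


def restrict_blocks(selection: FactorSelection) -> dict[str, tuple[str, ...]]:
    """Block membership restricted to the selected factors (SEP blocks kept)."""
    blocks = {
        "adulthood_sep": BLOCKS["adulthood_sep"],
        "childhood_sep": BLOCKS["childhood_sep"],
    }
    for block in ("material", "behavioural", "psychosocial"):
        blocks[block] = tuple(selection.selected.get(block, ()))
    return blocks


def fit_model_sequence(
    survival: pd.DataFrame,
    coded: pd.DataFrame,
    blocks: Mapping[str, Sequence[str]] | None = None,
    ties: str = "breslow",
    model_ids: Sequence[int] = tuple(range(1, 8)),
) -> dict[int, FittedModel]:
    """Fit the nested models, optionally with screened block membership."""
    fits = {}
    for mid in model_ids:
        spec = MODEL_SEQUENCE[mid]
        if blocks is not None:
            covs = tuple(c for b in spec.blocks for c in blocks.get(b, BLOCKS[b]))
            spec = ModelSpec(mid, spec.blocks, covariate_list=covs)
        fits[mid] = fit_ph_model(survival, coded, spec, ties=ties)
    return fits
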