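"""ICD-10 misclassification of law-enforcement-related deaths.

A matched death is *misclassified* when none of its multiple-cause ICD-10
codes falls in the legal-intervention set (Y35.0-Y35.4, Y35.6, Y35.7,
Y89.0; legal execution Y35.5 is excluded).  This module classifies
records, groups underlying causes into the reporting categories used for
cause-of-death tabulations, produces stratified misclassification tables
with exact binomial intervals and chi-squared tests, bands states by rate
and case count, and fits the nested random-intercept logistic model for
correlates of misclassification together with marginal predicted
probabilities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .glmm import NestedLogisticFit, fit_nested_logistic
from .matching import clopper_pearson

__all__ = [
    "CAUSE_CATEGORIES",
    "is_legal_intervention",
    "group_underlying_cause",
    "tabulate_misclassification",
    "state_rate_bands",
    "MisclassificationFit",
    "fit_multilevel_logistic",
    "marginal_probabilities",
    "REFERENCE_LEVELS",
]

CAUSE_CATEGORIES = (
    "legal_intervention",
    "assault",
    "undetermined_or_missing",
    "suicide",
    "accident",
    "circulatory_respiratory",
    "mental_behavioral",
    "other",
)

_LEGAL_SET = frozenset({"Y350", "Y351", "Y352", "Y353", "Y354", "Y356", "Y357", "Y890"})
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")

#: reference levels for the regression design (most common / benchmark groups)
REFERENCE_LEVELS = {
    "age_group": "18_44",
    "gender": "man",
    "race_ethnicity": "white",
    "mechanism_group": "firearm",
    "investigator_type": "medical_examiner",
    "urbanicity": "medium_metro",
    "income_quintile": "5",
}


def normalize_icd(code: str) -> str:
    """Uppercase, drop the decimal point, validate letter + 2 digits (+1)."""
    if code is None or (isinstance(code, float) and np.isnan(code)):
        raise ValueError("missing ICD-10 code")
    norm = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(norm):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return norm


def is_legal_intervention(multiple_causes) -> bool:
    """True when any multiple-cause code is a legal-intervention code.

    Accepts an iterable of codes or a single ';'-joined string.  An empty
    code list is a validation error (every death record carries at least
    its underlying cause).
    """
    if isinstance(multiple_causes, str):
        multiple_causes = [c for c in multiple_causes.split(";") if c.strip()]
    codes = [normalize_icd(c) for c in multiple_causes]
    if not codes:
        raise ValueError("record has no ICD-10 cause codes")
    return any(c in _LEGAL_SET for c in codes)


def group_underlying_cause(code: str) -> str:
    """Map an underlying-cause ICD-10 code to its reporting category.

    Ranges are checked in a fixed order on the normalized 3-character
    category (legal execution Y35.5 falls through to 'other').
    """
    norm = normalize_icd(code)
    cat = norm[:3]
    if (cat == "Y35" and norm != "Y355") or norm == "Y890":
        return "legal_intervention"
    if "X95" <= cat <= "Y09":
        return "assault"
    if "Y10" <= cat <= "Y34" or cat == "R99":
        return "undetermined_or_missing"
    if "X60" <= cat <= "X84":
        return "suicide"
    if "V01" <= cat <= "X59":
        return "accident"
    if "I00" <= cat <= "J99":
        return "circulatory_respiratory"
    if "F00" <= cat <= "F99":
        return "mental_behavioral"
    return "other"


def tabulate_misclassification(
    records: pd.DataFrame, covariate: str, level: float = 0.95
) -> pd.DataFrame:
    """Stratified misclassification table for one covariate.

    ``records`` needs a boolean ``misclassified`` column.  Each stratum
    row reports misclassified / properly classified counts, the percent
    misclassified with a Clopper-Pearson interval, and the chi-squared
    test of independence over the non-missing strata (no continuity
    correction; the 'missing' stratum is shown but excluded from the
    test).
    """
    if "misclassified" not in records.columns:
        raise ValueError("records need a boolean 'misclassified' column")
    values = records[covariate].astype(object).where(~records[covariate].isna(), "missing")
    levels = list(pd.unique(values))
    if not levels:
        raise ValueError("no strata for covariate " + covariate)

    cells = []
    for lv in levels:
        sub = records.loc[values == lv, "misclassified"].astype(bool)
        cells.append((lv, int(sub.sum()), int((~sub).sum())))

    test_cells = [(m, p) for lv, m, p in cells if lv != "missing"]
    if len(test_cells) >= 2 and all(m + p > 0 for m, p in test_cells):
        chi2, pval, _, _ = stats.chi2_contingency(np.array(test_cells), correction=False)
    else:
        chi2, pval = np.nan, np.nan

    rows = []
    for lv, m, p in cells:
        lo, hi = clopper_pearson(m, m + p, level)
        rows.append(
            {
                "covariate": covariate,
                "level": lv,
                "misclassified": m,
                "properly_classified": p,
                "total": m + p,
                "percent_misclassified": 100.0 * m / (m + p),
                "ci_low": 100.0 * lo,
                "ci_high": 100.0 * hi,
                "chi2": chi2,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def _rate_band(rate: float) -> str:
    if rate < 20:
        return "<20%"
    if rate < 40:
        return "20 to <40%"
    if rate < 60:
        return "40 to <60%"
    if rate < 80:
        return "60 to <80%"
    return ">=80%"


def state_rate_bands(records: pd.DataFrame) -> pd.DataFrame:
    """Per-state misclassification rates with rate and case-count bands.

    Bands are closed-open: rate bands <20, 20-<40, 40-<60, 60-<80, >=80
    percent; count bands <10, 10-<20, >=20 deaths.  States with no cases
    are absent.
    """
    if records["state"].isna().any():
        raise ValueError("state missing on some records")
    grouped = records.groupby("state")["misclassified"].agg(["sum", "count"])
    out = []
    for state, (mis, n) in grouped.iterrows():
        rate = 100.0 * mis / n
        rate_band = _rate_band(rate)
        count_band = "<10" if n < 10 else ("10 to <20" if n < 20 else ">=20")
        out.append(
            {
                "state": state,
                "deaths": int(n),
                "misclassified": int(mis),
                "percent_misclassified": rate,
                "rate_band": rate_band,
                "count_band": count_band,
            }
        )
    return pd.DataFrame(out).sort_values("state").reset_index(drop=True)


@dataclass
class MisclassificationFit:
    """Mixed-model results for correlates of misclassification."""

    model: NestedLogisticFit
    or_table: pd.DataFrame
    sigma2_county: float
    sigma2_state: float
    design_info: dict

    @property
    def converged(self) -> bool:
        return self.model.converged


def _build_design(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(records))}, index=records.index)
    for cov in covariates:
        ref = REFERENCE_LEVELS.get(cov)
        values = records[cov].astype(str)
        levels = [lv for lv in pd.unique(values) if lv != ref]
        if ref is not None and ref not in set(values):
            levels = levels[1:]  # degenerate: first observed level as reference
        for lv in sorted(levels):
            X[f"{cov}[{lv}]"] = (values == lv).astype(float)
    return X


def _design_from_params(frame: pd.DataFrame, param_names: list[str]) -> pd.DataFrame:
    """Reconstruct a design matrix from fitted coefficient names 'cov[level]'."""
    X = pd.DataFrame(index=frame.index)
    for name in param_names:
        if name == "intercept":
            X[name] = 1.0
            continue
        m = re.match(r"^(.*)\[(.*)\]$", name)
        if m is None:
            raise ValueError(f"cannot map coefficient {name!r} back to a covariate level")
        X[name] = (frame[m.group(1)].astype(str) == m.group(2)).astype(float)
    return X


def fit_multilevel_logistic(
    records: pd.DataFrame,
    counties: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    mode: str = "multivariable",
) -> MisclassificationFit | dict[str, MisclassificationFit]:
    """Fit the nested random-intercept logistic model for misclassification.

    ``records`` needs ``misclassified``, ``county_id``, ``state`` and the
    requested covariate columns (county-level covariates are joined from
    ``counties`` when absent).  ``mode`` is 'multivariable' (all
    covariates at once) or 'univariable' (one fit per covariate, random
    intercepts retained; returns a dict keyed by covariate).
    """
    records = records.copy()
    if counties is not None:
        county_cols = [
            c for c in ("income_quintile", "urbanicity", "investigator_type")
            if c not in records.columns
        ]
        if county_cols:
            records = records.merge(
                counties[["county_id"] + county_cols], on="county_id", how="left"
            )
    if covariates is None:
        covariates = [c for c in REFERENCE_LEVELS if c in records.columns]
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")

    y = records["misclassified"].astype(float).to_numpy()

    def _single(covs: list[str]) -> MisclassificationFit:
        X = _build_design(records, covs)
        fit = fit_nested_logistic(y, X, records["county_id"], records["state"])
        return MisclassificationFit(
            model=fit,
            or_table=fit.summary_table(),
            sigma2_county=fit.sigma2_county,
            sigma2_state=fit.sigma2_state,
            design_info={"covariates": covs, "reference_levels": REFERENCE_LEVELS},
        )

    if mode == "multivariable":
        return _single(covariates)
    if mode == "univariable":
        return {cov: _single([cov]) for cov in covariates}
    raise ValueError("mode must be 'multivariable' or 'univariable'")


def marginal_probabilities(
    fit: MisclassificationFit, records: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Average predicted misclassification probability per level of a variable.

    For each level, the variable is fixed at that level for every record,
    all other covariates stay at their observed values, random intercepts
    are set to zero, and predicted probabilities are averaged.  Intervals
    are delta-method Wald intervals over the fixed-effect covariance.
    """
    if not fit.converged:
        raise ValueError("model did not converge; marginal predictions unavailable")
    covariates = fit.design_info["covariates"]
    if variable not in covariates:
        raise ValueError(f"{variable!r} was not in the fitted model")
    beta = fit.model.params
    cov = fit.model.cov_params.to_numpy()
    levels = sorted(pd.unique(records[variable].astype(str)))

    rows = []
    for lv in levels:
        pseudo = records.copy()
        pseudo[variable] = lv
        X = _design_from_params(pseudo, list(beta.index))
        eta = X.to_numpy() @ beta.to_numpy()
        p = expit(eta)
        grad = (p * (1 - p))[:, None] * X.to_numpy()
        g = grad.mean(axis=0)
        se = float(np.sqrt(g @ cov @ g))
        est = float(p.mean())
        rows.append(
            {
                "level": lv,
                "probability": est,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
            }
        )
    return pd.DataFrame(rows)
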