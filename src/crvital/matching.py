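"""Deterministic linkage of media-registry cases to mortality records.

Mirrors a National-Death-Index-style deterministic pass: candidate pairs
need a case-insensitive exact first name, a near-match surname (Levenshtein
distance within a threshold), and year of birth within +/- 1 of the year
derived from the media-reported age.  Candidates are then confirmed on
death date (within 4 days of the injury date) and state; later deaths or
differing states survive only when the case carries an external
news-confirmation flag.  Ambiguous ties are reported unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb, gammaln

__all__ = [
    "MatchRules",
    "match_records",
    "summarize_match_rates",
    "fisher_exact_rxc",
    "clopper_pearson",
]


@dataclass(frozen=True)
class MatchRules:
    surname_max_edit: int = 2
    birth_year_tolerance: int = 1
    death_window_days: int = 4


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a.lower(), b.lower(), task="distance")["editDistance"]


def match_records(
    incidents: pd.DataFrame,
    mortality: pd.DataFrame,
    rules: MatchRules | None = None,
    study_year: int | None = None,
) -> pd.DataFrame:
    """Link each incident to at most one mortality record.

    Returns a frame with one row per incident: ``incident_id``,
    ``mortality_id`` (NA when unmatched), ``status`` in {matched,
    matched_with_confirmation, unmatched} and a ``criteria_log`` string.
    """
    rules = rules or MatchRules()
    if mortality["record_id"].duplicated().any():
        raise ValueError("duplicate mortality record ids")
    if study_year is None:
        study_year = int(pd.to_datetime(incidents["injury_date"]).dt.year.mode().iloc[0])

    # block on lowercase first name
    blocks: dict[str, list[int]] = {}
    for idx, name in enumerate(mortality["given_name"].astype(str)):
        blocks.setdefault(name.lower(), []).append(idx)
    m_surname = mortality["surname"].astype(str).to_numpy()
    m_birth = pd.to_numeric(mortality["birth_year"]).to_numpy()
    m_death = pd.to_datetime(mortality["death_date"]).to_numpy()
    m_state = mortality["death_state"].astype(str).to_numpy()
    m_id = mortality["record_id"].to_numpy()

    out = []
    for _, inc in incidents.iterrows():
        log: list[str] = []
        injury = pd.Timestamp(inc["injury_date"])
        confirmed = bool(inc.get("external_confirmation", False))
        age = inc.get("age")
        if age is None or pd.isna(age):
            out.append((inc["record_id"], None, "unmatched", "no_age:birth_year_underivable"))
            continue
        derived_birth = study_year - int(age)

        candidates = []
        for j in blocks.get(str(inc["given_name"]).lower(), []):
            if abs(m_birth[j] - derived_birth) > rules.birth_year_tolerance:
                continue
            if _edit_distance(str(inc["surname"]), m_surname[j]) > rules.surname_max_edit:
                continue
            delta = int((pd.Timestamp(m_death[j]) - injury).days)
            same_state = m_state[j] == str(inc["state"])
            if delta < -rules.death_window_days:
                log.append(f"{m_id[j]}:rejected_death_precedes_injury")
                continue
            if abs(delta) <= rules.death_window_days and same_state:
                candidates.append((j, abs(delta), "matched"))
                log.append(f"{m_id[j]}:date_state_ok")
            elif confirmed:
                candidates.append((j, abs(delta), "matched_with_confirmation"))
                log.append(f"{m_id[j]}:confirmed_late_or_out_of_state")
            else:
                log.append(f"{m_id[j]}:rejected_unconfirmed_date_or_state")

        if not candidates:
            out.append((inc["record_id"], None, "unmatched", ";".join(log) or "no_candidates"))
            continue
        candidates.sort(key=lambda c: c[1])
        if len(candidates) > 1 and candidates[0][1] == candidates[1][1]:
            out.append((inc["record_id"], None, "unmatched", "ambiguous_tie;" + ";".join(log)))
            continue
        j, _, status = candidates[0]
        out.append((inc["record_id"], m_id[j], status, ";".join(log)))

    return pd.DataFrame(out, columns=["incident_id", "mortality_id", "status", "criteria_log"])


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n <= 0:
        raise ValueError("n must be positive")
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else stats.beta.ppf(a, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - a, k + 1, n - k)
    return float(lo), float(hi)


def _fisher_exact_rx2(table: np.ndarray) -> float:
    """Exhaustive Fisher exact test for an r x 2 table.

    Conditional on all margins, P(table) = prod_i C(r_i, a_i) / C(N, c1);
    the p-value sums tables no more probable than the observed one.
    """
    rows = table.sum(axis=1).astype(int)
    c1 = int(table[:, 0].sum())
    logC = [gammaln(r + 1) - gammaln(np.arange(r + 1) + 1) - gammaln(r - np.arange(r + 1) + 1)
            for r in rows]
    n_total = int(rows.sum())
    log_denom = gammaln(n_total + 1) - gammaln(c1 + 1) - gammaln(n_total - c1 + 1)

    log_p_obs = sum(lc[int(a)] for lc, a in zip(logC, table[:, 0])) - log_denom
    tail_sums = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])
    r = len(rows)

    # recursive enumeration over first-column entries; the last rows are
    # evaluated as one vectorized broadcast sweep (range widths are bounded
    # by the smaller column margin, so the tree stays narrow)
    def leaf2(remaining: int, acc: float) -> float:
        i = r - 2
        lo = max(0, remaining - int(rows[i + 1]))
        hi = min(int(rows[i]), remaining)
        if lo > hi:
            return 0.0
        a = np.arange(lo, hi + 1)
        lp = acc + logC[i][a] + logC[i + 1][remaining - a] - log_denom
        return float(np.exp(lp[lp <= log_p_obs + 1e-7]).sum())

    def leaf3(remaining: int, acc: float) -> float:
        i = r - 3
        a = np.arange(0, min(int(rows[i]), remaining) + 1)
        b = np.arange(0, min(int(rows[i + 1]), remaining) + 1)
        c = remaining - a[:, None] - b[None, :]
        valid = (c >= 0) & (c <= int(rows[i + 2]))
        lp = np.full(valid.shape, -np.inf)
        cc = np.clip(c, 0, int(rows[i + 2]))
        lp[valid] = (
            acc
            + (logC[i][a][:, None] + logC[i + 1][b][None, :] + logC[i + 2][cc])[valid]
            - log_denom
        )
        return float(np.exp(lp[lp <= log_p_obs + 1e-7]).sum())

    def rec(i: int, remaining: int, acc: float) -> float:
        if r >= 3 and i == r - 3:
            return leaf3(remaining, acc)
        if i == r - 2:
            return leaf2(remaining, acc)
        total = 0.0
        lo = max(0, remaining - int(tail_sums[i]))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            total += rec(i + 1, remaining - a, acc + float(logC[i][a]))
        return total

    return float(min(1.0, rec(0, c1, 0.0)))


def fisher_exact_rxc(
    table: np.ndarray,
    exhaustive_max_total: int = 2000,
    exhaustive_max_tables: float = 5e6,
    mc_draws: int = 200_000,
    seed: int = 20150101,
) -> float:
    """Fisher exact test of independence for an r x c contingency table.

    2 x 2 tables use the classical exact test; r x 2 tables are enumerated
    exhaustively when the total is at most ``exhaustive_max_total`` and the
    margin-constrained table space is small enough; anything larger is
    handled by Monte Carlo over tables with fixed margins (seeded, at
    least ``mc_draws`` draws, reported with the add-one estimator).
    """
    table = np.asarray(table, dtype=int)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with nonzero margins")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    if table.shape[1] == 2 and table.sum() <= exhaustive_max_total:
        r = table.shape[0]
        n_tables_bound = comb(min(table.sum(axis=0)) + r - 1, r - 1)
        if n_tables_bound <= exhaustive_max_tables:
            return _fisher_exact_rx2(table)

    # Monte Carlo: probability of a table given margins via permanent-free formula
    def log_prob(t: np.ndarray) -> float:
        return float(
            gammaln(t.sum(axis=1) + 1).sum()
            + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(t.sum() + 1)
            - gammaln(t + 1).sum()
        )

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = sampler.rvs(size=mc_draws, random_state=rng)
    lp_obs = log_prob(table)
    lp = (
        gammaln(draws + 1).sum(axis=(1, 2)) * -1
        + gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(table.sum() + 1)
    )
    hits = int((lp <= lp_obs + 1e-7).sum())
    return (hits + 1) / (mc_draws + 1)


def summarize_match_rates(
    results: pd.DataFrame,
    incidents: pd.DataFrame,
    covariates: list[str],
    level: float = 0.95,
) -> pd.DataFrame:
    """Stratified match-rate table with exact binomial CIs and Fisher tests.

    A 'missing' stratum is reported per covariate but excluded from the
    test.  Covariates with a single observed level skip the test with a
    warning entry (p = NaN).
    """
    merged = incidents.merge(
        results[["incident_id", "status"]],
        left_on="record_id",
        right_on="incident_id",
        how="left",
    )
    merged["matched"] = merged["status"].isin(["matched", "matched_with_confirmation"])

    rows = []
    total_m = int(merged["matched"].sum())
    total_n = len(merged)
    lo, hi = clopper_pearson(total_m, total_n, level)
    rows.append(
        {
            "covariate": "total",
            "level": "total",
            "matched": total_m,
            "unmatched": total_n - total_m,
            "total": total_n,
            "proportion": total_m / total_n,
            "ci_low": lo,
            "ci_high": hi,
            "fisher_p": np.nan,
        }
    )
    for cov in covariates:
        values = merged[cov].astype(object).where(~merged[cov].isna(), "missing")
        levels = [lv for lv in pd.unique(values)]
        counts = []
        for lv in levels:
            sub = merged[values == lv]
            m = int(sub["matched"].sum())
            n = len(sub)
            counts.append((lv, m, n))
        test_cells = np.array([(m, n - m) for lv, m, n in counts if lv != "missing"])
        degenerate = (
            len(test_cells) < 2
            or (test_cells.sum(axis=0) > 0).sum() < 2
            or (test_cells.sum(axis=1) > 0).sum() < 2
        )
        p = np.nan if degenerate else fisher_exact_rxc(test_cells)
        for lv, m, n in counts:
            lo, hi = clopper_pearson(m, n, level)
            rows.append(
                {
                    "covariate": cov,
                    "level": lv,
                    "matched": m,
                    "unmatched": n - m,
                    "total": n,
                    "proportion": m / n,
                    "ci_low": lo,
                    "ci_high": hi,
                    "fisher_p": p,
                }
            )
    return pd.DataFrame(rows)
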