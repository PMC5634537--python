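"""Synthetic two-list death-registry generator.

Emulates the data structures behind a media-based registry of
law-enforcement-related deaths and the vital-statistics mortality file it
is matched against, with explicit control over everything the downstream
pipeline estimates:

* media capture probability ``p_media`` (list 1),
* a covariate-driven probability that the vital-statistics record carries
  a legal-intervention ICD-10 code (list 2), modelled on the logit scale
  with county and state random intercepts,
* the log cross-ratio ``dependence_alpha`` between the two list
  memberships, induced per incident so the generator matches the
  estimator's dependence-offset parameterization exactly,
* identifier noise (surname typos, birth-year slips, injury-to-death lag)
  for exercising the deterministic linkage.

Every death appears in the mortality collection — the registry holds all
deaths, only its ICD coding varies; the media list is a subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import names as _names
from .filters import FLAG_COLUMNS

__all__ = [
    "IdentifierNoise",
    "SyntheticConfig",
    "SimulationResult",
    "solve_joint_capture_probs",
    "generate_county_frame",
    "generate_incidents",
    "perturb_identifiers",
    "simulate",
]

URBANICITY_LEVELS = (
    "large_metro_central",
    "large_metro_fringe",
    "medium_metro",
    "small_metro",
    "micropolitan",
    "non_core",
)
INVESTIGATOR_LEVELS = ("medical_examiner", "coroner_elected", "coroner_appointed")

LEGAL_INTERVENTION_CODES = ("Y35.0", "Y35.1", "Y35.2", "Y35.3", "Y35.4", "Y35.6", "Y35.7", "Y89.0")

#: underlying-cause mixtures for misclassified deaths, by mechanism
#: (categories: assault, undetermined/missing, suicide, accident,
#: circulatory/respiratory, mental/behavioural, other)
_MISCLASS_CAUSE_MIX = {
    "firearm": ((("X95", 456), ("Y24", 11), ("X72", 16), ("W34", 1), ("I46.9", 2))),
    "taser": ((("Y04", 10), ("Y34", 8), ("W87", 10), ("I46.9", 7), ("F19.1", 5))),
    "struck_by_against": ((("Y00", 4), ("Y29", 2), ("W22", 1), ("I25.1", 5), ("F05", 2))),
    "motor_vehicle": ((("Y03", 1), ("V03", 3))),
    "neglect": ((("R99", 1), ("G93.1", 2))),
    "other_custody": ((("R99", 1),)),
}

_EXTRA_CAUSE_POOL = ("T14.8", "J96.0", "I46.9", "S06.9", "T79.4", "R57.8")

_AGE_RANGES = {"under_18": (12, 17), "18_44": (18, 44), "45_plus": (45, 80)}


def _norm_mix(d: dict[str, float]) -> dict[str, float]:
    total = float(sum(d.values()))
    return {k: v / total for k, v in d.items()}


def _default_covariate_mix() -> dict[str, dict[str, float]]:
    # death-level marginal frequencies observed in the 2015 media registry
    return {
        "age_group": _norm_mix({"under_18": 17, "18_44": 768, "45_plus": 301}),
        "gender": _norm_mix({"man": 1043, "woman": 43}),
        "race_ethnicity": _norm_mix(
            {"black": 294, "white": 553, "hispanic": 187, "aian": 12, "api": 22, "missing": 18}
        ),
        "mechanism": _norm_mix(
            {"firearm": 1008, "taser": 50, "struck_by_against": 20, "motor_vehicle": 5, "neglect": 3}
        ),
        "income_quintile": {str(q): 0.2 for q in range(1, 6)},
        "urbanicity": _norm_mix(
            dict(zip(URBANICITY_LEVELS, (391, 192, 237, 82, 77, 106)))
        ),
        "investigator_type": _norm_mix(dict(zip(INVESTIGATOR_LEVELS, (628, 423, 35)))),
    }


def _default_misclass_coefs() -> dict[str, float]:
    # conditional log-odds of misclassification; reference: firearm death in a
    # highest-income-quintile county.  Magnitudes follow the published
    # multivariable model (non-firearm OR 68.24; Q1..Q4 ORs ~7-10).
    return {
        "intercept": -0.056,
        "mechanism_group:non_firearm": float(np.log(68.24)),
        "income_quintile:4": float(np.log(8.32)),
        "income_quintile:3": float(np.log(7.02)),
        "income_quintile:2": float(np.log(10.39)),
        "income_quintile:1": float(np.log(10.11)),
    }


@dataclass(frozen=True)
class IdentifierNoise:
    """Perturbation probabilities for linkage identifiers."""

    surname_typo_prob: float = 0.0
    birth_year_error_prob: float = 0.0
    lag_zero_prob: float = 0.8
    lag_geometric_p: float = 0.35

    def validate(self) -> None:
        for name in ("surname_typo_prob", "birth_year_error_prob", "lag_zero_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.lag_geometric_p <= 1.0:
            raise ValueError("lag_geometric_p must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    true_total: int = 1166
    year: int = 2015
    p_media: float = 0.931
    dependence_alpha: float = 0.0
    misclass_coefs: dict[str, float] = field(default_factory=_default_misclass_coefs)
    sigma2_county: float = 7.1
    sigma2_state: float = 2.7
    covariate_mix: dict[str, dict[str, float]] = field(default_factory=_default_covariate_mix)
    n_states: int = 50
    counties_per_state: int = 10
    identifier_noise: IdentifierNoise = field(default_factory=IdentifierNoise)
    p_media_by_urbanicity: dict[str, float] | None = None
    multiple_cause_only_rate: float = 0.002
    unique_identifiers: bool = True
    seed: int = 20150000

    def validate(self) -> None:
        if self.true_total <= 0:
            raise ValueError("true_total must be positive")
        if not 0.0 < self.p_media < 1.0:
            raise ValueError("p_media must lie in (0, 1)")
        if self.n_states < 1 or self.counties_per_state < 1:
            raise ValueError("need at least one state and one county per state")
        if min(self.sigma2_county, self.sigma2_state) < 0:
            raise ValueError("random-intercept variances must be nonnegative")
        if not np.isfinite(self.dependence_alpha):
            raise ValueError("dependence_alpha must be finite")
        for var, mix in self.covariate_mix.items():
            if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"covariate mix for {var!r} must be a distribution")
        self.identifier_noise.validate()

    def rng_streams(self, n: int) -> list[np.random.Generator]:
        """Independent deterministic substreams derived from the global seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class SimulationResult:
    incidents: pd.DataFrame
    mortality: pd.DataFrame
    monthly_counts: pd.DataFrame
    counties: pd.DataFrame
    truth_flags: pd.DataFrame
    truth_cells: pd.DataFrame
    config: SyntheticConfig


def _log_cross_ratio(q11: float, p1: float, p2: float) -> float:
    q10 = p1 - q11
    q01 = p2 - q11
    q00 = 1.0 - p1 - p2 + q11
    return np.log(q11) + np.log(q00) - np.log(q10) - np.log(q01)


def solve_joint_capture_probs(p1: float, p2: float, alpha: float) -> tuple[float, float, float, float]:
    """Joint cell probabilities for two Bernoulli lists with log cross-ratio alpha.

    Given marginal capture probabilities ``p1``, ``p2`` and the log
    odds-ratio ``alpha`` between memberships, returns (q11, q10, q01, q00)
    with q11+q10 = p1, q11+q01 = p2 and log[(q11 q00)/(q10 q01)] = alpha.
    Solved by a bracketed root find in q11 over its Frechet interval.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("marginal probabilities must lie in (0, 1)")
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if alpha == 0.0:
        q11 = p1 * p2
    else:
        lo = max(0.0, p1 + p2 - 1.0)
        hi = min(p1, p2)
        eps = 1e-14 * max(1.0, hi)
        try:
            q11 = brentq(
                lambda q: _log_cross_ratio(q, p1, p2) - alpha,
                lo + eps,
                hi - eps,
                xtol=1e-15,
                rtol=8.9e-16,
            )
        except ValueError as exc:  # pragma: no cover - infeasible only at the boundary
            raise RuntimeError(
                f"no feasible q11 for p1={p1}, p2={p2}, alpha={alpha}: {exc}"
            ) from exc
    return q11, p1 - q11, p2 - q11, 1.0 - p1 - p2 + q11


def _solve_q11_array(p1: np.ndarray, p2: np.ndarray, alpha: float, iters: int = 70) -> np.ndarray:
    """Vectorized bisection version of :func:`solve_joint_capture_probs`."""
    p1 = np.broadcast_to(np.asarray(p1, float), np.broadcast_shapes(np.shape(p1), np.shape(p2)))
    p2 = np.broadcast_to(np.asarray(p2, float), p1.shape)
    if alpha == 0.0:
        return p1 * p2
    lo = np.maximum(0.0, p1 + p2 - 1.0) + 1e-15
    hi = np.minimum(p1, p2) - 1e-15
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f = (
            np.log(mid)
            + np.log1p(-p1 - p2 + mid)
            - np.log(p1 - mid)
            - np.log(p2 - mid)
            - alpha
        )
        too_high = f > 0
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    return 0.5 * (lo + hi)


def _sample_levels(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    levels = np.array(list(mix.keys()), dtype=object)
    probs = np.array(list(mix.values()), dtype=float)
    return levels[rng.choice(len(levels), size=n, p=probs / probs.sum())]


def generate_county_frame(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """County table with state membership and county-level covariates."""
    config.validate()
    if rng is None:
        rng = config.rng_streams(1)[0]
    n = config.n_states * config.counties_per_state
    state_ids = [f"S{s + 1:02d}" for s in range(config.n_states) for _ in range(config.counties_per_state)]
    county_ids = [
        f"S{s + 1:02d}C{c + 1:03d}"
        for s in range(config.n_states)
        for c in range(config.counties_per_state)
    ]
    mix = config.covariate_mix
    return pd.DataFrame(
        {
            "county_id": county_ids,
            "state_id": state_ids,
            "income_quintile": _sample_levels(rng, mix["income_quintile"], n).astype(int),
            "urbanicity": _sample_levels(rng, mix["urbanicity"], n),
            "investigator_type": _sample_levels(rng, mix["investigator_type"], n),
        }
    )


def _coef_lookup(coefs: dict[str, float], frame: pd.DataFrame) -> np.ndarray:
    """Sum configured log-odds contributions over each row's covariate levels."""
    eta = np.full(len(frame), float(coefs.get("intercept", 0.0)))
    for key, value in coefs.items():
        if key == "intercept":
            continue
        column, _, level = key.partition(":")
        if column not in frame.columns:
            raise ValueError(f"misclass_coefs references unknown covariate {column!r}")
        eta += np.where(frame[column].astype(str) == level, float(value), 0.0)
    return eta


def generate_incidents(
    config: SyntheticConfig,
    counties: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the full cohort of true deaths and both registry views.

    Returns ``(incidents, mortality, latent)`` where ``incidents`` holds
    only media-captured deaths, ``mortality`` holds every death (death
    date initialized to the injury date; see :func:`perturb_identifiers`
    for the lag model), and ``latent`` carries the per-death truth flags.
    """
    config.validate()
    if rng is None:
        rng = config.rng_streams(2)[1]
    n = config.true_total
    mix = config.covariate_mix

    county_rows = counties.iloc[rng.integers(0, len(counties), size=n)].reset_index(drop=True)
    frame = pd.DataFrame(
        {
            "person_id": [f"P{i + 1:06d}" for i in range(n)],
            "county_id": county_rows["county_id"].to_numpy(),
            "state": county_rows["state_id"].to_numpy(),
            "income_quintile": county_rows["income_quintile"].to_numpy(),
            "urbanicity": county_rows["urbanicity"].to_numpy(),
            "investigator_type": county_rows["investigator_type"].to_numpy(),
            "age_group": _sample_levels(rng, mix["age_group"], n),
            "gender": _sample_levels(rng, mix["gender"], n),
            "race_ethnicity": _sample_levels(rng, mix["race_ethnicity"], n),
            "mechanism": _sample_levels(rng, mix["mechanism"], n),
        }
    )
    frame["mechanism_group"] = np.where(frame["mechanism"] == "firearm", "firearm", "non_firearm")

    lo = frame["age_group"].map(lambda g: _AGE_RANGES[g][0]).to_numpy()
    hi = frame["age_group"].map(lambda g: _AGE_RANGES[g][1]).to_numpy()
    frame["age"] = rng.integers(lo, hi + 1)

    year_start = pd.Timestamp(f"{config.year}-01-01")
    days_in_year = (pd.Timestamp(f"{config.year + 1}-01-01") - year_start).days
    frame["injury_date"] = year_start + pd.to_timedelta(
        rng.integers(0, days_in_year, size=n), unit="D"
    )

    # identifiers
    given_pool = _names.name_pool(np.random.default_rng(rng.integers(2**31)), 300)
    surname_pool = _names.name_pool(np.random.default_rng(rng.integers(2**31)), 3000, 3)
    given = rng.choice(given_pool, size=n)
    surname = rng.choice(surname_pool, size=n)
    if config.unique_identifiers:
        # keep (first name, surname-neighbourhood, birth-year window) combos
        # unique so deterministic linkage is exercised without true ambiguity
        import edlib

        seen: dict[str, list[tuple[str, int]]] = {}
        birth = config.year - frame["age"].to_numpy()
        for i in range(n):
            for _ in range(200):
                clash = any(
                    abs(int(birth[i]) - b) <= 2
                    and edlib.align(surname[i].lower(), s.lower(), task="distance")["editDistance"] <= 4
                    for s, b in seen.get(given[i], ())
                )
                if not clash:
                    break
                given[i] = given_pool[rng.integers(len(given_pool))]
                surname[i] = surname_pool[rng.integers(len(surname_pool))]
            seen.setdefault(given[i], []).append((surname[i], int(birth[i])))
    frame["given_name"] = given
    frame["surname"] = surname
    frame["birth_year"] = config.year - frame["age"]

    # misclassification process with nested random intercepts
    county_index = counties.reset_index().set_index("county_id")["index"]
    state_codes, state_uniques = pd.factorize(counties["state_id"])
    u = rng.normal(0.0, np.sqrt(config.sigma2_county), size=len(counties))
    v = rng.normal(0.0, np.sqrt(config.sigma2_state), size=len(state_uniques))
    c_idx = county_index.loc[frame["county_id"]].to_numpy()
    s_idx = state_codes[c_idx]
    eta = _coef_lookup(config.misclass_coefs, frame) + u[c_idx] + v[s_idx]
    p_classified = 1.0 - expit(eta)  # misclassification prob is expit(eta)

    # joint (media, classified) draw with the configured log cross-ratio
    if config.p_media_by_urbanicity:
        p1 = frame["urbanicity"].map(
            lambda lvl: config.p_media_by_urbanicity.get(lvl, config.p_media)
        ).to_numpy(float)
    else:
        p1 = np.full(n, config.p_media)
    p2 = np.clip(p_classified, 1e-9, 1 - 1e-9)
    q11 = _solve_q11_array(p1, p2, config.dependence_alpha)
    classified = rng.random(n) < p2
    p_media_given_c = np.where(classified, q11 / p2, (p1 - q11) / (1.0 - p2))
    in_media = rng.random(n) < p_media_given_c

    mortality, latent_cause = _assign_causes(config, frame, classified, rng)

    flags = pd.DataFrame({c: False for c in FLAG_COLUMNS}, index=frame.index)
    incidents = pd.concat(
        [
            pd.DataFrame(
                {
                    "record_id": "C" + frame["person_id"].str.slice(1),
                    "given_name": frame["given_name"],
                    "surname": frame["surname"],
                    "age": frame["age"],
                    "gender": frame["gender"],
                    "race_ethnicity": frame["race_ethnicity"],
                    "injury_date": frame["injury_date"],
                    "death_year": config.year,
                    "state": frame["state"],
                    "county_id": frame["county_id"],
                    "mechanism": frame["mechanism"],
                    "external_confirmation": False,
                }
            ),
            flags,
        ],
        axis=1,
    ).loc[in_media].reset_index(drop=True)

    latent = pd.DataFrame(
        {
            "person_id": frame["person_id"],
            "incident_id": "C" + frame["person_id"].str.slice(1),
            "mortality_id": "D" + frame["person_id"].str.slice(1),
            "in_media": in_media,
            "nvss_classified": classified,
            "p_classified": p2,
            "mechanism": frame["mechanism"],
            "mechanism_group": frame["mechanism_group"],
            "county_id": frame["county_id"],
            "state": frame["state"],
            "underlying_cause": latent_cause,
        }
    )
    return incidents, mortality, latent


def _assign_causes(config, frame, classified, rng):
    """ICD-10 coding for every death; returns (mortality frame, underlying causes)."""
    n = len(frame)
    underlying = np.empty(n, dtype=object)
    multiple = [None] * n
    legal_codes = np.array(LEGAL_INTERVENTION_CODES, dtype=object)

    for i in range(n):
        extras = list(rng.choice(_EXTRA_CAUSE_POOL, size=rng.integers(1, 4), replace=False))
        if classified[i]:
            legal = str(legal_codes[rng.integers(len(legal_codes))])
            if rng.random() < config.multiple_cause_only_rate:
                underlying[i] = "X95"  # legal intervention only among multiple causes
                multiple[i] = [underlying[i], legal] + extras
            else:
                underlying[i] = legal
                multiple[i] = [legal] + extras
        else:
            mix = _MISCLASS_CAUSE_MIX[frame["mechanism"].iat[i]]
            codes = np.array([c for c, _ in mix], dtype=object)
            wts = np.array([w for _, w in mix], dtype=float)
            underlying[i] = str(codes[rng.choice(len(codes), p=wts / wts.sum())])
            multiple[i] = [underlying[i]] + extras

    mortality = pd.DataFrame(
        {
            "record_id": "D" + frame["person_id"].str.slice(1),
            "given_name": frame["given_name"],
            "surname": frame["surname"],
            "birth_year": frame["birth_year"],
            "death_date": frame["injury_date"],  # lag applied by perturb_identifiers
            "death_state": frame["state"],
            "underlying_cause": underlying,
            "multiple_causes": [";".join(m) for m in multiple],
        }
    )
    return mortality, underlying


def perturb_identifiers(
    mortality: pd.DataFrame,
    noise: IdentifierNoise,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Apply identifier noise to a mortality collection.

    Surname typos are single-character substitutions; birth years shift by
    +/-1; death dates move to injury date + lag with P(lag = 0) =
    ``lag_zero_prob`` and a geometric day count otherwise (censored at
    Dec 31 of the death year so annual truth accounting is preserved).
    Perturbation indicator columns are appended for linkage scoring.
    """
    noise.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = mortality.copy()
    n = len(out)

    typo = rng.random(n) < noise.surname_typo_prob
    surnames = out["surname"].to_numpy(object).copy()
    for i in np.flatnonzero(typo):
        s = surnames[i]
        pos = rng.integers(len(s))
        repl = chr(ord("a") + rng.integers(26))
        while repl == s[pos].lower():
            repl = chr(ord("a") + rng.integers(26))
        surnames[i] = s[:pos] + repl + s[pos + 1 :]
    out["surname"] = surnames

    by_err = rng.random(n) < noise.birth_year_error_prob
    shift = rng.choice([-1, 1], size=n)
    out["birth_year"] = out["birth_year"] + np.where(by_err, shift, 0)

    lagged = rng.random(n) >= noise.lag_zero_prob
    lag = np.where(lagged, rng.geometric(noise.lag_geometric_p, size=n), 0)
    death = pd.to_datetime(out["death_date"]) + pd.to_timedelta(lag, unit="D")
    year_end = pd.to_datetime(out["death_date"]).dt.year.map(lambda y: pd.Timestamp(f"{y}-12-31"))
    out["death_date"] = np.minimum(death, year_end)

    out["perturbed_surname"] = typo
    out["perturbed_birth_year"] = by_err
    out["lag_days"] = np.minimum(
        lag, (year_end - pd.to_datetime(mortality["death_date"])).dt.days
    )
    return out


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Run the full generator: counties, cohort, identifier noise, truth table."""
    config.validate()
    rng_county, rng_cohort, rng_noise = config.rng_streams(3)
    counties = generate_county_frame(config, rng_county)
    incidents, mortality, latent = generate_incidents(config, counties, rng_cohort)
    mortality = perturb_identifiers(mortality, config.identifier_noise, rng_noise)

    death_dates = pd.to_datetime(mortality.set_index("record_id")["death_date"])
    latent = latent.copy()
    latent["death_date"] = death_dates.loc[latent["mortality_id"]].to_numpy()
    latent["quarter"] = (pd.to_datetime(latent["death_date"]).dt.month - 1) // 3 + 1

    # media follow-up confirms death dates that lag past the matching window
    lag = mortality.set_index("record_id")["lag_days"]
    confirm = lag.loc[("D" + incidents["record_id"].str.slice(1)).to_numpy()].to_numpy() > 4
    incidents = incidents.assign(external_confirmation=confirm)

    months = pd.DataFrame({"year": config.year, "month": range(1, 13)})
    classified_months = pd.to_datetime(
        latent.loc[latent["nvss_classified"], "death_date"]
    ).dt.month.value_counts()
    months["count"] = months["month"].map(classified_months).fillna(0).astype(int)

    cells = (
        latent.assign(
            cell=lambda d: np.select(
                [
                    d["in_media"] & d["nvss_classified"],
                    d["in_media"] & ~d["nvss_classified"],
                    ~d["in_media"] & d["nvss_classified"],
                ],
                ["n11", "n10", "n01"],
                default="n00",
            )
        )
        .groupby(["quarter", "cell"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["n10", "n01", "n11", "n00"], fill_value=0)
        .reset_index()
    )
    cells.insert(0, "stratum", "Q" + cells.pop("quarter").astype(str))

    return SimulationResult(
        incidents=incidents,
        mortality=mortality,
        monthly_counts=months,
        counties=counties,
        truth_flags=latent,
        truth_cells=cells,
        config=config,
    )
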