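import numpy as np
import pandas as pd
import pytest

from crvital.glmm import NestedLogisticFit
from crvital.misclassification import (
    MisclassificationFit,
    fit_multilevel_logistic,
    group_underlying_cause,
    is_legal_intervention,
    marginal_probabilities,
    state_rate_bands,
    tabulate_misclassification,
)


class TestLegalInterventionClassifier:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            (["X95", "Y35.0"], True),
            (["Y35.5"], False),  # legal execution is excluded
            (["X95"], False),
            (["Y89.0"], True),
            (["y35.4"], True),  # case-insensitive, decimal optional
            ("X95;T14.8;Y357", True),
        ],
    )
    def test_multiple_cause_scan(self, codes, expected):
        assert is_legal_intervention(codes) is expected

    def test_empty_or_malformed_rejected(self):
        with pytest.raises(ValueError):
            is_legal_intervention([])
        with pytest.raises(ValueError, match="Q5"):
            is_legal_intervention(["Q5"])


class TestCauseGrouping:
    @pytest.mark.parametrize(
        "code, category",
        [
            ("Y35.0", "legal_intervention"),
            ("Y35", "legal_intervention"),
            ("Y89.0", "legal_intervention"),
            ("Y35.5", "other"),  # legal execution falls through
            ("X95", "assault"),
            ("Y09", "assault"),
            ("R99", "undetermined_or_missing"),
            ("Y10", "undetermined_or_missing"),
            ("Y34", "undetermined_or_missing"),
            ("X60", "suicide"),
            ("X84", "suicide"),
            ("V01", "accident"),
            ("W34", "accident"),
            ("X59", "accident"),
            ("I21.9", "circulatory_respiratory"),
            ("J96.0", "circulatory_respiratory"),
            ("F05", "mental_behavioral"),
            ("T71", "other"),
        ],
    )
    def test_range_membership(self, code, category):
        assert group_underlying_cause(code) == category

    def test_grouper_consistent_with_classifier(self):
        # every underlying cause grouped as legal intervention also scans
        # positive on the multiple-cause classifier
        for code in ["Y35.0", "Y35.1", "Y35.2", "Y35.3", "Y35.4", "Y35.6", "Y35.7", "Y89.0"]:
            assert group_underlying_cause(code) == "legal_intervention"
            assert is_legal_intervention([code])
        # the converse fails by design: legal intervention may appear only
        # among the multiple causes
        assert is_legal_intervention(["X95", "Y35.0"]) and group_underlying_cause("X95") == "assault"


def mechanism_fixture():
    rows = []
    for grp, (mis, ok) in {"firearm": (486, 434), "non_firearm": (61, 10)}.items():
        rows += [{"mechanism_group": grp, "misclassified": True}] * mis
        rows += [{"mechanism_group": grp, "misclassified": False}] * ok
    df = pd.DataFrame(rows)
    df["state"] = "S01"
    return df


class TestTabulation:
    def test_published_mechanism_rows(self):
        table = tabulate_misclassification(mechanism_fixture(), "mechanism_group")
        nf = table[table["level"] == "non_firearm"].iloc[0]
        assert (nf["misclassified"], nf["total"]) == (61, 71)
        assert round(nf["percent_misclassified"], 1) == 85.9
        assert (round(nf["ci_low"], 1), round(nf["ci_high"], 1)) == (75.6, 93.0)
        assert nf["p_value"] < 0.01
        # row sums partition each stratum
        assert (table["misclassified"] + table["properly_classified"] == table["total"]).all()
        assert table["total"].sum() == 991

    def test_total_rate(self):
        df = mechanism_fixture()
        assert round(100 * df["misclassified"].mean(), 1) == 55.2

    def test_all_misclassified_stratum_bound(self):
        df = pd.DataFrame({"g": ["a"] * 9 + ["b"] * 9,
                           "misclassified": [True] * 9 + [False] * 9})
        table = tabulate_misclassification(df, "g")
        row = table[table["level"] == "a"].iloc[0]
        assert row["percent_misclassified"] == 100.0
        assert row["ci_low"] == pytest.approx(100 * (0.025 ** (1 / 9)))

    def test_missing_stratum_reported_but_excluded_from_test(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 40 + ["b"] * 40 + [None] * 10,
                "misclassified": [True] * 30 + [False] * 10 + [True] * 10 + [False] * 30 + [True] * 10,
            }
        )
        table = tabulate_misclassification(df, "g")
        assert "missing" in set(table["level"])
        from scipy.stats import chi2_contingency

        expected = chi2_contingency([[30, 10], [10, 30]], correction=False)[1]
        assert table["p_value"].iloc[0] == pytest.approx(expected)


class TestStateBands:
    def test_banding(self):
        df = pd.DataFrame(
            {
                "state": ["A"] * 12 + ["B"] * 97,
                "misclassified": [True] * 12 + [True] * 17 + [False] * 80,
            }
        )
        bands = state_rate_bands(df).set_index("state")
        assert bands.loc["A", "rate_band"] == ">=80%"
        assert bands.loc["A", "count_band"] == "10 to <20"
        assert bands.loc["B", "percent_misclassified"] == pytest.approx(100 * 17 / 97)
        assert bands.loc["B", "rate_band"] == "<20%"
        assert bands.loc["B", "count_band"] == ">=20"

    def test_states_without_cases_absent(self):
        df = pd.DataFrame({"state": ["A"] * 3, "misclassified": [True, False, False]})
        assert state_rate_bands(df)["state"].tolist() == ["A"]


def _clustered_frame(rng, n, n_states, cps, beta0, beta1, s_c, s_s, p_x=0.3):
    state = rng.integers(0, n_states, n)
    county = state * cps + rng.integers(0, cps, n)
    x = (rng.random(n) < p_x).astype(float)
    u = rng.normal(0, s_c, n_states * cps)
    v = rng.normal(0, s_s, n_states)
    eta = beta0 + beta1 * x + u[county] + v[state]
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame(
        {
            "misclassified": y,
            "mechanism_group": np.where(x == 1, "non_firearm", "firearm"),
            "county_id": [f"C{c}" for c in county],
            "state": [f"S{s}" for s in state],
        }
    )


class TestMultilevelModel:
    def test_no_cluster_effects_recovers_sample_odds_ratio(self):
        rng = np.random.default_rng(123)
        df = _clustered_frame(rng, 4000, 8, 5, -0.4, 1.1, 0.0, 0.0)
        fit = fit_multilevel_logistic(df, covariates=["mechanism_group"])
        t = pd.crosstab(df["mechanism_group"], df["misclassified"])
        sample_log_or = np.log(
            t.loc["non_firearm", True] * t.loc["firearm", False]
            / (t.loc["non_firearm", False] * t.loc["firearm", True])
        )
        assert fit.sigma2_county <= 0.05 and fit.sigma2_state <= 0.05
        assert fit.model.params["mechanism_group[non_firearm]"] == pytest.approx(
            sample_log_or, abs=0.02
        )

    def test_univariable_mode_returns_per_covariate_fits(self):
        rng = np.random.default_rng(5)
        df = _clustered_frame(rng, 1500, 6, 4, -0.2, 0.8, 0.5, 0.3)
        df["gender"] = np.where(rng.random(len(df)) < 0.9, "man", "woman")
        fits = fit_multilevel_logistic(df, covariates=["mechanism_group", "gender"], mode="univariable")
        assert set(fits) == {"mechanism_group", "gender"}
        assert all(f.converged for f in fits.values())

    def test_or_table_shape(self):
        rng = np.random.default_rng(17)
        df = _clustered_frame(rng, 1200, 6, 4, -0.2, 0.8, 0.4, 0.2)
        fit = fit_multilevel_logistic(df, covariates=["mechanism_group"])
        tab = fit.or_table
        assert {"or", "or_low", "or_high", "p"} <= set(tab.columns)
        assert (tab["or_low"] <= tab["or"]).all() and (tab["or"] <= tab["or_high"]).all()


class TestMarginalProbabilities:
    @staticmethod
    def _manual_fit(params: dict, covariates):
        idx = list(params)
        model = NestedLogisticFit(
            params=pd.Series(params),
            cov_params=pd.DataFrame(np.eye(len(idx)) * 1e-4, index=idx, columns=idx),
            sigma2_county=0.0,
            sigma2_state=0.0,
            loglik=0.0,
            converged=True,
            n_obs=10,
            n_counties=2,
            n_states=2,
        )
        return MisclassificationFit(model, model.summary_table(), 0.0, 0.0,
                                    {"covariates": covariates, "reference_levels": {}})

    def test_null_model_predicts_half_everywhere(self):
        fit = self._manual_fit({"intercept": 0.0, "mechanism_group[non_firearm]": 0.0},
                               ["mechanism_group"])
        records = pd.DataFrame({"mechanism_group": ["firearm"] * 6 + ["non_firearm"] * 4})
        out = marginal_probabilities(fit, records, "mechanism_group")
        assert out["probability"].tolist() == pytest.approx([0.5, 0.5])

    def test_degenerate_single_covariate_matches_direct_average(self):
        from scipy.special import expit

        fit = self._manual_fit({"intercept": -0.3, "mechanism_group[non_firearm]": 1.2},
                               ["mechanism_group"])
        records = pd.DataFrame({"mechanism_group": ["firearm"] * 7 + ["non_firearm"] * 3})
        out = marginal_probabilities(fit, records, "mechanism_group").set_index("level")
        assert out.loc["firearm", "probability"] == pytest.approx(expit(-0.3))
        assert out.loc["non_firearm", "probability"] == pytest.approx(expit(0.9))
        # positive coefficient implies the higher predicted probability
        assert out.loc["non_firearm", "probability"] > out.loc["firearm", "probability"]

    def test_unconverged_fit_rejected(self):
        fit = self._manual_fit({"intercept": 0.0}, ["g"])
        fit.model.converged = False
        with pytest.raises(ValueError, match="converge"):
            marginal_probabilities(fit, pd.DataFrame({"g": ["a"]}), "g")
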