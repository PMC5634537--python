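import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crvital.synthetic import (
    IdentifierNoise,
    SyntheticConfig,
    _solve_q11_array,
    generate_county_frame,
    generate_incidents,
    perturb_identifiers,
    simulate,
    solve_joint_capture_probs,
)


class TestJointCaptureProbs:
    def test_independence_symmetric(self):
        assert solve_joint_capture_probs(0.5, 0.5, 0.0) == pytest.approx((0.25,) * 4)

    def test_independence_is_product_of_marginals(self):
        q11, q10, q01, q00 = solve_joint_capture_probs(0.93, 0.45, 0.0)
        assert q11 == pytest.approx(0.4185)

    def test_root_find_against_grid_oracle(self):
        # brute-force grid search over q11 as the independent oracle
        p1 = p2 = 0.6
        alpha = 0.93
        grid = np.linspace(max(0, p1 + p2 - 1) + 1e-6, min(p1, p2) - 1e-6, 2_000_001)
        lcr = np.log(grid) + np.log1p(-p1 - p2 + grid) - np.log(p1 - grid) - np.log(p2 - grid)
        oracle = grid[np.argmin(np.abs(lcr - alpha))]
        q11, q10, q01, q00 = solve_joint_capture_probs(p1, p2, alpha)
        assert q11 == pytest.approx(oracle, abs=1e-6)
        assert q11 + q10 == pytest.approx(p1, abs=1e-10)
        assert q11 + q01 == pytest.approx(p2, abs=1e-10)
        assert np.log(q11 * q00 / (q10 * q01)) == pytest.approx(alpha, abs=1e-8)

    @pytest.mark.parametrize("p1", [0.1, 0.5, 0.931])
    @pytest.mark.parametrize("p2", [0.2, 0.45, 0.8])
    @pytest.mark.parametrize("alpha", [-1.5, -0.3, 0.0, 0.93, 2.0])
    def test_marginals_and_cross_ratio_preserved(self, p1, p2, alpha):
        q11, q10, q01, q00 = solve_joint_capture_probs(p1, p2, alpha)
        assert min(q11, q10, q01, q00) >= 0
        assert q11 + q10 + q01 + q00 == pytest.approx(1.0, abs=1e-9)
        assert q11 + q10 == pytest.approx(p1, abs=1e-9)
        assert q11 + q01 == pytest.approx(p2, abs=1e-9)
        assert np.log(q11 * q00 / (q10 * q01)) == pytest.approx(alpha, abs=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        alpha=st.floats(-3.0, 3.0),
    )
    def test_property_valid_joint_distribution(self, p1, p2, alpha):
        q11, q10, q01, q00 = solve_joint_capture_probs(p1, p2, alpha)
        assert min(q11, q10, q01, q00) >= -1e-12
        assert q11 + q10 == pytest.approx(p1, abs=1e-9)
        assert q11 + q01 == pytest.approx(p2, abs=1e-9)
        if min(q11, q10, q01, q00) > 1e-12:
            assert np.log(q11 * q00 / (q10 * q01)) == pytest.approx(alpha, abs=1e-6)

    def test_q11_monotone_in_alpha(self):
        qs = [solve_joint_capture_probs(0.7, 0.4, a)[0] for a in (-1.0, 0.0, 0.5, 1.5)]
        assert all(a < b for a, b in zip(qs, qs[1:]))

    def test_vectorized_solver_matches_scalar(self):
        p2 = np.array([0.1, 0.45, 0.77])
        vec = _solve_q11_array(0.93, p2, 0.93)
        scalar = [solve_joint_capture_probs(0.93, p, 0.93)[0] for p in p2]
        assert vec == pytest.approx(scalar, abs=1e-10)

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError):
            solve_joint_capture_probs(0.0, 0.5, 0.0)


class TestCountyFrame:
    def test_counts_and_membership(self):
        cfg = SyntheticConfig(n_states=2, counties_per_state=3)
        frame = generate_county_frame(cfg)
        assert len(frame) == 6
        assert frame.groupby("state_id").size().tolist() == [3, 3]
        assert frame["county_id"].is_unique

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_states=5, counties_per_state=4, seed=99)
        pd.testing.assert_frame_equal(generate_county_frame(cfg), generate_county_frame(cfg))

    def test_quintile_frequencies_within_sampling_error(self):
        # 10,000 counties, each quintile p = 0.2: 3-SE binomial band
        cfg = SyntheticConfig(n_states=100, counties_per_state=100, seed=7)
        frame = generate_county_frame(cfg)
        freq = frame["income_quintile"].value_counts(normalize=True)
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert ((freq - 0.2).abs() <= 3 * se).all()

    def test_invalid_mix_rejected(self):
        cfg = SyntheticConfig(covariate_mix={**SyntheticConfig().covariate_mix,
                                             "income_quintile": {"1": 0.6, "2": 0.6}})
        with pytest.raises(ValueError, match="distribution"):
            generate_county_frame(cfg)


class TestGenerateIncidents:
    def test_neutral_coefficients_give_half_rate(self):
        # logit^-1(0) = 0.5 classification when all effects vanish
        cfg = SyntheticConfig(
            true_total=10_000,
            misclass_coefs={"intercept": 0.0},
            sigma2_county=0.0,
            sigma2_state=0.0,
            unique_identifiers=False,
            seed=21,
        )
        counties = generate_county_frame(cfg)
        _, _, latent = generate_incidents(cfg, counties)
        rate = latent["nvss_classified"].mean()
        assert abs(rate - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_media_coverage_matches_p_media(self):
        cfg = SyntheticConfig(true_total=10_000, p_media=0.93, dependence_alpha=0.0,
                              unique_identifiers=False, seed=22)
        counties = generate_county_frame(cfg)
        incidents, mortality, latent = generate_incidents(cfg, counties)
        cover = latent["in_media"].mean()
        assert abs(cover - 0.93) <= 3 * np.sqrt(0.93 * 0.07 / 10_000)
        assert len(incidents) == int(latent["in_media"].sum())
        assert len(mortality) == 10_000  # the registry holds every death

    def test_latent_odds_ratio_recovers_generating_effect(self):
        # sample log-OR of misclassification for non-firearm vs firearm
        target = float(np.log(68.24))
        cfg = SyntheticConfig(
            true_total=40_000,
            misclass_coefs={"intercept": -0.056, "mechanism_group:non_firearm": target},
            sigma2_county=0.0,
            sigma2_state=0.0,
            unique_identifiers=False,
            seed=23,
        )
        counties = generate_county_frame(cfg)
        _, _, latent = generate_incidents(cfg, counties)
        t = pd.crosstab(latent["mechanism_group"], latent["nvss_classified"])
        a, b = t.loc["non_firearm", False], t.loc["non_firearm", True]
        c, d = t.loc["firearm", False], t.loc["firearm", True]
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or - target) <= 3 * se

    def test_dependence_induced_at_individual_level(self):
        # positive alpha inflates the both-lists cell above independence
        common = dict(true_total=30_000, p_media=0.6,
                      misclass_coefs={"intercept": 0.0}, sigma2_county=0.0,
                      sigma2_state=0.0, unique_identifiers=False, seed=24)
        counties = generate_county_frame(SyntheticConfig(**common))
        _, _, indep = generate_incidents(SyntheticConfig(**common, dependence_alpha=0.0), counties)
        _, _, dep = generate_incidents(SyntheticConfig(**common, dependence_alpha=0.93), counties)

        def log_cross_ratio(latent):
            t = pd.crosstab(latent["in_media"], latent["nvss_classified"])
            return np.log(
                t.loc[True, True] * t.loc[False, False] / (t.loc[True, False] * t.loc[False, True])
            )

        se = np.sqrt(4 * 4 / 30_000)  # rough: all cells ~ n/4
        assert abs(log_cross_ratio(indep)) <= 4 * se
        assert abs(log_cross_ratio(dep) - 0.93) <= 4 * se


class TestPerturbIdentifiers:
    def base(self, n=2000, seed=31):
        cfg = SyntheticConfig(true_total=n, unique_identifiers=False, seed=seed)
        counties = generate_county_frame(cfg)
        _, mortality, _ = generate_incidents(cfg, counties)
        return mortality

    def test_zero_noise_is_identity(self):
        mortality = self.base()
        out = perturb_identifiers(
            mortality, IdentifierNoise(0.0, 0.0, lag_zero_prob=1.0), rng=5
        )
        pd.testing.assert_frame_equal(
            out[mortality.columns], mortality, check_dtype=False
        )
        assert (out["lag_days"] == 0).all()

    def test_point_mass_lag_keeps_death_on_injury_date(self):
        mortality = self.base()
        out = perturb_identifiers(mortality, IdentifierNoise(lag_zero_prob=1.0), rng=6)
        assert (pd.to_datetime(out["death_date"]) == pd.to_datetime(mortality["death_date"])).all()

    def test_typo_fraction_within_sampling_error(self):
        mortality = self.base(n=10_000, seed=32)
        out = perturb_identifiers(mortality, IdentifierNoise(surname_typo_prob=0.1), rng=7)
        frac = out["perturbed_surname"].mean()
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 10_000)
        changed = out["surname"] != mortality["surname"]
        assert (changed == out["perturbed_surname"]).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            IdentifierNoise(surname_typo_prob=1.5).validate()


class TestSimulate:
    def test_truth_table_conserves_total(self, noisy_cohort):
        cells = noisy_cohort.truth_cells
        assert cells[["n10", "n01", "n11", "n00"]].to_numpy().sum() == 1000
        assert (cells[["n10", "n01", "n11", "n00"]] >= 0).all().all()
        flags = noisy_cohort.truth_flags
        assert flags["in_media"].sum() == len(noisy_cohort.incidents)
        assert len(flags) == len(noisy_cohort.mortality) == 1000

    def test_monthly_counts_match_classified_deaths(self, noisy_cohort):
        total = noisy_cohort.monthly_counts["count"].sum()
        assert total == int(noisy_cohort.truth_flags["nvss_classified"].sum())
        assert sorted(noisy_cohort.monthly_counts["month"]) == list(range(1, 13))

    def test_same_seed_reproduces_everything(self):
        cfg = SyntheticConfig(true_total=300, seed=77)
        a, b = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(a.incidents, b.incidents)
        pd.testing.assert_frame_equal(a.mortality, b.mortality)
        pd.testing.assert_frame_equal(a.truth_cells, b.truth_cells)

    def test_quarters_follow_death_dates(self, noisy_cohort):
        flags = noisy_cohort.truth_flags
        expected = (pd.to_datetime(flags["death_date"]).dt.month - 1) // 3 + 1
        assert (flags["quarter"] == expected).all()
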