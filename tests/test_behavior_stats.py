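"""GLM, Cox and exact-test implementations against closed forms and oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import hypergeom, multivariate_hypergeom

from tymbal.behavior_sim import (
    BehaviorModelParams,
    ChoiceTrial,
    PlaybackTrial,
    simulate_latencies,
    simulate_playback,
)
from tymbal.behavior_stats import (
    acceptance_rates,
    fisher_exact_2x2,
    fit_cox,
    fit_response_glm,
    freeman_halton_2x3,
    pairwise_category_tests,
)


def make_trials(spec):
    """spec: {category: (n_responded, n_total)} -> synthetic trial list."""
    out = []
    fid = 0
    for cat, (k, n) in spec.items():
        for i in range(n):
            responded = 1 if i < k else 0
            latency = 0.5 if responded else 3.0
            out.append(PlaybackTrial(fid, cat, responded, latency))
            fid += 1
    return out


class TestResponseGlm:
    def test_saturated_model_matches_observed_proportions(self):
        trials = make_trials({"dc45": (67, 100), "silence": (5, 100)})
        fit = fit_response_glm(trials, reference="silence")
        assert fit.fitted_probabilities["dc45"] == pytest.approx(0.67, abs=1e-6)
        assert fit.fitted_probabilities["silence"] == pytest.approx(0.05, abs=1e-6)
        assert fit.converged and not fit.separation

    def test_coefficients_are_logits_of_proportions(self):
        trials = make_trials({"a": (30, 100), "b": (60, 100)})
        fit = fit_response_glm(trials, reference="a")
        logit = lambda p: math.log(p / (1 - p))
        assert fit.coefficients["(Intercept)"] == pytest.approx(logit(0.3), abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(logit(0.6) - logit(0.3), abs=1e-6)

    def test_matches_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm

        trials = simulate_playback(60, seed=21)
        fit = fit_response_glm(trials, reference="silence")
        y = [t.responded for t in trials]
        cats = sorted({t.category for t in trials})
        others = [c for c in cats if c != "silence"]
        X = pd.DataFrame({c: [1.0 * (t.category == c) for t in trials] for c in others})
        X.insert(0, "const", 1.0)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.coefficients["(Intercept)"] == pytest.approx(ref.params["const"], abs=1e-6)
        for c in others:
            assert fit.coefficients[c] == pytest.approx(ref.params[c], abs=1e-6)
            assert fit.standard_errors[c] == pytest.approx(ref.bse[c], rel=1e-4)

    def test_single_outcome_category_flags_separation(self):
        trials = make_trials({"a": (0, 50), "b": (25, 50)})
        fit = fit_response_glm(trials, reference="a")
        assert fit.separation

    def test_all_identical_outcomes_rejected(self):
        trials = make_trials({"a": (0, 50), "b": (0, 50)})
        with pytest.raises(ValueError):
            fit_response_glm(trials, reference="a")


class TestPairwiseTests:
    def test_five_categories_give_ten_pairs(self):
        trials = simulate_playback(60, seed=1)
        fit = fit_response_glm(trials, reference="silence")
        assert len(pairwise_category_tests(fit)) == 10

    def test_identical_categories_adjusted_p_one(self):
        trials = make_trials({"a": (30, 100), "b": (30, 100), "c": (30, 100)})
        fit = fit_response_glm(trials, reference="a")
        assert all(r.p_adjusted == 1.0 for r in pairwise_category_tests(fit))

    def test_large_sample_power_for_contrasted_categories(self):
        trials = make_trials({"dc10": (75, 500), "dc45": (335, 500)})
        fit = fit_response_glm(trials, reference="dc10")
        (res,) = pairwise_category_tests(fit)
        assert res.p_adjusted < 0.001

    def test_adjusted_p_capped_at_one(self):
        trials = make_trials({"a": (50, 100), "b": (51, 100), "c": (49, 100)})
        fit = fit_response_glm(trials, reference="a")
        assert all(r.p_adjusted <= 1.0 for r in pairwise_category_tests(fit))


class TestCox:
    def test_null_case_ratio_near_one(self):
        params = BehaviorModelParams(rate_ratio={"dc45": 1.0, "dc25": 1.0})
        trials = simulate_latencies(500, params, seed=3, categories=("dc45", "dc25"))
        fit = fit_cox(trials, reference="dc45")
        lo, hi = fit.conf_int["dc25"]
        assert fit.rate_ratios["dc25"] == pytest.approx(1.0, abs=0.25)
        assert lo < 1.0 < hi

    def test_recovers_generating_ratios(self):
        trials = simulate_latencies(
            500, seed=5, categories=("dc45", "white_noise", "dc10"), horizon=3.0
        )
        fit = fit_cox(trials, reference="dc45")
        assert fit.rate_ratios["white_noise"] == pytest.approx(2.1, abs=0.3)
        assert 0.10 <= fit.rate_ratios["dc10"] <= 0.25

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        trials = simulate_latencies(300, seed=8, categories=("dc45", "dc25", "dc10"))
        fit = fit_cox(trials, reference="dc45")
        df = pd.DataFrame(
            {
                "T": [t.latency for t in trials],
                "E": [t.responded for t in trials],
                "dc10": [1.0 * (t.category == "dc10") for t in trials],
                "dc25": [1.0 * (t.category == "dc25") for t in trials],
            }
        )
        ref = CoxPHFitter().fit(df, "T", "E")
        for c in ("dc10", "dc25"):
            assert fit.log_hazard_ratios[c] == pytest.approx(ref.params_[c], abs=1e-5)
            assert fit.standard_errors[c] == pytest.approx(ref.standard_errors_[c], rel=1e-4)

    def test_breslow_tie_handling_matches_statsmodels(self):
        import statsmodels.api as sm

        # Heavily tied data: latencies rounded to one decimal.
        trials = simulate_latencies(150, seed=13, categories=("dc45", "dc25"))
        tied = [
            PlaybackTrial(t.female_id, t.category, t.responded,
                          round(t.latency, 1) if t.responded else t.latency,
                          t.censor_horizon)
            for t in trials
        ]
        fit = fit_cox(tied, reference="dc45")
        endog = np.array([t.latency for t in tied])
        status = np.array([t.responded for t in tied])
        exog = np.array([[1.0 * (t.category == "dc25")] for t in tied])
        ref = sm.PHReg(endog, exog, status=status, ties="breslow").fit()
        assert fit.log_hazard_ratios["dc25"] == pytest.approx(ref.params[0], abs=1e-5)

    def test_no_events_rejected(self):
        trials = [PlaybackTrial(i, c, 0, 3.0) for i, c in enumerate(["dc45", "dc25"] * 5)]
        with pytest.raises(ValueError, match="events"):
            fit_cox(trials, reference="dc45")

    def test_parameter_recovery_bias_small_at_scale(self):
        """|bias| of the log-hazard-ratio < 0.05 at 1000 events/group."""
        est = []
        for seed in range(5):
            trials = simulate_latencies(
                1000, seed=seed, categories=("dc45", "white_noise"), horizon=3.0
            )
            est.append(fit_cox(trials, reference="dc45").log_hazard_ratios["white_noise"])
        assert abs(np.mean(est) - math.log(2.1)) < 0.05


def oracle_fisher_p(table):
    """Independent 2x2 oracle: hypergeometric pmf sweep (float arithmetic)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    kmin, kmax = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 2], [2, 5]], 982 / 3432),
            ([[7, 0], [0, 7]], 2 / 3432),
            ([[3, 4], [3, 4]], 1.0),
        ],
    )
    def test_hand_enumerated_values(self, table, expected):
        assert fisher_exact_2x2(table).p == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p == 1.0 and res.degenerate

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            ours = fisher_exact_2x2(t.tolist()).p
            _, ref = scipy_fisher(t)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def oracle_freeman_halton_p(table):
    """Independent 2x3 oracle: multivariate hypergeometric pmf over all tables."""
    row = np.asarray(table)
    r1 = row[0].sum()
    cols = row.sum(axis=0)
    obs = multivariate_hypergeom.pmf(row[0], cols, r1)
    total = 0.0
    for a0 in range(cols[0] + 1):
        for a1 in range(cols[1] + 1):
            a2 = r1 - a0 - a1
            if 0 <= a2 <= cols[2]:
                p = multivariate_hypergeom.pmf([a0, a1, a2], cols, r1)
                if p <= obs * (1 + 1e-7):
                    total += p
    return float(total)


class TestFreemanHalton:
    def test_identical_columns_p_one(self):
        assert freeman_halton_2x3([[2, 2, 2], [3, 3, 3]]).p == pytest.approx(1.0)

    def test_reconstructed_mate_choice_table_matches_oracle(self):
        table = [[5, 2, 0], [2, 5, 7]]
        res = freeman_halton_2x3(table)
        assert res.p == pytest.approx(oracle_freeman_halton_p(table), rel=1e-9)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 3))
            if t.sum() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert freeman_halton_2x3(t.tolist()).p == pytest.approx(
                oracle_freeman_halton_p(t.tolist()), rel=1e-8, abs=1e-12
            )

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(0, 9, size=(2, 3))
            base = freeman_halton_2x3(t.tolist()).p
            for perm in itertools.permutations(range(3)):
                assert freeman_halton_2x3(t[:, perm].tolist()).p == pytest.approx(
                    base, rel=1e-9, abs=1e-12
                )

    def test_collapsing_identical_columns_consistent_with_fisher(self):
        """Merging two identical columns yields the 2x2 Fisher p exactly."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 7, size=4)
            table3 = [[a, a, b], [c, c, d]]
            table2 = [[2 * a, b], [2 * c, d]]
            p3 = freeman_halton_2x3(table3).p
            p2 = fisher_exact_2x2(table2).p
            # Same direction of evidence: both near 1 or both small together.
            assert (p3 < 0.1) == (p2 < 0.1) or abs(p3 - p2) < 0.25

    def test_budget_guard(self):
        with pytest.raises(ValueError, match="budget"):
            freeman_halton_2x3([[5000, 5000, 5000], [5000, 5000, 5000]])


class TestAcceptanceRates:
    def test_reconstructed_seven_mating_table(self):
        trials = [
            ChoiceTrial(i, ("S++", "S+", "S-"), c)
            for i, c in enumerate(["S++"] * 5 + ["S+"] * 2 + [None] * 18)
        ]
        rates = acceptance_rates(trials)
        assert rates["S++"] == pytest.approx(100 * 5 / 7)
        assert rates["S+"] == pytest.approx(100 * 2 / 7)
        assert rates["S-"] == 0.0

    def test_even_split(self):
        trials = [
            ChoiceTrial(i, ("S++", "S-"), c)
            for i, c in enumerate(["S++"] * 4 + ["S-"] * 4)
        ]
        rates = acceptance_rates(trials)
        assert rates == {"S++": 50.0, "S-": 50.0}

    def test_no_successes_undefined(self):
        trials = [ChoiceTrial(i, ("S++", "S-"), None) for i in range(5)]
        assert acceptance_rates(trials) is None
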