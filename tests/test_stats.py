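import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lichenphys import stats as ls


# ---------------------------------------------------------------------------
# normality screen


class TestNormalityScreen:
    def test_normal_sample_keeps_identity(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i, 1.0, 50) for i in range(3)}
        res = ls.normality_screen(groups)
        assert res.transformation == "identity"
        assert res.shapiro_p > 0.05

    def test_lognormal_sample_chooses_log(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": np.exp(rng.normal(i, 1.2, 60)) for i in range(3)}
        res = ls.normality_screen(groups)
        assert res.transformation == "log"
        assert res.shapiro_p > 0.05

    def test_small_group_skipped(self):
        rng = np.random.default_rng(1)
        groups = {"big": rng.normal(0, 1, 40), "tiny": [1.0, 2.0]}
        res = ls.normality_screen(groups)
        assert res.skipped_groups == ("tiny",)

    def test_nonpositive_values_skip_log(self):
        rng = np.random.default_rng(5)
        # heavy-tailed with negatives: log unavailable, sqrt unavailable
        groups = {f"g{i}": rng.standard_cauchy(60) for i in range(2)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ls.normality_screen(groups)
        assert res.transformation == "identity"
        assert res.warning is not None


# ---------------------------------------------------------------------------
# ANOVA


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = ls.one_way_anova({"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]})
        assert res.F == pytest.approx(21.0, abs=1e-12)
        assert res.df_between == 2
        assert res.df_within == 6

    def test_identical_groups_f_zero(self):
        res = ls.one_way_anova({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self):
        g1 = {"A": [1.0, 2.0], "B": [4.0, 5.0], "C": [2.5, 3.5]}
        g2 = {k: [v + 17.3 for v in vals] for k, vals in g1.items()}
        assert ls.one_way_anova(g1).F == pytest.approx(ls.one_way_anova(g2).F, rel=1e-9)

    def test_zero_within_variance_sentinel(self):
        res = ls.one_way_anova({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert math.isinf(res.F)
        assert res.p == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_scipy_oracle(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        k = data.draw(st.integers(2, 5))
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, rng.integers(3, 8)) for i in range(k)}
        ours = ls.one_way_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert ours.F == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-8)


# ---------------------------------------------------------------------------
# Tukey + compact letter display


def _cld_consistent(letters, pairwise_p, alpha=0.05):
    """Defining property: share a letter iff not significantly different."""
    for (a, b), p in pairwise_p.items():
        share = set(letters[a]) & set(letters[b])
        if p < alpha and share:
            return False
        if p >= alpha and not share:
            return False
    return True


class TestTukeyCLD:
    def test_hand_example_letters(self):
        groups = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]}
        res = ls.tukey_cld(groups)
        assert res.letters == {"A": "a", "B": "a", "C": "b"}
        # A-C studentized range statistic is 5 / sqrt(1/3) ~ 8.66
        assert res.pairwise_p[("A", "C")] < 0.05
        assert res.pairwise_p[("A", "B")] >= 0.05

    def test_no_significant_pairs_single_letter(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0, 1, 5) for i in range(4)}
        res = ls.tukey_cld(groups)
        assert all(v == "a" for v in res.letters.values())

    def test_two_groups(self):
        res = ls.tukey_cld({"A": [1.0, 1.1, 0.9], "B": [9.0, 9.1, 8.9]})
        assert sorted(res.letters.values()) == ["a", "b"]
        same = ls.tukey_cld({"A": [1.0, 1.1, 0.9], "B": [1.05, 1.0, 1.1]})
        assert same.letters["A"] == same.letters["B"]

    def test_matches_scipy_tukey_pvalues(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(i * 1.0, 1.0, 6) for i in range(4)}
        ours = ls.tukey_pairwise(groups)
        ref = sps.tukey_hsd(*groups.values())
        names = list(groups)
        for (a, b), p in ours.items():
            i, j = names.index(a), names.index(b)
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 6))
    def test_cld_property_random_data(self, seed, k):
        rng = np.random.default_rng(seed)
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, int(rng.integers(3, 7)))
            for i in range(k)
        }
        res = ls.tukey_cld(groups)
        assert all(res.letters.values()), "every group must get a letter"
        assert _cld_consistent(res.letters, res.pairwise_p)


# ---------------------------------------------------------------------------
# Pearson


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = ls.pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.df == 2

    def test_perfect_negative(self):
        x = np.arange(5.0)
        res = ls.pearson(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_fixed_points_vs_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        res = ls.pearson(x, y)
        # brute-force product-moment formula
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x**2).sum() - x.sum() ** 2) * math.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert res.r == pytest.approx(num / den, abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ls.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# proportional odds


def simulate_ordinal(rng, n, beta, zeta, x=None):
    if x is None:
        x = rng.normal(0, 1, n)
    zeta = np.asarray(zeta, dtype=float)
    cdf = 1.0 / (1.0 + np.exp(-(zeta[None, :] - beta * x[:, None])))
    u = rng.uniform(0, 1, n)
    y = 1 + (u[:, None] > cdf).sum(axis=1)
    return x, y


class TestProportionalOdds:
    def test_symmetric_design_zero_beta(self):
        fit = ls.fit_proportional_odds([1, 2, 1, 2], [0.0, 0.0, 1.0, 1.0])
        assert fit.beta == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        x, y = simulate_ordinal(rng, 500, 1.5, [-1.0, 0.5, 2.0])
        fit = ls.fit_proportional_odds(y, x)
        assert fit.converged
        assert abs(fit.beta - 1.5) < 2 * fit.se_beta

    def test_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(11)
        x, y = simulate_ordinal(rng, 300, 0.8, [-0.5, 1.0])
        fit = ls.fit_proportional_odds(y, x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = OrderedModel(
                pd.Series(y).astype("category"), x[:, None], distr="logit"
            ).fit(method="bfgs", disp=0)
        assert fit.beta == pytest.approx(ref.params.iloc[0], abs=1e-4)
        assert fit.se_beta == pytest.approx(ref.bse.iloc[0], rel=1e-3)
        # statsmodels parameterizes thresholds as (z1, log-increments)
        ref_zeta = [ref.params.iloc[1], ref.params.iloc[1] + math.exp(ref.params.iloc[2])]
        np.testing.assert_allclose(fit.zeta, ref_zeta, atol=1e-4)

    def test_two_categories_equal_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x, y = simulate_ordinal(rng, 400, 1.2, [0.3])
        fit = ls.fit_proportional_odds(y, x)
        ref = sm.Logit(y - 1, sm.add_constant(x)).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.zeta[0] == pytest.approx(-ref.params[0], abs=1e-6)

    def test_rescaling_equivariance(self):
        rng = np.random.default_rng(17)
        x, y = simulate_ordinal(rng, 300, 1.0, [-1.0, 1.0])
        fit = ls.fit_proportional_odds(y, x)
        fit10 = ls.fit_proportional_odds(y, x / 10.0)
        assert fit10.beta == pytest.approx(10 * fit.beta, rel=1e-4)
        assert fit10.t == pytest.approx(fit.t, rel=1e-3)

    def test_zeta_strictly_increasing(self):
        rng = np.random.default_rng(19)
        x, y = simulate_ordinal(rng, 200, 0.5, [-1.0, 0.0, 1.0, 2.0])
        fit = ls.fit_proportional_odds(y, x)
        assert all(b > a for a, b in zip(fit.zeta, fit.zeta[1:]))

    def test_loglik_beats_null(self):
        rng = np.random.default_rng(23)
        x, y = simulate_ordinal(rng, 200, 1.0, [-0.5, 0.5])
        fit = ls.fit_proportional_odds(y, x)
        # null model: beta fixed at 0, zeta at the empirical cumulative logits
        p_hat = np.array([np.mean(y <= j) for j in (1, 2)])
        ll_null = 0.0
        probs = np.diff(np.concatenate([[0.0], p_hat, [1.0]]))
        for j in (1, 2, 3):
            ll_null += np.sum(y == j) * math.log(probs[j - 1])
        assert fit.loglik >= ll_null - 1e-9

    def test_complete_separation_flagged(self):
        y = np.array([1] * 10 + [2] * 10)
        x = np.concatenate([np.linspace(0, 0.9, 10), np.linspace(1.1, 2, 10)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ls.fit_proportional_odds(y, x)
        assert not fit.converged
        assert math.isfinite(fit.beta)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 observed categories"):
            ls.fit_proportional_odds([1, 1, 1], [0.0, 1.0, 2.0])


# ---------------------------------------------------------------------------
# habitat scan


@pytest.fixture(scope="module")
def scan_input(panel0):
    from lichenphys.curve_features import compile_core_parameters
    from lichenphys.io import core_parameters_frame
    from lichenphys.synthetic import SPECIES_RANKS

    params = [compile_core_parameters(r) for r in panel0.runs]
    return core_parameters_frame(params), SPECIES_RANKS


class TestHabitatScan:
    def test_water_parameters_positive_and_ranked(self, scan_input):
        df, ranks = scan_input
        fits = ls.habitat_association_scan(df, ranks)
        by_name = {f.predictor: f for f in fits}
        assert by_name["max_wc_mm"].beta > 0
        assert by_name["min_wc_mm"].beta > 0
        # sorted by |t| descending
        ts = [abs(f.t) for f in fits if math.isfinite(f.t)]
        assert ts == sorted(ts, reverse=True)

    def test_species_means_mode(self, scan_input):
        df, ranks = scan_input
        fits = ls.habitat_association_scan(df, ranks, species_means=True)
        assert all(f.n == 7 for f in fits)

    def test_missing_rank_rejected(self, scan_input):
        df, ranks = scan_input
        partial = {k: v for k, v in ranks.items() if k != "Patl"}
        with pytest.raises(ValueError, match="Patl"):
            ls.habitat_association_scan(df, partial)


# ---------------------------------------------------------------------------
# published-summary utilities


class TestSummaryUtilities:
    @given(
        mean=st.floats(-10, 10),
        sd=st.floats(0.01, 5.0),
        n=st.integers(2, 6),
    )
    def test_reconstruction_moments_exact(self, mean, sd, n):
        v = ls.reconstruct_group(mean, sd, n)
        assert v.mean() == pytest.approx(mean, abs=1e-9)
        assert v.std(ddof=1) == pytest.approx(sd, rel=1e-9)

    def test_summary_anova_equals_raw_anova(self):
        rng = np.random.default_rng(31)
        groups = {f"g{i}": rng.normal(i, 1.0, 4) for i in range(3)}
        raw = ls.one_way_anova(groups)
        summ = ls.anova_from_summary(
            [g.mean() for g in groups.values()],
            [g.std(ddof=1) for g in groups.values()],
            [len(g) for g in groups.values()],
        )
        assert summ.F == pytest.approx(raw.F, rel=1e-9)
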