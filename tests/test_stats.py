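"""Instability statistics: exact enumeration modes, calibration, regression."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ogmrepeat.simulate import synthesize_cohort
from ogmrepeat.stats import (
    SubjectRecord,
    anderson_darling,
    expansion_status,
    fit_log_linear,
    mann_whitney,
    spearman,
    wilcoxon_paired,
)


class TestAndersonDarling:
    def test_calibration_under_the_null(self):
        """Normal samples rarely rejected at alpha = 0.05."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            if anderson_darling(x).pvalue > 0.05:
                hits += 1
        assert hits >= 90

    def test_power_against_lognormal(self, rng):
        x = rng.lognormal(0, 1, 200)
        assert anderson_darling(x).pvalue < 0.001

    def test_location_scale_invariance(self, rng):
        x = rng.normal(3, 2, 120)
        a = anderson_darling(x)
        b = anderson_darling(5.0 + 0.1 * x)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_degenerate_flagged_and_small_n_rejected(self):
        assert anderson_darling([1.0] * 10).degenerate
        with pytest.raises(ValueError):
            anderson_darling([1, 2, 3])


def _midranks(values):
    """Independent midrank computation by sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 5], [10, 20, 22, 90], n_boot=50)
        assert r.rho == pytest.approx(1.0)

    def test_antitone_pairs(self):
        r = spearman([1, 2, 4], [2, 1, 0], n_boot=50)
        assert r.rho == pytest.approx(-1.0)

    def test_ties_match_hand_midrank_oracle(self):
        x = [1, 2, 2, 3, 4, 4]
        y = [5, 5, 7, 8, 8, 9]
        rho = spearman(x, y, n_boot=50).rho
        rx, ry = _midranks(x), _midranks(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_constant_input_flagged(self):
        assert spearman([1, 1, 1], [1, 2, 3], n_boot=10).degenerate

    def test_subject_bootstrap_ci_brackets_rho(self, rng):
        n_subj, per = 20, 30
        ids = np.repeat(np.arange(n_subj), per)
        x = np.repeat(rng.uniform(50, 110, n_subj), per)
        y = x * 3 + rng.normal(0, 150, n_subj * per)
        r = spearman(x, y, subject_ids=ids, n_boot=200, seed=4)
        assert r.ci_low < r.rho < r.ci_high
        assert r.rho > 0.3

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(1, 10, 40)
        y = rng.uniform(1, 10, 40)
        a = spearman(x, y, n_boot=10).rho
        b = spearman(np.exp(x), y**3, n_boot=10).rho
        assert a == pytest.approx(b)


def mw_enumeration_oracle(a, b):
    """Two-sided p by enumerating labelings, U from pairwise comparisons."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(idx_a):
        set_a = set(idx_a)
        ua = 0.0
        for i in idx_a:
            for j in range(len(pooled)):
                if j in set_a:
                    continue
                if pooled[i] > pooled[j]:
                    ua += 1.0
                elif pooled[i] == pooled[j]:
                    ua += 0.5
        return ua

    centre = na * (len(pooled) - na) / 2.0
    obs = abs(u_stat(range(na)) - centre)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(combo) - centre) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.exact
        assert r.pvalue == 1.0

    def test_complete_separation_small_n(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0
        assert r.pvalue == pytest.approx(0.1)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(20):
            na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            a = rng.integers(0, 5, na)
            b = rng.integers(0, 5, nb)
            got = mann_whitney(a, b)
            assert got.exact
            assert got.pvalue == pytest.approx(mw_enumeration_oracle(a, b))

    def test_large_shift_detected_asymptotically(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(3, 1, 40)
        r = mann_whitney(a, b)
        assert not r.exact
        assert r.pvalue < 0.001

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 6)
        mine = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.pvalue == pytest.approx(ref.pvalue)


def wilcoxon_signflip_oracle(diffs):
    """Exact two-sided p by enumerating every sign assignment."""
    d = [x for x in diffs if x != 0]
    ranks = _midranks([abs(x) for x in d])
    total = sum(ranks)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    hits = count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += 1
        if abs(w - total / 2) >= abs(w_obs - total / 2) - 1e-9:
            hits += 1
    return hits / count


class TestWilcoxonPaired:
    def test_nine_uniform_positive_pairs(self):
        """Nine pairs, all positive differences: exact two-sided
        p = 2/2^9 = 0.00390625 (prints as 0.004)."""
        r = wilcoxon_paired(np.arange(1.0, 10.0))
        assert r.exact
        assert r.pvalue == pytest.approx(2 / 512)
        assert round(r.pvalue, 3) == 0.004

    def test_antisymmetric_pairs_give_p_one(self):
        r = wilcoxon_paired([1, -1, 2, -2, 3, -3])
        assert r.pvalue == 1.0

    def test_matches_signflip_enumeration(self, rng):
        for _ in range(20):
            d = rng.integers(-5, 6, 6)
            d = d[d != 0]
            if d.size < 5:
                continue
            got = wilcoxon_paired(d)
            assert got.pvalue == pytest.approx(wilcoxon_signflip_oracle(d))

    def test_zero_differences_dropped(self):
        r = wilcoxon_paired([0, 0, 1, 2, 3, 4, 5])
        assert r.n_used == 5
        with pytest.raises(ValueError):
            wilcoxon_paired([0.0, 0.0])

    def test_agrees_with_scipy_exact_tie_free(self):
        d = [1.5, -2.25, 3.125, 4.0625, -5.5, 6.75, 7.875]
        mine = wilcoxon_paired(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert mine.pvalue == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation(self, rng):
        d = rng.normal(1.0, 1.0, 40)
        r = wilcoxon_paired(d)
        assert not r.exact
        assert r.pvalue < 0.001

    def test_monotone_transform_invariance(self, rng):
        a = rng.uniform(1, 5, 10)
        b = rng.uniform(1, 5, 10)
        # a strictly monotone transform applied to both members of each pair
        # preserves difference signs only if it is affine increasing; rank
        # tests are invariant to scaling of the differences
        r1 = wilcoxon_paired(a - b)
        r2 = wilcoxon_paired(3.0 * (a - b))
        assert r1.pvalue == r2.pvalue


class TestLogLinearModel:
    def test_noiseless_slope_recovered_exactly(self):
        df = synthesize_cohort(15, beta_size=0.02, beta_age=0.0, noise_sd=0.0, seed=1)
        fit = fit_log_linear(df, with_age=False, with_interaction=False)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.params["progenitor_size_c"] == pytest.approx(0.02)

    def test_interaction_recovered_within_3se(self):
        hits = 0
        for seed in range(100):
            df = synthesize_cohort(
                40, beta_interaction=5e-4, noise_sd=0.05, seed=seed
            )
            fit = fit_log_linear(df)
            est = fit.params["size_x_age_c"]
            se = fit.bse["size_x_age_c"]
            if abs(est - 5e-4) < 3 * se:
                hits += 1
        assert hits >= 95

    def test_centring_reduces_predictor_interaction_correlation(self, rng):
        for seed in range(10):
            df = synthesize_cohort(30, beta_interaction=2e-4, seed=seed)
            fit = fit_log_linear(df)
            assert abs(fit.corr_centred) < abs(fit.corr_uncentred)

    def test_residuals_orthogonal_to_centred_predictors(self):
        df = synthesize_cohort(30, beta_interaction=2e-4, noise_sd=0.1, seed=3)
        fit = fit_log_linear(df)
        resid = fit.model.resid
        X = fit.model.model.exog
        assert np.allclose(X.T @ resid, 0, atol=1e-7)

    def test_too_few_subjects_rejected(self):
        df = synthesize_cohort(5, seed=0)
        with pytest.raises(ValueError):
            fit_log_linear(df)

    def test_collinear_design_rejected(self):
        df = synthesize_cohort(20, seed=0)
        df["age"] = df["progenitor_long"]  # perfectly collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_log_linear(df, with_interaction=False)


class TestSubjectRecord:
    def test_expansion_threshold_is_50_repeats(self):
        assert expansion_status(50) == "positive"
        assert expansion_status(49.9) == "negative"
        rec = SubjectRecord("s1", 60, "F", "CEC", (17, 63), 2500.0)
        assert rec.expansion_status == "positive"

    def test_misordered_alleles_rejected(self):
        with pytest.raises(ValueError):
            SubjectRecord("s1", 60, "F", "BL", (63, 17), 100.0)
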