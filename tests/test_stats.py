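import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cardioformant.cohort_stats import (
    assign_groups,
    holm_bonferroni,
    label_group,
    optimal_window,
    rank_sites_formants,
    required_sample_size,
    sweep_window_lengths,
    ttest_from_summary,
    two_sample_ttest,
)
from cardioformant.errors import MissingCellError, ParameterError
from cardioformant.pcg_io import SITES


def holm_oracle(p_values):
    """Hand-executed step-down adjustment, independent of the implementation."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda kv: kv[1])
    adjusted = [None] * m
    running = 0.0
    for rank, (idx, p) in enumerate(indexed):
        running = max(running, (m - rank) * p)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def make_feature_table(rng, shifts=None, n_per_group=(12, 10), L=10.0):
    """16-cell feature table with optional per-cell mean shifts for PAH."""
    shifts = shifts or {}
    rows = []
    n_norm, n_pah = n_per_group
    for site in SITES:
        for f in (1, 2, 3, 4):
            delta = shifts.get((site, f), 0.0)
            for i in range(n_norm):
                rows.append((f"N{i}", "normal", site, f, L, rng.normal(0.0, 1.0)))
            for i in range(n_pah):
                rows.append((f"P{i}", "PAH", site, f, L, rng.normal(delta, 1.0)))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "site", "formant", "window_length_s", "value"]
    )


class TestTwoSampleTtest:
    def test_identical_groups(self):
        t, df, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert df == 4
        assert p == 1.0

    def test_shifted_groups_are_most_extreme_permutation(self):
        xs, ys = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t_obs, _, p = two_sample_ttest(xs, ys)
        # exact permutation oracle over all 20 label splits of the 6 values
        pooled = np.array(xs + ys)
        t_perm = []
        for combo in itertools.combinations(range(6), 3):
            a = pooled[list(combo)]
            b = pooled[[i for i in range(6) if i not in combo]]
            t_perm.append(stats.ttest_ind(a, b, equal_var=True).statistic)
        assert abs(t_obs) == pytest.approx(np.max(np.abs(t_perm)))
        assert p < 0.001

    def test_agrees_with_summary_form(self, rng):
        xs, ys = rng.normal(0, 1, 14), rng.normal(0.5, 2, 9)
        raw = two_sample_ttest(xs, ys)
        summ = ttest_from_summary(
            xs.mean(), xs.std(ddof=1), xs.size, ys.mean(), ys.std(ddof=1), ys.size
        )
        assert raw == pytest.approx(summ, rel=1e-12)

    def test_degenerate_variance(self):
        with pytest.raises(ParameterError):
            two_sample_ttest([1.0, 1.0], [1.0, 1.0])

    def test_too_small_group(self):
        with pytest.raises(ParameterError):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestTtestFromSummary:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (14.1, 18.0, 11.9, 17.4, 0.64),  # age row
            (95.4, 23.3, 87.6, 24.3, 0.21),  # heart-rate row
            (4.4, 2.5, 3.4, 1.0, 0.06),  # pulmonary blood-flow index row
            (120.9, 42.0, 120.0, 36.5, 0.93),  # height row
        ],
    )
    def test_printed_cohort_rows(self, m1, s1, m2, s2, expected):
        t, df, p = ttest_from_summary(m1, s1, 35, m2, s2, 25)
        assert df == 58
        assert round(p, 2) == expected

    def test_equal_means(self):
        t, _, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert (t, p) == (0.0, 1.0)

    def test_zero_pooled_variance(self):
        with pytest.raises(ParameterError):
            ttest_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestHolmBonferroni:
    def test_single_p(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])

    def test_hand_executed_example(self):
        assert holm_bonferroni([0.01, 0.02, 0.30]) == pytest.approx([0.03, 0.04, 0.30])

    def test_all_permutations_up_to_five(self):
        base = [0.001, 0.02, 0.04, 0.2, 0.9]
        for k in range(1, 6):
            for perm in itertools.permutations(base[:k]):
                assert holm_bonferroni(list(perm)) == pytest.approx(holm_oracle(perm))

    def test_bounds(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(p * p.size, 1.0) + 1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 20)
        _, adj, _, _ = multipletests(p, method="holm")
        assert holm_bonferroni(p) == pytest.approx(adj)

    def test_invalid_p(self):
        with pytest.raises(ParameterError):
            holm_bonferroni([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8)
    )
    def test_property_matches_oracle(self, p_values):
        assert holm_bonferroni(p_values) == pytest.approx(holm_oracle(p_values))


class TestGrouping:
    def test_label_rule(self):
        assert label_group(25.0, 10.0) == "PAH"
        assert label_group(93.0, 15.0) == "PAH"
        assert label_group(24.9, 10.0) == "normal"
        assert label_group(5.0, 14.0) == "normal"
        assert label_group(30.0, 20.0) is None

    def test_assign_groups_excludes_high_wedge(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "mPAp_mmHg": [30.0, 12.0, 40.0],
                "PAWp_mmHg": [10.0, 8.0, 18.0],
            }
        )
        with pytest.warns(UserWarning, match="wedge"):
            out = assign_groups(meta)
        assert list(out["subject_id"]) == ["a", "b"]
        assert list(out["group"]) == ["PAH", "normal"]


class TestRankSitesFormants:
    def test_planted_cell_ranks_first(self, rng):
        table = make_feature_table(rng, shifts={("2LICS", 1): -2.5})
        results = rank_sites_formants(table)
        assert len(results) == 16
        assert (results[0].site, results[0].formant) == ("2LICS", 1)
        assert results[0].p_corrected <= 0.05

    def test_two_planted_effects_ordered(self, rng):
        table = make_feature_table(rng, shifts={("2LICS", 1): -3.0, ("apex", 2): -1.0})
        results = rank_sites_formants(table)
        first = (results[0].site, results[0].formant)
        assert first == ("2LICS", 1)
        ranks = {(r.site, r.formant): i for i, r in enumerate(results)}
        assert ranks[("2LICS", 1)] < ranks[("apex", 2)]

    def test_null_rarely_significant_after_correction(self):
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            table = make_feature_table(np.random.default_rng(seed))
            results = rank_sites_formants(table)
            hits += results[0].p_corrected <= 0.05
        # family-wise rate <= alpha; binomial(60, 0.05) upper tail
        assert hits <= 9

    def test_missing_cell_errors(self, rng):
        table = make_feature_table(rng)
        table = table[~((table["site"] == "apex") & (table["formant"] == 3))]
        with pytest.raises(MissingCellError, match="apex"):
            rank_sites_formants(table)

    def test_corrected_at_least_raw(self, rng):
        for r in rank_sites_formants(make_feature_table(rng)):
            assert r.p_corrected >= r.p_raw


class TestSweepWindowLengths:
    def make_sweep_table(self, rng, effect_by_length):
        rows = []
        for L, delta in effect_by_length.items():
            for i in range(12):
                rows.append((f"N{i}", "normal", "2LICS", 1, L, rng.normal(0, 1)))
            for i in range(10):
                rows.append((f"P{i}", "PAH", "2LICS", 1, L, rng.normal(delta, 1)))
        return pd.DataFrame(
            rows, columns=["subject_id", "group", "site", "formant", "window_length_s", "value"]
        )

    def test_optimum_at_strongest_length(self, rng):
        effects = {float(L): 0.0 for L in range(1, 21)}
        effects[10.0] = -4.0
        results = sweep_window_lengths(self.make_sweep_table(rng, effects))
        assert len(results) == 20
        best = optimal_window(results)
        assert best.window_length == 10.0
        assert best.p_corrected <= 0.05

    def test_corrected_at_least_raw_everywhere(self, rng):
        effects = {float(L): -0.5 for L in range(1, 21)}
        for r in sweep_window_lengths(self.make_sweep_table(rng, effects)):
            assert r.p_corrected >= r.p_raw

    def test_null_family_wise_rate(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            effects = {float(L): 0.0 for L in range(1, 21)}
            results = sweep_window_lengths(self.make_sweep_table(rng, effects))
            hits += min(r.p_corrected for r in results) <= 0.05
        # binomial(200, 0.05): P(X > 19) < 1e-3
        assert hits <= 19


class TestTypeICalibration:
    def test_uncorrected_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        n_rep = 2000
        xs = rng.standard_normal((n_rep, 35))
        ys = rng.standard_normal((n_rep, 25))
        p = stats.ttest_ind(xs, ys, axis=1, equal_var=True).pvalue
        rate = np.mean(p <= 0.05)
        tol = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rate == pytest.approx(0.05, abs=tol)


class TestRequiredSampleSize:
    def test_printed_power_analysis(self):
        n = required_sample_size(4.75e5, 4.56e5, 9.85e3, alpha=0.05, power=0.90)
        assert n == 6

    def test_noncentral_t_gives_seven(self):
        n = required_sample_size(4.75e5, 4.56e5, 9.85e3, method="noncentral_t")
        assert n == 7

    def test_unit_effect(self):
        assert required_sample_size(0.0, 1.0, 1.0, alpha=0.05, power=0.90) == 22

    def test_zero_effect_errors(self):
        with pytest.raises(ParameterError):
            required_sample_size(1.0, 1.0, 1.0)

    def test_invalid_alpha(self):
        with pytest.raises(ParameterError):
            required_sample_size(0.0, 1.0, 1.0, alpha=1.5)

    def test_monte_carlo_power_at_returned_n(self):
        n = required_sample_size(0.0, 1.0, 1.0)  # 22 per group
        rng = np.random.default_rng(11)
        n_rep = 3000
        xs = rng.normal(0.0, 1.0, (n_rep, n))
        ys = rng.normal(1.0, 1.0, (n_rep, n))
        p = stats.ttest_ind(xs, ys, axis=1, equal_var=True).pvalue
        assert np.mean(p <= 0.05) >= 0.90 - 0.03
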