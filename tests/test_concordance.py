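"""Concordance statistics: enumeration oracles for U and Fisher tests,
pairwise-counting vs trapezoidal AUC, CI contracts and BH monotonicity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ptcscreen import synthetic
from ptcscreen.concordance import (auc_confidence_interval, bh_adjust,
                                   build_contingency, concordance_accuracy,
                                   fisher_exact, mann_whitney, normalize_recist,
                                   roc_auc, standardize_viability,
                                   waterfall_table)


def _outcomes(viabilities, classes):
    return pd.DataFrame({"pA": viabilities, "recist": classes})


class TestStandardize:
    def test_hand_z_scores(self):
        assert np.allclose(standardize_viability([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_on_z_scores(self):
        z = standardize_viability([0.2, 0.9, 1.4, 0.6])
        assert np.allclose(standardize_viability(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize_viability([0.5, 0.5, 0.5])


class TestContingency:
    def test_study_margins(self):
        spec = synthetic.CohortSpec(n_crpr=8, n_sd=40, n_pd=12, seed=1)
        table = build_contingency(synthetic.simulate_cohort(spec))
        assert list(table.sum(axis=0)) == [8, 40, 12]
        assert table.to_numpy().sum() == 60

    def test_all_effective_fills_top_row(self):
        table = build_contingency(_outcomes([0.1, 0.3, 0.5], ["CR", "SD", "PD"]))
        assert table.loc["effective"].sum() == 3
        assert table.loc["not_effective"].sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(_outcomes([0.5], ["near-CR"]))

    def test_cr_and_pr_merge(self):
        assert normalize_recist("CR") == normalize_recist("PR") == "CR/PR"


class TestAccuracy:
    def test_hand_toy(self):
        out = _outcomes([0.3, 0.9, 0.5], ["CR/PR", "PD", "PD"])
        assert concordance_accuracy(out, "CRPR_vs_PD") == pytest.approx(2 / 3)

    def test_sd_dropped_vs_merged(self, toy_outcomes):
        # toy cohort is perfectly separated at 0.7
        assert concordance_accuracy(toy_outcomes, "CRPR_vs_PD") == 1.0
        assert concordance_accuracy(toy_outcomes, "CRPR_vs_SDPD") == 1.0

    def test_row_order_invariance(self, toy_outcomes):
        shuffled = toy_outcomes.sample(frac=1.0, random_state=0)
        for mode in ("CRPR_vs_PD", "CRPR_vs_SDPD"):
            assert concordance_accuracy(shuffled, mode) == pytest.approx(
                concordance_accuracy(toy_outcomes, mode))


def _enumerate_mw_p(a, b):
    """Exact two-sided p by enumerating all labelings of the pooled values."""
    pooled = np.concatenate([a, b])
    n = len(a)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
        return sum((x < y) + 0.5 * (x == y) for x in aa for y in bb)

    observed = u_stat(range(n))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n)]
    mean_u = len(a) * len(b) / 2.0
    dev = abs(observed - mean_u)
    return sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / len(us)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_labeling_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(np.arange(1, 13))[: rng.integers(3, 7)].astype(float)
        b = rng.uniform(0, 20, rng.integers(3, 7))
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_enumerate_mw_p(a, b), abs=1e-12)

    def test_exact_and_normal_agree_at_n8(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        exact = mann_whitney(a, b)
        approx = mann_whitney(np.concatenate([a, [99.0]]), b)  # force asymptotic
        assert exact.method == "exact"
        from scipy import stats
        p_asym = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(exact.p_value - p_asym) < 0.01


class TestRocAuc:
    def test_perfect_separation(self, toy_outcomes):
        assert roc_auc(toy_outcomes).auc == 1.0

    def test_hand_counted_three_quarters(self):
        out = _outcomes([0.2, 0.4, 0.3, 0.9], ["CR/PR", "CR/PR", "PD", "PD"])
        assert roc_auc(out).auc == pytest.approx(0.75)

    def test_shuffled_labels_average_half(self, rng):
        vals = rng.uniform(0, 2, 30)
        aucs = []
        for _ in range(200):
            labels = rng.permutation(["CR/PR"] * 10 + ["PD"] * 20)
            aucs.append(roc_auc(_outcomes(vals, labels)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_outcomes([0.5, 0.6], ["CR/PR", "CR/PR"]))

    def test_pairwise_counting_equals_trapezoidal_integration(self, rng):
        """Independent oracle: sklearn's trapezoidal ROC integration."""
        from sklearn.metrics import roc_auc_score

        for _ in range(300):
            n_pos = rng.integers(2, 10)
            n_neg = rng.integers(2, 10)
            # discrete support forces ties
            pa = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9, 1.2], n_pos + n_neg)
            labels = ["CR/PR"] * n_pos + ["PD"] * n_neg
            ours = roc_auc(_outcomes(pa, labels)).auc
            oracle = roc_auc_score([1] * n_pos + [0] * n_neg, -pa)
            assert ours == pytest.approx(oracle, abs=1e-12)


class TestAucCI:
    def test_bounds_bracket_auc(self, rng):
        out = _outcomes(rng.uniform(0, 2, 40),
                        ["CR/PR"] * 15 + ["PD"] * 25)
        auc = roc_auc(out).auc
        lo, hi = auc_confidence_interval(out, seed=0)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_degenerate_auc_falls_back_to_bootstrap(self, toy_outcomes):
        with pytest.warns(UserWarning, match="bootstrap"):
            lo, hi = auc_confidence_interval(toy_outcomes, seed=0)
        assert hi == 1.0

    def test_bootstrap_reproducible_under_seed(self, rng):
        out = _outcomes(rng.uniform(0, 2, 30), ["CR/PR"] * 10 + ["PD"] * 20)
        a = auc_confidence_interval(out, method="bootstrap", seed=12)
        b = auc_confidence_interval(out, method="bootstrap", seed=12)
        assert a == b


def _enumerate_fisher_p(table):
    """Two-sided Fisher p by summing hypergeometric tables at fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9)

    def test_independent_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 11, size=(2, 2))
        assert table.sum() <= 40
        assert fisher_exact(table) == pytest.approx(
            _enumerate_fisher_p(table), abs=1e-10)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestWaterfall:
    def test_sorted_descending_and_permutation(self, toy_outcomes):
        out = waterfall_table(toy_outcomes)
        assert list(out["pA"]) == sorted(toy_outcomes["pA"], reverse=True)
        assert sorted(out["sample_id"]) == sorted(toy_outcomes["sample_id"])

    def test_ties_keep_input_order(self):
        df = _outcomes([0.5, 0.9, 0.5], ["SD", "PD", "SD"])
        df["tag"] = ["first", "top", "second"]
        out = waterfall_table(df)
        assert list(out["tag"]) == ["top", "first", "second"]


class TestBhAdjust:
    def test_monotone_preserving(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_empty_ok(self):
        assert bh_adjust([]).size == 0


def test_binormal_cohort_recovers_target_auc():
    """Cohorts generated at AUC theta estimate theta without bias (n=60)."""
    theta = 0.75
    aucs = [roc_auc(synthetic.simulate_cohort(
        synthetic.CohortSpec.for_target_auc(theta, seed=s))).auc
        for s in range(60)]
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - theta) < 3 * se + 1e-9
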