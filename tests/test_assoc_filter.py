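import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aoptox.assoc_filter import (AssociationRecord, EndpointTable, associate, bh_fdr,
                                 bootstrap_ci, build_m3, fisher_z_ci, pearson_r,
                                 rank_biserial, rank_group_test, retain_pair,
                                 sample_size_threshold, transform_continuous_endpoint)


def bh_oracle(pvals):
    """Brute-force step-up: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def rank_biserial_oracle(toxic, nontoxic):
    wins = ties = 0
    for t in toxic:
        for n in nontoxic:
            wins += t > n
            ties += t == n
    a = (wins + 0.5 * ties) / (len(toxic) * len(nontoxic))
    return 2 * a - 1


class TestTransforms:
    @pytest.mark.parametrize("dose,expected", [(1, 0.0), (10, -1.0), (50, -math.log10(50))])
    def test_negative_log_dose(self, dose, expected):
        assert transform_continuous_endpoint(dose) == pytest.approx(expected)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            transform_continuous_endpoint(0.0)

    @pytest.mark.parametrize("n,expected", [(400, 0.1), (100, 0.2), (50, 2 / math.sqrt(50))])
    def test_sample_size_threshold(self, n, expected):
        assert sample_size_threshold(n) == pytest.approx(expected)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBhFdr:
    def test_spec_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(rnd.sample(range(p.size), p.size))
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFisherZ:
    def test_null_interval_closed_form(self):
        lo, hi = fisher_z_ci(0.0, 28)
        expected = math.tanh(stats.norm.ppf(0.975) / 5.0)
        assert hi == pytest.approx(expected, abs=1e-12)
        assert lo == pytest.approx(-expected, abs=1e-12)

    def test_width_shrinks_with_n(self):
        widths = [fisher_z_ci(0.0, n)[1] - fisher_z_ci(0.0, n)[0] for n in (10, 10**3, 10**4)]
        assert widths[0] > widths[1] > widths[2]

    def test_asymmetric_toward_zero(self):
        lo, hi = fisher_z_ci(0.5, 28)
        assert lo < 0.5 < hi
        assert (0.5 - lo) > (hi - 0.5)

    def test_degenerate_correlation_warns(self):
        with pytest.warns(UserWarning):
            lo, hi = fisher_z_ci(1.0, 30)
        assert (lo, hi) == (1.0, 1.0)


class TestBootstrap:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(20.0)
        lo, hi = bootstrap_ci(x, x, n_boot=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert bootstrap_ci(x, y, seed=3) == bootstrap_ci(x, y, seed=3)

    def test_coverage_of_true_correlation(self):
        """95% percentile CI covers rho=0.5 in >=90% of simulation repeats."""
        rho, n = 0.5, 200
        rng = np.random.default_rng(2)
        cov = 0
        for rep in range(100):
            z = rng.standard_normal(n)
            x = z
            y = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(n)
            lo, hi = bootstrap_ci(x, y, n_boot=500, seed=rep)
            cov += lo <= rho <= hi
        assert cov >= 90


class TestRankTests:
    def test_exact_wilcoxon_for_complete_separation(self):
        p, used = rank_group_test([1, 2, 3], [4, 5, 6])
        assert used == "wilcoxon"
        assert p == pytest.approx(0.1)  # 2/20 orderings, two-sided

    def test_ties_route_to_brunner_munzel(self):
        with pytest.warns(UserWarning):
            _, used = rank_group_test([1.0, 2.0, 3.0], [2.0, 5.0, 6.0])
        assert used == "brunner_munzel"

    def test_identical_groups_not_significant(self):
        x = list(np.linspace(0, 1, 8))
        p, used = rank_group_test(x, list(x))
        assert used == "brunner_munzel"
        assert p > 0.9

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            rank_group_test([1.0], [2.0, 3.0])


class TestRankBiserial:
    @pytest.mark.parametrize("toxic,nontoxic,expected", [
        ([5, 6, 7], [1, 2, 3], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [2, 3, 4], -(1 - 2 * 2.0 / 9)),
    ])
    def test_known_values(self, toxic, nontoxic, expected):
        assert rank_biserial(toxic, nontoxic) == pytest.approx(expected)

    def test_matches_pairwise_enumeration_small_groups(self):
        """Tie-aware U-statistic agrees with brute force for all sizes <= 6."""
        rng = np.random.default_rng(4)
        for _ in range(400):
            n1, n2 = rng.integers(1, 7), rng.integers(1, 7)
            toxic = rng.integers(0, 5, n1).astype(float)
            nontoxic = rng.integers(0, 5, n2).astype(float)
            assert rank_biserial(toxic, nontoxic) == pytest.approx(
                rank_biserial_oracle(toxic, nontoxic), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial([], [1.0])


class TestRetention:
    def _rec(self, stat, q, n, kind="continuous"):
        return AssociationRecord(pathway_id="p", endpoint_id="e", n=n, stat=stat,
                                 p=0.0, test_used="pearson", kind=kind, q=q)

    @pytest.mark.parametrize("stat,q,n,expected", [
        (0.15, 0.01, 400, True),    # passes r_min 0.1 and 2/sqrt(400)=0.1
        (0.15, 0.01, 100, False),   # 2/sqrt(100)=0.2 exceeds r
        (-0.5, 1e-6, 1000, False),  # negative correlations never retained
    ])
    def test_continuous_rule(self, stat, q, n, expected):
        assert retain_pair(self._rec(stat, q, n)) is expected

    def test_binary_rule(self):
        assert retain_pair(self._rec(0.3, 0.01, 50, kind="binary"))
        assert not retain_pair(self._rec(-0.3, 0.01, 50, kind="binary"))
        assert not retain_pair(self._rec(0.3, 0.2, 50, kind="binary"))

    @settings(deadline=None, max_examples=200)
    @given(r1=st.floats(-1, 1), r2=st.floats(-1, 1), q=st.floats(0, 1),
           n=st.integers(4, 10_000))
    def test_monotone_in_effect_size(self, r1, r2, q, n):
        lo, hi = sorted((r1, r2))
        for kind in ("continuous", "binary"):
            if retain_pair(self._rec(lo, q, n, kind)):
                assert retain_pair(self._rec(hi, q, n, kind))


class TestBuildM3:
    def test_no_retained_pairs_gives_zero_matrix(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.normal(size=(3, 40)),
                              index=["p0", "p1", "p2"],
                              columns=[f"c{i}" for i in range(40)])
        ep = EndpointTable("e0", "continuous",
                           pd.Series(rng.normal(size=40), index=scores.columns))
        recs = associate(scores, [ep], seed=0)
        m3 = build_m3(recs, list(scores.index), ["e0"])
        assert m3.shape == (3, 1)
        # with pure noise at n=40 the 2/sqrt(n)=0.32 floor makes retention rare
        assert m3.sum() <= 1

    def test_q_values_assigned_within_endpoint(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(size=(4, 60)),
                              index=list("abcd"), columns=[f"c{i}" for i in range(60)])
        y = scores.loc["a"] * 0.8 + rng.normal(scale=0.5, size=60)
        ep = EndpointTable("e0", "continuous", pd.Series(y.to_numpy(), index=scores.columns))
        recs = associate(scores, [ep], seed=0)
        build_m3(recs, list(scores.index), ["e0"])
        assert all(np.isfinite(r.q) for r in recs)
        strong = next(r for r in recs if r.pathway_id == "a")
        assert strong.retained
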