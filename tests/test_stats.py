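"""Rank tests, van Elteren stratification, multiplicity, networks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from catfish.errors import ParameterError
from catfish.stats import (
    bh_adjust,
    correlation_network,
    holm_adjust,
    mww_test,
    spearman_test,
    stratified_mww,
)


def enumeration_mww_p(x, y):
    """Independent oracle: exact two-sided p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = abs(sum(
        1 for a in x for b in y if a > b
    ) - n1 * len(y) / 2)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        count += abs(u - n1 * len(ys) / 2) >= obs - 1e-12
    return count / total


class TestMWW:
    def test_separated_samples_exact(self):
        res = mww_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        # all 3 x-values below all y: U (x over y) = 0; 2 of C(6,3)=20
        # labelings are as extreme, so two-sided p = 0.1
        assert min(res.u, 9 - res.u) == 0
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(enumeration_mww_p(
            np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        ))

    def test_exact_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal(4)
            y = rng.standard_normal(5)
            res = mww_test(x, y)
            assert res.p == pytest.approx(enumeration_mww_p(x, y))

    def test_identical_multisets_are_degenerate(self):
        res = mww_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(100)
        reps = 2000
        rej = 0
        for _ in range(reps):
            rej += mww_test(rng.standard_normal(20), rng.standard_normal(20)).p < 0.05
        assert 0.04 <= rej / reps <= 0.06

    def test_empty_sample_raises(self):
        with pytest.raises(ParameterError):
            mww_test([], [1.0])


def perm_oracle_stratified(df, n_perm=10_000, seed=0):
    """Within-stratum label-permutation null for the van Elteren statistic.

    Recomputes the weighted centred rank-sum from scratch on numpy arrays,
    independently of the implementation under test.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    strata = []
    g1 = sorted(df["group"].unique())[0]
    for _, sub in df.groupby("stratum"):
        ranks = rankdata(sub["value"].to_numpy())
        is_g1 = (sub["group"] == g1).to_numpy()
        n_all = len(ranks)
        weight = 1.0 / (n_all + 1.0)
        mean = is_g1.sum() * (n_all + 1) / 2.0
        strata.append((ranks, is_g1, weight, mean))

    def statistic(masks):
        return sum(
            w * (ranks[m].sum() - mean)
            for (ranks, _, w, mean), m in zip(strata, masks)
        )

    obs = statistic([m for _, m, _, _ in strata])
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic([rng.permutation(m) for _, m, _, _ in strata])
    return float(np.mean(np.abs(null) >= abs(obs) - 1e-12))


class TestStratifiedMWW:
    def test_single_stratum_reduces_to_mww(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12) + 0.8
        df = pd.DataFrame({
            "value": np.concatenate([x, y]),
            "group": ["a"] * 12 + ["b"] * 12,
            "stratum": "s1",
        })
        res = stratified_mww(df)
        plain = mww_test(x, y, use_continuity=False)
        assert res.p == pytest.approx(plain.p, abs=1e-12)
        # and close to the default continuity-corrected branch
        assert res.p == pytest.approx(mww_test(x, y).p, abs=0.02)

    def test_opposite_shifts_cancel(self):
        x = np.arange(8.0)
        rows = []
        for stratum, shift in (("s1", 3.0), ("s2", -3.0)):
            rows += [(v, "a", stratum) for v in x]
            rows += [(v + shift, "b", stratum) for v in x]
        res = stratified_mww(pd.DataFrame(rows, columns=["value", "group", "stratum"]))
        assert abs(res.statistic) < 1e-9
        assert res.p == pytest.approx(1.0)

    def test_strata_missing_a_group_are_skipped(self):
        rows = [(1.0, "a", "s1"), (2.0, "b", "s1"), (3.0, "a", "s2")]
        res = stratified_mww(pd.DataFrame(rows, columns=["value", "group", "stratum"]))
        assert res.n_strata_used == 1
        assert res.skipped_strata == ("s2",)
        with pytest.raises(ParameterError):
            stratified_mww(pd.DataFrame(
                [(1.0, "a", "s1"), (2.0, "a", "s1"), (1.0, "b", "s2")],
                columns=["value", "group", "stratum"],
            ))

    def test_matches_permutation_oracle_on_small_instances(self):
        rng = np.random.default_rng(8)
        for rep in range(4):
            rows = []
            for s in ("s1", "s2", "s3"):
                n = rng.integers(3, 7)
                rows += [(v, "a", s) for v in rng.standard_normal(n)]
                rows += [(v + 0.5, "b", s) for v in rng.standard_normal(n)]
            df = pd.DataFrame(rows, columns=["value", "group", "stratum"])
            p_perm = perm_oracle_stratified(df, n_perm=4000, seed=rep)
            assert stratified_mww(df).p == pytest.approx(p_perm, abs=0.03)

    def test_power_under_common_shift(self):
        rng = np.random.default_rng(12)
        reps = 200
        hits = 0
        for _ in range(reps):
            rows = []
            for s in range(9):
                rows += [(v, "a", f"s{s}") for v in rng.standard_normal(8)]
                rows += [(v + 1.0, "b", f"s{s}") for v in rng.standard_normal(8)]
            df = pd.DataFrame(rows, columns=["value", "group", "stratum"])
            hits += stratified_mww(df).p < 0.05
        assert hits / reps > 0.9


class TestAdjustments:
    def test_holm_hand_oracle(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_bh_hand_oracle(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_capped(self):
        np.testing.assert_allclose(holm_adjust([0.5] * 4), [1.0] * 4)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_adjusted_at_least_raw_and_order_preserved(self, adjust):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        adj = adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_invalid_pvalues_raise(self, adjust):
        with pytest.raises(ParameterError):
            adjust([0.5, 1.2])


class TestSpearman:
    def test_exact_small_n_against_scipy_approx_direction(self):
        x = [1.0, 2, 3, 4, 5, 6]
        rho, p = spearman_test(x, x)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(6) * 2, rel=0.5)

    def test_exact_permutation_p_for_n5(self):
        # perfectly anti-ranked n=5: 2 of 120 permutations are as extreme
        rho, p = spearman_test([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 120)

    def test_constant_input_flagged(self):
        rho, p = spearman_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_t_approx_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        rho, p = spearman_test(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCorrelationNetwork:
    def _features(self, rng, n=16, structures=6, klass="any"):
        cols = {f"s{i:02d}__{klass}": rng.standard_normal(n) for i in range(structures)}
        return pd.DataFrame(cols)

    def test_identical_columns_yield_perfect_edge(self):
        rng = np.random.default_rng(0)
        df = self._features(rng)
        df["s01__any"] = df["s00__any"]
        g = correlation_network(df, "any")
        assert g.has_edge("s00", "s01")
        assert g["s00"]["s01"]["rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        df = self._features(rng)
        df["s02__any"] = df["s01__any"] * 0.9 + 0.1 * rng.standard_normal(16)
        g1 = correlation_network(df, "any")
        df2 = df.copy()
        df2["s01__any"] = np.exp(df2["s01__any"])  # strictly monotone
        g2 = correlation_network(df2, "any")
        assert set(g1.edges) == set(g2.edges)
        for u, v in g1.edges:
            assert g1[u][v]["rho"] == pytest.approx(g2[u][v]["rho"])

    def test_all_missing_column_keeps_node_without_edges(self):
        rng = np.random.default_rng(6)
        df = self._features(rng)
        df["s03__any"] = np.nan
        g = correlation_network(df, "any")
        assert "s03" in g.nodes
        assert not any("s03" in e for e in g.edges)

    def test_planted_correlated_block_recovered(self):
        rng = np.random.default_rng(9)
        found = 0
        reps = 30
        for _ in range(reps):
            df = self._features(rng, n=16, structures=8)
            base = rng.standard_normal(16)
            for s in ("s00", "s01", "s02"):
                df[f"{s}__any"] = 0.95 * base + math.sqrt(1 - 0.95**2) * rng.standard_normal(16)
            g = correlation_network(df, "any")
            found += all(
                g.has_edge(u, v)
                for u, v in itertools.combinations(("s00", "s01", "s02"), 2)
            )
        assert found / reps >= 0.8

    def test_unknown_class_raises(self):
        with pytest.raises(ParameterError):
            correlation_network(pd.DataFrame({"s0__any": [1.0, 2, 3, 4]}), "coloc")
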