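import numpy as np
import pandas as pd
import pytest
from scipy import stats

import moultmap as mm
from moultmap.ctree import _independence_test


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.size ** 2 * (a.size - 1))
                     + vb ** 2 / (b.size ** 2 * (b.size - 1)))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def anova_oracle(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, N = len(groups), allv.size
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return F, 2 * min(stats.f.sf(F, k - 1, N - k), 0.5)


def tukey_oracle_p(groups, i, j):
    """Studentized-range p-value for the (j, i) Tukey comparison."""
    k = len(groups)
    N = sum(g.size for g in groups)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - k)
    diff = groups[j].mean() - groups[i].mean()
    se = np.sqrt(msw / 2 * (1 / groups[i].size + 1 / groups[j].size))
    q = abs(diff) / se
    return stats.studentized_range.sf(q, k, N - k)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples(self):
        res = mm.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_example(self):
        res = mm.welch_t([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-1.549, abs=5e-4)
        assert res.df == pytest.approx(2.94, abs=5e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 11), rng.normal(0.5, 2, 9)
        r1, r2 = mm.welch_t(a, b), mm.welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_small_group_or_degenerate_rejected(self):
        with pytest.raises(ValueError):
            mm.welch_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            mm.welch_t([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

class TestManova:
    def test_identical_groups(self):
        g = np.tile([[1.0, 2.0]], (5, 1))
        res = mm.manova_pillai([g, g])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_second_dimension_reduces_to_anova(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([rng.normal(0, 1, 12), np.full(12, 7.0)])
        b = np.column_stack([rng.normal(1, 1, 15), np.full(15, 7.0)])
        res = mm.manova_pillai([a, b])
        F, _ = anova_oracle([a[:, 0], b[:, 0]])
        assert res.statistic == pytest.approx(F, rel=1e-9)

    def test_matches_statsmodels_pillai(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(11)
        frames = []
        for gi, (mu1, mu2) in enumerate([(0, 0), (1, 0.5), (0.3, -0.4)]):
            frames.append(pd.DataFrame({
                "y1": rng.normal(mu1, 1, 14), "y2": rng.normal(mu2, 1, 14),
                "g": str(gi)}))
        df = pd.concat(frames, ignore_index=True)
        sm_res = MANOVA.from_formula("y1 + y2 ~ C(g)", data=df).mv_test()
        table = sm_res.results["C(g)"]["stat"]
        groups = [df[df.g == g][["y1", "y2"]].to_numpy() for g in "012"]
        res = mm.manova_pillai(groups)
        assert res.estimate == pytest.approx(table.loc["Pillai's trace", "Value"], rel=1e-8)
        assert res.statistic == pytest.approx(table.loc["Pillai's trace", "F Value"], rel=1e-8)
        assert res.p == pytest.approx(table.loc["Pillai's trace", "Pr > F"], abs=1e-10)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

class TestAnovaTukey:
    def test_identical_groups_zero_f_zero_differences(self):
        g = np.array([1.0, 2.0, 3.0])
        anova, pairs = mm.anova_tukey([g, g])
        assert anova.statistic == 0.0 and anova.p == 1.0
        assert all(p.estimate == 0.0 for p in pairs)

    def test_near_degenerate_means_recovered(self):
        rng = np.random.default_rng(0)
        eps = 1e-9
        groups = [np.full(4, m) + rng.normal(0, eps, 4) for m in (0.0, 1.0, 2.0)]
        _, pairs = mm.anova_tukey(groups)
        by_name = {p.name: p.estimate for p in pairs}
        assert by_name["2-1"] == pytest.approx(1.0, abs=1e-6)
        assert by_name["3-1"] == pytest.approx(2.0, abs=1e-6)

    def test_pair_orientation_is_later_minus_earlier(self):
        groups = [np.array([0.0, 0.1, -0.1]), np.array([2.0, 2.1, 1.9])]
        _, pairs = mm.anova_tukey(groups, labels=["3", "5"])
        assert pairs[0].name == "5-3"
        assert pairs[0].estimate == pytest.approx(2.0)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            mm.anova_tukey([np.array([1.0, 2.0])])


# ---------------------------------------------------------------------------
# conditional inference tree
# ---------------------------------------------------------------------------

def _frame(y, **cov):
    df = pd.DataFrame({"d13C_raw": y[:, 0], "d18O_raw": y[:, 1]})
    for k, v in cov.items():
        if isinstance(v[0], str):
            df[k] = pd.array(v, dtype="string")
        else:
            df[k] = v
    return df


class TestIndependenceTest:
    def test_constant_covariate_gives_zero_statistic(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(30, 2))
        g = np.ones((30, 1)) * 4.0
        stat, df, p = _independence_test(g, h)
        assert stat == 0.0 and p == 1.0

    def test_bivariate_response_gives_chi2_2_df(self):
        rng = np.random.default_rng(2)
        stat, df, p = _independence_test(rng.normal(size=(40, 1)),
                                         rng.normal(size=(40, 2)))
        assert df == 2

    def test_invariant_to_affine_transform_of_covariate(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=(25, 1))
        h = rng.normal(size=(25, 2))
        s1 = _independence_test(g, h)[0]
        s2 = _independence_test(3.0 * g - 7.0, h)[0]
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestTree:
    def test_well_separated_groups_split_on_group_id(self):
        rng = np.random.default_rng(0)
        y = np.vstack([rng.normal([0, 0], 0.1, (30, 2)),
                       rng.normal([1, 1], 0.1, (30, 2))])  # 10 SDs apart
        df = _frame(y, group=["a"] * 30 + ["b"] * 30,
                    junk=rng.normal(size=60))
        cit = mm.fit_cit(df, covariates=["group", "junk"])
        assert cit.root_.selected_covariate == "group"
        assert cit.root_.adjusted_p < 0.001
        left, right = cit.root_.children
        assert {left.n, right.n} == {30}

    def test_constant_response_yields_single_terminal_node(self):
        y = np.tile([[1.0, 2.0]], (30, 1))
        df = _frame(y, x=np.arange(30.0))
        cit = mm.fit_cit(df, covariates=["x"])
        assert cit.root_.is_terminal
        assert len(cit.nodes_) == 1

    def test_numeric_cutpoint_is_max_left_observed_value(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([np.linspace(20, 23.5, 25), np.linspace(24.5, 28, 25)])
        y = np.vstack([rng.normal([0, 0], 0.2, (25, 2)),
                       rng.normal([3, 3], 0.2, (25, 2))])
        df = _frame(y, tarsus=x)
        cit = mm.fit_cit(df, covariates=["tarsus"])
        assert cit.root_.selected_covariate == "tarsus"
        assert cit.root_.cutpoint == pytest.approx(23.5)

    def test_node_ids_are_depth_first_preorder(self):
        rng = np.random.default_rng(8)
        y = np.vstack([rng.normal([0, 0], 0.1, (20, 2)),
                       rng.normal([2, 2], 0.1, (20, 2)),
                       rng.normal([5, 5], 0.1, (20, 2))])
        df = _frame(y, g=["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        cit = mm.fit_cit(df, covariates=["g"])
        ids = [nd.node_id for nd in cit.nodes_]
        assert ids == list(range(1, len(ids) + 1))
        # children partition the parent's records
        for nd in cit.nodes_:
            if nd.children:
                merged = np.sort(np.concatenate(
                    [c.indices for c in nd.children]))
                assert np.array_equal(merged, np.sort(nd.indices))

    def test_missing_covariate_values_are_tolerated(self):
        rng = np.random.default_rng(9)
        y = np.vstack([rng.normal([0, 0], 0.1, (25, 2)),
                       rng.normal([2, 2], 0.1, (25, 2))])
        x = np.concatenate([np.zeros(25), np.ones(25)])
        x[::10] = np.nan
        df = _frame(y, x=x)
        cit = mm.fit_cit(df, covariates=["x"])
        assert not cit.root_.is_terminal
        assert cit.labels_.size == 50  # every row (incl. missing x) labelled

    def test_split_recovery_rate(self):
        """With two well-separated groups the grouping covariate is chosen
        at the root in >= 95% of 200 replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(200):
            y = np.vstack([rng.normal([0, 0], 0.5, (30, 2)),
                           rng.normal([2, 2], 0.5, (30, 2))])
            df = _frame(y, group=["a"] * 30 + ["b"] * 30,
                        noise1=rng.normal(size=60), noise2=rng.normal(size=60))
            cit = mm.fit_cit(df, covariates=["group", "noise1", "noise2"])
            hits += cit.root_.selected_covariate == "group"
        assert hits / 200 >= 0.95

    def test_too_few_records_rejected(self):
        y = np.random.default_rng(0).normal(size=(5, 2))
        df = _frame(y, x=np.arange(5.0))
        with pytest.raises(ValueError, match="at least"):
            mm.fit_cit(df, covariates=["x"])


class TestOracleAgreement:
    """welch_t, ANOVA and Tukey against brute-force formulas on random
    small instances (tight numerical agreement)."""

    def test_welch_against_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2),
                           rng.integers(3, 12))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2),
                           rng.integers(3, 12))
            res = mm.welch_t(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_anova_and_tukey_against_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 9))
                      for _ in range(k)]
            anova, pairs = mm.anova_tukey(groups)
            F, _ = anova_oracle(groups)
            assert anova.statistic == pytest.approx(F, abs=1e-10)
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    pair = pairs[idx]
                    idx += 1
                    assert pair.estimate == pytest.approx(
                        groups[j].mean() - groups[i].mean(), abs=1e-12)
                    assert pair.p == pytest.approx(
                        tukey_oracle_p(groups, i, j), abs=1e-8)
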