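"""Group statistics: gating, Kruskal-Wallis, KS, t reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from microgt.stats import (
    GroupSample,
    compare_cohorts,
    kruskal_wallis,
    ks_two_sample,
    lilliefors_gate,
    t_from_summary,
    unpaired_t,
)


def g(label, values):
    return GroupSample(label=label, values=np.asarray(values, dtype=float))


class TestKruskalWallis:
    def test_hand_computed_h_and_mean_ranks(self):
        res = kruskal_wallis([g("a", [1, 2, 3]), g("b", [4, 5, 6])])
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        assert res.mean_ranks == {"a": 2.0, "b": 5.0}

    def test_identical_groups(self):
        res = kruskal_wallis([g("a", [1.0, 1.0]), g("b", [1.0, 1.0])])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            xs = [rng.integers(0, 6, size=rng.integers(5, 20)).astype(float)
                  for _ in range(3)]
            if all(np.all(x == xs[0][0]) for x in xs):
                continue
            res = kruskal_wallis([g(str(i), x) for i, x in enumerate(xs)])
            h, p = sps.kruskal(*xs)
            assert res.statistic == pytest.approx(h, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        xs = [rng.normal(size=8), rng.normal(1.0, 1.0, size=6), rng.normal(size=7)]
        res1 = kruskal_wallis([g(str(i), x) for i, x in enumerate(xs)])
        res2 = kruskal_wallis([g(str(i), np.exp(x)) for i, x in enumerate(xs)])
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-10)

    def test_mean_ranks_within_bounds(self, rng):
        xs = [rng.normal(size=10) for _ in range(3)]
        res = kruskal_wallis([g(str(i), x) for i, x in enumerate(xs)])
        for r in res.mean_ranks.values():
            assert 1.0 <= r <= 30.0


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sample(g("a", [1, 2, 3]), g("b", [1, 2, 3]))
        assert res.statistic == 0.0

    def test_disjoint_supports(self):
        res = ks_two_sample(g("a", [1, 2]), g("b", [10, 11]))
        assert res.statistic == 1.0

    def test_hand_computed_d(self):
        res = ks_two_sample(g("a", [1, 2, 3]), g("b", [2, 3, 4]))
        assert res.statistic == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=30), rng.normal(0.5, 1.2, size=40)
            r1 = ks_two_sample(g("a", a), g("b", b))
            r2 = ks_two_sample(g("b", b), g("a", a))
            assert r1.statistic == r2.statistic
            assert 0.0 <= r1.statistic <= 1.0

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=200), rng.normal(0.3, 1.0, size=150)
            res = ks_two_sample(g("a", a), g("b", b))
            d, p = sps.ks_2samp(a, b, method="asymp")
            assert res.statistic == pytest.approx(d, abs=1e-12)
            assert res.p_value == pytest.approx(p, rel=0.05, abs=1e-6)


class TestT:
    def test_equal_means_give_zero(self):
        res = t_from_summary(5.0, 1.0, 4, 5.0, 2.0, 4)
        assert res.statistic == 0.0

    def test_published_cortex_value(self):
        # soluble vs formic-acid-extracted amyloid, n = 4 each
        res = t_from_summary(1.9, 0.7, 4, 422.6, 118.1, 4)
        assert res.df == 6
        assert res.statistic == pytest.approx(-3.5627, rel=0.02)

    def test_published_behavior_value(self):
        res = t_from_summary(-10.5, 10.1, 5, -46.1, 5.6, 5)
        assert res.df == 8
        assert abs(res.statistic) == pytest.approx(3.0735, rel=0.02)

    def test_unpaired_matches_summary_form(self, rng):
        a, b = rng.normal(size=9), rng.normal(1.0, 2.0, size=14)
        res = unpaired_t(g("a", a), g("b", b))
        sem = lambda x: x.std(ddof=1) / np.sqrt(x.size)
        ref = t_from_summary(a.mean(), sem(a), a.size, b.mean(), sem(b), b.size)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-12)

    def test_sign_convention_first_minus_second(self, rng):
        a = rng.normal(size=10)
        res = unpaired_t(g("a", a), g("b", a + 3.0))
        assert res.statistic < 0

    def test_identical_samples(self, rng):
        a = rng.normal(size=8)
        with pytest.raises(ValueError):
            unpaired_t(g("a", np.ones(5)), g("b", np.ones(5)))
        res = unpaired_t(g("a", a), g("b", a.copy()))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_bad_sem_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 0.0, 4, 2.0, 1.0, 4)


class TestGate:
    def test_normal_sample_parametric(self):
        x = np.random.default_rng(0).normal(size=200)
        assert lilliefors_gate(g("a", x)) == "parametric"

    def test_exponential_sample_nonparametric(self):
        rejected = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=100)
            rejected += lilliefors_gate(g("a", x)) == "nonparametric"
        assert rejected > 45

    def test_heteroscedastic_groups_nonparametric(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1.0, 100)
        b = rng.normal(0, 5.0, 100)
        assert lilliefors_gate([g("a", a), g("b", b)]) == "nonparametric"

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            lilliefors_gate(g("a", np.ones(20)))

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            lilliefors_gate(g("a", [1.0, 2.0, 3.0]))


def test_compare_cohorts_table(rng):
    rows = []
    for metric in ("mean_degree", "modularity_q"):
        for grp, shift in (("WT", 1.0), ("FAD", 0.0), ("Act", 0.5)):
            for s in range(5):
                rows.append({
                    "metric": metric, "group": grp,
                    "value": shift + rng.normal(0, 0.1),
                })
    out = compare_cohorts(pd.DataFrame(rows))
    assert set(out["metric"]) == {"mean_degree", "modularity_q"}
    assert (out["method"] == "Kruskal-Wallis H").all()
    assert {"mean_rank[WT]", "mean[WT]", "sem[WT]"} <= set(out.columns)
    assert (out["p_value"] < 0.05).all()


def test_permuted_labels_equalize_mean_ranks(rng):
    # identical distributions: mean ranks agree in expectation
    diffs = []
    for _ in range(200):
        pooled = rng.normal(size=30)
        rng.shuffle(pooled)
        res = kruskal_wallis([g("a", pooled[:15]), g("b", pooled[15:])])
        diffs.append(res.mean_ranks["a"] - res.mean_ranks["b"])
    assert abs(np.mean(diffs)) < 1.0
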