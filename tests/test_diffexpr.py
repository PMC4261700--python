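"""Normalization, the two-library test, q-values, calls and intersections."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hadpipe.diffexpr import (
    call_dets,
    delta_ct,
    det_tallies,
    intersect_up_sets,
    mars_statistic,
    mars_table,
    qvalues,
    sample_correlations,
    tmm_normalization,
)


def _counts(data, samples=None):
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    return df


class TestTmm:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, size=200)
        counts = _counts({"a": col, "b": col})
        f = tmm_normalization(counts)
        assert f["a"] == pytest.approx(1.0) and f["b"] == pytest.approx(1.0)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, size=300)
        counts = _counts({"a": col, "b": 2 * col})
        f = tmm_normalization(counts)
        # every gene-wise M is 0 after library-size adjustment
        assert f["a"] == pytest.approx(1.0, abs=1e-9)
        assert f["b"] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_toy_with_dominating_gene(self):
        # 10 genes; sample b doubles one dominating gene, all else equal
        base = np.array([100, 120, 80, 150, 200, 90, 110, 140, 60, 5000])
        other = base.copy()
        other[9] = 3 * base[9]
        counts = _counts({"a": base, "b": other})
        f = tmm_normalization(counts, ref_sample="a")
        # hand computation: after trimming by M and A the dominating gene and
        # extremes drop out; remaining Ms are all log2(Na/Nb) exactly
        na, nb = base.sum(), other.sum()
        kept_m = np.log2((base / nb) / (base / na))  # equal for all null genes
        expected = 2.0 ** kept_m[0]
        assert f["b"] / f["a"] == pytest.approx(expected / 1.0, rel=1e-6)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_geometric_mean_always_one(self):
        rng = np.random.default_rng(2)
        counts = _counts({s: rng.integers(0, 500, size=100) for s in "abcd"})
        f = tmm_normalization(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)


class TestMars:
    def test_perfect_null(self):
        r = mars_statistic(100, 100, 1e6, 1e6)
        assert r.M == 0.0 and r.z == 0.0 and r.p == 1.0

    def test_agrees_with_exact_conditional_binomial(self):
        r = mars_statistic(100, 50, 1e6, 1e6)
        exact = stats.binomtest(100, 150, 0.5).pvalue
        assert abs(r.p - exact) <= 0.01

    def test_swap_negates_m_and_z_preserves_p(self):
        r1 = mars_statistic(80, 130, 2e6, 1e6)
        r2 = mars_statistic(130, 80, 1e6, 2e6)
        assert r1.M == pytest.approx(-r2.M)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == r2.p

    def test_both_zero_not_tested(self):
        r = mars_statistic(0, 0, 1e6, 1e6)
        assert not r.tested and math.isnan(r.p)

    def test_table_matches_scalar(self):
        counts = _counts({"a": [10, 0, 300], "b": [20, 5, 280]})
        lib = pd.Series({"a": 1e6, "b": 1e6})
        tab = mars_table(counts, "a", "b", lib)
        for i, (k1, k2) in enumerate([(10, 20), (0, 5), (300, 280)]):
            r = mars_statistic(k1, k2, 1e6, 1e6)
            assert tab["M"].iloc[i] == pytest.approx(r.M)
            assert tab["p"].iloc[i] == pytest.approx(r.p)


class TestQvalues:
    def test_single_p_bh(self):
        with pytest.warns(UserWarning):
            q = qvalues([0.01], method="storey")  # falls back to BH
        assert q[0] == pytest.approx(0.01)

    def test_bh_step_up_hand_case(self):
        q = qvalues([0.01, 0.02, 0.03], method="bh")
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        q = qvalues(p, method="storey")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        assert qvalues(p[perm], "storey") == pytest.approx(qvalues(p, "storey")[perm])

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=10**4)
        q = qvalues(p, method="storey")
        # q ~= pi0 * BH q; with uniform p the smallest q estimates pi0 * m * p(1)
        bh = qvalues(p, method="bh")
        implied_pi0 = np.median(q[bh > 0] / bh[bh > 0])
        assert 0.9 <= implied_pi0 <= 1.0


class TestCallsAndSets:
    def test_threshold_gates(self):
        df = pd.DataFrame(
            {"M": [2.0, 0.5, -2.0, 2.0], "q": [0.01, 0.01, 0.01, 0.2]},
            index=["up_gene", "small_fc", "down_gene", "not_sig"],
        )
        called = call_dets(df)
        assert list(called["call"]) == ["up", "ns", "down", "ns"]
        assert det_tallies(called) == {"up": 1, "down": 1, "total_de": 2}

    def test_p_gate_configurable(self):
        df = pd.DataFrame({"M": [2.0], "p": [0.01]})
        called = call_dets(df, stat_col="p")
        assert list(called["call"]) == ["up"]

    def test_intersections_match_brute_force(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        contrasts = ["Caf/Cof", "Caf/Cuf", "Caf/Tof", "Cam/Com", "Cam/Cum", "Cam/Tom"]
        sex_of = {c: ("f" if c.endswith("f") else "m") for c in contrasts}
        up = {c: set(rng.choice(genes, size=25, replace=False)) for c in contrasts}
        out = intersect_up_sets(up, sex_of)
        brute_f = up["Caf/Cof"] & up["Caf/Cuf"] & up["Caf/Tof"]
        brute_m = up["Cam/Com"] & up["Cam/Cum"] & up["Cam/Tom"]
        assert out["consistent_f"] == brute_f
        assert out["consistent_m"] == brute_m
        assert out["consistent_all"] == brute_f & brute_m

    def test_disjoint_and_identical_sets(self):
        sex_of = {"a": "f", "b": "f"}
        assert intersect_up_sets({"a": {"g1"}, "b": {"g2"}}, sex_of)["consistent_f"] == set()
        assert intersect_up_sets({"a": {"g1"}, "b": {"g1"}}, sex_of)["consistent_all"] == {"g1"}


class TestCorrelationsAndDeltaCt:
    def test_self_and_monotone_transform_correlation_one(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 1000, size=50).astype(float)
        counts = pd.DataFrame({"a": x, "b": x ** 2})  # monotone transform
        lib = pd.Series({"a": 1.0, "b": 1.0})
        rho = sample_correlations(counts, lib)
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_ranked_toy_with_tie(self):
        counts = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 2, 4, 5, 6]})
        lib = pd.Series({"a": 1.0, "b": 1.0})
        rho = sample_correlations(counts, lib)
        expected = stats.spearmanr([1, 2, 3, 4, 5], [2, 2, 4, 5, 6]).statistic
        assert rho.loc["a", "b"] == pytest.approx(expected)

    def test_zero_variance_column_undefined(self):
        counts = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        lib = pd.Series({"a": 1.0, "b": 1.0})
        rho = sample_correlations(counts, lib)
        assert math.isnan(rho.loc["a", "b"]) and math.isnan(rho.loc["b", "b"])

    @pytest.mark.parametrize(
        "t,r,expected", [(20.0, 20.0, 1.0), (18.0, 20.0, 4.0), (22.0, 20.0, 0.25)]
    )
    def test_delta_ct_scalar(self, t, r, expected):
        assert delta_ct(t, r) == pytest.approx(expected)

    def test_delta_ct_replicates(self):
        mean, sd = delta_ct([20.0, 20.0, 20.0], [20.0, 20.0, 20.0])
        assert mean == pytest.approx(1.0) and sd == 0.0

    def test_delta_ct_errors(self):
        with pytest.raises(ValueError):
            delta_ct([20.0], [])
        with pytest.raises(ValueError):
            delta_ct(-1.0, 20.0)
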