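import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from skyisland.containers import DistanceMatrix, ValidationError
from skyisland.distances import bray_curtis
from skyisland.permtests import (mantel, mantel_correlogram, partial_mantel,
                                 permanova, progressive_holm)


def dm(pts_or_vals, labels=None, from_points=True):
    if from_points:
        vals = squareform(pdist(np.asarray(pts_or_vals, float)))
    else:
        vals = np.asarray(pts_or_vals, float)
    labels = labels or [f"s{i}" for i in range(vals.shape[0])]
    return DistanceMatrix(labels, vals)


# ---------------------------------------------------------------------------
# independent brute-force oracles (definitional, no shared code paths)


def oracle_mantel(A, B, alternative="greater"):
    n = A.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(M):
        return stats.pearsonr(M[iu], B[iu]).statistic

    obs = corr(A)
    vals = []
    for p in itertools.permutations(range(n)):
        Ap = A[np.ix_(p, p)]
        vals.append(corr(Ap))
    vals = np.asarray(vals)
    if alternative == "greater":
        count = (vals >= obs - 1e-12).sum()
    else:
        count = (np.abs(vals) >= abs(obs) - 1e-12).sum()
    return obs, count / len(vals)


def oracle_partial_mantel(A, B, C):
    n = A.shape[0]
    iu = np.triu_indices(n, 1)

    def pcor(a):
        rab = stats.pearsonr(a, B[iu]).statistic
        rac = stats.pearsonr(a, C[iu]).statistic
        rbc = stats.pearsonr(B[iu], C[iu]).statistic
        return (rab - rac * rbc) / np.sqrt((1 - rac ** 2) * (1 - rbc ** 2))

    obs = pcor(A[iu])
    count = total = 0
    for p in itertools.permutations(range(n)):
        total += 1
        if pcor(A[np.ix_(p, p)][iu]) >= obs - 1e-12:
            count += 1
    return obs, count / total


def oracle_permanova_oneway(D, groups):
    """Definitional PERMANOVA for one categorical factor: SS from within-group
    pairwise distances (Excoffier identity), exhaustive permutations."""
    groups = np.asarray(groups)
    n = len(groups)

    def pseudo_f(g):
        sst = (D[np.triu_indices(n, 1)] ** 2).sum() / n
        ssw = 0.0
        for lv in np.unique(g):
            idx = np.flatnonzero(g == lv)
            sub = D[np.ix_(idx, idx)]
            ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ssa = sst - ssw
        a = len(np.unique(g))
        return (ssa / (a - 1)) / (ssw / (n - a)), ssa / sst

    obs_f, obs_r2 = pseudo_f(groups)
    count = total = 0
    for p in itertools.permutations(range(n)):
        total += 1
        if pseudo_f(groups[list(p)])[0] >= obs_f - 1e-12:
            count += 1
    return obs_f, obs_r2, count / total


# ---------------------------------------------------------------------------


class TestPermanova:
    def test_perfect_separation(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 50.0)])
        design = pd.DataFrame({"grp": ["a"] * 4 + ["b"] * 4},
                              index=[f"s{i}" for i in range(8)])
        res = permanova(dm(pts), design, n_perm=199, seed=0)
        assert res.r_squared("grp") > 0.999
        # permutations preserving the two identical blocks tie the observed F
        assert res.p_value("grp") <= 0.05

    def test_matches_classical_anova(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=15)
        groups = np.repeat(["a", "b", "c"], 5)
        design = pd.DataFrame({"grp": groups},
                              index=[f"s{i}" for i in range(15)])
        res = permanova(dm(y[:, None]), design, n_perm=99, seed=0)
        f_classic = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res.table.loc["grp", "F"] == pytest.approx(f_classic, abs=1e-8)

    def test_exhaustive_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        groups = np.array(["a", "a", "b", "b", "a", "b"])
        design = pd.DataFrame({"grp": groups},
                              index=[f"s{i}" for i in range(6)])
        d = dm(pts)
        res = permanova(d, design, exhaustive=True)
        obs_f, obs_r2, p = oracle_permanova_oneway(d.values, groups)
        assert res.table.loc["grp", "F"] == pytest.approx(obs_f, abs=1e-10)
        assert res.r_squared("grp") == pytest.approx(obs_r2, abs=1e-10)
        assert res.p_value("grp") == pytest.approx(p, abs=1e-12)

    def test_continuous_term_equals_rda_partition(self):
        # with Euclidean distances, dbRDA on one continuous predictor equals
        # multivariate regression of the raw coordinates on that predictor
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(10, 3))
        v = rng.normal(size=10)
        design = pd.DataFrame({"v": v}, index=[f"s{i}" for i in range(10)])
        res = permanova(dm(Y), design, n_perm=99, seed=0)
        Yc = Y - Y.mean(axis=0)
        vc = (v - v.mean())[:, None]
        H = vc @ np.linalg.pinv(vc)
        r2_rda = ((H @ Yc) ** 2).sum() / (Yc ** 2).sum()
        assert res.r_squared("v") == pytest.approx(r2_rda, abs=1e-10)

    def test_r2_partition_sums_to_one(self, tiny_community, tiny_sites):
        bc = bray_curtis(tiny_community)
        design = tiny_sites.data[["elevation", "volcano"]]
        res = permanova(bc, design, n_perm=99, seed=0)
        r2 = res.table.loc[res.table.index != "Total", "R2"]
        assert r2.sum() == pytest.approx(1.0, abs=1e-10)
        assert res.table.loc[res.table.index != "Total", "df"].sum() == 5

    def test_collinear_term_rejected(self, tiny_community, tiny_sites):
        bc = bray_curtis(tiny_community)
        design = tiny_sites.data[["volcano", "watershed"]].copy()
        # watershed is a relabelling of volcano in the fixture -> collinear
        with pytest.raises(ValidationError, match="watershed"):
            permanova(bc, design, n_perm=99, seed=0)

    def test_matches_skbio_oneway(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 2))
        pts[4:] += 1.5
        groups = ["a"] * 4 + ["b"] * 5
        d = dm(pts)
        sk_res = sk_permanova(
            skbio.DistanceMatrix(d.values, ids=d.labels), groups,
            permutations=99)
        design = pd.DataFrame({"grp": groups}, index=d.labels)
        res = permanova(d, design, n_perm=99, seed=0)
        assert res.table.loc["grp", "F"] == pytest.approx(
            sk_res["test statistic"], abs=1e-8)


class TestMantel:
    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        d1 = dm(rng.normal(size=(7, 2)))
        assert mantel(d1, d1, n_perm=99, seed=0).r == pytest.approx(1.0)
        d2 = DistanceMatrix(d1.labels, 3.5 * d1.values)
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        dA = dm(rng.normal(size=(5, 2)))
        dB = dm(rng.normal(size=(5, 2)), labels=dA.labels)
        res = mantel(dA, dB, exhaustive=True)
        obs, p = oracle_mantel(dA.values, dB.values)
        assert res.r == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(5)
        dA = dm(rng.normal(size=(8, 2)))
        dB = dm(rng.normal(size=(8, 2)), labels=dA.labels)
        r_sk, _, _ = sk_mantel(skbio.DistanceMatrix(dA.values),
                               skbio.DistanceMatrix(dB.values),
                               permutations=0)
        assert mantel(dA, dB, n_perm=99, seed=0).r == pytest.approx(
            r_sk, abs=1e-10)

    def test_constant_matrix_rejected(self):
        ones = np.ones((4, 4)) - np.eye(4)
        d1 = dm(ones, from_points=False)
        d2 = dm(np.random.default_rng(0).normal(size=(4, 2)),
                labels=d1.labels)
        with pytest.raises(ValidationError, match="constant"):
            mantel(d1, d2, n_perm=99, seed=0)


class TestPartialMantel:
    def test_controlling_for_itself_gives_zero(self):
        rng = np.random.default_rng(6)
        dA = dm(rng.normal(size=(7, 2)))
        dB = dm(rng.normal(size=(7, 2)), labels=dA.labels)
        res = partial_mantel(dA, dB, dB, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-10)

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(7)
        rs, rps = [], []
        for _ in range(30):
            dA = dm(rng.normal(size=(12, 2)))
            dB = dm(rng.normal(size=(12, 2)), labels=dA.labels)
            dC = dm(rng.normal(size=(12, 2)), labels=dA.labels)
            rs.append(mantel(dA, dB, n_perm=99, seed=0).r)
            rps.append(partial_mantel(dA, dB, dC, n_perm=99, seed=0).r)
        assert np.mean(np.abs(np.array(rs) - np.array(rps))) < 0.05

    def test_exhaustive_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        dA = dm(rng.normal(size=(5, 2)))
        dB = dm(rng.normal(size=(5, 2)), labels=dA.labels)
        dC = dm(rng.normal(size=(5, 2)), labels=dA.labels)
        res = partial_mantel(dA, dB, dC, exhaustive=True)
        obs, p = oracle_partial_mantel(dA.values, dB.values, dC.values)
        assert res.r == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)


class TestCorrelogram:
    def test_monotone_response_gives_negative_first_class(self):
        elev = np.linspace(0, 1500, 12)
        pred = dm(np.abs(elev[:, None] - elev[None, :]), from_points=False)
        resp = dm(pred.values / 1500.0, from_points=False,
                  labels=pred.labels)
        res = mantel_correlogram(resp, pred, class_width=300.0, n_perm=99,
                                 seed=0)
        cls = res.classes
        assert cls.iloc[0]["r"] < 0  # near pairs more similar than average
        tested = cls[cls["tested"]]
        assert tested.iloc[-1]["r"] > cls.iloc[0]["r"]  # decay of similarity

    def test_null_response_rarely_significant(self):
        rng = np.random.default_rng(9)
        elev = np.linspace(0, 1500, 12)
        pred = dm(np.abs(elev[:, None] - elev[None, :]), from_points=False)
        n_sig = 0
        n_runs = 30
        for i in range(n_runs):
            resp = dm(rng.normal(size=(12, 3)), labels=pred.labels)
            res = mantel_correlogram(resp, pred, class_width=300.0,
                                     n_perm=99, seed=i)
            sig = (res.classes["P_corrected"].dropna() <= 0.05).any()
            n_sig += sig
        assert n_sig <= 0.1 * n_runs + 1

    def test_pairs_counted_once(self):
        elev = np.linspace(0, 1000, 9)
        pred = dm(np.abs(elev[:, None] - elev[None, :]), from_points=False)
        resp = dm(np.random.default_rng(0).normal(size=(9, 2)),
                  labels=pred.labels)
        res = mantel_correlogram(resp, pred, class_width=250.0, n_perm=99,
                                 seed=0)
        assert res.classes["n_pairs"].sum() == 9 * 8 // 2


def test_progressive_holm_matches_statsmodels_prefix():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    ps = [0.01, 0.2, 0.03, 0.5, 0.04]
    out = progressive_holm(ps)
    for i in range(len(ps)):
        ref = sm.multipletests(ps[:i + 1], method="holm")[1][i]
        assert out[i] == pytest.approx(ref, abs=1e-12)
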