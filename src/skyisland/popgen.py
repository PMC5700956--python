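"""Hierarchical distance-based AMOVA, pairwise FST, genotype distances,
and isolation by distance.

Two distance scales coexist here on purpose:

* ``genotype_sq_distance`` is the Smouse-Peakall squared distance between
  diploid multilocus genotypes (identical 0; AA-AB 1; AB-AC 1; AB-CD 2;
  AA-BC 3; AA-BB 4), the individual-level metric used for genetic
  ordinations and environmental fitting.

* ``amova`` and ``pairwise_fst`` partition variance at the allele-copy
  level (squared distances between allele copies, i.e. the codominant
  allele-frequency mode of classical AMOVA). Under the Balding-Nichols
  hierarchy the allele-level F_RT and F_SR equal the simulation targets
  in expectation, which is what makes parameter-recovery oracles possible;
  the genotype-level metric would inflate them by up to a factor of two.

Variance components come from the expected-mean-square linear system with
unequal-sample-size coefficients; F statistics are ratios of components;
P values are permutational (populations among regions for F_RT,
individuals among populations within regions for F_SR, individuals among
all populations for F_ST), with the add-one estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, GenotypeMatrix, ValidationError
from .permtests import MantelResult, mantel

__all__ = [
    "AmovaResult", "IbdResult",
    "genotype_sq_distance", "amova", "pairwise_fst", "ibd",
]

log = logging.getLogger("skyisland")


# ---------------------------------------------------------------------------
# genotype (individual-level) squared distance


def _one_hot_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Allele-count tensor Y (n, L, K) and per-call valid mask (n, L)."""
    calls = g.calls
    valid = ~g.missing_mask()
    K = int(calls.max()) + 1 if calls.size else 1
    n, L = valid.shape
    Y = np.zeros((n, L, K), dtype=np.int16)
    for slot in range(2):
        codes = calls[:, :, slot]
        for k in range(K):
            Y[:, :, k] += (codes == k) & valid
    return Y, valid


def genotype_sq_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Smouse-Peakall squared genotype distance, summed over shared loci.

    Per locus the squared distance is half the squared Euclidean distance
    between allele-count vectors, which reproduces the definitional table
    (AA-AA 0, AA-AB 1, AB-AC 1, AB-CD 2, AA-BC 3, AA-BB 4). Loci missing
    in either individual are skipped for that pair only.
    """
    all_missing = g.missing_mask().all(axis=1)
    if all_missing.any():
        bad = [g.individuals[i] for i in np.flatnonzero(all_missing)]
        raise ValidationError(f"individuals with all-missing calls: {bad}")
    Y, valid = _one_hot_counts(g)
    V = valid.astype(float)
    shared = V @ V.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValidationError(
            f"no shared scored loci between {g.individuals[i]!r} "
            f"and {g.individuals[j]!r}")
    D = np.zeros_like(shared)
    for k in range(Y.shape[2]):
        Zk = Y[:, :, k] * V
        sq = (Zk ** 2) @ V.T
        D += sq + sq.T - 2.0 * Zk @ Zk.T
    return DistanceMatrix(list(g.individuals), 0.5 * D, name="smouse_peakall_sq")


# ---------------------------------------------------------------------------
# AMOVA machinery (allele-copy level)


def _group_ss(counts: np.ndarray, m: np.ndarray) -> float:
    """Sum over loci of SS within one group from pooled allele counts.

    counts: (L, K) allele-copy counts; m: (L,) total copies per locus.
    SS_locus = (m^2 - sum_k c_k^2) / (2 m), the pairwise-mismatch identity.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ss = (m.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=1)) \
             / (2.0 * m)
    return float(np.where(m > 0, ss, 0.0).sum())


@dataclass
class AmovaResult:
    table: pd.DataFrame          # source, df, SS, MS, variance, pct_total
    components: dict             # sigma2_a, sigma2_b, sigma2_c (raw)
    f_rt: float
    f_sr: float
    f_st: float
    p_f_rt: float | None
    p_f_sr: float | None
    p_f_st: float | None
    truncated: bool              # True if any raw component < 0 was clamped
    grouping: dict = field(default_factory=dict)  # population -> region


class _AmovaData:
    """Pre-digested genotype data for fast permutation of AMOVA statistics."""

    def __init__(self, g: GenotypeMatrix, region_of_pop: dict):
        self.pops = g.populations
        self.regions = sorted({region_of_pop[p] for p in self.pops}, key=str)
        if len(self.regions) < 2:
            raise ValidationError("AMOVA needs at least two regions (F_RT undefined)")
        self.pop_index = {p: i for i, p in enumerate(self.pops)}
        self.region_index = {r: i for i, r in enumerate(self.regions)}
        self.ind_pop = np.array([self.pop_index[p] for p in g.population])
        self.pop_region = np.array([self.region_index[region_of_pop[p]]
                                    for p in self.pops])
        Y, valid = _one_hot_counts(g)
        n, L, K = Y.shape
        self.Y = Y.reshape(n, L * K).astype(float)
        self.valid = valid.astype(float)
        self.L, self.K = L, K
        self.n = n
        self.n_pop = np.bincount(self.ind_pop, minlength=len(self.pops))

    def _pooled(self, member_of: np.ndarray, n_groups: int):
        """Pooled allele counts (G, L, K) and copies (G, L) for a grouping of
        individuals given by ``member_of``."""
        ind = np.zeros((n_groups, self.n))
        ind[member_of, np.arange(self.n)] = 1.0
        counts = (ind @ self.Y).reshape(n_groups, self.L, self.K)
        m = 2.0 * (ind @ self.valid)
        return counts, m

    def ss_for(self, ind_pop: np.ndarray, pop_region: np.ndarray):
        """(SS_AR, SS_AP, SS_WP) for a given individual->pop, pop->region map."""
        P = len(self.pops)
        R = len(self.regions)
        cp, mp = self._pooled(ind_pop, P)
        ss_wp = sum(_group_ss(cp[p], mp[p]) for p in range(P))
        # pool populations into regions
        cr = np.zeros((R, self.L, self.K))
        mr = np.zeros((R, self.L))
        for p in range(P):
            cr[pop_region[p]] += cp[p]
            mr[pop_region[p]] += mp[p]
        ss_wr = sum(_group_ss(cr[r], mr[r]) for r in range(R))
        ss_total = _group_ss(cr.sum(axis=0), mr.sum(axis=0))
        return ss_total - ss_wr, ss_wr - ss_wp, ss_wp

    def components(self, ind_pop: np.ndarray, pop_region: np.ndarray):
        """Variance components via the unequal-size EMS linear system."""
        ss_ar, ss_ap, ss_wp = self.ss_for(ind_pop, pop_region)
        P, R = len(self.pops), len(self.regions)
        copies = 2.0 * np.bincount(ind_pop, minlength=P)  # allele copies per pop
        N = copies.sum()
        Nr = np.zeros(R)
        for p in range(P):
            Nr[pop_region[p]] += copies[p]
        df_ar, df_ap, df_wp = R - 1, P - R, N - P
        if df_wp <= 0:
            raise ValidationError(
                "AMOVA needs within-population degrees of freedom")
        ms_ar, ms_wp = ss_ar / df_ar, ss_wp / df_wp
        s2c = ms_wp
        if df_ap == 0:
            # every population is its own region: the among-populations-
            # within-regions level vanishes and the design is two-level
            n_0 = (N - (Nr ** 2).sum() / N) / df_ar
            s2a = (ms_ar - s2c) / n_0
            return (s2a, 0.0, s2c), (ss_ar, 0.0, ss_wp), (df_ar, 0, df_wp)
        sum_np2_over_nr = sum(
            (copies[pop_region == r] ** 2).sum() / Nr[r] for r in range(R))
        n_prime = (N - sum_np2_over_nr) / df_ap
        n_2 = (sum_np2_over_nr - (copies ** 2).sum() / N) / df_ar
        n_3 = (N - (Nr ** 2).sum() / N) / df_ar
        ms_ap = ss_ap / df_ap
        s2b = (ms_ap - s2c) / n_prime
        s2a = (ms_ar - s2c - n_2 * s2b) / n_3
        return (s2a, s2b, s2c), (ss_ar, ss_ap, ss_wp), (df_ar, df_ap, df_wp)


def _f_stats(comp, truncate: bool):
    s = np.asarray(comp, dtype=float)
    truncated = bool((s < 0).any())
    if truncate:
        s = np.clip(s, 0.0, None)
    a, b, c = s
    total = a + b + c
    f_rt = a / total if total > 0 else 0.0
    f_sr = b / (b + c) if (b + c) > 0 else 0.0
    f_st = (a + b) / total if total > 0 else 0.0
    return f_rt, f_sr, f_st, truncated


def amova(g: GenotypeMatrix, grouping: dict, n_perm: int = 1000, seed: int = 0,
          truncate: bool = True, drop_singletons: bool = True) -> AmovaResult:
    """Three-level AMOVA: regions / populations within regions / within pops.

    ``grouping`` maps each population label to its region (elevation zone,
    volcano or watershed). Populations of one individual are discarded
    first (with a log notice) unless ``drop_singletons`` is False.
    ``n_perm = 0`` skips the permutation tests (point estimates only).
    """
    singles = g.singleton_populations()
    if singles and drop_singletons:
        log.info("AMOVA: discarding single-individual populations %s", singles)
        g = g.drop_singleton_populations()
    missing = [p for p in g.populations if p not in grouping]
    if missing:
        raise ValidationError(f"populations without region assignment: {missing}")

    data = _AmovaData(g, grouping)
    comp, ss, dfs = data.components(data.ind_pop, data.pop_region)
    f_rt, f_sr, f_st, truncated = _f_stats(comp, truncate)
    if truncated:
        log.warning("AMOVA: negative variance component truncated to 0 "
                    "for F statistics (raw values kept in the table)")

    p_rt = p_sr = p_st = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        # F_RT: permute whole populations among regions
        count = 0
        for _ in range(n_perm):
            perm_region = data.pop_region[rng.permutation(len(data.pops))]
            c, _, _ = data.components(data.ind_pop, perm_region)
            if _f_stats(c, truncate)[0] >= f_rt - 1e-12:
                count += 1
        p_rt = (1 + count) / (1 + n_perm)
        # F_SR: permute individuals among populations within regions
        count = 0
        ind_region = data.pop_region[data.ind_pop]
        for _ in range(n_perm):
            perm = np.arange(data.n)
            for r in range(len(data.regions)):
                idx = np.flatnonzero(ind_region == r)
                perm[idx] = idx[rng.permutation(idx.size)]
            c, _, _ = data.components(data.ind_pop[perm], data.pop_region)
            if _f_stats(c, truncate)[1] >= f_sr - 1e-12:
                count += 1
        p_sr = (1 + count) / (1 + n_perm)
        # F_ST: permute individuals among all populations
        count = 0
        for _ in range(n_perm):
            c, _, _ = data.components(data.ind_pop[rng.permutation(data.n)],
                                      data.pop_region)
            if _f_stats(c, truncate)[2] >= f_st - 1e-12:
                count += 1
        p_st = (1 + count) / (1 + n_perm)

    total_ss = sum(ss)
    total_df = dfs[0] + dfs[1] + dfs[2]
    comp_trunc = np.clip(comp, 0.0, None)
    total_var = comp_trunc.sum()
    pct = 100.0 * comp_trunc / total_var if total_var > 0 else np.zeros(3)
    table = pd.DataFrame({
        "source": ["Among regions", "Among populations within regions",
                   "Within populations", "Total"],
        "df": [dfs[0], dfs[1], dfs[2], total_df],
        "SS": [ss[0], ss[1], ss[2], total_ss],
        "MS": [ss[i] / dfs[i] if dfs[i] > 0 else np.nan for i in range(3)]
              + [np.nan],
        "variance": [comp[0], comp[1], comp[2], sum(comp)],
        "pct_total": [pct[0], pct[1], pct[2], 100.0],
    }).set_index("source")
    return AmovaResult(table, {"sigma2_a": comp[0], "sigma2_b": comp[1],
                               "sigma2_c": comp[2]},
                       f_rt, f_sr, f_st, p_rt, p_sr, p_st, truncated,
                       dict(grouping))


def two_level_fst(g: GenotypeMatrix, pops: tuple) -> float:
    """Allele-level two-population FST (negative estimates clamped to 0)."""
    sub = g.subset_populations(list(pops))
    # two-level AMOVA == three-level with each population its own region is
    # degenerate; solve the two-level EMS system directly
    data = _AmovaData(sub, {p: p for p in sub.populations})
    P = len(sub.populations)
    cp, mp = data._pooled(data.ind_pop, P)
    ss_wp = sum(_group_ss(cp[p], mp[p]) for p in range(P))
    ss_tot = _group_ss(cp.sum(axis=0), mp.sum(axis=0))
    ss_ap = ss_tot - ss_wp
    copies = 2.0 * np.bincount(data.ind_pop, minlength=P)
    N = copies.sum()
    df_ap, df_wp = P - 1, N - P
    n0 = (N - (copies ** 2).sum() / N) / df_ap
    ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
    s2a = (ms_ap - ms_wp) / n0
    s2c = ms_wp
    if s2a + s2c <= 0:
        return 0.0
    return max(0.0, s2a / (s2a + s2c))


def pairwise_fst(g: GenotypeMatrix) -> DistanceMatrix:
    """Population-by-population FST matrix from two-level allele AMOVA.

    Negative estimates are clamped to 0; clamped pairs are listed in the
    result's ``metadata["clamped_pairs"]``.
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations for pairwise FST")
    small = [p for p, n in g.pop_sizes().items() if n < 2]
    if small:
        raise ValidationError(
            f"populations with fewer than 2 individuals: {small}")
    n = len(pops)
    vals = np.zeros((n, n))
    clamped = []
    for i in range(n):
        for j in range(i + 1, n):
            f = two_level_fst(g, (pops[i], pops[j]))
            if f == 0.0:
                clamped.append((pops[i], pops[j]))
            vals[i, j] = vals[j, i] = f
    return DistanceMatrix(pops, vals, name="pairwise_fst",
                          metadata={"clamped_pairs": clamped})


# ---------------------------------------------------------------------------
# isolation by distance


@dataclass
class IbdResult:
    mantel: MantelResult
    slope: float
    intercept: float
    n_populations: int
    elevation_range: tuple | None = None

    @property
    def r(self) -> float:
        return self.mantel.r

    @property
    def r_squared(self) -> float:
        return self.mantel.r_squared

    @property
    def p_value(self) -> float:
        return self.mantel.p_value


def ibd(fst: DistanceMatrix, geo: DistanceMatrix, n_perm: int = 10_000,
        seed: int = 0, elevations: dict | None = None) -> IbdResult:
    """Isolation by distance: linearized FST against ln(km + 1) distance.

    FST is linearized as f / (1 - f); geographic distance (km) is
    transformed as ln(d + 1). A Mantel test gives r and P; an OLS fit over
    the upper-triangle pairs gives the reported slope and intercept.
    """
    f = fst.condensed()
    if (f >= 1.0).any():
        raise ValidationError("FST of 1 cannot be linearized (f/(1-f) undefined)")
    lin = DistanceMatrix(fst.labels, fst.values / (1.0 - fst.values),
                         name="linearized_fst")
    lngeo = DistanceMatrix(geo.labels, np.log1p(geo.values), name="ln_geo")
    m = mantel(lin, lngeo.align(lin.labels), n_perm=n_perm, seed=seed)
    x = lngeo.align(lin.labels).condensed()
    y = lin.condensed()
    slope, intercept = np.polyfit(x, y, 1)
    rng = None
    if elevations is not None:
        vals = [elevations[p] for p in fst.labels]
        rng = (min(vals), max(vals))
    return IbdResult(m, float(slope), float(intercept), len(fst.labels), rng)
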