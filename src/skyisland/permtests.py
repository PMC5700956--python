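"""Permutational MANOVA on distance matrices, the Mantel family, and the
Mantel correlogram.

PERMANOVA uses the McArdle-Anderson framework: Gower-center the squared
distances, G = -1/2 C (d o d) C with C = I - 11'/n, take sequential
(Type I) sums of squares from hat matrices of the accumulated design
columns, and test each term's pseudo-F by jointly permuting rows and
columns of the distance matrix. P values use the add-one estimator, or
exact enumeration over all n! permutations on request (feasible for
n <= 6).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, ValidationError, aligned_condensed

__all__ = [
    "PermanovaResult", "MantelResult", "CorrelogramResult",
    "permanova", "mantel", "partial_mantel", "mantel_correlogram",
    "progressive_holm",
]

log = logging.getLogger("skyisland")

_EPS = 1e-12


def _permutations(n: int, n_perm: int, seed: int, exhaustive: bool) -> np.ndarray:
    if exhaustive:
        return np.array(list(itertools.permutations(range(n))))
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms..., Residual, Total; cols: df, SS, F, R2, P

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "P"])


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * C @ (D ** 2) @ C


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValidationError(f"categorical term {term!r} has fewer than 2 levels")
        # treatment coding; the intercept absorbs the first level
        return np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])
    vals = col.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError(f"term {term!r} has missing values")
    return vals[:, None]


def permanova(d: DistanceMatrix, design: pd.DataFrame, terms: list[str] | None = None,
              n_perm: int = 10_000, seed: int = 0,
              exhaustive: bool = False) -> PermanovaResult:
    """Sequential-SS PERMANOVA of a distance matrix on sample-level terms.

    ``design`` rows must align with the distance-matrix labels; ``terms``
    (default: all columns, in order) are entered sequentially, so term
    order matters, as in any Type I decomposition.
    """
    if list(design.index) != list(d.labels):
        if set(design.index) != set(d.labels):
            raise ValidationError("design rows do not match distance-matrix labels")
        design = design.loc[d.labels]
    terms = list(terms) if terms is not None else list(design.columns)
    n = len(d)
    G = _gower_center(d.values)
    ss_total = float(np.trace(G))

    hats = []  # accumulated hat matrices, one per term
    X = np.ones((n, 1))
    rank_prev = 1
    dfs = []
    for term in terms:
        X = np.hstack([X, _term_columns(design, term)])
        rank = np.linalg.matrix_rank(X)
        if rank == rank_prev:
            raise ValidationError(
                f"term {term!r} is collinear with terms entered before it")
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(X @ np.linalg.pinv(X))

    df_res = n - rank_prev
    if df_res <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")

    dfs_arr = np.array(dfs, dtype=float)
    tiny = _EPS * max(abs(ss_total), 1.0)

    def seq_ss(Gm: np.ndarray) -> np.ndarray:
        tr = np.array([float((H * Gm).sum()) for H in hats])
        prev = np.concatenate([[0.0], tr[:-1]])
        return tr - prev

    def pseudo_f(ss_terms: np.ndarray, ss_res: float) -> np.ndarray:
        # a numerically-zero residual (perfect fit) gives an infinite F
        if ss_res <= tiny:
            return np.full(len(ss_terms), np.inf)
        return (ss_terms / dfs_arr) / (ss_res / df_res)

    ss_terms = seq_ss(G)
    ss_res = max(ss_total - ss_terms.sum(), 0.0)
    F_obs = pseudo_f(ss_terms, ss_res)

    perms = _permutations(n, n_perm, seed, exhaustive)
    count = np.zeros(len(terms))
    for p in perms:
        Gp = G[np.ix_(p, p)]
        ssp = seq_ss(Gp)
        ssr = max(ss_total - ssp.sum(), 0.0)
        count += pseudo_f(ssp, ssr) >= F_obs - _EPS
    if exhaustive:
        P = count / len(perms)
    else:
        P = (1.0 + count) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append((term, dfs[i], ss_terms[i], F_obs[i],
                     ss_terms[i] / ss_total, P[i]))
    rows.append(("Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "P"]
                         ).set_index("term")
    return PermanovaResult(table)


# ---------------------------------------------------------------------------
# Mantel family


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    kind: str  # "simple" | "partial"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if den == 0:
        raise ValidationError("constant upper triangle; Mantel r undefined")
    return float((a * b).sum() / den)


def _perm_condensed(values: np.ndarray, perm: np.ndarray, iu) -> np.ndarray:
    return values[np.ix_(perm, perm)][iu]


def _tail_count(stats: np.ndarray, obs: float, alternative: str) -> int:
    if alternative == "greater":
        return int((stats >= obs - _EPS).sum())
    if alternative == "two-sided":
        return int((np.abs(stats) >= abs(obs) - _EPS).sum())
    raise ValidationError(f"unknown alternative {alternative!r}")


def mantel(dA: DistanceMatrix, dB: DistanceMatrix, n_perm: int = 10_000,
           seed: int = 0, alternative: str = "greater",
           exhaustive: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the n(n-1)/2 upper-triangle pairs;
    P permutes rows/columns of ``dA`` jointly (one-sided 'greater' by
    default, the standard alternative for similarity hypotheses).
    """
    a, b = aligned_condensed(dA, dB)
    r = _pearson(a, b)
    n = len(dA)
    iu = np.triu_indices(n, k=1)
    A = dA.values
    perms = _permutations(n, n_perm, seed, exhaustive)
    stats = np.array([_pearson(_perm_condensed(A, p, iu), b) for p in perms])
    count = _tail_count(stats, r, alternative)
    p = count / len(perms) if exhaustive else (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r, r * r, p, len(perms), "simple")


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = np.sqrt((1 - rac ** 2) * (1 - rbc ** 2))
    if den == 0:
        return 0.0
    return (rab - rac * rbc) / den


def partial_mantel(dA: DistanceMatrix, dB: DistanceMatrix, dC: DistanceMatrix,
                   n_perm: int = 10_000, seed: int = 0,
                   alternative: str = "greater",
                   exhaustive: bool = False) -> MantelResult:
    """Partial Mantel correlation r(AB.C), permuting rows/columns of ``dA``."""
    a, b, c = aligned_condensed(dA, dB, dC)
    rbc = _pearson(b, c)
    r = _partial_r(_pearson(a, b), _pearson(a, c), rbc)
    n = len(dA)
    iu = np.triu_indices(n, k=1)
    A = dA.values
    perms = _permutations(n, n_perm, seed, exhaustive)
    stats = np.empty(len(perms))
    for i, p in enumerate(perms):
        ap = _perm_condensed(A, p, iu)
        stats[i] = _partial_r(_pearson(ap, b), _pearson(ap, c), rbc)
    count = _tail_count(stats, r, alternative)
    pval = count / len(perms) if exhaustive else (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r, r * r, pval, len(perms), "partial")


# ---------------------------------------------------------------------------
# Mantel correlogram


@dataclass
class CorrelogramResult:
    classes: pd.DataFrame
    # columns: class_lower, class_upper, n_pairs, r, P, P_corrected, tested


def progressive_holm(ps: list[float]) -> list[float]:
    """Progressive Holm correction: class i is corrected within classes 1..i."""
    out = []
    for i in range(len(ps)):
        sub = np.asarray(ps[:i + 1], dtype=float)
        m = len(sub)
        order = np.argsort(sub)
        adj = np.empty(m)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, (m - k) * sub[idx])
            adj[idx] = min(1.0, running)
        out.append(float(adj[i]))
    return out


def mantel_correlogram(dResp: DistanceMatrix, dPred: DistanceMatrix,
                       class_width: float | None = None,
                       breaks: np.ndarray | None = None,
                       n_perm: int = 999, seed: int = 0,
                       test_beyond_half: bool = False) -> CorrelogramResult:
    """Mantel correlogram of a response matrix over classes of a predictor.

    Each predictor-distance class gets a Mantel test between ``dResp`` and
    the 0/1 indicator of "pair falls in this class". With this coding a
    *negative* r means pairs in the class are more similar than average
    (positive autocorrelation). Classes beyond the one that carries the
    cumulative 50% of pairs are reported but untested by default (their P
    is NaN). Corrected P values use the progressive Holm procedure.
    """
    resp, pred = aligned_condensed(dResp, dPred)
    if breaks is None:
        if class_width is None:
            raise ValidationError("give either class_width or explicit breaks")
        top = float(pred.max())
        breaks = np.arange(0.0, top + class_width, class_width)
        if breaks[-1] <= top:
            breaks = np.append(breaks, breaks[-1] + class_width)
    breaks = np.asarray(breaks, dtype=float)
    if len(breaks) < 3:
        raise ValidationError("need at least 2 distance classes")

    n = len(dResp)
    iu = np.triu_indices(n, k=1)
    R = dResp.values
    perms = _permutations(n, n_perm, seed, False)
    total_pairs = resp.size

    rows = []
    cum = 0
    half_reached = False
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        inclass = (pred >= lo) & (pred < hi)
        npairs = int(inclass.sum())
        if npairs == 0:
            log.info("correlogram: dropping empty class [%g, %g)", lo, hi)
            continue
        tested = not half_reached or test_beyond_half
        cum += npairs
        if not half_reached and cum > total_pairs / 2:
            half_reached = True  # classes *after* this one go untested
        ind = inclass.astype(float)
        if ind.std() == 0:  # all pairs in one class: r undefined
            rows.append((lo, hi, npairs, np.nan, np.nan, False))
            continue
        r = _pearson(resp, ind)
        if tested:
            stats = np.array([_pearson(_perm_condensed(R, p, iu), ind)
                              for p in perms])
            count = _tail_count(stats, r, "two-sided")
            pval = (1.0 + count) / (1.0 + n_perm)
        else:
            pval = np.nan
        rows.append((lo, hi, npairs, r, pval, tested))

    df = pd.DataFrame(rows, columns=["class_lower", "class_upper", "n_pairs",
                                     "r", "P", "tested"])
    corrected = np.full(len(df), np.nan)
    tested_idx = df.index[df["tested"] & df["P"].notna()]
    corrected[tested_idx] = progressive_holm(list(df.loc[tested_idx, "P"]))
    df["P_corrected"] = corrected
    return CorrelogramResult(df[["class_lower", "class_upper", "n_pairs",
                                 "r", "P", "P_corrected", "tested"]])
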