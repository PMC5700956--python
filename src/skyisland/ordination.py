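"""Non-metric multidimensional scaling and environmental vector fitting.

NMDS follows the standard Kruskal formulation: minimize stress-1
sqrt(sum (theta(d_ij) - delta_ij)^2 / sum delta_ij^2), where delta are
configuration distances and theta is the isotonic (monotone
non-decreasing, pool-adjacent-violators) regression of delta on the input
dissimilarities with primary tie-breaking. The configuration step is
SMACOF-style majorization (Guttman transform); multiple random starts plus
one metric-scaling (PCoA) start; the best solution is centered and
principal-axis rotated, with axis signs fixed so the largest-|score|
entry of each axis is positive.

Vector fitting regresses a centered site variable on the site scores and
assesses the squared multiple correlation by permutation, the way
community ecologists fit environmental vectors onto an ordination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .containers import DistanceMatrix, ValidationError

__all__ = ["OrdinationResult", "EnvfitResult", "nmds", "fit_vector",
           "procrustes_correlation"]


@dataclass
class OrdinationResult:
    labels: list
    scores: np.ndarray  # (n, k), centered, principal-axis rotated
    stress: float       # Kruskal stress-1
    n_starts: int
    converged: bool
    stress_history: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def axis_names(self) -> list[str]:
        return [f"NMDS{i + 1}" for i in range(self.k)]


@dataclass
class EnvfitResult:
    direction: np.ndarray  # unit vector of axis loadings
    r_squared: float
    p_value: float
    n_permutations: int


def _pcoa_start(D: np.ndarray, k: int) -> np.ndarray:
    """Classical metric scaling start configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0, None)
    return V[:, order] * np.sqrt(w)


def _disparities(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarities.

    Primary tie-breaking: within tied dissimilarities, pairs are ordered by
    their current configuration distance, so ties impose no constraint.
    """
    order = np.lexsort((delta, d))
    iso = IsotonicRegression(increasing=True)
    theta_sorted = iso.fit_transform(np.arange(d.size), delta[order])
    theta = np.empty_like(theta_sorted)
    theta[order] = theta_sorted
    return theta


def _stress1(delta: np.ndarray, theta: np.ndarray) -> float:
    denom = float((delta ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((delta - theta) ** 2).sum()) / denom)


def _guttman_update(X: np.ndarray, theta: np.ndarray, delta: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def _run_start(D: np.ndarray, X: np.ndarray, max_iter: int, tol: float):
    """One NMDS start; returns (X, stress, history). Stress never increases:
    an (numerically) increasing step reverts to the previous configuration."""
    X = X - X.mean(axis=0)
    delta = pdist(X)
    theta = _disparities(squareform(D, checks=False), delta)
    stress = _stress1(delta, theta)
    history = [stress]
    d = squareform(D, checks=False)
    for _ in range(max_iter):
        X_new = _guttman_update(X, theta, delta)
        X_new = X_new - X_new.mean(axis=0)
        delta_new = pdist(X_new)
        theta_new = _disparities(d, delta_new)
        stress_new = _stress1(delta_new, theta_new)
        if stress_new > stress:
            break  # keep the previous (better) configuration
        X, delta, theta = X_new, delta_new, theta_new
        improvement = stress - stress_new
        stress = stress_new
        history.append(stress)
        if improvement < tol * max(stress, 1e-12):
            break
    return X, stress, history


def procrustes_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Correlation-like Procrustes agreement sqrt(1 - m2) between configurations."""
    _, _, m2 = procrustes(A, B)
    return math.sqrt(max(0.0, 1.0 - m2))


def _principal_axis(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    R = X @ Vt.T
    for j in range(R.shape[1]):
        i = np.argmax(np.abs(R[:, j]))
        if R[i, j] < 0:
            R[:, j] = -R[:, j]
    return R


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int = 0,
         procrustes_tol: float = 0.01) -> OrdinationResult:
    """Kruskal NMDS of a dissimilarity matrix in k dimensions."""
    n = len(d)
    if n < k + 1:
        # k+1 points can still embed exactly (e.g. an equilateral triangle in 2-D)
        raise ValidationError(f"need at least k + 1 = {k + 1} sites, got {n}")
    D = d.values
    rng = np.random.default_rng(seed)
    solutions = []
    for s in range(max(1, n_starts)):
        if s == 0:
            X0 = _pcoa_start(D, k)
            if np.allclose(X0, 0):  # degenerate metric start
                X0 = rng.normal(size=(n, k))
        else:
            X0 = rng.normal(size=(n, k))
        solutions.append(_run_start(D, X0, max_iter, tol))
    solutions.sort(key=lambda t: t[1])
    X_best, stress, history = solutions[0]
    if len(solutions) > 1 and n > k:
        converged = (procrustes_correlation(solutions[0][0], solutions[1][0])
                     >= 1.0 - procrustes_tol)
    else:
        converged = True
    return OrdinationResult(list(d.labels), _principal_axis(X_best), stress,
                            max(1, n_starts), converged, history)


def fit_vector(ordn: OrdinationResult, v, n_perm: int = 999, seed: int = 0,
               exhaustive: bool = False) -> EnvfitResult:
    """Fit one continuous or 0/1 site variable onto the ordination.

    Least-squares regression of the centered variable on the site scores;
    R^2 = 1 - SS_res/SS_tot; the direction is the normalized coefficient
    vector; P is one-sided by permutation of the variable across sites
    (add-one estimator), or exact over all n! permutations if ``exhaustive``.
    """
    v = np.asarray(v, dtype=float)
    n = len(ordn.labels)
    if v.shape != (n,):
        raise ValidationError(f"need one value per ordinated site ({n}), got {v.shape}")
    if np.isnan(v).any():
        raise ValidationError("vector contains missing values")
    vc = v - v.mean()
    ss_tot = float((vc ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("vector has zero variance")
    X = ordn.scores
    coef, *_ = np.linalg.lstsq(X, vc, rcond=None)
    fitted = X @ coef
    r2 = float((fitted ** 2).sum()) / ss_tot
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else coef
    H = X @ np.linalg.pinv(X)
    eps = 1e-12
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        V = vc[perms]
        r2_perm = ((V @ H) ** 2).sum(axis=1) / (V ** 2).sum(axis=1)
        p = float((r2_perm >= r2 - eps).sum()) / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        V = vc[perms]
        r2_perm = ((V @ H) ** 2).sum(axis=1) / (V ** 2).sum(axis=1)
        p = (1.0 + float((r2_perm >= r2 - eps).sum())) / (1.0 + n_perm)
        n_used = n_perm
    return EnvfitResult(direction, r2, p, n_used)
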