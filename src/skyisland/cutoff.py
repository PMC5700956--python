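"""Lowland/highland boundary detection.

Two scan procedures locate the elevation cutoff that best separates the
two zones:

* the community scan ordinates the presence/absence Bray-Curtis matrix
  once (NMDS), then fits, for every threshold on a 50-m grid, the binary
  vector "sampled at or above the threshold" onto that ordination and
  takes the threshold with the highest R^2 — with a tie rule that re-runs
  the scan on the abundance matrix when two distinct splits score within
  ``tie_tol`` of each other;

* the genetic scan evaluates every midpoint between successive distinct
  population elevations, computes the among-zone F_RT of a two-region
  AMOVA for each, and takes the admissible maximum, falling back to the
  best admissible split when the global maximum would leave fewer than
  two populations in a zone ("fell at one end" rule).

Zone convention everywhere: lowland strictly below the cutoff, highland
at or above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityMatrix, GenotypeMatrix, SiteTable, ValidationError
from .distances import bray_curtis
from .ordination import fit_vector, nmds
from .popgen import amova

__all__ = ["CutoffScan", "community_cutoff_scan", "genetic_cutoff_scan",
           "bonferroni", "candidate_thresholds"]


@dataclass
class CutoffScan:
    candidates: pd.DataFrame
    score_type: str               # "envfit_r2" | "f_rt"
    best_threshold: float
    secondary_threshold: float | None = None
    selection_rule_applied: str = "none"
    # none | second_highest_at_end | abundance_tiebreak
    details: dict = field(default_factory=dict)


def bonferroni(alpha: float, m_tests: int) -> float:
    """Bonferroni-corrected per-test alpha: alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m_tests < 1:
        raise ValidationError(f"m_tests must be >= 1, got {m_tests}")
    return alpha / m_tests


def candidate_thresholds(elevations) -> list[float]:
    """Median between each pair of successive distinct station elevations."""
    elevs = sorted(set(float(e) for e in elevations))
    if len(elevs) < 2:
        raise ValidationError("need at least two distinct elevations")
    return [(a + b) / 2.0 for a, b in zip(elevs[:-1], elevs[1:])]


def _threshold_grid(elev: np.ndarray, step: float,
                    origin: float | None) -> np.ndarray:
    """50-m-style grid covering (min_elev, max_elev].

    The grid origin defaults to the minimum sampled elevation rounded up to
    the step (configurable, since field gradients rarely start on a round
    number).
    """
    lo, hi = float(elev.min()), float(elev.max())
    start = origin if origin is not None else math.ceil(lo / step) * step
    if start <= lo:
        start += step
    grid = np.arange(start, hi + step / 2, step)
    return grid[(grid > lo) & (grid <= hi)]


def community_cutoff_scan(comm: CommunityMatrix, sites: SiteTable,
                          step: float = 50.0, grid_origin: float | None = None,
                          nmds_params: dict | None = None,
                          n_perm: int = 999, seed: int = 0,
                          tie_tol: float = 0.01) -> CutoffScan:
    """Ordination-based 50-m sweep for the community cutoff.

    One NMDS of the presence/absence Bray-Curtis matrix serves all
    thresholds; each threshold's binary above-or-at vector is fitted onto
    it. Thresholds bounded by the same pair of stations produce the same
    split and hence the same R^2; the tie rule compares *distinct* splits,
    and a near-tie (< ``tie_tol`` in R^2) is broken by re-running the scan
    on the abundance matrix.
    """
    if list(comm.sites) != list(sites.site_ids):
        if set(comm.sites) != set(sites.site_ids):
            raise ValidationError("community sites do not match the site table")
        sites = sites.subset(comm.sites)
    elev = sites.elevation.to_numpy()
    grid = _threshold_grid(elev, step, grid_origin)
    splits = [(t, elev >= t) for t in grid]
    splits = [(t, b) for t, b in splits if 0 < b.sum() < b.size]
    if not splits:
        raise ValidationError("no admissible threshold on the grid "
                              "(every candidate split is constant)")

    params = dict(k=2, n_starts=20, max_iter=300, tol=1e-7)
    params.update(nmds_params or {})
    ordn = nmds(bray_curtis(comm, use_presence=True), seed=seed, **params)

    def scan(ordination):
        rows = []
        for i, (t, b) in enumerate(splits):
            fit = fit_vector(ordination, b.astype(float), n_perm=n_perm,
                             seed=seed + 1 + i)
            rows.append((t, *fit.direction[:2], fit.r_squared, fit.p_value))
        return pd.DataFrame(rows,
                            columns=["threshold", "NMDS1", "NMDS2", "R2", "P"])

    cand = scan(ordn)
    # group grid thresholds that define the same split of sites
    keys = ["/".join(map(str, b.astype(int))) for _, b in splits]
    cand["split"] = keys
    by_split = cand.groupby("split", sort=False).agg(
        threshold=("threshold", "min"), R2=("R2", "max")).reset_index()
    by_split = by_split.sort_values("R2", ascending=False)
    best = by_split.iloc[0]
    rule = "none"
    secondary = None
    details = {"stress": ordn.stress, "converged": ordn.converged}
    if len(by_split) > 1 and best["R2"] - by_split.iloc[1]["R2"] < tie_tol:
        tied = by_split[by_split["R2"] > best["R2"] - tie_tol]
        ab_ordn = nmds(bray_curtis(comm, use_presence=False), seed=seed, **params)
        ab = scan(ab_ordn)
        ab["split"] = keys
        ab_scores = ab.groupby("split", sort=False)["R2"].max()
        tied = tied.assign(abundance_R2=[ab_scores[s] for s in tied["split"]])
        tied = tied.sort_values("abundance_R2", ascending=False)
        best = tied.iloc[0]
        secondary = float(tied.iloc[1]["threshold"]) if len(tied) > 1 else None
        rule = "abundance_tiebreak"
        details["abundance_scan"] = ab.drop(columns="split")
    return CutoffScan(cand.drop(columns="split"), "envfit_r2",
                      float(best["threshold"]), secondary, rule, details)


def genetic_cutoff_scan(g: GenotypeMatrix, sites: SiteTable,
                        n_perm: int = 0, seed: int = 0) -> CutoffScan:
    """F_RT-maximizing sweep over midpoints between population elevations.

    Candidate thresholds are the medians between successive distinct
    elevational sampling stations of the populations. Each candidate splits
    populations into a lowland (< t) and a highland (>= t) zone and is
    scored by the among-zone F_RT of a two-region AMOVA. A candidate is
    admissible only if both zones keep >= 2 populations; when the global
    maximum is inadmissible the second-highest (best admissible) value is
    selected and the rule is flagged. ``n_perm`` > 0 adds a permutation P
    for the selected threshold.
    """
    g = g.drop_singleton_populations()
    pop_elev = g.pop_elevation(sites)
    elevs = sorted(set(pop_elev.values()))
    if len(elevs) < 3:
        raise ValidationError(
            "need populations at >= 3 distinct elevations for the sweep")
    candidates = candidate_thresholds(elevs)

    rows = []
    for t in candidates:
        grouping = {p: ("highland" if e >= t else "lowland")
                    for p, e in pop_elev.items()}
        n_low = sum(1 for z in grouping.values() if z == "lowland")
        n_high = len(grouping) - n_low
        admissible = n_low >= 2 and n_high >= 2
        res = amova(g, grouping, n_perm=0)
        rows.append((t, res.f_rt, admissible))
    cand = pd.DataFrame(rows, columns=["threshold", "F_RT", "admissible"])

    adm = cand[cand["admissible"]]
    if adm.empty:
        raise ValidationError("no admissible candidate threshold "
                              "(cannot keep 2 populations per zone)")
    global_best = cand.loc[cand["F_RT"].idxmax()]
    best_adm = adm.loc[adm["F_RT"].idxmax()]
    if bool(global_best["admissible"]):
        best, rule = global_best, "none"
    else:
        best, rule = best_adm, "second_highest_at_end"

    details = {}
    if n_perm > 0:
        t = float(best["threshold"])
        grouping = {p: ("highland" if e >= t else "lowland")
                    for p, e in pop_elev.items()}
        res = amova(g, grouping, n_perm=n_perm, seed=seed)
        details["p_f_rt"] = res.p_f_rt
        cand.loc[cand["threshold"] == t, "P"] = res.p_f_rt
    return CutoffScan(cand, "f_rt", float(best["threshold"]),
                      None, rule, details)
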