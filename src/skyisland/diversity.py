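"""Additive per-site partitioning of species richness (gamma = alpha + beta)
and its regression against elevation.

The contribution-diversity partition attributes to each site i a share of
the total richness: gamma_i = sum over species j present at i of 1/m_j
(m_j = number of occupied sites), alpha_i = S_i / n (site richness over
site count), beta_i = gamma_i - alpha_i. The gamma contributions sum
exactly to the total species richness, which gives the partition its
conservation law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CommunityMatrix, SiteTable, ValidationError

__all__ = ["DiversityPartition", "RegressionResult",
           "contribution_diversity", "regress_vs_elevation"]


@dataclass
class DiversityPartition:
    per_site: pd.DataFrame  # index site_id; columns alpha, beta, gamma

    @property
    def totals(self) -> pd.Series:
        return self.per_site.sum(axis=0)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def contribution_diversity(comm: CommunityMatrix) -> DiversityPartition:
    """Richness-index contribution diversity on the presence/absence view."""
    P = comm.presence.to_numpy()
    n_sites = P.shape[0]
    if n_sites < 2:
        raise ValidationError("need at least 2 sites to partition diversity")
    occ = P.sum(axis=0)  # m_j: sites occupied per species
    missing = np.flatnonzero(occ == 0)
    if missing.size:
        names = [comm.species[j] for j in missing]
        raise ValidationError(
            f"species with zero occurrences must be pruned first: {names}")
    gamma = (P / occ[None, :]).sum(axis=1)
    alpha = P.sum(axis=1) / n_sites
    beta = gamma - alpha
    df = pd.DataFrame({"alpha": alpha, "beta": beta, "gamma": gamma},
                      index=comm.sites)
    return DiversityPartition(df)


def regress_vs_elevation(part: DiversityPartition,
                         sites: SiteTable) -> dict[str, RegressionResult]:
    """OLS of each diversity component on elevation (two-sided slope t-test)."""
    df = part.per_site
    if set(df.index) != set(sites.site_ids):
        raise ValidationError("partition sites do not match the site table")
    elev = sites.elevation.loc[df.index].to_numpy()
    n = len(df)
    if n < 3:
        raise ValidationError("need at least 3 sites for regression")
    if np.ptp(elev) == 0:
        raise ValidationError("elevation is constant; regression undefined")
    out = {}
    for comp in ("alpha", "beta", "gamma"):
        y = df[comp].to_numpy(dtype=float)
        res = stats.linregress(elev, y)
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        out[comp] = RegressionResult(float(res.slope), float(res.intercept),
                                     float(r2), float(adj),
                                     float(res.pvalue), n)
    return out
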