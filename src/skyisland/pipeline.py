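"""End-to-end two-level analysis: community structure and within-species
genetic structure along the elevation gradient.

`run_pipeline` wires the stages together the way the full study runs:
simulate (or accept) the landscape, community and genotypes; test spatial
factors with PERMANOVA; check spatial autocorrelation (Mantel) and the
elevation signal controlling for geography (partial Mantel); profile the
decay of community similarity with elevation difference (Mantel
correlogram); partition diversity and regress it on elevation; detect the
community cutoff; then, on the genetic side, run the hierarchical AMOVA
for elevation zones / volcanoes / watersheds, pairwise FST + isolation by
distance, and the F_RT-maximizing genetic cutoff sweep.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import distances, diversity, permtests, popgen
from .containers import CommunityMatrix, GenotypeMatrix, SiteTable
from .cutoff import bonferroni, community_cutoff_scan, genetic_cutoff_scan
from .io import RunConfig
from .simulate import (SimulationConfig, gen_community, gen_genotypes,
                       gen_landscape, field_landscape)

log = logging.getLogger("skyisland")

__all__ = ["run_pipeline", "community_analyses", "genetic_analyses"]


def community_analyses(sites: SiteTable, comm: CommunityMatrix,
                       run: RunConfig) -> dict:
    seed = run.seed
    bc = distances.bray_curtis(comm, use_presence=True)
    geo = distances.geographic_distance(sites)
    elev_d = distances.euclidean_1d(sites.elevation, name="elevation_diff")

    design = pd.DataFrame({
        "elevation": sites.elevation,
        "volcano": sites.data["volcano"],
        "watershed": sites.data["watershed"],
    }, index=sites.site_ids)
    perm = permtests.permanova(bc, design, n_perm=run.n_perm_manova, seed=seed)

    man = permtests.mantel(bc, geo, n_perm=run.n_perm_mantel, seed=seed + 1)
    pman = permtests.partial_mantel(bc, elev_d, geo,
                                    n_perm=run.n_perm_mantel, seed=seed + 2)
    corr = permtests.mantel_correlogram(bc, elev_d,
                                        class_width=run.correlogram_class_width,
                                        n_perm=max(run.n_perm_envfit, 99),
                                        seed=seed + 3)
    part = diversity.contribution_diversity(comm.drop_absent_species())
    regs = diversity.regress_vs_elevation(part, sites)
    scan = community_cutoff_scan(comm, sites, step=run.cutoff_step,
                                 n_perm=run.n_perm_envfit, seed=seed + 4)
    return {
        "permanova": perm,
        "mantel_geography": man,
        "partial_mantel_elevation": pman,
        "correlogram": corr,
        "diversity_partition": part,
        "diversity_regressions": regs,
        "community_cutoff": scan,
    }


def genetic_analyses(sites: SiteTable, g: GenotypeMatrix, cutoff_m: float,
                     run: RunConfig) -> dict:
    seed = run.seed
    g = g.drop_singleton_populations()
    pop_elev = g.pop_elevation(sites)
    groupings = {
        "elevation": {p: ("highland" if e >= cutoff_m else "lowland")
                      for p, e in pop_elev.items()},
        "volcano": {p: sites.data.loc[s, "volcano"]
                    for p, s in g.pop_site.items()},
        "watershed": {p: sites.data.loc[s, "watershed"]
                      for p, s in g.pop_site.items()},
    }
    amovas = {}
    for i, (factor, grouping) in enumerate(groupings.items()):
        if len(set(grouping.values())) < 2:
            log.info("skipping AMOVA factor %s: single region", factor)
            continue
        amovas[factor] = popgen.amova(g, grouping, n_perm=run.n_perm_amova,
                                      seed=seed + 10 + i)
    fst = popgen.pairwise_fst(g)
    pop_sites = sites.subset([g.pop_site[p] for p in fst.labels])
    geo = distances.geographic_distance(pop_sites)
    geo = distances.DistanceMatrix(fst.labels, geo.values, name=geo.name)
    ibd_all = popgen.ibd(fst, geo, n_perm=run.n_perm_ibd, seed=seed + 20,
                         elevations=pop_elev)
    scan = genetic_cutoff_scan(g, sites, n_perm=run.n_perm_amova, seed=seed + 21)
    return {
        "amova": amovas,
        "pairwise_fst": fst,
        "ibd": ibd_all,
        "genetic_cutoff": scan,
        "alpha_amova": bonferroni(0.05, 3),
        "alpha_ibd": bonferroni(0.05, 2),
    }


def run_pipeline(sim: SimulationConfig, run: RunConfig | None = None,
                 landscape: str = "field") -> dict:
    """Simulate one study and run the full two-level analysis.

    ``landscape="field"`` uses the 31-site field-design layout (sites spread
    over the whole gradient); ``"grid"`` uses the regular station grid of
    the simulation config.
    """
    run = run or RunConfig(seed=sim.seed)
    sites = field_landscape(sim.seed) if landscape == "field" \
        else gen_landscape(sim)
    comm = gen_community(sites, sim)
    g = gen_genotypes(sites, sim)
    out = {"sites": sites, "community": comm, "genotypes": g}
    out["community_results"] = community_analyses(sites, comm, run)
    cutoff = out["community_results"]["community_cutoff"].best_threshold
    out["genetic_results"] = genetic_analyses(sites, g, cutoff, run)
    return out


def summarize(report: dict) -> dict:
    """Flatten a pipeline report into plain numbers (JSON-serializable)."""
    c = report["community_results"]
    gres = report["genetic_results"]
    perm = c["permanova"].table
    s = {
        "permanova_elevation_R2": float(perm.loc["elevation", "R2"]),
        "permanova_elevation_P": float(perm.loc["elevation", "P"]),
        "mantel_geography_r2": c["mantel_geography"].r_squared,
        "mantel_geography_P": c["mantel_geography"].p_value,
        "partial_mantel_elevation_r2": c["partial_mantel_elevation"].r_squared,
        "partial_mantel_elevation_P": c["partial_mantel_elevation"].p_value,
        "community_cutoff_m": c["community_cutoff"].best_threshold,
        "genetic_cutoff_m": gres["genetic_cutoff"].best_threshold,
        "ibd_slope": gres["ibd"].slope,
        "ibd_P": gres["ibd"].p_value,
        "alpha_amova_bonferroni": gres["alpha_amova"],
        "alpha_ibd_bonferroni": gres["alpha_ibd"],
    }
    for factor, res in gres["amova"].items():
        s[f"amova_{factor}_F_RT"] = res.f_rt
        s[f"amova_{factor}_P"] = res.p_f_rt
    for comp, reg in c["diversity_regressions"].items():
        s[f"diversity_{comp}_slope"] = reg.slope
        s[f"diversity_{comp}_adj_R2"] = reg.adjusted_r_squared
        s[f"diversity_{comp}_P"] = reg.p_value
    return s
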