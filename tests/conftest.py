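import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from skyisland.containers import CommunityMatrix, GenotypeMatrix, SiteTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_community() -> CommunityMatrix:
    """Six-site, five-species presence matrix used across oracle tests."""
    m = np.array([
        [1, 1, 0, 0, 1],
        [0, 1, 1, 0, 0],
        [0, 0, 1, 1, 1],
        [1, 0, 0, 1, 0],
        [1, 1, 1, 0, 1],
        [0, 0, 1, 1, 0],
    ])
    return CommunityMatrix(pd.DataFrame(
        m, index=[f"s{i}" for i in range(1, 7)],
        columns=[f"sp{j}" for j in range(1, 6)]))


@pytest.fixture(scope="session")
def tiny_sites(tiny_community) -> SiteTable:
    df = pd.DataFrame({
        "elevation": [100.0, 300.0, 500.0, 700.0, 900.0, 1100.0],
        "volcano": ["A", "A", "B", "B", "C", "C"],
        "watershed": ["A1", "A1", "B1", "B1", "C1", "C1"],
        "x": [0.0, 1.0, 10.0, 11.0, 20.0, 21.0],
        "y": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
    }, index=tiny_community.sites)
    return SiteTable(df, coord_system="planar")


def make_genotypes(pop_calls: dict, loci: list[str] | None = None,
                   pop_site: dict | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {population: [[ (a,b) per locus ] per ind]}."""
    individuals, pops, rows = [], [], []
    for pop, inds in pop_calls.items():
        for i, ind in enumerate(inds):
            individuals.append(f"{pop}_i{i + 1}")
            pops.append(pop)
            rows.append(ind)
    calls = np.array(rows, dtype=np.int16)
    L = calls.shape[1]
    loci = loci or [f"L{j + 1}" for j in range(L)]
    pop_site = pop_site or {p: p for p in pop_calls}
    return GenotypeMatrix(individuals, loci, calls,
                          np.array(pops, dtype=object), pop_site)


@pytest.fixture(scope="session")
def amova_fixture() -> GenotypeMatrix:
    """3 regions x 6 populations x 12 individuals, 4 biallelic loci.

    Deterministic toy data with real structure: region R1 leans towards
    allele 0, R3 towards allele 1, R2 is mixed; populations differ within
    regions.
    """
    AA, AB, BB = (0, 0), (0, 1), (1, 1)
    pops = {
        "p1": [[AA, AA, AB, AA], [AA, AB, AA, AA]],
        "p2": [[AB, AA, AA, AB], [AA, AA, AB, AA]],
        "p3": [[AB, AB, BB, AB], [AB, BB, AB, AA]],
        "p4": [[BB, AB, AB, AB], [AB, AB, BB, AB]],
        "p5": [[BB, BB, AB, BB], [BB, BB, BB, AB]],
        "p6": [[BB, AB, BB, BB], [AB, BB, BB, BB]],
    }
    sites = {"p1": "s1", "p2": "s2", "p3": "s3",
             "p4": "s4", "p5": "s5", "p6": "s6"}
    return make_genotypes(pops, pop_site=sites)


AMOVA_FIXTURE_REGIONS = {"p1": "R1", "p2": "R1", "p3": "R2",
                         "p4": "R2", "p5": "R3", "p6": "R3"}


@pytest.fixture(scope="session")
def amova_regions() -> dict:
    return dict(AMOVA_FIXTURE_REGIONS)
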