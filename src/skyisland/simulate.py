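"""Synthetic sky-island landscapes, communities and SNP genotypes.

Everything downstream is testable against known ground truth generated
here: a volcano/watershed/stream/station landscape, an elevationally
structured community (high species turnover, flat richness), and
biallelic genotypes with nested allele-frequency divergence between
elevation zones (Balding-Nichols hierarchy) so that the AMOVA-scale
F_RT and F_SR of the simulated data are known.

Seeding: one root seed; each generator stage derives an independent
stream keyed by the stage name, so adding stages never perturbs the
draws of earlier ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CommunityMatrix, GenotypeMatrix, SiteTable

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "gen_landscape",
    "gen_community",
    "gen_genotypes",
    "stage_rng",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for one generator stage under a root seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults emulate the study conditions of the motivating system: four
    volcanoes, two watersheds each, stations spanning 45-1830 m, 35 mayfly
    species in two elevation guilds either side of an 850 m lowland/highland
    boundary, and eight SNP-genotyped populations of ten individuals with a
    between-zone divergence of F_RT = 0.3.
    """

    # landscape
    n_volcanoes: int = 4
    n_watersheds_per_volcano: int = 2
    streams_per_watershed: int = 1
    stations_per_stream: int = 4
    elev_min: float = 45.0
    elev_max: float = 1830.0
    elevation_jitter: float = 0.0  # sd (m) of station-elevation jitter
    volcano_spacing_km: float = 45.0
    # community
    n_species: int = 35
    true_cutoff: float = 850.0
    niche_gap: float = 0.0            # optima kept this far from the cutoff
    breadth_range: tuple = (250.0, 400.0)   # niche breadth (m)
    highland_breadth_factor: float = 1.0    # <1: narrower highland niches
    highland_occupancy_factor: float = 0.55  # highland species are patchier
    occupancy_max: float = 0.9
    abundance_mean: float = 8.0
    nb_size: float = 1.0              # negative-binomial dispersion (size)
    # genetics
    n_populations: int = 8
    individuals_per_population: int = 10
    n_loci: int = 500
    target_F_RT: float = 0.3
    target_F_SR: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_volcanoes=self.n_volcanoes,
            n_watersheds_per_volcano=self.n_watersheds_per_volcano,
            streams_per_watershed=self.streams_per_watershed,
            stations_per_stream=self.stations_per_stream,
            n_species=self.n_species,
            n_populations=self.n_populations,
            individuals_per_population=self.individuals_per_population,
            n_loci=self.n_loci,
        )
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        for name, f in (("target_F_RT", self.target_F_RT),
                        ("target_F_SR", self.target_F_SR)):
            if not 0.0 <= f < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {f}")
        if self.target_F_RT + self.target_F_SR >= 1.0:
            raise ConfigurationError("target_F_RT + target_F_SR must be < 1")
        if not self.elev_min < self.elev_max:
            raise ConfigurationError("elev_min must be below elev_max")
        if not self.elev_min < self.true_cutoff < self.elev_max:
            raise ConfigurationError("true_cutoff must lie within the elevation range")


# ---------------------------------------------------------------------------
# landscape


def gen_landscape(config: SimulationConfig) -> SiteTable:
    """Lay out volcanoes, watersheds, streams and stations on a plane (km).

    Volcano centres sit on a ring with ``volcano_spacing_km`` radius; each
    stream radiates outward in its watershed's sector, stations running from
    near the summit (high elevation) outward (low elevation). Station
    elevations are evenly spaced over the configured range, optionally
    jittered.
    """
    rng = stage_rng(config.seed, "landscape")
    rows = []
    n_v = config.n_volcanoes
    for v in range(n_v):
        angle = 2 * np.pi * v / n_v
        cx = config.volcano_spacing_km * np.cos(angle)
        cy = config.volcano_spacing_km * np.sin(angle)
        n_w = config.n_watersheds_per_volcano
        for w in range(n_w):
            for s in range(config.streams_per_watershed):
                stream_angle = (
                    2 * np.pi * (w + (s + 0.5) / config.streams_per_watershed) / n_w
                    + rng.normal(0, 0.1)
                )
                elevs = np.linspace(config.elev_min, config.elev_max,
                                    config.stations_per_stream)
                if config.elevation_jitter > 0:
                    elevs = elevs + rng.normal(0, config.elevation_jitter, elevs.size)
                    elevs = np.clip(elevs, 1.0, None)
                for t, e in enumerate(elevs):
                    frac = (e - config.elev_min) / (config.elev_max - config.elev_min)
                    r = 1.0 + 8.0 * (1.0 - frac)  # lower stations farther from summit
                    rows.append({
                        "site_id": f"V{v + 1}W{w + 1}S{s + 1}T{t + 1}",
                        "elevation": float(e),
                        "volcano": f"V{v + 1}",
                        "watershed": f"V{v + 1}W{w + 1}",
                        "x": float(cx + r * np.cos(stream_angle)),
                        "y": float(cy + r * np.sin(stream_angle)),
                    })
    df = pd.DataFrame(rows).set_index("site_id")
    return SiteTable(df, coord_system="planar")


def field_landscape(seed: int = 0) -> SiteTable:
    """31-site landscape emulating the field design.

    Sixteen streams across four volcanoes sampled at a lower and an upper
    section would give 32 sites; three unreachable upper sections were
    replaced by two extra stations in one stream, yielding 31.
    """
    cfg = replace(SimulationConfig(seed=seed),
                  n_watersheds_per_volcano=2, streams_per_watershed=2,
                  stations_per_stream=2)
    base = gen_landscape(cfg).data.copy()
    rng = stage_rng(seed, "field-landscape")
    # spread station elevations over the gradient instead of two fixed levels
    n = len(base)
    elevs = np.linspace(cfg.elev_min, cfg.elev_max, n)
    base["elevation"] = rng.permutation(elevs)
    # drop three upper sections, add two extra stations on the first stream
    upper = base.index[base.index.str.endswith("T2")]
    drop = list(upper[:3])
    kept = base.drop(index=drop)
    extra_elevs = rng.uniform(cfg.elev_min, cfg.elev_max, 2)
    extras = []
    first = kept.iloc[0]
    for i, e in enumerate(extra_elevs):
        extras.append({
            "site_id": f"{kept.index[0][:-2]}X{i + 1}",
            "elevation": float(e), "volcano": first["volcano"],
            "watershed": first["watershed"],
            "x": float(first["x"] + rng.normal(0, 0.5)),
            "y": float(first["y"] + rng.normal(0, 0.5)),
        })
    out = pd.concat([kept, pd.DataFrame(extras).set_index("site_id")])
    # pin the extremes so the realized range matches the configured one
    out.iloc[out.index.get_indexer([out["elevation"].idxmin()]),
             out.columns.get_loc("elevation")] = cfg.elev_min
    out.iloc[out.index.get_indexer([out["elevation"].idxmax()]),
             out.columns.get_loc("elevation")] = cfg.elev_max
    return SiteTable(out, coord_system="planar")


# ---------------------------------------------------------------------------
# community


def species_niches(config: SimulationConfig) -> pd.DataFrame:
    """Niche optimum (m) and breadth (m) per species, in two elevation guilds.

    Optima are drawn uniformly within each guild's band (kept ``niche_gap``
    metres clear of the cutoff so the boundary falls between guilds).
    Highland species are patchier (lower occupancy ceiling, optionally
    narrower niches) — each occupies fewer sites, which drives beta
    diversity up with elevation — and guild sizes are weighted by band
    width over (breadth x occupancy) so expected richness stays flat
    along the gradient.
    """
    rng = stage_rng(config.seed, "species")
    pad = 80.0
    lo_band = (config.elev_min - pad, config.true_cutoff - config.niche_gap)
    hi_band = (config.true_cutoff + config.niche_gap, config.elev_max + pad)
    # flat expected richness: n_guild ~ span / (breadth * occupancy)
    w_lo = lo_band[1] - lo_band[0]
    w_hi = (hi_band[1] - hi_band[0]) / (config.highland_breadth_factor
                                        * config.highland_occupancy_factor)
    n_lo = int(round(config.n_species * w_lo / (w_lo + w_hi)))
    n_lo = min(max(n_lo, 1), config.n_species - 1)
    n_hi = config.n_species - n_lo
    opt = np.concatenate([
        rng.uniform(*lo_band, n_lo),
        rng.uniform(*hi_band, n_hi),
    ])
    breadth = rng.uniform(*config.breadth_range, config.n_species)
    breadth[n_lo:] *= config.highland_breadth_factor
    p_max = np.full(config.n_species, config.occupancy_max)
    p_max[n_lo:] *= config.highland_occupancy_factor
    guild = np.array(["lowland"] * n_lo + ["highland"] * n_hi)
    return pd.DataFrame({
        "species": [f"sp{j + 1:02d}" for j in range(config.n_species)],
        "optimum": opt, "breadth": breadth, "p_max": p_max, "guild": guild,
    }).set_index("species")


def occupancy_probability(elevation, optimum, breadth, p_max) -> np.ndarray:
    """Unimodal occupancy curve: p_max * exp(-0.5 ((e - opt)/breadth)^2)."""
    z = (np.asarray(elevation, float)[:, None] - np.asarray(optimum, float)[None, :]) \
        / np.asarray(breadth, float)[None, :]
    return np.asarray(p_max, float) * np.exp(-0.5 * z ** 2)


def gen_community(sites: SiteTable, config: SimulationConfig,
                  niches: pd.DataFrame | None = None) -> CommunityMatrix:
    """Draw a sites x species abundance matrix from the niche model.

    Occupancy is Bernoulli with the unimodal elevation curve; conditional
    abundance is 1 + NegBin(size, mean) so present species have count >= 1.
    """
    if niches is None:
        niches = species_niches(config)
    rng = stage_rng(config.seed, "community")
    p_max = (niches["p_max"].to_numpy() if "p_max" in niches.columns
             else config.occupancy_max)
    p = occupancy_probability(sites.elevation.to_numpy(),
                              niches["optimum"].to_numpy(),
                              niches["breadth"].to_numpy(), p_max)
    present = rng.random(p.shape) < p
    mean_extra = max(config.abundance_mean - 1.0, 1e-9)
    size = config.nb_size
    # numpy's negative_binomial(n, p) has mean n(1-p)/p
    nb_p = size / (size + mean_extra)
    counts = 1 + rng.negative_binomial(size, nb_p, p.shape)
    counts = np.where(present, counts, 0)
    df = pd.DataFrame(counts, index=sites.site_ids, columns=list(niches.index))
    return CommunityMatrix(df)


# ---------------------------------------------------------------------------
# genotypes


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols draw: Beta with given mean and variance mean(1-mean)F.

    F = 0 degenerates to the mean itself; frequencies already fixed at 0 or 1
    stay fixed.
    """
    mean = np.asarray(mean, float)
    if F <= 0:
        return mean.copy()
    out = mean.copy()
    interior = (mean > 0) & (mean < 1)
    a = mean[interior] * (1 - F) / F
    b = (1 - mean[interior]) * (1 - F) / F
    out[interior] = rng.beta(a, b)
    return out


def assign_population_sites(sites: SiteTable, config: SimulationConfig,
                            rng: np.random.Generator) -> list[str]:
    """Pick one site per population, spread evenly across the elevation range."""
    order = sites.elevation.sort_values()
    n = config.n_populations
    if n > len(order):
        raise ConfigurationError(
            f"{n} populations requested but only {len(order)} sites available")
    idx = np.round(np.linspace(0, len(order) - 1, n)).astype(int)
    # resolve collisions deterministically by walking to the next free site
    chosen: list[int] = []
    for i in idx:
        while i in chosen:
            i += 1
        chosen.append(min(i, len(order) - 1))
    return [order.index[i] for i in chosen]


def gen_genotypes(sites: SiteTable, config: SimulationConfig,
                  pop_sites: list[str] | None = None) -> GenotypeMatrix:
    """Biallelic SNP genotypes under a two-zone Balding-Nichols hierarchy.

    Per locus: ancestral frequency p ~ U(0.1, 0.9); each elevation zone
    (below / at-or-above ``true_cutoff``) draws its frequency from a Beta
    with mean p and variance p(1-p) * target_F_RT; populations nest inside
    their zone with target_F_SR; diploid genotypes are binomial draws
    (Hardy-Weinberg within population).
    """
    rng = stage_rng(config.seed, "genotypes")
    if pop_sites is None:
        pop_sites = assign_population_sites(sites, config, rng)
    elev = sites.elevation
    pop_labels = [f"pop_{s}" for s in pop_sites]
    zones = np.array([elev.loc[s] >= config.true_cutoff for s in pop_sites])
    if not (zones.any() and (~zones).any()):
        raise ConfigurationError("true_cutoff must split populations into two zones")

    L = config.n_loci
    p_anc = rng.uniform(0.1, 0.9, L)
    zone_freq = {z: _beta_draw(rng, p_anc, config.target_F_RT) for z in (False, True)}
    n_ind = config.individuals_per_population
    calls = np.empty((config.n_populations * n_ind, L, 2), dtype=np.int16)
    individuals, population = [], []
    for k, (lab, z) in enumerate(zip(pop_labels, zones)):
        p_pop = _beta_draw(rng, zone_freq[bool(z)], config.target_F_SR)
        dosage = rng.binomial(2, p_pop, (n_ind, L))
        block = slice(k * n_ind, (k + 1) * n_ind)
        calls[block, :, 0] = dosage >= 1  # het -> (0, 1); hom alt -> (1, 1)
        calls[block, :, 1] = dosage == 2
        individuals += [f"{lab}_i{i + 1}" for i in range(n_ind)]
        population += [lab] * n_ind
    return GenotypeMatrix(individuals, [f"L{j + 1:04d}" for j in range(L)],
                          calls, np.array(population, dtype=object),
                          dict(zip(pop_labels, pop_sites)))


def zone_of(elevation: float, cutoff: float) -> str:
    """Standard zone labels: lowland below the cutoff, highland at or above."""
    return "highland" if elevation >= cutoff else "lowland"
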