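"""Core data containers shared by every analysis stage.

The pipeline moves four objects around: a table of sampling sites (the
spatial backbone: elevation, volcano, watershed, coordinates), a sites x
species community matrix, a diploid multilocus genotype table with an
individual -> population -> site hierarchy, and square symmetric distance
matrices (the lingua franca between stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteTable",
    "CommunityMatrix",
    "GenotypeMatrix",
    "DistanceMatrix",
    "ValidationError",
]

MISSING = -1  # sentinel allele code for missing calls


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class SiteTable:
    """Sampling sites with elevation (m), volcano, watershed and coordinates.

    ``coord_system`` is ``"planar"`` (x, y in km; synthetic landscapes) or
    ``"lonlat"`` (x = longitude, y = latitude in decimal degrees; field data).
    """

    data: pd.DataFrame
    coord_system: str = "planar"

    REQUIRED = ("elevation", "volcano", "watershed", "x", "y")

    def __post_init__(self) -> None:
        if self.coord_system not in ("planar", "lonlat"):
            raise ValidationError(f"unknown coord_system {self.coord_system!r}")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"site table missing columns: {missing}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        elev = pd.to_numeric(self.data["elevation"], errors="coerce")
        bad = self.data.index[~(elev > 0) | elev.isna()].tolist()
        if bad:
            raise ValidationError(f"non-positive or missing elevation at sites: {bad}")
        if self.data[["volcano", "watershed"]].isna().any().any():
            raise ValidationError("every site needs exactly one volcano and watershed label")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def elevation(self) -> pd.Series:
        return self.data["elevation"].astype(float)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, site_ids) -> "SiteTable":
        return SiteTable(self.data.loc[list(site_ids)].copy(), self.coord_system)


@dataclass
class CommunityMatrix:
    """Sites x species abundance matrix; ``presence`` gives the binary view."""

    data: pd.DataFrame  # index: site_id, columns: species, integer counts

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("community matrix must be numeric")
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("community matrix contains missing values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at site {self.data.index[i]!r}, "
                f"species {self.data.columns[j]!r}"
            )
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("site ids and species labels must be unique")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return (self.data > 0).astype(int)

    def drop_absent_species(self) -> "CommunityMatrix":
        """Drop species with zero occurrences across all sites."""
        keep = self.data.columns[(self.data > 0).any(axis=0)]
        return CommunityMatrix(self.data[keep].copy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes with an individual->population->site hierarchy.

    ``calls`` has shape (n_individuals, n_loci, 2) with small non-negative
    integer allele codes; missing calls are ``MISSING`` in both slots.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    population: np.ndarray  # population label per individual
    pop_site: dict  # population label -> site_id

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        self.population = np.asarray(self.population, dtype=object)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match ({n}, {L}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise ValidationError("individual ids must be unique")
        if len(self.population) != n:
            raise ValidationError("one population label per individual required")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValidationError(
                f"half-missing call (ploidy != 2) for {self.individuals[i]!r} "
                f"at locus {self.loci[j]!r}"
            )
        unknown = [p for p in self.populations if p not in self.pop_site]
        if unknown:
            raise ValidationError(f"populations without a site assignment: {unknown}")

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.population))

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_sizes(self) -> dict:
        return {p: int((self.population == p).sum()) for p in self.populations}

    def singleton_populations(self) -> list:
        """Populations represented by exactly one individual (flagged for exclusion)."""
        return [p for p, n in self.pop_sizes().items() if n == 1]

    def drop_singleton_populations(self) -> "GenotypeMatrix":
        keep = ~np.isin(self.population, self.singleton_populations())
        return self.subset_individuals(np.flatnonzero(keep))

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        pops = set(self.population[idx])
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx].copy(),
            self.population[idx].copy(),
            {p: s for p, s in self.pop_site.items() if p in pops},
        )

    def subset_populations(self, pops) -> "GenotypeMatrix":
        keep = np.flatnonzero(np.isin(self.population, list(pops)))
        return self.subset_individuals(keep)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask, True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def dosage(self) -> np.ndarray:
        """(n, L) count of allele '1' per call for biallelic 0/1 data; NaN if missing."""
        d = (self.calls == 1).sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def pop_elevation(self, sites: SiteTable) -> dict:
        """Elevation (m) of each population's site."""
        elev = sites.elevation
        return {p: float(elev.loc[s]) for p, s in self.pop_site.items()}


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with ordered labels."""

    labels: list
    values: np.ndarray
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distance matrix entries must be non-negative")
        # exact symmetry/zero-diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.values[self.values < 0] = 0.0

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy condensed form)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def align(self, labels) -> "DistanceMatrix":
        """Reorder to the given label order (must be a permutation of ours)."""
        labels = list(labels)
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise ValidationError("label sets differ; cannot align distance matrices")
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.name,
                              dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def aligned_condensed(*dms: DistanceMatrix) -> list[np.ndarray]:
    """Condensed vectors of several matrices after aligning all to the first."""
    ref = dms[0]
    out = [ref.condensed()]
    for dm in dms[1:]:
        out.append(dm.align(ref.labels).condensed())
    return out
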