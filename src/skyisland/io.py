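"""Readers and writers for the interchange formats.

All tabular formats are comma-separated UTF-8 text with a header row and
the identifier in the first column. Lines starting with '#' are metadata
headers (every writer records at least the run seed and parameters there,
so a written artifact carries its provenance). Genotypes travel either as
a GenAlEx-style codominant table (two columns per locus, 1-based integer
allele codes, 0 = missing) or as VCF (biallelic SNPs, 1-based positions),
with a sample -> population -> site key file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (MISSING, CommunityMatrix, GenotypeMatrix, SiteTable,
                         ValidationError)

__all__ = [
    "RunConfig", "read_sites", "write_sites", "read_community",
    "write_community", "read_genotypes", "write_genotypes_genalex",
    "read_popkey", "write_table", "read_table",
]

log = logging.getLogger("skyisland")


@dataclass
class RunConfig:
    """Stage parameters of a pipeline run.

    Permutation defaults follow the analysis design: 10,000 for
    PERMANOVA / Mantel / IBD, 1,000 for AMOVA and environmental fitting.
    """

    seed: int = 0
    out_dir: str = "results"
    n_perm_manova: int = 10_000
    n_perm_mantel: int = 10_000
    n_perm_ibd: int = 10_000
    n_perm_amova: int = 1_000
    n_perm_envfit: int = 1_000
    cutoff_step: float = 50.0
    correlogram_class_width: float = 200.0
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_perm_manova", "n_perm_mantel", "n_perm_ibd",
                     "n_perm_amova", "n_perm_envfit"):
            if getattr(self, name) < 99:
                raise ValidationError(f"{name} must be >= 99")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# generic header-carrying tables


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """CSV with '# key=value' header lines recording run provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


# ---------------------------------------------------------------------------
# sites and communities


def write_sites(sites: SiteTable, path, params: dict | None = None) -> None:
    df = sites.data.copy()
    df["coord_system"] = sites.coord_system
    write_table(df, path, params)


def read_sites(path) -> SiteTable:
    df = read_table(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate site ids in {path}: {dups}")
    coord = "planar"
    if "coord_system" in df.columns:
        systems = set(df["coord_system"])
        if len(systems) > 1:
            raise ValidationError(f"mixed coordinate systems in {path}: {systems}")
        coord = systems.pop()
        df = df.drop(columns="coord_system")
    df["elevation"] = pd.to_numeric(df["elevation"], errors="coerce")
    return SiteTable(df, coord_system=coord)


def write_community(comm: CommunityMatrix, path, params: dict | None = None) -> None:
    write_table(comm.data, path, params)


def read_community(path, sites: SiteTable | None = None) -> CommunityMatrix:
    df = read_table(path, index_col=0)
    bad = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        for sid in df.index[vals.isna()]:
            bad.append((sid, col, df.loc[sid, col]))
        df[col] = vals
    if bad:
        raise ValidationError(f"non-numeric counts in {path}: {bad[:5]}")
    neg = np.argwhere(df.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative count in {path} at site {df.index[i]!r}, "
            f"species {df.columns[j]!r}")
    comm = CommunityMatrix(df)
    if sites is not None and set(comm.sites) != set(sites.site_ids):
        only_c = sorted(set(comm.sites) - set(sites.site_ids))
        only_s = sorted(set(sites.site_ids) - set(comm.sites))
        raise ValidationError(
            f"site-id mismatch: community-only {only_c}, sites-only {only_s}")
    return comm


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_genalex(g: GenotypeMatrix, path,
                            params: dict | None = None) -> None:
    """GenAlEx-style codominant table: two columns per locus, allele codes
    written 1-based, 0 for missing."""
    cols = {}
    for j, locus in enumerate(g.loci):
        for slot in (0, 1):
            codes = g.calls[:, j, slot].astype(int)
            cols[f"{locus}.{slot + 1}"] = np.where(codes == MISSING, 0, codes + 1)
    df = pd.DataFrame({"population": g.population,
                       "site_id": [g.pop_site[p] for p in g.population],
                       **cols},
                      index=pd.Index(g.individuals, name="sample_id"))
    write_table(df, path, params)


def _genalex_to_matrix(df: pd.DataFrame) -> GenotypeMatrix:
    meta_cols = [c for c in ("population", "site_id") if c in df.columns]
    if "population" not in meta_cols:
        raise ValidationError("genotype table needs a 'population' column")
    locus_cols = [c for c in df.columns if c not in meta_cols]
    loci = []
    for c in locus_cols:
        base = c.rsplit(".", 1)[0]
        if base not in loci:
            loci.append(base)
    pairs = []
    for locus in loci:
        a, b = f"{locus}.1", f"{locus}.2"
        if a not in df.columns or b not in df.columns:
            raise ValidationError(f"locus {locus!r} lacks two allele columns")
        pairs.append((a, b))
    n, L = len(df), len(loci)
    calls = np.full((n, L, 2), MISSING, dtype=np.int16)
    for j, (a, b) in enumerate(pairs):
        for slot, col in enumerate((a, b)):
            codes = pd.to_numeric(df[col], errors="raise").astype(int).to_numpy()
            calls[:, j, slot] = np.where(codes == 0, MISSING, codes - 1)
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        i, j = np.argwhere(half)[0]
        raise ValidationError(
            f"ploidy != 2 (one missing allele) for {df.index[i]!r} "
            f"at locus {loci[j]!r}")
    if "site_id" in df.columns:
        pop_site = dict(zip(df["population"], df["site_id"]))
    else:
        pop_site = {p: p for p in df["population"].unique()}
    g = GenotypeMatrix(list(df.index.astype(str)), loci, calls,
                       df["population"].to_numpy(dtype=object), pop_site)
    singles = g.singleton_populations()
    if singles:
        log.warning("single-individual populations flagged for exclusion: %s",
                    singles)
    return g


def read_popkey(path) -> pd.DataFrame:
    """Sample -> population -> site key (columns: sample_id, population, site_id)."""
    df = read_table(path)
    need = {"sample_id", "population", "site_id"}
    if not need.issubset(df.columns):
        raise ValidationError(f"popkey must have columns {sorted(need)}")
    return df.set_index("sample_id")


def _read_vcf(path, popkey: pd.DataFrame, strict: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popkey.index]
    if absent:
        raise ValidationError(f"samples absent from popkey: {absent}")
    loci, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            msg = (f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} "
                   f"(REF={rec.REF}, ALT={rec.ALT})")
            if strict:
                raise ValidationError(msg)
            log.warning("skipping %s", msg)
            continue
        loci.append(f"{rec.CHROM}:{rec.POS}")
        col = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = (a, b)
        columns.append(col)
    if not loci:
        raise ValidationError(f"no usable biallelic SNP records in {path}")
    calls = np.stack(columns, axis=1)
    pops = popkey.loc[samples, "population"].to_numpy(dtype=object)
    pop_site = dict(zip(popkey["population"], popkey["site_id"]))
    return GenotypeMatrix(samples, loci, calls, pops, pop_site)


def read_genotypes(path, format: str = "genalex",
                   popkey=None, strict: bool = False) -> GenotypeMatrix:
    """Read genotypes from a GenAlEx-style table or a VCF (+ popkey file)."""
    if format == "genalex":
        df = read_table(path, index_col=0)
        return _genalex_to_matrix(df)
    if format == "vcf":
        if popkey is None:
            raise ValidationError("reading VCF requires a popkey file")
        key = popkey if isinstance(popkey, pd.DataFrame) else read_popkey(popkey)
        return _read_vcf(path, key, strict)
    raise ValidationError(f"unknown genotype format {format!r}")
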