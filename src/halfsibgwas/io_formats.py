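"""Genotype, phenotype, family and pedigree containers plus their text dialects.

Genotypes travel as PLINK-style text ``.ped``/``.map`` pairs (biallelic,
diploid, allele letters from ``{A, C, G, T}``, missing call ``0 0``).
Phenotypes, family maps and pedigrees are tab-delimited tables with headers.
All writers are bit-deterministic given identical inputs.

Internally a SNP's calls are stored as the dosage of "allele 1", the
alphabetically first of the two alleles observed at the locus (the ordering
used by U.S. Holstein SNP reports: A before C/G/T, C before G/T, G before T).
Missing calls are coded as dosage -1 and are excluded, not imputed, from every
per-SNP test and frequency computation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1

#: The 31 routinely evaluated U.S. Holstein traits: 13 production / health /
#: reproduction traits followed by 18 body conformation traits.
DEFAULT_TRAITS: tuple[str, ...] = (
    "MY", "FY", "PY", "FPC", "PPC", "PL", "SCS", "DPR", "SCE", "DCE",
    "SSB", "DSB", "NM",
    "STA", "STR", "BD", "RW", "DF", "RA", "FUA", "RUH", "UD", "UC",
    "FTP", "RTP", "TL", "FA", "RLS", "RLR", "FL", "FS",
)

#: Traits for which a LOW value is favorable (somatic cell score, calving-ease
#: and stillbirth traits); every other trait is high-favorable.  DSB is included
#: by analogy with SSB and may be overridden.
LOW_FAVORABLE: frozenset[str] = frozenset({"SCS", "SCE", "DCE", "SSB", "DSB"})

PRODUCTION_TRAITS: tuple[str, ...] = DEFAULT_TRAITS[:13]
CONFORMATION_TRAITS: tuple[str, ...] = DEFAULT_TRAITS[13:]


def default_trait_directions() -> dict[str, str]:
    """Direction-of-favorability flag (``high``/``low``) for the 31 default traits."""
    return {t: ("low" if t in LOW_FAVORABLE else "high") for t in DEFAULT_TRAITS}


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs biallelic diploid genotypes with map metadata.

    Attributes
    ----------
    individual_ids : list of str
    snp_ids : list of str
    chromosome : array of str, per SNP ("1".."29", "X")
    position : int array, 1-based base-pair coordinate per SNP
    alleles : (m, 2) array of single letters; column 0 is allele 1
        (alphabetically first); a never-observed second allele is "0".
    dosage : (n, m) int8 array, count of allele 1 per call; -1 = missing.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    alleles: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(self.chromosome) != m or len(self.position) != m:
            raise ValueError("map arrays do not align with snp_ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_individuals(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.int64)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            self.snp_ids,
            self.chromosome,
            self.position,
            self.alleles,
            self.dosage[idx],
        )

    def subset_snps(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.int64)
        return GenotypeMatrix(
            self.individual_ids,
            [self.snp_ids[j] for j in idx],
            self.chromosome[idx],
            self.position[idx],
            self.alleles[idx],
            self.dosage[:, idx],
        )

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chromosome == str(chrom)


@dataclass
class FamilyStructure:
    """Sire half-sib family map with an optional deeper pedigree.

    ``family_blocks`` is an ordered partition of the genotyped individuals by
    sire; ``pedigree`` (optional) holds (child, sire, dam, birth_year) rows for
    ancestor tracing and may extend far beyond the genotyped set.
    """

    sire_of: dict[str, str]
    family_blocks: dict[str, list[str]] = field(default=None)  # type: ignore[assignment]
    pedigree: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.family_blocks is None:
            blocks: dict[str, list[str]] = {}
            for ind, sire in self.sire_of.items():
                blocks.setdefault(sire, []).append(ind)
            self.family_blocks = blocks
        counted = sum(len(v) for v in self.family_blocks.values())
        if counted != len(self.sire_of):
            raise ValueError("family_blocks is not a partition of the individuals")

    @property
    def sires(self) -> list[str]:
        return list(self.family_blocks)

    def sizes(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.family_blocks.items()}

    def codes_for(self, individual_ids: list[str]) -> np.ndarray:
        """Integer family code per individual, in ``individual_ids`` order."""
        index = {s: i for i, s in enumerate(self.family_blocks)}
        return np.array([index[self.sire_of[i]] for i in individual_ids], dtype=np.int64)


@dataclass
class PhenotypeTable:
    """Per-individual trait values with direction-of-favorability flags."""

    values: pd.DataFrame  # index = individual ids, columns = trait names
    directions: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate individual ids in phenotype table")
        missing = [t for t in self.values.columns if t not in self.directions]
        if missing:
            raise ValueError(f"traits without a direction flag: {missing}")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, trait: str, individual_ids: list[str]) -> np.ndarray:
        if trait not in self.values.columns:
            raise KeyError(f"trait {trait!r} absent from phenotype table")
        return self.values.loc[individual_ids, trait].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# PLINK-style .ped/.map text dialect
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, ped_path, map_path,
                  families: FamilyStructure | None = None) -> None:
    """Write a PLINK-style text ``.ped``/``.map`` pair.

    .ped rows: FID IID sire dam sex phenotype, then two allele letters per SNP
    in map order; missing calls written as ``0 0``.  Column 3 carries the sire
    id when ``families`` is given.  1-based inclusive coordinates (.map
    convention).
    """
    if g.n_individuals == 0:
        raise ValueError("cannot write a .ped file with no individuals")
    a1 = g.alleles[:, 0]
    a2 = g.alleles[:, 1]
    with open(map_path, "w") as fh:
        for j, sid in enumerate(g.snp_ids):
            fh.write(f"{g.chromosome[j]}\t{sid}\t0\t{int(g.position[j])}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individual_ids):
            sire = families.sire_of.get(ind, "0") if families is not None else "0"
            fid = sire if families is not None else "F0"
            row = [fid, ind, sire, "0", "2", "-9"]
            d = g.dosage[i]
            for j in range(g.n_snps):
                if d[j] == MISSING:
                    row += ["0", "0"]
                elif d[j] == 2:
                    row += [a1[j], a1[j]]
                elif d[j] == 1:
                    row += [a1[j], a2[j]]
                else:
                    row += [a2[j], a2[j]]
            fh.write(" ".join(row) + "\n")


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, FamilyStructure]:
    """Read a PLINK-style text ``.ped``/``.map`` pair.

    Allele 1 at each SNP is the alphabetically first observed allele; the
    missing code ``0`` is preserved as missing dosage.  Raises on ragged rows,
    on a SNP count mismatch between the two files, and on more than two
    distinct non-missing alleles at a locus (naming the SNP).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    snp_ids = mp["snp_id"].tolist()
    chrom = mp["chrom"].to_numpy(dtype=object).astype(str)
    pos = mp["pos"].to_numpy(dtype=np.int64)
    m = len(snp_ids)

    individual_ids: list[str] = []
    sire_of: dict[str, str] = {}
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped line {ln}: expected {6 + 2 * m} fields for {m} SNPs, "
                    f"got {len(parts)}")
            individual_ids.append(parts[1])
            sire_of[parts[1]] = parts[2]
            allele_rows.append(np.array(parts[6:], dtype="U1"))
    calls = (np.vstack(allele_rows) if allele_rows
             else np.empty((0, 2 * m), dtype="U1"))
    first = calls[:, 0::2]
    second = calls[:, 1::2]

    alleles = np.full((m, 2), "0", dtype="U1")
    n = len(individual_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        obs = np.concatenate([first[:, j], second[:, j]])
        distinct = sorted(set(obs) - {"0"})
        if len(distinct) > 2:
            raise ValueError(
                f"SNP {snp_ids[j]}: more than two alleles observed ({distinct})")
        for k, a in enumerate(distinct):
            alleles[j, k] = a
        called = (first[:, j] != "0") & (second[:, j] != "0")
        if distinct:
            a1 = distinct[0]
            dosage[called, j] = ((first[called, j] == a1).astype(np.int8)
                                 + (second[called, j] == a1).astype(np.int8))
    g = GenotypeMatrix(individual_ids, snp_ids, chrom, pos, alleles, dosage)
    fams = FamilyStructure(sire_of)
    return g, fams


# ---------------------------------------------------------------------------
# Phenotype / pedigree tables
# ---------------------------------------------------------------------------

def write_phenotypes(ph: PhenotypeTable, path) -> None:
    df = ph.values.copy()
    df.insert(0, "individual_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path, directions: dict[str, str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    df = df.set_index("individual_id")
    if directions is None:
        directions = default_trait_directions()
        directions.update({t: "high" for t in df.columns if t not in directions})
    return PhenotypeTable(df, directions)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# Pedigree descendant tracing
# ---------------------------------------------------------------------------

def _pedigree_graph(families: FamilyStructure) -> nx.DiGraph:
    if families.pedigree is None:
        raise ValueError("FamilyStructure carries no pedigree edges")
    graph = nx.DiGraph()
    for _, row in families.pedigree.iterrows():
        child = row["child"]
        graph.add_node(child)
        for parent_col in ("sire", "dam"):
            parent = row.get(parent_col)
            if parent is not None and str(parent) not in ("0", "nan", ""):
                graph.add_edge(str(parent), child)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("pedigree contains a cycle")
    return graph


def pedigree_descendants(families: FamilyStructure, ancestor_id: str,
                         target_set) -> tuple[int, set[str]]:
    """Members of ``target_set`` descending from ``ancestor_id``.

    Reachability follows parent->child edges of the pedigree.  Returns the
    (count, subset); the ancestor itself counts as its own descendant when it
    belongs to the target set, matching how "related to a bull" is tallied in
    pedigree studies.
    """
    graph = _pedigree_graph(families)
    if ancestor_id not in graph:
        raise KeyError(f"unknown ancestor id {ancestor_id!r}")
    reach = nx.descendants(graph, ancestor_id) | {ancestor_id}
    hit = set(target_set) & reach
    return len(hit), hit


def common_descendants(families: FamilyStructure, ancestor_a: str,
                       ancestor_b: str, target_set) -> tuple[int, set[str]]:
    """Intersection of two ancestors' descendant sets within ``target_set``."""
    _, da = pedigree_descendants(families, ancestor_a, target_set)
    _, db = pedigree_descendants(families, ancestor_b, target_set)
    both = da & db
    return len(both), both


def write_genotype_package(g: GenotypeMatrix, families: FamilyStructure,
                           phenotypes: PhenotypeTable, outdir) -> dict[str, Path]:
    """Write the full text bundle (.ped/.map, phenotypes, family map)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "phen": outdir / "phenotypes.tsv",
        "fam": outdir / "families.tsv",
    }
    write_ped_map(g, paths["ped"], paths["map"], families)
    write_phenotypes(phenotypes, paths["phen"])
    pd.DataFrame({"individual_id": list(families.sire_of),
                  "sire": [families.sire_of[i] for i in families.sire_of]}
                 ).to_csv(paths["fam"], sep="\t", index=False)
    return paths
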