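"""Genome stratification analysis: IBS distance, classical MDS, elite cluster.

The workflow mirrors how selection-driven stratification is visualised in
livestock GWAS: pairwise identity-by-state similarity over a SNP panel,
classical (Torgerson) multidimensional scaling of the distance 1 - IBS, and a
2-means split of the top two coordinates (C1, C2) in which the smaller cluster
is labelled "elite".  Per-chromosome MDS supports the X-vs-autosome contrast:
daughters of one sire share an identical sire X haplotype, so the X chromosome
stratifies a large half-sib family far more cleanly than any recombining
autosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .io_formats import FamilyStructure, GenotypeMatrix
from .kinship import ibs_matrix, _usable_snps
from .io_formats import MISSING


def ibs_similarity(g: GenotypeMatrix,
                   snp_subset: np.ndarray | None = None) -> np.ndarray:
    """Pairwise IBS similarity in [0, 1] (see :func:`kinship.ibs_matrix`)."""
    d = g.dosage if snp_subset is None else g.dosage[:, np.asarray(snp_subset)]
    usable = _usable_snps(d)
    if usable.size == 0:
        raise ValueError("no usable SNPs in the requested subset")
    return ibs_matrix(d[:, usable])


@dataclass
class MDSResult:
    coordinates: np.ndarray   # (n, k), columns ordered by eigenvalue
    eigenvalues: np.ndarray   # non-increasing, positive
    chromosome_scope: str     # "all" or a chromosome label
    individual_ids: list[str]

    def frame(self) -> pd.DataFrame:
        cols = {f"C{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        df = pd.DataFrame({"individual_id": self.individual_ids,
                           "scope": self.chromosome_scope, **cols})
        return df


def classical_mds(similarity: np.ndarray, n_dims: int = 2,
                  individual_ids: list[str] | None = None,
                  scope: str = "all") -> MDSResult:
    """Classical (Torgerson) MDS of the distance D = 1 - similarity.

    Double-centers -0.5 * D∘D, eigendecomposes, and returns the top ``n_dims``
    eigenvectors scaled by sqrt(eigenvalue); dimensions with non-positive
    eigenvalues are excluded.  Coordinate columns have zero mean by
    construction.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    n = s.shape[0]
    d2 = (1.0 - s) ** 2
    b = -0.5 * d2
    b -= b.mean(axis=0, keepdims=True)
    b -= b.mean(axis=1, keepdims=True)
    b = (b + b.T) / 2.0
    take = min(n_dims, n - 1) if n > 1 else 1
    vals, vecs = eigh(b, subset_by_index=(max(0, n - take), n - 1))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    keep = vals > max(1e-12, 1e-12 * abs(vals[0]) if vals.size else 0)
    vals = vals[keep]
    vecs = vecs[:, keep]
    coords = vecs * np.sqrt(vals)
    if coords.size == 0:
        coords = np.zeros((n, 1))
        vals = np.zeros(1)
    ids = individual_ids if individual_ids is not None else [str(i) for i in range(n)]
    return MDSResult(coords, vals, scope, list(ids))


def orient_axes(mds: MDSResult, elite_ids: set[str]) -> MDSResult:
    """Fix axis signs so the elite cluster's mean C1 (and C2) is positive."""
    mask = np.array([i in elite_ids for i in mds.individual_ids])
    if mask.any():
        coords = mds.coordinates.copy()
        for j in range(coords.shape[1]):
            if coords[mask, j].mean() < 0:
                coords[:, j] = -coords[:, j]
        return MDSResult(coords, mds.eigenvalues, mds.chromosome_scope,
                         mds.individual_ids)
    return mds


def mds_per_chromosome(g: GenotypeMatrix, n_dims: int = 2) -> dict[str, MDSResult]:
    """Classical MDS separately for each chromosome label present in the map."""
    out: dict[str, MDSResult] = {}
    for chrom in dict.fromkeys(g.chromosome):
        subset = np.flatnonzero(g.chrom_mask(chrom))
        sim = ibs_similarity(g, subset)
        out[str(chrom)] = classical_mds(sim, n_dims, g.individual_ids,
                                        scope=str(chrom))
    return out


@dataclass
class ClusterAssignment:
    labels: dict[str, str]      # individual -> "elite" | "average"
    elite_ids: set[str]
    method: str

    @property
    def average_ids(self) -> set[str]:
        return {i for i, lab in self.labels.items() if lab == "average"}


def assign_clusters(mds: MDSResult, k: int = 2,
                    known_elite_family: list[str] | None = None,
                    random_state: int = 0) -> ClusterAssignment:
    """Elite/average split: 2-means on (C1, C2), smaller cluster = elite.

    When ``known_elite_family`` is given the assignment is direct labeling of
    those ids (the "160 elite cows" usage) and no clustering runs.
    """
    if known_elite_family is not None:
        elite = set(known_elite_family)
        labels = {i: ("elite" if i in elite else "average")
                  for i in mds.individual_ids}
        return ClusterAssignment(labels, elite, "known-family")
    if k != 2:
        raise ValueError("only k=2 clustering is supported")
    if len(mds.individual_ids) < 2:
        raise ValueError("need at least two individuals to cluster")
    xy = mds.coordinates[:, :2]
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(xy)
    counts = np.bincount(km.labels_, minlength=2)
    elite_label = int(np.argmin(counts))
    elite = {i for i, lab in zip(mds.individual_ids, km.labels_)
             if lab == elite_label}
    labels = {i: ("elite" if i in elite else "average")
              for i in mds.individual_ids}
    return ClusterAssignment(labels, elite, "2-means")


def cluster_purity(assigned_elite: set[str], true_elite: set[str]) -> float:
    """min(precision, recall) of the elite call: |A∩T| / max(|A|, |T|)."""
    if not assigned_elite or not true_elite:
        return 0.0
    return len(assigned_elite & true_elite) / max(len(assigned_elite),
                                                  len(true_elite))


def elite_purity_by_chromosome(g: GenotypeMatrix, families: FamilyStructure,
                               elite_sire: str) -> pd.Series:
    """2-means elite recovery purity from per-chromosome MDS coordinates."""
    true_elite = set(families.family_blocks[elite_sire])
    out = {}
    for chrom, mds in mds_per_chromosome(g).items():
        assign = assign_clusters(mds)
        out[chrom] = cluster_purity(assign.elite_ids, true_elite)
    return pd.Series(out, name="purity")


def export_mds(results, path) -> None:
    """Write MDS coordinates as a tab-delimited table (individual, scope, C1..)."""
    if isinstance(results, MDSResult):
        results = [results]
    frames = [r.frame() for r in results]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.8g")
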