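"""Relatedness matrices for mixed-model association.

Three flavors: identity-by-state (IBS) allele sharing, the allele-frequency
standardized genotype Gram matrix popularised by the Balding-Nichols model of
subpopulation divergence, and the 0/1 family-incidence Gram matrix ZZ' that
encodes half-sib membership (the bridge between the mixed model and the
compound-symmetry GLS parameterization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, FamilyStructure, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    values: np.ndarray  # (n, n) symmetric
    flavor: str         # "IBS", "BN" or "family"
    individual_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")


def ibs_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise mean proportion of shared alleles from a dosage matrix.

    For dosages a, b in {0,1,2} the shared-allele count is 2 - |a - b|, so
    s_ij = 1 - mean|d_i - d_j| / 2 over SNPs where both are called.  Computed
    with three indicator matmuls; O(n^2 m).
    """
    called = dosage != MISSING
    h = [np.ascontiguousarray((dosage == k) & called, dtype=np.float64)
         for k in (0, 1, 2)]
    # sum over SNPs of |d_i - d_j|: adjacent mismatches count 1, opposite
    # homozygotes count 2
    absdiff = (h[0] @ h[1].T + h[1] @ h[0].T
               + h[1] @ h[2].T + h[2] @ h[1].T
               + 2.0 * (h[0] @ h[2].T + h[2] @ h[0].T))
    pairs = np.ascontiguousarray(called, dtype=np.float64)
    n_called = pairs @ pairs.T
    if np.any(n_called == 0):
        raise ValueError("some individual pair shares no called SNP")
    sim = 1.0 - absdiff / (2.0 * n_called)
    np.fill_diagonal(sim, 1.0)
    return (sim + sim.T) / 2.0


def kinship_ibs(g: GenotypeMatrix, snp_subset: np.ndarray | None = None) -> KinshipMatrix:
    """IBS kinship: mean fraction of alleles shared, in [0, 1], unit diagonal.

    All called SNPs contribute (monomorphic loci simply add full sharing);
    only columns with no called genotype at all are dropped.
    """
    d = g.dosage if snp_subset is None else g.dosage[:, snp_subset]
    usable = _usable_snps(d)
    if usable.size == 0:
        raise ValueError("no called SNPs for IBS")
    return KinshipMatrix(ibs_matrix(d[:, usable]), "IBS", list(g.individual_ids))


def _usable_snps(dosage: np.ndarray) -> np.ndarray:
    """Columns with at least one called genotype."""
    return np.flatnonzero((dosage != MISSING).any(axis=0))


def kinship_bn(g: GenotypeMatrix) -> KinshipMatrix:
    """Allele-frequency standardized genotype Gram matrix (m SNPs averaged).

    Per SNP the dosage is centered by 2*p and scaled by sqrt(2p(1-p)) with p
    the sample frequency of allele 1; K = S S' / m over the m polymorphic
    SNPs.  Missing dosages contribute zero after centering (mean imputation).
    """
    d = g.dosage.astype(np.float64)
    called = g.dosage != MISSING
    d[~called] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    n_dropped = g.n_snps - int(poly.sum())
    if n_dropped:
        logger.info("kinship_bn: dropped %d monomorphic/uncalled SNPs", n_dropped)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; BN kinship undefined")
    z = (d[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    z = np.nan_to_num(z)
    k = z @ z.T / z.shape[1]
    return KinshipMatrix((k + k.T) / 2.0, "BN", list(g.individual_ids))


def kinship_family(families: FamilyStructure,
                   individual_ids: list[str] | None = None) -> KinshipMatrix:
    """Family-incidence Gram matrix ZZ': K_ij = 1 iff same sire, K_ii = 1."""
    ids = individual_ids or list(families.sire_of)
    codes = families.codes_for(ids)
    k = (codes[:, None] == codes[None, :]).astype(np.float64)
    return KinshipMatrix(k, "family", list(ids))
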