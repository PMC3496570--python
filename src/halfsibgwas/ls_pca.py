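"""Least-squares association, genotype PCA, and the elite-exclusion rerun.

Uncorrected least squares (LS) tests each SNP's three genotype classes with
ordinary least squares - the fastest and the most stratification-prone method.
PCA correction adds the top principal components of the standardized genotype
matrix (default 20) as covariates; excluding a set of individuals (the
"analysis without the elite cows" rerun) recomputes principal components and
allele frequencies on the retained animals, a full reanalysis rather than a
row drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc
from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class PcaBasis:
    """Orthonormal individual-space principal components of the genotypes."""

    components: np.ndarray          # (n, k), orthonormal columns
    explained_variance: np.ndarray  # non-increasing
    individual_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def standardized_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Dosage centered by 2p and scaled by sqrt(2p(1-p)); monomorphic dropped.

    Missing dosages contribute zero after centering (mean imputation), the
    standard choice for genotype PCA.
    """
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic SNPs")
    z = (d[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    return np.nan_to_num(z)


def compute_pcs(g: GenotypeMatrix, n_components: int = 20) -> PcaBasis:
    """Top principal components over individuals from standardized genotypes."""
    if n_components >= g.n_individuals:
        raise ValueError("n_components must be below the number of individuals")
    z = standardized_dosage(g)
    z = z - z.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, s.size)
    ev = (s[:k] ** 2) / z.shape[1]
    return PcaBasis(u[:, :k], ev, list(g.individual_ids))


def ls_scan(g: GenotypeMatrix, phenotypes: PhenotypeTable, trait: str,
            covariates: np.ndarray | PcaBasis | None = None,
            n_pcs: int = 0, exclude: set | None = None,
            coding: str = "classes", contrast_provider=None) -> pd.DataFrame:
    """Ordinary least squares scan, optionally PCA-corrected or elite-excluded.

    ``n_pcs > 0`` computes that many genotype principal components on the
    analysed individuals and adds them as covariates (the PCA method);
    ``covariates`` may supply an explicit basis or covariate matrix instead.
    ``exclude`` removes individuals before anything - including the PCA - is
    computed.
    """
    if exclude:
        keep = [i for i, ind in enumerate(g.individual_ids)
                if ind not in exclude]
        g = g.subset_individuals(keep)
    ids = g.individual_ids
    y = phenotypes.vector(trait, ids)

    parts = []
    if isinstance(covariates, PcaBasis):
        if covariates.individual_ids != list(ids):
            raise ValueError("PCA basis individuals do not match the scan set")
        parts.append(covariates.components)
    elif covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        parts.append(cov if cov.ndim == 2 else cov[:, None])
    if n_pcs:
        parts.append(compute_pcs(g, n_pcs).components)
    fixed = np.hstack(parts) if parts else None

    def identity_for(mask: np.ndarray):
        return lambda a: np.asarray(a, dtype=float)

    return assoc.scan_snps(g, y, fixed, identity_for, coding=coding,
                           contrast_provider=contrast_provider)
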