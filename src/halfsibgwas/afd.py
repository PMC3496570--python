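"""Allele-frequency-difference (AFD) scoring between elite and average clusters.

For each SNP the favorable allele per trait is the allele whose estimated
additive effect moves the trait in its desirable direction (up for yields,
down for somatic cell score and calving-difficulty traits); its frequency is
counted over called genotypes separately in the elite and the average
cluster, and AFD = |freq_elite - freq_average|.  The unsigned difference is
identical for either allele of a biallelic SNP, so genome-wide threshold
counts (e.g. how many markers exceed AFD 0.3 or 0.4) do not depend on the
orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc
from .io_formats import MISSING, GenotypeMatrix
from .stratification import ClusterAssignment


def favorable_allele(est_additive: float, allele1: str, allele2: str,
                     direction: str) -> str | None:
    """The allele moving the trait in its desirable direction, or None on a tie.

    ``est_additive`` is the fitted additive effect of allele 1 (positive means
    allele 1 raises the trait).  For high-favorable traits a positive effect
    makes allele 1 favorable; for low-favorable traits (somatic cell score,
    calving ease, stillbirth) the sign rule is reversed.
    """
    if direction not in ("high", "low"):
        raise ValueError(f"unknown trait direction {direction!r}")
    if est_additive == 0 or not np.isfinite(est_additive):
        return None
    wants_allele1 = (est_additive > 0) == (direction == "high")
    return allele1 if wants_allele1 else allele2


def cluster_frequencies(g: GenotypeMatrix, clusters: ClusterAssignment,
                        snp: int | None = None):
    """Allele-1 frequency over called genotypes in each cluster.

    Returns ``(freq_elite, freq_average, n_elite_called, n_average_called)``
    as scalars for a single SNP or as arrays for all SNPs; a cluster with no
    called genotype at a SNP gets frequency NaN (flagged unavailable).
    """
    elite_mask = np.array([clusters.labels[i] == "elite"
                           for i in g.individual_ids])
    if not elite_mask.any() or elite_mask.all():
        raise ValueError("both clusters must be non-empty")

    def freq(block: np.ndarray):
        called = block != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called, block, 0).sum(axis=0) / (2.0 * n_called)
        return np.where(n_called > 0, f, np.nan), n_called

    fe, ne = freq(g.dosage[elite_mask])
    fa, na = freq(g.dosage[~elite_mask])
    if snp is not None:
        return float(fe[snp]), float(fa[snp]), int(ne[snp]), int(na[snp])
    return fe, fa, ne, na


def afd_value(freq_elite: float, freq_average: float) -> float:
    """Unsigned allele-frequency difference between the two clusters."""
    return abs(freq_elite - freq_average)


def afd_table(g: GenotypeMatrix, clusters: ClusterAssignment,
              results_by_trait: dict[str, pd.DataFrame] | None = None,
              directions: dict[str, str] | None = None,
              thresholds: tuple[float, ...] = (0.3, 0.4)):
    """Per-SNP AFD records plus counts of SNPs at or above each threshold.

    Without association results, one record per SNP oriented on allele 1.
    With per-trait results (and trait directions), one record per SNP-trait
    pair carrying the favorable-allele label and its per-cluster frequencies;
    the unsigned AFD - hence every threshold count - is orientation-free.
    Rows are AFD-ranked, ties broken by (chromosome, position).
    """
    fe, fa, ne, na = cluster_frequencies(g, clusters)
    base = pd.DataFrame({
        "snp_id": g.snp_ids,
        "chromosome": g.chromosome,
        "position": g.position,
        "freq_elite": fe, "freq_average": fa,
        "n_elite_called": ne, "n_average_called": na,
        "afd": np.abs(fe - fa),
    })
    if results_by_trait is None:
        table = base.copy()
        table.insert(3, "trait", pd.NA)
        table.insert(4, "favorable_allele", g.alleles[:, 0])
    else:
        if directions is None:
            raise ValueError("trait directions required with association results")
        frames = []
        for trait, res in results_by_trait.items():
            res = res.set_index("snp_id")
            direction = directions[trait]
            fav, f_e, f_a = [], [], []
            for j, sid in enumerate(g.snp_ids):
                est = res.at[sid, "est_additive"] if sid in res.index else np.nan
                lab = (favorable_allele(float(est), g.alleles[j, 0],
                                        g.alleles[j, 1], direction)
                       if np.isfinite(est) else None)
                if lab == g.alleles[j, 1]:  # orient frequencies on allele 2
                    f_e.append(1.0 - fe[j])
                    f_a.append(1.0 - fa[j])
                else:
                    f_e.append(fe[j])
                    f_a.append(fa[j])
                fav.append(lab)
            frame = base.copy()
            frame["freq_elite"] = f_e
            frame["freq_average"] = f_a
            frame["afd"] = np.abs(np.array(f_e) - np.array(f_a))
            frame.insert(3, "trait", trait)
            frame.insert(4, "favorable_allele", fav)
            frames.append(frame)
        table = pd.concat(frames, ignore_index=True)

    key = assoc.chrom_sort_key(table["chromosome"])
    order = np.lexsort((table["position"].to_numpy(), key,
                        -table["afd"].fillna(-1.0).to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    per_snp_afd = base["afd"].to_numpy()
    counts = {thr: int(np.nansum(per_snp_afd >= thr)) for thr in thresholds}
    return table, counts
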