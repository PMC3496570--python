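"""Genome and per-chromosome MDS of the simulated population; elite cluster.

Reads the population written by 01_simulate_population.py, computes IBS
similarity and classical MDS coordinates genome-wide and per chromosome,
assigns elite/average clusters by 2-means on (C1, C2), and reports how
cleanly each chromosome separates the elite half-sib family.  The shared
sire-X haplotype makes the X chromosome stand out against every autosome.
Writes plot-ready coordinate tables and the purity summary under
results/stratification/.
"""

from pathlib import Path

import pandas as pd

from halfsibgwas import io_formats, stratification

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stratification"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g, families = io_formats.read_ped_map(ROOT / "population" / "genotypes.ped",
                                          ROOT / "population" / "genotypes.map")
    elite_sire = max(families.sizes(), key=families.sizes().get)
    elite = set(families.family_blocks[elite_sire])

    sim = stratification.ibs_similarity(g)
    mds = stratification.classical_mds(sim, 2, g.individual_ids)
    mds = stratification.orient_axes(mds, elite)
    assign = stratification.assign_clusters(mds)
    purity = stratification.cluster_purity(assign.elite_ids, elite)
    print(f"genome-wide MDS: 2-means elite cluster of {len(assign.elite_ids)} "
          f"cows, purity vs the largest half-sib family {purity:.3f}")
    stratification.export_mds(mds, OUT / "mds_genome.tsv")

    per_chrom = stratification.mds_per_chromosome(g)
    stratification.export_mds(list(per_chrom.values()), OUT / "mds_per_chromosome.tsv")
    per_purity = stratification.elite_purity_by_chromosome(g, families,
                                                           elite_sire)
    per_purity.rename_axis("chromosome").to_frame().to_csv(
        OUT / "elite_purity_by_chromosome.tsv", sep="\t")
    best_auto = per_purity.drop("X").idxmax()
    print(f"per-chromosome elite purity: X = {per_purity['X']:.3f}, "
          f"best autosome ({best_auto}) = {per_purity.drop('X').max():.3f}")

    labels = pd.DataFrame({"individual_id": g.individual_ids,
                           "cluster": [assign.labels[i] for i in g.individual_ids]})
    labels.to_csv(OUT / "cluster_assignment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
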