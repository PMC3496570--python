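"""Generate the emulated half-sib study population and write its text bundle.

Produces a scaled version of the study conditions (1,654 cows in 355 sire
families with a 160-daughter elite family; marker count reduced to 3,000 SNPs
on 29 autosomes + X so the whole analysis chain runs in seconds) plus an
elite-confounded variant used by the association-scan drivers.  Writes
PLINK-style .ped/.map, phenotypes, the family map, and the planted-locus
truth table under results/population/.
"""

from pathlib import Path

from halfsibgwas import io_formats, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "population"
SEED = 1


def main() -> None:
    cfg = simulate.study_scale_config(seed=SEED, n_snps_total=3000)
    pop = simulate.simulate_population(cfg)
    paths = io_formats.write_genotype_package(pop.genotypes, pop.families,
                                              pop.phenotypes, OUT)
    sizes = sorted(pop.families.sizes().values())
    print(f"population: {pop.genotypes.n_individuals} cows, "
          f"{len(sizes)} sire families (sizes {sizes[0]}..{sizes[-1]}), "
          f"{pop.genotypes.n_snps} SNPs")
    print(f"elite family: {pop.elite_sire} with {len(pop.elite_ids)} daughters")

    confounded = simulate.simulate_population(
        simulate.confounded_config(seed=SEED))
    cpaths = io_formats.write_genotype_package(
        confounded.genotypes, confounded.families, confounded.phenotypes,
        OUT / "confounded")
    confounded.truth.to_csv(OUT / "confounded" / "truth.tsv", sep="\t",
                            index=False)
    print(f"confounded population: {confounded.genotypes.n_individuals} cows, "
          f"{len(confounded.truth)} planted loci "
          f"(mean realized elite-average gap "
          f"{(confounded.truth.elite_freq_realized - confounded.truth.average_freq_realized).mean():.2f})")
    for name, p in {**paths, **{f'confounded_{k}': v for k, v in cpaths.items()}}.items():
        print(f"  wrote {p}")


if __name__ == "__main__":
    main()
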