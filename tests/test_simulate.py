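"""Generator invariants: determinism, family structure, X sharing, frequencies."""

import numpy as np
import pytest

from halfsibgwas import simulate
from halfsibgwas.simulate import PlantedLocus, SimulationConfig


def test_seed_determinism():
    cfg = simulate.null_config(n_families=10, family_size=4, n_snps=30, seed=9)
    a = simulate.simulate_population(cfg)
    b = simulate.simulate_population(cfg)
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    assert a.phenotypes.values.equals(b.phenotypes.values)
    assert a.families.sire_of == b.families.sire_of


def test_dosage_conservation_and_single_sire(small_pop):
    d = small_pop.genotypes.dosage
    assert set(np.unique(d)) <= {0, 1, 2}
    for ind in small_pop.genotypes.individual_ids:
        assert ind in small_pop.families.sire_of


def test_study_size_family_structure():
    cfg = SimulationConfig(n_snps_per_chromosome={"1": 5}, n_autosomes=1,
                           include_x=False, trait_catalog=("MY",), seed=1)
    pop = simulate.simulate_population(cfg)
    sizes = list(pop.families.sizes().values())
    assert sum(sizes) == 1654
    assert len(sizes) == 355
    assert max(sizes) == 160
    assert min(sizes) >= 1
    assert len(pop.elite_ids) == 160


def test_infeasible_family_sizes_rejected():
    with pytest.raises(ValueError, match="sum"):
        SimulationConfig(n_individuals=10, n_sires=2, elite_family_size=5,
                         family_sizes=(5, 6)).validate()
    with pytest.raises(ValueError, match="out of range"):
        SimulationConfig(n_snps_per_chromosome={"1": 10}, n_autosomes=1,
                         include_x=False,
                         planted_loci=(PlantedLocus(99, 0.5, 0.5),)).validate()


def test_x_haplotype_shared_within_family():
    # single sire, X only, no recombination: paternal X identical in all
    cfg = SimulationConfig(
        n_individuals=40, n_sires=1, elite_family_size=40,
        n_snps_per_chromosome={"X": 50}, n_autosomes=0, include_x=True,
        recombination_rate=0.0, trait_catalog=("MY",), seed=5)
    pop = simulate.simulate_population(cfg)
    sire_x = pop.sire_haplotypes["X"][0]
    # each genotype = shared sire haplotype + one maternal allele in {0, 1}
    maternal = pop.genotypes.dosage - sire_x[None, :]
    assert set(np.unique(maternal)) <= {0, 1}


def test_x_sharing_across_families():
    cfg = simulate.mds_config(seed=2)
    pop = simulate.simulate_population(cfg)
    x_cols = pop.genotypes.chrom_mask("X")
    x_idx = pop.sire_haplotypes["x_index"]
    sire_list = list(pop.families.family_blocks)
    for si, sire in enumerate(sire_list[:10]):
        rows = [pop.genotypes.individual_ids.index(i)
                for i in pop.families.family_blocks[sire]]
        diff = (pop.genotypes.dosage[np.ix_(rows, x_idx)]
                - pop.sire_haplotypes["X"][si][None, :])
        assert set(np.unique(diff)) <= {0, 1}


def test_planted_afd_realized_within_binomial_bounds():
    # 200 elite + 2000 average at planted frequencies 0.9 / 0.1
    cfg = SimulationConfig(
        n_individuals=2200, n_sires=401, elite_family_size=200,
        n_snps_per_chromosome={"1": 50}, n_autosomes=1, include_x=False,
        planted_loci=(PlantedLocus(0, 0.9, 0.1),),
        trait_catalog=("MY",), seed=42)
    pop = simulate.simulate_population(cfg)
    # independent frequency-count oracle straight off the dosage matrix
    elite_rows = [pop.genotypes.individual_ids.index(i) for i in pop.elite_ids]
    avg_rows = [pop.genotypes.individual_ids.index(i) for i in pop.average_ids]
    fe = pop.genotypes.dosage[elite_rows, 0].sum() / (2 * len(elite_rows))
    fa = pop.genotypes.dosage[avg_rows, 0].sum() / (2 * len(avg_rows))
    assert abs((fe - fa) - 0.8) <= 0.06
    t = pop.truth.iloc[0]
    assert t.elite_freq_realized == pytest.approx(fe)
    assert t.average_freq_realized == pytest.approx(fa)


def test_average_cluster_frequency_converges_to_base(rng):
    cfg = simulate.null_config(n_families=250, family_size=4, n_snps=200,
                               seed=17)
    pop = simulate.simulate_population(cfg)
    freq = pop.genotypes.dosage.mean(axis=0) / 2.0
    # recover base frequencies through the config's own generator stream
    gen = np.random.default_rng((cfg.seed, 0))
    a, b = cfg.base_freq_beta
    base = np.clip(gen.beta(a, b, size=200), *cfg.freq_clip)
    bound = 4.0 * np.sqrt(base * (1 - base) / (2 * pop.genotypes.n_individuals))
    # paternal transmission adds sire-sampling variance; allow 2x the
    # i.i.d.-binomial envelope and require near-total compliance
    assert np.mean(np.abs(freq - base) <= 2 * bound) > 0.97


def test_degenerate_phenotypes_equal_mu():
    cfg = simulate.null_config(n_families=5, family_size=4, n_snps=10, seed=2,
                               sigma_f2=0.0, sigma_e2=0.0)
    pop = simulate.simulate_population(cfg)
    assert np.allclose(pop.phenotypes.values["MY"], cfg.mu)


def test_noiseless_additive_effect_is_exactly_2a():
    a = 1.7
    cfg = SimulationConfig(
        n_individuals=40, n_sires=9, elite_family_size=8,
        n_snps_per_chromosome={"1": 20}, n_autosomes=1, include_x=False,
        planted_loci=(PlantedLocus(3, 0.5, 0.5, effect=a, traits=("MY",)),),
        sigma_f2=0.0, sigma_e2=0.0, trait_catalog=("MY",), seed=8)
    pop = simulate.simulate_population(cfg)
    y = pop.phenotypes.values["MY"].to_numpy()
    d = pop.genotypes.dosage[:, 3]
    if (d == 2).any() and (d == 0).any():
        assert np.allclose(y[d == 2].mean() - y[d == 0].mean(), 2 * a)
    assert np.allclose(np.unique(y), np.unique(cfg.mu + a * np.unique(d)))


def test_low_favorable_trait_effect_sign_flipped():
    a = 2.0
    cfg = SimulationConfig(
        n_individuals=40, n_sires=9, elite_family_size=8,
        n_snps_per_chromosome={"1": 10}, n_autosomes=1, include_x=False,
        planted_loci=(PlantedLocus(0, 0.5, 0.5, effect=a, traits=("SCS",)),),
        sigma_f2=0.0, sigma_e2=0.0, trait_catalog=("SCS",), seed=8)
    pop = simulate.simulate_population(cfg)
    y = pop.phenotypes.values["SCS"].to_numpy()
    d = pop.genotypes.dosage[:, 0]
    # SCS is low-favorable: planted favorable allele 1 must DECREASE it
    assert y[d == 2].mean() < y[d == 0].mean()


def test_intraclass_correlation_recovered_by_anova_oracle():
    cfg = simulate.null_config(n_families=500, family_size=10, n_snps=5,
                               sigma_f2=1.0, sigma_e2=3.0, seed=21)
    pop = simulate.simulate_population(cfg)
    y = pop.phenotypes.values["MY"].to_numpy()
    codes = pop.families.codes_for(pop.genotypes.individual_ids)
    # one-way ANOVA moment estimator of the intraclass correlation
    k = 10
    groups = y.reshape(-1, k) if np.all(np.diff(codes) >= 0) else None
    means = np.array([y[codes == c].mean() for c in range(500)])
    msb = k * means.var(ddof=1)
    msw = np.mean([y[codes == c].var(ddof=1) for c in range(500)])
    icc = (msb - msw) / (msb + (k - 1) * msw)
    assert abs(icc - 0.25) <= 0.03


def test_yaml_config_round_trip(tmp_path):
    text = """
n_individuals: 30
n_sires: 7
elite_family_size: 6
n_snps_per_chromosome: {"1": 15}
n_autosomes: 1
include_x: false
trait_catalog: [MY, SCS]
planted_loci:
  - {snp_index: 2, elite_freq: 0.8, average_freq: 0.2, effect: 1.0, traits: [MY]}
seed: 4
"""
    path = tmp_path / "cfg.yaml"
    path.write_text(text)
    cfg = SimulationConfig.from_yaml(path)
    assert cfg.n_individuals == 30
    assert cfg.planted_loci[0].elite_freq == 0.8
    pop = simulate.simulate_population(cfg)
    assert pop.genotypes.n_snps == 15
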