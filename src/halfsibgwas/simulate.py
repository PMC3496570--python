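"""Forward simulation of a half-sib dairy cow population with planted stratification.

The generator emulates the structure of a contemporary U.S. Holstein GWAS
sample: ~1,654 genotyped cows in 355 paternal half-sib families (sizes 1-160),
one "elite" family of ~160 daughters of a single high-merit sire, ~45k
biallelic SNPs on 29 autosomes plus X, and PTA-like phenotypes composed of a
family variance component, planted SNP effects, and residual noise.

Key structural features reproduced:

* every cow has exactly one sire; dams are unrelated draws from population
  allele frequencies, so phenotypes are equicorrelated within a family
  (compound-symmetry covariance, intraclass correlation rho);
* each daughter's paternal gamete is a recombined copy of her sire's two
  haplotypes (Poisson crossover counts, uniform breakpoints); on the X
  chromosome (outside an optional pseudo-autosomal prefix) the sire has a
  single haplotype which every daughter inherits intact, so all daughters of
  one sire share an identical sire-derived X;
* the elite family is sampled from allele frequencies diverged from the
  general population - at explicitly planted loci (with chosen elite/average
  frequencies and per-allele effects) and, mildly, genome-wide - so the elite
  cluster separates in IBS/MDS space the way selection-driven stratification
  does in real data;
* optionally the elite family's phenotype mean is shifted in the favorable
  direction, creating the genome/phenotype stratification overlap that
  confounds uncorrected association tests.

All randomness flows from ``SimulationConfig.seed``; identical configs give
bit-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io_formats import (DEFAULT_TRAITS, FamilyStructure, GenotypeMatrix,
                         PhenotypeTable, default_trait_directions)

_LETTERS = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedLocus:
    """A SNP whose elite/average frequencies (and optionally effect) are planted.

    ``effect`` is the additive per-allele effect (trait units) of allele 1 on
    each trait in ``traits``; the realized sign is flipped for low-favorable
    traits so that allele 1 is always the *favorable* allele at a planted
    locus.  ``effect=0`` plants pure frequency divergence with no true effect.
    """

    snp_index: int
    elite_freq: float
    average_freq: float
    effect: float = 0.0
    traits: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the half-sib population generator.

    Defaults mirror the emulated study population: 1,654 cows, 355 sires,
    one elite family of 160, 45,878 SNPs on 29 autosomes + X, family variance
    1 and residual variance 3 (intraclass correlation 0.25), one expected
    crossover per chromosome per meiosis.
    """

    n_individuals: int = 1654
    n_sires: int = 355
    elite_family_size: int = 160
    family_sizes: tuple[int, ...] | None = None  # explicit sizes (elite first)
    n_snps_per_chromosome: dict | None = None    # chrom label -> count
    n_snps_total: int = 45_878                   # used when per-chrom map is None
    n_autosomes: int = 29
    include_x: bool = True
    base_freq_beta: tuple[float, float] = (2.0, 2.0)
    freq_clip: tuple[float, float] = (0.02, 0.98)
    planted_loci: tuple[PlantedLocus, ...] = ()
    elite_divergence_frac: float = 0.0
    elite_divergence_gap: float = 0.0
    sigma_f2: float = 1.0
    sigma_e2: float = 3.0
    mu: float = 0.0
    trait_catalog: tuple[str, ...] = DEFAULT_TRAITS
    trait_directions: dict | None = None
    elite_mean_shift: float = 0.0  # trait units, toward the favorable direction
    recombination_rate: float = 1.0  # expected crossovers / chromosome / meiosis
    x_par_snps: int = 0  # pseudo-autosomal prefix length on X (recombining)
    seed: int = 0

    def directions(self) -> dict[str, str]:
        d = default_trait_directions()
        d.update({t: "high" for t in self.trait_catalog if t not in d})
        if self.trait_directions:
            d.update(self.trait_directions)
        return d

    def chromosome_map(self) -> dict[str, int]:
        """Chromosome label -> SNP count, X last."""
        if self.n_snps_per_chromosome is not None:
            return {str(k): int(v) for k, v in self.n_snps_per_chromosome.items()}
        n_chrom = self.n_autosomes + (1 if self.include_x else 0)
        per = self.n_snps_total // n_chrom
        counts = {str(c): per for c in range(1, self.n_autosomes + 1)}
        if self.include_x:
            counts["X"] = self.n_snps_total - per * self.n_autosomes
        else:
            counts[str(self.n_autosomes)] += self.n_snps_total - per * n_chrom
        return counts

    def validate(self) -> None:
        if not (0 < self.elite_family_size <= self.n_individuals):
            raise ValueError("elite_family_size must be in (0, n_individuals]")
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_sires:
                raise ValueError("family_sizes length must equal n_sires")
            if sum(self.family_sizes) != self.n_individuals:
                raise ValueError("family sizes do not sum to n_individuals")
            if min(self.family_sizes) < 1:
                raise ValueError("family sizes must be >= 1")
            if self.family_sizes[0] != self.elite_family_size:
                raise ValueError("family_sizes[0] must equal elite_family_size")
        elif self.n_individuals - self.elite_family_size < self.n_sires - 1:
            raise ValueError("too many sires for the non-elite individuals")
        if self.sigma_f2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        m = sum(self.chromosome_map().values())
        for pl in self.planted_loci:
            if not (0 <= pl.snp_index < m):
                raise ValueError(f"planted locus index {pl.snp_index} out of range")
            if not (0 < pl.elite_freq < 1 and 0 < pl.average_freq < 1):
                raise ValueError("planted frequencies must lie in (0, 1)")
            for t in pl.traits:
                if t not in self.trait_catalog:
                    raise ValueError(f"planted locus trait {t!r} not in trait_catalog")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_loci" in raw:
            raw["planted_loci"] = tuple(
                PlantedLocus(**{**p, "traits": tuple(p.get("traits", ()))})
                for p in raw["planted_loci"])
        for key in ("family_sizes", "trait_catalog"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    families: FamilyStructure
    phenotypes: PhenotypeTable
    truth: pd.DataFrame  # planted loci with realized cluster frequencies
    sire_haplotypes: dict  # "autosomes": (n_sires, 2, m_auto); "X": (n_sires, m_x)
    elite_sire: str
    config: SimulationConfig

    @property
    def elite_ids(self) -> list[str]:
        return list(self.families.family_blocks[self.elite_sire])

    @property
    def average_ids(self) -> list[str]:
        elite = set(self.elite_ids)
        return [i for i in self.genotypes.individual_ids if i not in elite]


def _family_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Elite family first, remaining individuals split among the other sires.

    Non-elite sizes are drawn from a geometric distribution (half-sib family
    sizes are strongly right-skewed in AI-bred cattle) and adjusted to sum
    exactly, never below 1.
    """
    if cfg.family_sizes is not None:
        return np.asarray(cfg.family_sizes, dtype=np.int64)
    rest_n = cfg.n_individuals - cfg.elite_family_size
    k = cfg.n_sires - 1
    if k == 0:
        return np.array([cfg.elite_family_size], dtype=np.int64)
    mean = rest_n / k
    sizes = rng.geometric(min(1.0, 1.0 / mean), size=k).astype(np.int64)
    # repair the sum while keeping each size >= 1
    diff = rest_n - int(sizes.sum())
    while diff != 0:
        i = int(rng.integers(k))
        if diff > 0:
            sizes[i] += 1
            diff -= 1
        elif sizes[i] > 1:
            sizes[i] -= 1
            diff += 1
    return np.concatenate([[cfg.elite_family_size], sizes])


def _recombine(hap_pair: np.ndarray, n_daughters: int, rate: float,
               rng: np.random.Generator) -> np.ndarray:
    """Paternal gametes for one chromosome: (n_daughters, m) from a (2, m) pair.

    Crossover count is Poisson(rate); breakpoints uniform on the SNP index
    range; the starting haplotype is a fair coin.
    """
    m = hap_pair.shape[1]
    out = np.empty((n_daughters, m), dtype=np.int8)
    for d in range(n_daughters):
        k = rng.poisson(rate)
        src = int(rng.integers(2))
        if k == 0 or m == 1:
            out[d] = hap_pair[src]
            continue
        cuts = np.sort(rng.integers(1, m, size=k))
        source = np.full(m, src, dtype=np.int8)
        for c in cuts:
            source[c:] = 1 - source[c:]
        out[d] = hap_pair[source, np.arange(m)]
    return out


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Generate a half-sib population; see module docstring for the model."""
    config.validate()
    rng = np.random.default_rng((config.seed, 0))

    chrom_map = config.chromosome_map()
    chroms = list(chrom_map)
    m = sum(chrom_map.values())
    chrom_arr = np.concatenate([np.full(c, lab, dtype=object)
                                for lab, c in chrom_map.items()]).astype(str)
    # within-chromosome positions: 50 kb spacing, 1-based
    pos = np.concatenate([1 + 50_000 * np.arange(c, dtype=np.int64)
                          for c in chrom_map.values()])
    x_mask = chrom_arr == "X"

    a, b = config.base_freq_beta
    lo, hi = config.freq_clip
    base = np.clip(rng.beta(a, b, size=m), lo, hi)

    average_freq = base.copy()
    elite_freq = base.copy()
    if config.elite_divergence_frac > 0 and config.elite_divergence_gap > 0:
        n_div = int(round(config.elite_divergence_frac * m))
        div_idx = rng.choice(m, size=n_div, replace=False)
        gap = config.elite_divergence_gap
        up = base[div_idx] + gap <= 0.99
        shifted = np.where(up, base[div_idx] + gap, base[div_idx] - gap)
        elite_freq[div_idx] = np.clip(shifted, 0.01, 0.99)
    for pl in config.planted_loci:
        elite_freq[pl.snp_index] = pl.elite_freq
        average_freq[pl.snp_index] = pl.average_freq

    # allele letters: two distinct letters per SNP, allele 1 alphabetically first
    pairs = np.stack([rng.permutation(4)[:2] for _ in range(m)])
    pairs.sort(axis=1)
    alleles = _LETTERS[pairs]

    sizes = _family_sizes(config, rng)
    n_sires = len(sizes)
    sire_ids = [f"S{i + 1:04d}" for i in range(n_sires)]
    elite_sire = sire_ids[0]

    # sire haplotypes: elite sire from elite frequencies, others from average
    sire_freq = np.tile(average_freq, (n_sires, 1))
    sire_freq[0] = elite_freq
    auto_idx = np.flatnonzero(~x_mask)
    x_idx = np.flatnonzero(x_mask)
    sire_auto = (rng.random((n_sires, 2, auto_idx.size))
                 < sire_freq[:, None, auto_idx]).astype(np.int8)
    sire_x = (rng.random((n_sires, x_idx.size))
              < sire_freq[:, x_idx]).astype(np.int8)

    n = config.n_individuals
    individual_ids = [f"C{i + 1:05d}" for i in range(n)]
    sire_of: dict[str, str] = {}
    paternal = np.empty((n, m), dtype=np.int8)

    # autosomal index offsets (within auto_idx ordering = genome order minus X)
    auto_offsets = []
    off_a = 0
    for lab in chroms:
        if lab != "X":
            c = chrom_map[lab]
            auto_offsets.append((off_a, off_a + c))
            off_a += c

    row = 0
    for s in range(n_sires):
        fam_n = int(sizes[s])
        ids = individual_ids[row:row + fam_n]
        for ind in ids:
            sire_of[ind] = sire_ids[s]
        gam_auto = np.empty((fam_n, auto_idx.size), dtype=np.int8)
        for lo_a, hi_a in auto_offsets:
            gam_auto[:, lo_a:hi_a] = _recombine(
                sire_auto[s][:, lo_a:hi_a], fam_n,
                config.recombination_rate, rng)
        paternal[row:row + fam_n][:, auto_idx] = gam_auto
        if x_idx.size:
            # whole sire X transmitted intact outside the pseudo-autosomal prefix
            xh = np.tile(sire_x[s], (fam_n, 1))
            par = min(config.x_par_snps, x_idx.size)
            if par:
                freqs = elite_freq if s == 0 else average_freq
                xh[:, :par] = (rng.random((fam_n, par))
                               < freqs[x_idx[:par]]).astype(np.int8)
            paternal[row:row + fam_n][:, x_idx] = xh
        row += fam_n

    elite_n = int(sizes[0])
    # planted loci plant CLUSTER frequencies: the elite family's paternal
    # allele there is an independent draw at the elite frequency, bypassing
    # the single sire's two haplotypes (whose sampling noise would otherwise
    # dominate the realized cluster frequency)
    planted_idx = np.array([pl.snp_index for pl in config.planted_loci],
                           dtype=np.int64)
    if planted_idx.size:
        paternal[np.ix_(np.arange(elite_n), planted_idx)] = (
            rng.random((elite_n, planted_idx.size))
            < elite_freq[planted_idx]).astype(np.int8)

    # maternal gametes: unrelated dams; elite-family dams from elite frequencies
    maternal = np.empty((n, m), dtype=np.int8)
    maternal[:elite_n] = (rng.random((elite_n, m)) < elite_freq).astype(np.int8)
    maternal[elite_n:] = (rng.random((n - elite_n, m)) < average_freq).astype(np.int8)

    dosage = (paternal + maternal).astype(np.int8)
    g = GenotypeMatrix(individual_ids, [f"SNP{j + 1:06d}" for j in range(m)],
                       chrom_arr, pos, alleles, dosage)
    blocks: dict[str, list[str]] = {}
    row = 0
    for s in range(n_sires):
        blocks[sire_ids[s]] = individual_ids[row:row + int(sizes[s])]
        row += int(sizes[s])
    families = FamilyStructure(sire_of, blocks)

    truth = _truth_table(g, config, elite_n)

    pop = SimulatedPopulation(
        genotypes=g, families=families,
        phenotypes=None,  # type: ignore[arg-type]
        truth=truth,
        sire_haplotypes={"autosomes": sire_auto, "X": sire_x,
                         "autosome_index": auto_idx, "x_index": x_idx},
        elite_sire=elite_sire, config=config)
    pop.phenotypes = simulate_phenotypes(pop, config)
    return pop


def _truth_table(g: GenotypeMatrix, config: SimulationConfig,
                 elite_n: int) -> pd.DataFrame:
    rows = []
    for pl in config.planted_loci:
        j = pl.snp_index
        d_e = g.dosage[:elite_n, j]
        d_a = g.dosage[elite_n:, j]
        rows.append({
            "snp_id": g.snp_ids[j], "snp_index": j,
            "chromosome": g.chromosome[j], "position": int(g.position[j]),
            "elite_freq_target": pl.elite_freq,
            "average_freq_target": pl.average_freq,
            "elite_freq_realized": float(d_e.mean() / 2) if d_e.size else np.nan,
            "average_freq_realized": float(d_a.mean() / 2) if d_a.size else np.nan,
            "effect": pl.effect,
            "traits": ",".join(pl.traits),
        })
    return pd.DataFrame(rows, columns=[
        "snp_id", "snp_index", "chromosome", "position",
        "elite_freq_target", "average_freq_target",
        "elite_freq_realized", "average_freq_realized", "effect", "traits"])


def simulate_phenotypes(pop: SimulatedPopulation,
                        config: SimulationConfig | None = None) -> PhenotypeTable:
    """PTA-like phenotypes: y = mu + sum(dosage x effect) + family + residual.

    Per trait, each cow's value is the population mean plus the planted
    additive SNP effects (sign flipped for low-favorable traits so planted
    allele 1 is favorable), a Gaussian family effect shared by all daughters
    of one sire (variance ``sigma_f2``), an optional favorable-direction mean
    shift for the elite family, and Gaussian residual noise (``sigma_e2``).
    """
    cfg = config or pop.config
    rng = np.random.default_rng((cfg.seed, 1))
    g = pop.genotypes
    fam_codes = pop.families.codes_for(g.individual_ids)
    n_fam = len(pop.families.family_blocks)
    n = g.n_individuals
    directions = cfg.directions()
    elite_mask = np.array([pop.families.sire_of[i] == pop.elite_sire
                           for i in g.individual_ids])

    values = {}
    for trait in cfg.trait_catalog:
        if trait not in directions:
            raise ValueError(f"trait {trait!r} has no direction flag")
        sign = 1.0 if directions[trait] == "high" else -1.0
        y = np.full(n, cfg.mu, dtype=float)
        for pl in cfg.planted_loci:
            if trait in pl.traits and pl.effect != 0.0:
                d = g.dosage[:, pl.snp_index].astype(float)
                d[d == -1] = np.nan
                y += sign * pl.effect * np.nan_to_num(d)
        fam_eff = rng.normal(0.0, np.sqrt(cfg.sigma_f2), size=n_fam)
        y += fam_eff[fam_codes]
        y += sign * cfg.elite_mean_shift * elite_mask
        y += rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=n)
        values[trait] = y
    df = pd.DataFrame(values, index=pd.Index(g.individual_ids,
                                             name="individual_id"))
    return PhenotypeTable(df, directions)


def null_config(n_families: int = 100, family_size: int = 10,
                n_snps: int = 2000, sigma_f2: float = 1.0,
                sigma_e2: float = 3.0, seed: int = 0,
                traits: tuple[str, ...] = ("MY",)) -> SimulationConfig:
    """A no-stratification, no-effect intraclass population (null model).

    Equal-size families, no elite divergence, no planted loci: every SNP is a
    pure null marker under compound-symmetry phenotype covariance.
    """
    return SimulationConfig(
        n_individuals=n_families * family_size, n_sires=n_families,
        elite_family_size=family_size,
        family_sizes=tuple([family_size] * n_families),
        n_snps_per_chromosome={"1": n_snps}, n_autosomes=1, include_x=False,
        elite_divergence_frac=0.0, elite_divergence_gap=0.0,
        sigma_f2=sigma_f2, sigma_e2=sigma_e2,
        trait_catalog=traits, seed=seed)


def confounded_config(n_individuals: int = 600, n_sires: int = 56,
                      elite_family_size: int = 100, n_snps: int = 800,
                      n_planted: int = 20, planted_effect: float = 0.0,
                      elite_mean_shift: float = 2.0, seed: int = 0,
                      n_autosomes: int = 1, include_x: bool = False,
                      traits: tuple[str, ...] = ("MY",)) -> SimulationConfig:
    """An elite-confounded population: diverged elite cluster + shifted phenotype.

    The elite family's sampling frequencies differ from the average cluster by
    0.4 at half the SNPs, `n_planted` loci are planted with a 0.85/0.15
    elite/average frequency split (gap 0.7), and the elite family's phenotype
    mean is shifted by ``elite_mean_shift`` trait units (default 2.0 = one
    phenotypic SD at the default variance components).  With
    ``planted_effect=0`` every SNP is a true null, so uncorrected association
    tests are confounded purely by stratification.
    """
    chrom_map = {str(c + 1): n_snps // (n_autosomes + (1 if include_x else 0))
                 for c in range(n_autosomes)}
    if include_x:
        chrom_map["X"] = n_snps - sum(chrom_map.values())
    m = sum(chrom_map.values())
    step = max(1, m // max(n_planted, 1))
    planted = tuple(PlantedLocus(snp_index=j * step + step // 2,
                                 elite_freq=0.85, average_freq=0.15,
                                 effect=planted_effect, traits=traits)
                    for j in range(n_planted))
    return SimulationConfig(
        n_individuals=n_individuals, n_sires=n_sires,
        elite_family_size=elite_family_size,
        n_snps_per_chromosome=chrom_map, n_autosomes=n_autosomes,
        include_x=include_x, planted_loci=planted,
        elite_divergence_frac=0.5, elite_divergence_gap=0.4,
        elite_mean_shift=elite_mean_shift, trait_catalog=traits, seed=seed)


def two_cluster_config(n_individuals: int = 600, elite_size: int = 200,
                       n_snps: int = 2000, elite_mean_shift: float = 2.0,
                       seed: int = 0) -> SimulationConfig:
    """Two homogeneous subpopulations with a 0.4 frequency gap at half the SNPs.

    No family covariance (``sigma_f2=0``): the only structure is the cluster
    split (frequency gap 0.4 at half the SNPs) and the cluster phenotype mean
    shift, the canonical scenario for checking that principal-component
    correction restores type-I calibration that plain least squares loses.
    """
    return SimulationConfig(
        n_individuals=n_individuals, n_sires=1 + (n_individuals - elite_size),
        elite_family_size=elite_size,
        family_sizes=tuple([elite_size] + [1] * (n_individuals - elite_size)),
        n_snps_per_chromosome={"1": n_snps}, n_autosomes=1, include_x=False,
        elite_divergence_frac=0.5, elite_divergence_gap=0.4,
        sigma_f2=0.0, sigma_e2=4.0, elite_mean_shift=elite_mean_shift,
        trait_catalog=("MY",), seed=seed)


def simulate_polygenic_trait(g, h2: float = 0.5, seed: int = 0) -> np.ndarray:
    """A polygenic phenotype from the genotypes themselves at heritability h2.

    Every polymorphic SNP gets an effect on the standardized dosage scale,
    drawn i.i.d. normal; the genetic values are rescaled to variance h2 and
    Gaussian noise of variance 1 - h2 is added.
    """
    from .ls_pca import standardized_dosage
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    rng = np.random.default_rng((seed, 2))
    z = standardized_dosage(g)
    w = rng.normal(size=z.shape[1]) / np.sqrt(z.shape[1])
    gval = z @ w
    gval *= np.sqrt(h2) / gval.std()
    return gval + rng.normal(0.0, np.sqrt(1.0 - h2), size=gval.size)


def mds_config(seed: int = 0) -> SimulationConfig:
    """Scaled stratification scenario for per-chromosome MDS analysis.

    600 cows (a 60-daughter elite family among 121 sires, non-elite mean
    family size ~4.5), 10 autosomes and X at 80 SNPs each, no planted
    divergence: the elite cluster's separation comes from half-sib
    relatedness alone, and the X chromosome's shared sire haplotype roughly
    doubles the within-family X similarity relative to any recombining
    autosome.
    """
    return SimulationConfig(
        n_individuals=600, n_sires=121, elite_family_size=60,
        n_snps_per_chromosome={str(c): 80 for c in range(1, 11)} | {"X": 80},
        n_autosomes=10, include_x=True,
        trait_catalog=("MY",), seed=seed)


def study_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The full emulated study population (1,654 cows / 355 sires / 45,878 SNPs)."""
    return replace(SimulationConfig(seed=seed), **overrides)
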