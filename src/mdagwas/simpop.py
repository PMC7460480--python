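"""Forward-in-time simulator of a pedigreed livestock population.

The simulated design mirrors a QMSim-style two-phase protocol: a long
historical phase of discrete random-mating generations builds up
mutation-drift-recombination equilibrium LD, after which a short pedigreed
phase (a sire/dam breeding scheme with replacement and positive assortative
mating) produces the genotyped cohort.  Phenotypes are the sum of a QTL
genetic score, a pedigree polygenic effect and a normal residual, calibrated
so that the QTL score explains ``h2_qtl`` and total genetic effects
``h2_total`` of the phenotypic variance.

Loci live on equal-length autosomes with one genetic Morgan per chromosome.
Meiosis is modelled as a Markov walk along each chromosome: the transmitted
haplotype switches between the two parental haplotypes independently in each
inter-locus interval with probability equal to the interval's genetic length
(no interference), and the phase at the start of every chromosome is random.
Recurrent two-way mutation flips an allele with probability ``mutation_rate``
per meiosis per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulationError",
    "DegenerateSimulationError",
    "scaled_config",
    "place_loci",
    "simulate_historical",
    "simulate_recent",
    "assign_effects",
    "compute_phenotypes",
    "subsample",
    "simulate_dataset",
    "FounderPool",
    "Population",
    "Dataset",
]


class SimulationError(ValueError):
    """Invalid simulation configuration or state."""


class DegenerateSimulationError(SimulationError):
    """The realized population cannot support the requested calibration."""


@dataclass
class SimConfig:
    """Parameters of the simulated population.

    Defaults reproduce the full-scale study design: a 29-autosome bovine
    genome with 56,996 evenly spaced SNPs and 203 random QTLs, 1000
    historical generations, and a 100-sire / 4000-dam breeding scheme whose
    last three generations (12,000 animals) are genotyped.
    """

    n_chromosomes: int = 29
    n_snps: int = 56_996
    n_qtls: int = 203
    chrom_length_bp: int = 100_000_000
    morgans_per_chrom: float = 1.0
    mutation_rate: float = 2.5e-5
    n_hist_generations: int = 1000
    hist_pop_size: int = 1000
    n_sires: int = 100
    n_dams: int = 4000
    n_recent_generations: int = 10
    n_genotyped_generations: int = 3
    sire_replacement: float = 0.2
    dam_replacement: float = 0.3
    male_proportion: float = 0.5
    var_phenotypic: float = 1.0
    h2_total: float = 0.5
    h2_qtl: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.h2_qtl <= self.h2_total <= 1.0):
            raise SimulationError(
                f"need 0 <= h2_qtl <= h2_total <= 1, got h2_qtl={self.h2_qtl}, "
                f"h2_total={self.h2_total}"
            )
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_hist_generations",
            "hist_pop_size",
            "n_sires",
            "n_dams",
            "n_recent_generations",
            "n_genotyped_generations",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.n_snps < 0 or self.n_qtls < 0:
            raise SimulationError("locus counts must be non-negative")
        if self.n_genotyped_generations > self.n_recent_generations:
            raise SimulationError(
                "n_genotyped_generations cannot exceed n_recent_generations"
            )
        if self.n_snps + self.n_qtls > self.n_chromosomes * self.chrom_length_bp:
            raise SimulationError("more loci than representable positions")
        for name in ("sire_replacement", "dam_replacement", "male_proportion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent generator for a pipeline stage, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


def scaled_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale study conditions: a 5,000-SNP / 50-QTL genome on 29
    autosomes and a 17-sire / 667-dam scheme (the full design's 1:40 mating
    ratio) whose last three generations give 2,001 genotyped animals.

    The genetic map is shrunk with the marker count (0.3 Morgan per
    chromosome at Ne=300 against 1 Morgan at Ne=1000 for the full panel) so
    that 4*Ne*c per marker interval — hence the LD between adjacent markers
    and between QTLs and their flanking SNPs — matches the full design.
    """
    cfg = SimConfig(
        n_snps=5000,
        n_qtls=50,
        morgans_per_chrom=0.3,
        n_hist_generations=100,
        hist_pop_size=300,
        n_sires=17,
        n_dams=667,
        n_recent_generations=5,
        n_genotyped_generations=3,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# locus map


def place_loci(config: SimConfig) -> pd.DataFrame:
    """Locus map: evenly spaced SNPs plus uniform-random QTLs.

    Returns a DataFrame with columns ``chrom`` (1-based int), ``bp``
    (1-based position) and ``role`` ("SNP" or "QTL"), sorted by (chrom, bp).
    SNPs left over when ``n_snps`` is not divisible by ``n_chromosomes`` are
    spread one per chromosome starting from chromosome 1.
    """
    config.validate()
    rng = config.rng(11)
    n_chr = config.n_chromosomes
    base, extra = divmod(config.n_snps, n_chr)
    chroms, bps, roles = [], [], []
    taken: set[tuple[int, int]] = set()
    for c in range(1, n_chr + 1):
        k = base + (1 if c <= extra else 0)
        if k > config.chrom_length_bp:
            raise SimulationError(f"chromosome {c}: {k} SNPs exceed positions")
        if k:
            spacing = config.chrom_length_bp / (k + 1)
            pos = np.maximum(1, np.round(spacing * np.arange(1, k + 1))).astype(np.int64)
            # even spacing can collide only if spacing < 1, excluded above
            chroms.extend([c] * k)
            bps.extend(pos.tolist())
            roles.extend(["SNP"] * k)
            taken.update((c, int(p)) for p in pos)
    placed = 0
    while placed < config.n_qtls:
        c = int(rng.integers(1, n_chr + 1))
        p = int(rng.integers(1, config.chrom_length_bp + 1))
        if (c, p) in taken:
            continue
        taken.add((c, p))
        chroms.append(c)
        bps.append(p)
        roles.append("QTL")
        placed += 1
    loci = pd.DataFrame({"chrom": chroms, "bp": bps, "role": roles})
    loci = loci.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)
    return loci


def _switch_probabilities(loci: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-locus probability that meiosis switches parental haplotype in the
    interval ending at that locus.  Chromosome starts get 0.5 (random phase)."""
    bp = loci["bp"].to_numpy(np.float64)
    chrom = loci["chrom"].to_numpy()
    d = np.empty(len(loci))
    d[0] = 0.5
    same = chrom[1:] == chrom[:-1]
    morgans = (bp[1:] - bp[:-1]) / config.chrom_length_bp * config.morgans_per_chrom
    d[1:] = np.where(same, np.minimum(morgans, 0.5), 0.5)
    return d


@dataclass
class FounderPool:
    """Final historical generation: phased genotypes ready for breeding."""

    haplotypes: np.ndarray  # (n, 2, L) uint8 allele states
    loci: pd.DataFrame
    config: SimConfig

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1, dtype=np.int8)


def _make_gametes(
    parent_haps: np.ndarray,
    switch_p: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant, mutated gamete per parent row of ``parent_haps``."""
    m, _, L = parent_haps.shape
    switches = rng.random((m, L)) < switch_p
    pick = np.cumsum(switches, axis=1, dtype=np.int64) & 1
    gam = np.where(pick == 0, parent_haps[:, 0, :], parent_haps[:, 1, :]).astype(np.uint8)
    if mu > 0:
        n_mut = rng.binomial(m * L, mu)
        if n_mut:
            idx = rng.integers(0, m * L, size=n_mut)
            gam.reshape(-1)[idx] ^= 1
    return gam


def _random_mating_generation(
    haps: np.ndarray,
    n_offspring: int,
    switch_p: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = haps.shape[0]
    pa = rng.integers(0, n, n_offspring)
    pb = rng.integers(0, n, n_offspring)
    clash = pa == pb  # avoid selfing
    while clash.any():
        pb[clash] = rng.integers(0, n, int(clash.sum()))
        clash = pa == pb
    g1 = _make_gametes(haps[pa], switch_p, mu, rng)
    g2 = _make_gametes(haps[pb], switch_p, mu, rng)
    return np.stack([g1, g2], axis=1)


def simulate_historical(
    config: SimConfig,
    loci: Optional[pd.DataFrame] = None,
    founder_frequency: float = 0.5,
) -> FounderPool:
    """Evolve ``hist_pop_size`` diploids for ``n_hist_generations`` of
    discrete random mating with recombination and two-way recurrent mutation.

    Founder haplotypes start with allele frequency ``founder_frequency`` at
    every locus (0.5, the usual forward-simulation initial state, by
    default); drift then prunes variation while mutation restores it.
    Monomorphic loci are permitted.
    """
    config.validate()
    if loci is None:
        loci = place_loci(config)
    rng = config.rng(23)
    L = len(loci)
    switch_p = _switch_probabilities(loci, config)
    n = config.hist_pop_size
    if n < 2:
        raise SimulationError("historical population needs at least 2 individuals")
    if founder_frequency == 0.0:
        haps = np.zeros((n, 2, L), dtype=np.uint8)
    else:
        haps = (rng.random((n, 2, L)) < founder_frequency).astype(np.uint8)
    for _ in range(config.n_hist_generations):
        haps = _random_mating_generation(haps, n, switch_p, config.mutation_rate, rng)
    return FounderPool(haplotypes=haps, loci=loci, config=config)


# ---------------------------------------------------------------------------
# recent pedigreed phase


class _PolygenicBackground:
    """Genome-realized infinitesimal background.

    The polygenic effect is the sum of a tiny normal effect at every SNP
    locus, scaled so founders have variance ``var_pg``.  This has the same
    first two moments as the classical pedigree polygenic model (offspring
    value = parent average + Mendelian-sampling deviate of half the founder
    variance) but the Mendelian sampling is realized by meiosis on the
    simulated genome, so relationship matrices computed from markers capture
    the polygenic variance instead of mistaking its within-family part for
    residual noise.
    """

    def __init__(self, loci: pd.DataFrame, var_pg: float, founder_haps: np.ndarray,
                 rng: np.random.Generator):
        self.snp_cols = np.flatnonzero((loci["role"] == "SNP").to_numpy())
        self.u = rng.standard_normal(len(self.snp_cols))
        self.scale = 0.0
        if var_pg > 0 and len(self.snp_cols):
            raw = self._raw(founder_haps)
            v = raw.var(ddof=1) if len(raw) > 1 else 0.0
            if v > 0:
                self.scale = float(np.sqrt(var_pg / v))

    def _raw(self, haps: np.ndarray) -> np.ndarray:
        G = haps[:, :, self.snp_cols].sum(axis=1).astype(np.float64)
        return G @ self.u

    def values(self, haps: np.ndarray) -> np.ndarray:
        if self.scale == 0.0 or not len(self.snp_cols):
            return np.zeros(haps.shape[0])
        return self._raw(haps) * self.scale


@dataclass
class Population:
    """Pedigreed population with phased genotypes for every animal.

    ``pedigree`` columns: id, sire, dam (0 = founder), sex ("M"/"F"),
    generation (0 = breeding founders), genotyped flag, polygenic value and —
    once :func:`compute_phenotypes` has run — phenotype and true breeding
    value.  Row *i* of ``haplotypes`` belongs to pedigree row *i*.
    """

    pedigree: pd.DataFrame
    haplotypes: np.ndarray  # (n, 2, L)
    loci: pd.DataFrame
    config: SimConfig
    qtl_effects: Optional[np.ndarray] = None

    def genotypes(self, rows: Optional[np.ndarray] = None) -> np.ndarray:
        haps = self.haplotypes if rows is None else self.haplotypes[rows]
        return haps.sum(axis=1, dtype=np.int8)

    @property
    def genotyped_rows(self) -> np.ndarray:
        return np.flatnonzero(self.pedigree["genotyped"].to_numpy())


def simulate_recent(founders: FounderPool, config: SimConfig) -> Population:
    """Breed ``n_recent_generations`` of pedigreed offspring.

    Each generation every dam produces one offspring.  Replacement sires and
    dams are drawn at random from the newest male/female offspring; mating is
    positive assortative — the selected sires and dams are each ranked by
    their (provisional) phenotype and paired rank against rank.  The final
    ``n_genotyped_generations`` are flagged genotyped.
    """
    config.validate()
    rng = config.rng(37)
    need = config.n_sires + config.n_dams
    haps = founders.haplotypes
    if haps.shape[0] == 0:
        raise SimulationError("empty founder pool")
    switch_p = _switch_probabilities(founders.loci, config)
    if haps.shape[0] < need:
        # expand the last historical generation by one random-mating round so
        # the breeding scheme can be seeded (QMSim-style expansion)
        haps = _random_mating_generation(haps, need, switch_p, config.mutation_rate, rng)

    var_pg = (config.h2_total - config.h2_qtl) * config.var_phenotypic
    var_noise = max(config.var_phenotypic - var_pg, 0.0)

    founder_rows = rng.permutation(haps.shape[0])[:need]
    all_haps = [haps[founder_rows]]
    n_founders = need

    ids = np.arange(1, n_founders + 1)
    sex = np.array(["M"] * config.n_sires + ["F"] * config.n_dams)
    background = _PolygenicBackground(founders.loci, var_pg, haps[founder_rows], rng)
    polygenic = background.values(haps[founder_rows])
    mating_phen = polygenic + rng.normal(0.0, np.sqrt(var_noise), n_founders)

    ped = {
        "id": [ids],
        "sire": [np.zeros(n_founders, dtype=np.int64)],
        "dam": [np.zeros(n_founders, dtype=np.int64)],
        "sex": [sex],
        "generation": [np.zeros(n_founders, dtype=np.int64)],
        "polygenic": [polygenic],
        "mating_phen": [mating_phen],
    }

    # working state: row indices into the concatenated haplotype store
    sire_rows = np.arange(config.n_sires)
    dam_rows = np.arange(config.n_sires, n_founders)
    row_id = dict(zip(range(n_founders), ids))
    row_pg = dict(zip(range(n_founders), polygenic))
    row_mp = dict(zip(range(n_founders), mating_phen))
    next_id = n_founders + 1
    next_row = n_founders
    store = np.concatenate(all_haps, axis=0)

    def rows_arr(rows):
        return store[rows]

    for gen in range(1, config.n_recent_generations + 1):
        # assortative pairing: rank sires and dams by provisional phenotype
        s_sorted = sire_rows[np.argsort([row_mp[r] for r in sire_rows], kind="stable")]
        d_sorted = dam_rows[np.argsort([row_mp[r] for r in dam_rows], kind="stable")]
        n_d, n_s = len(d_sorted), len(s_sorted)
        sire_for_dam = s_sorted[(np.arange(n_d) * n_s) // n_d]

        g_s = _make_gametes(rows_arr(sire_for_dam), switch_p, config.mutation_rate, rng)
        g_d = _make_gametes(rows_arr(d_sorted), switch_p, config.mutation_rate, rng)
        off_haps = np.stack([g_s, g_d], axis=1)
        store = np.concatenate([store, off_haps], axis=0)

        off_pg = background.values(off_haps)
        off_mp = off_pg + rng.normal(0.0, np.sqrt(var_noise), n_d)
        off_sex = np.where(rng.random(n_d) < config.male_proportion, "M", "F")
        off_ids = np.arange(next_id, next_id + n_d)
        off_rows = np.arange(next_row, next_row + n_d)

        ped["id"].append(off_ids)
        ped["sire"].append(np.array([row_id[r] for r in sire_for_dam]))
        ped["dam"].append(np.array([row_id[r] for r in d_sorted]))
        ped["sex"].append(off_sex)
        ped["generation"].append(np.full(n_d, gen, dtype=np.int64))
        ped["polygenic"].append(off_pg)
        ped["mating_phen"].append(off_mp)

        for r, i, p, m in zip(off_rows, off_ids, off_pg, off_mp):
            row_id[r], row_pg[r], row_mp[r] = i, p, m
        next_id += n_d
        next_row += n_d

        if gen < config.n_recent_generations:
            # random replacement of a fraction of each parent sex
            males = off_rows[off_sex == "M"]
            females = off_rows[off_sex == "F"]
            n_rep_s = min(int(round(config.sire_replacement * n_s)), len(males))
            n_rep_d = min(int(round(config.dam_replacement * n_d)), len(females))
            if n_rep_s:
                out = rng.choice(n_s, n_rep_s, replace=False)
                new = rng.choice(males, n_rep_s, replace=False)
                sire_rows = sire_rows.copy()
                sire_rows[out] = new
            if n_rep_d:
                out = rng.choice(n_d, n_rep_d, replace=False)
                new = rng.choice(females, n_rep_d, replace=False)
                dam_rows = dam_rows.copy()
                dam_rows[out] = new

    pedigree = pd.DataFrame({k: np.concatenate(v) for k, v in ped.items()})
    first_geno = config.n_recent_generations - config.n_genotyped_generations + 1
    pedigree["genotyped"] = pedigree["generation"] >= first_geno
    return Population(
        pedigree=pedigree, haplotypes=store, loci=founders.loci, config=config
    )


# ---------------------------------------------------------------------------
# genetic effects and phenotypes


def assign_effects(pop: Population, config: SimConfig) -> np.ndarray:
    """Draw QTL allele-substitution effects and scale them so the QTL score
    variance among genotyped animals equals ``h2_qtl * var_phenotypic``.

    Raw magnitudes are gamma(shape 0.4) with random sign — a heavy-tailed
    effect-size distribution under which a few QTLs carry most of the
    variance — then rescaled in-sample.
    """
    config.validate()
    rng = config.rng(53)
    qtl_cols = np.flatnonzero((pop.loci["role"] == "QTL").to_numpy())
    eff = rng.gamma(0.4, 1.0, len(qtl_cols)) * rng.choice([-1.0, 1.0], len(qtl_cols))
    if config.h2_qtl == 0:
        pop.qtl_effects = np.zeros(len(qtl_cols))
        return pop.qtl_effects
    rows = pop.genotyped_rows
    if len(rows) == 0:
        raise SimulationError("no genotyped animals to calibrate QTL effects on")
    G = pop.haplotypes[rows][:, :, qtl_cols].sum(axis=1).astype(np.float64)
    score = G @ eff
    v = score.var(ddof=1)
    if v <= 0:
        raise DegenerateSimulationError(
            "all QTLs are monomorphic among genotyped animals; cannot scale effects"
        )
    eff *= np.sqrt(config.h2_qtl * config.var_phenotypic / v)
    pop.qtl_effects = eff
    return eff


def compute_phenotypes(
    pop: Population, effects: np.ndarray, config: SimConfig
) -> Population:
    """Phenotype = QTL score + polygenic value + N(0, (1-h2_total)·var_phen).

    Polygenic values come from the genome-realized infinitesimal background
    sampled during breeding (see :class:`_PolygenicBackground`): founder
    variance (h2_total-h2_qtl)·var_phen, offspring value = parent average +
    a Mendelian-sampling deviate realized by meiosis.  All three components
    are calibrated in-sample among genotyped animals — the same enforced
    scaling the QTL score receives — because with few sire families the
    realized polygenic variance drifts around its nominal value, and the
    nominal variances define the study conditions.
    """
    config.validate()
    rng = config.rng(67)
    qtl_cols = np.flatnonzero((pop.loci["role"] == "QTL").to_numpy())
    G = pop.haplotypes[:, :, qtl_cols].sum(axis=1).astype(np.float64)
    qtl_score = G @ effects
    var_e = (1.0 - config.h2_total) * config.var_phenotypic
    var_pg = (config.h2_total - config.h2_qtl) * config.var_phenotypic
    resid = rng.normal(0.0, np.sqrt(var_e), len(qtl_score))
    pg = pop.pedigree["polygenic"].to_numpy().copy()
    rows = pop.genotyped_rows

    def _calibrate(x, target):
        v = x[rows].var(ddof=1) if len(rows) > 1 else 0.0
        return x * np.sqrt(target / v) if v > 0 and target >= 0 else x

    pg = _calibrate(pg, var_pg)
    resid = _calibrate(resid, var_e)
    pop.pedigree["polygenic"] = pg
    pop.pedigree["qtl_score"] = qtl_score
    pop.pedigree["tbv"] = qtl_score + pg
    pop.pedigree["phenotype"] = qtl_score + pg + resid
    return pop


# ---------------------------------------------------------------------------
# datasets


@dataclass
class Dataset:
    """Analysis-ready view: SNP genotypes, phenotype table and QTL map."""

    genotypes: "object"  # plinkio.GenotypeMatrix
    phenotypes: pd.DataFrame  # id, sex, generation, phenotype
    qtl_map: pd.DataFrame  # chrom, bp, effect


def _to_dataset(pop: Population, rows: np.ndarray) -> Dataset:
    from .plinkio import GenotypeMatrix

    snp_cols = np.flatnonzero((pop.loci["role"] == "SNP").to_numpy())
    qtl_cols = np.flatnonzero((pop.loci["role"] == "QTL").to_numpy())
    geno = pop.haplotypes[rows][:, :, snp_cols].sum(axis=1).astype(np.int8)
    ped = pop.pedigree.iloc[rows]
    iids = ped["id"].astype(str).to_numpy()
    snp_loci = pop.loci.iloc[snp_cols]
    markers = pd.DataFrame(
        {
            "marker": [
                f"snp{c}_{b}" for c, b in zip(snp_loci["chrom"], snp_loci["bp"])
            ],
            "chrom": snp_loci["chrom"].to_numpy(),
            "bp": snp_loci["bp"].to_numpy(),
            "a1": "B",
            "a2": "A",
        }
    )
    gm = GenotypeMatrix(iids=iids, genotypes=geno, markers=markers)
    pheno = ped[["id", "sex", "generation", "phenotype"]].copy()
    pheno["id"] = pheno["id"].astype(str)
    pheno = pheno.reset_index(drop=True)
    if pop.qtl_effects is None:
        raise SimulationError("assign_effects must run before building a dataset")
    qtl_loci = pop.loci.iloc[qtl_cols]
    qtl_map = pd.DataFrame(
        {
            "chrom": qtl_loci["chrom"].to_numpy(),
            "bp": qtl_loci["bp"].to_numpy(),
            "effect": pop.qtl_effects,
        }
    )
    return Dataset(genotypes=gm, phenotypes=pheno, qtl_map=qtl_map)


def subsample(pop: Population, n: int, seed: int) -> Dataset:
    """Uniform random sample (without replacement) of genotyped animals."""
    rows = pop.genotyped_rows
    if n > len(rows):
        raise SimulationError(f"requested {n} animals but only {len(rows)} genotyped")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    chosen = np.sort(rng.choice(rows, size=n, replace=False))
    return _to_dataset(pop, chosen)


def simulate_dataset(config: SimConfig, n: Optional[int] = None) -> Dataset:
    """Run the whole simulation pipeline and return the genotyped cohort
    (or a random ``n``-animal subsample of it)."""
    founders = simulate_historical(config)
    pop = simulate_recent(founders, config)
    effects = assign_effects(pop, config)
    compute_phenotypes(pop, effects, config)
    if n is None:
        return _to_dataset(pop, pop.genotyped_rows)
    return subsample(pop, n, seed=config.seed)
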