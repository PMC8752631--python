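"""Synthetic wild/cultivar cohorts with implanted hard sweeps.

The generator emulates the demography of a recently domesticated, clonally
propagated tree crop: a structured wild metapopulation (several regional
groups exchanging rare migrants) from which a handful of founder trees were
taken, followed by a few sexual generations of seedling evaluation in which
the best individuals were selected as parents, and finally clonal release of
cultivars.  Standing wild variation is initialized with a neutral coalescent
(msprime) at a mutation rate rescaled to desk scale so that theta = 4*N*mu
matches the per-bp diversity observed in such crops (~4e-4); the domestication
generations are then simulated forward with recombination, de novo mutation
and selection at the implanted sweep loci.

Two selection modes are available.  ``truncation`` (default) scores each
seedling as sum_l s_l * dosage_l + N(0, sigma_e^2) and keeps the top
``n_parents`` as parents of the next generation — truncation selection on a
highly heritable trait, which is how orchard selections are actually made and
the only mechanism that can move an allele to sweep frequencies within 2-4
sexual generations.  ``fitness`` uses classical viability weights 1, 1+s/2,
1+s per locus (multiplicative across loci) on parent sampling; with 2-4
generations it produces only mild frequency shifts and is provided for
comparison.

Outputs are a VCF (GT:DP, QUAL populated), a two-column population map, a
GFF3 gene annotation with a single-copy flag, and a machine-readable truth
record of the implanted sweeps; everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .variant_io import GenotypeMatrix

# mutation rate of Nelumbo nucifera, the closest relative with an estimate;
# used for real-data dating, while `mu` below is the desk-scale rescaled rate
LITERAL_MU = 4.175e-9
GENERATION_TIME_YEARS = 8.0

WILD_POP = "wild"
CULT_POP = "cultivar"


@dataclass
class SimConfig:
    """Study conditions for the two-population domestication simulation.

    The defaults are desk-scale: per-deme wild size 200 with mu chosen so
    that theta = 4*N*mu = 4e-4 per bp (the observed per-bp diversity scale),
    three wild demes with migration set for strong regional divergence, six
    founder trees, and three generations of seedling selection.
    """

    n_chrom: int = 5
    chrom_length: int = 1_000_000
    N_wild: int = 200              # diploid size of each wild deme
    n_wild_demes: int = 3
    migration_rate: float = 1.7e-3  # per-generation migrant fraction
    n_founders: int = 6
    N_cult: int = 400              # seedlings raised per generation
    n_parents: int = 25            # selections kept as parents each cycle
    n_generations_dom: int = 4
    # desk-scale rescaling: N is reduced and mu, rrate inflated by the same
    # factor (~40 against mu = 4.175e-9 and 1 cM/Mb), preserving theta and rho.
    # With three demes the metapopulation size is 3*N_wild = 600, so
    # 4 * 600 * mu = 4.2e-4 per bp, the diversity scale seen in such crops.
    mu: float = 1.75e-7            # per bp per generation (rescaled)
    rrate: float = 4e-7            # Morgans per bp (rescaled from 1e-8)
    sweep_loci: tuple[tuple[int, int, float], ...] = ()  # (chrom idx, pos, s)
    selection_mode: str = "truncation"  # or "fitness"
    score_noise_sd: float = 0.5
    # sampled panel sizes follow the resequencing design of such studies:
    # ~40 wild accessions against ~60 cultivars/selected lines
    n_sampled_wild: int = 42
    n_sampled_cult: int = 59
    mean_depth: float = 20.0
    qual_fail_frac: float = 0.0
    missing_frac: float = 0.0
    max_restarts: int = 100
    seed: int = 0
    # gene annotation layout
    genes_per_chrom: int = 40
    gene_length: int = 5_000
    gene_spacing: int = 25_000
    single_copy_frac: float = 0.5
    # real-world metadata carried for reporting; not used at desk scale
    generation_time_years: float = GENERATION_TIME_YEARS
    literal_mu: float = LITERAL_MU

    def __post_init__(self) -> None:
        if self.n_founders > self.N_wild:
            raise ValueError("n_founders cannot exceed N_wild")
        if self.n_generations_dom < 0:
            raise ValueError("n_generations_dom must be >= 0")
        for frac in (self.qual_fail_frac, self.missing_frac,
                     self.single_copy_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for c, pos, s in self.sweep_loci:
            if not 0 <= c < self.n_chrom:
                raise ValueError(f"sweep chromosome index {c} out of range")
            if not 0 <= pos < self.chrom_length:
                raise ValueError(f"sweep position {pos} outside chromosome")
            if s < 0:
                raise ValueError("selection coefficient must be >= 0")
        if self.selection_mode not in ("truncation", "fitness"):
            raise ValueError("selection_mode must be 'truncation' or 'fitness'")
        if self.selection_mode == "truncation" and self.n_parents < 2:
            raise ValueError("need at least 2 parents per generation")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SweepTruth:
    chrom: str
    pos: int  # 0-based
    s: float
    final_freq: float  # beneficial-allele frequency among sampled cultivars
    carrier_hap: int = -1  # founder haplotype seeded with the allele


@dataclass
class SimTruth:
    sweeps: list[SweepTruth]
    founder_ids: list[str]
    seed: int
    n_restarts: int
    initializer: str
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            dict(sweeps=[asdict(s) for s in self.sweeps],
                 founder_ids=self.founder_ids, seed=self.seed,
                 n_restarts=self.n_restarts, initializer=self.initializer,
                 config=self.config),
            indent=2, default=_json_default,
        )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SimResult:
    config: SimConfig
    positions: list[np.ndarray]   # per chromosome, 0-based, sorted
    wild_haps: list[np.ndarray]   # per chromosome, (n_sites, 2*n_sampled_wild)
    cult_haps: list[np.ndarray]   # per chromosome, (n_sites, 2*n_sampled_cult)
    truth: SimTruth

    @property
    def wild_samples(self) -> list[str]:
        return [f"W{i + 1:03d}" for i in range(self.config.n_sampled_wild)]

    @property
    def cult_samples(self) -> list[str]:
        return [f"V{i + 1:03d}" for i in range(self.config.n_sampled_cult)]


class SweepLostError(RuntimeError):
    pass


def _wild_coalescent(config: SimConfig, seed: int):
    """Sampled wild haplotypes plus founder haplotypes from msprime."""
    import msprime

    if config.n_wild_demes > 1:
        demography = msprime.Demography.island_model(
            [config.N_wild] * config.n_wild_demes, config.migration_rate)
        deme_names = [p.name for p in demography.populations]
    else:
        demography = msprime.Demography()
        demography.add_population(name="pop_0", initial_size=config.N_wild)
        deme_names = ["pop_0"]

    # wild sample spread round-robin across demes; founders from deme 0
    wild_per_deme = np.zeros(config.n_wild_demes, dtype=int)
    for i in range(config.n_sampled_wild):
        wild_per_deme[i % config.n_wild_demes] += 1
    samples = [
        msprime.SampleSet(int(nd), population=deme_names[d], ploidy=2)
        for d, nd in enumerate(wild_per_deme) if nd > 0
    ]
    samples.append(msprime.SampleSet(config.n_founders, population=deme_names[0],
                                     ploidy=2))

    rng_seeds = np.random.default_rng(seed).integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=samples, demography=demography,
        sequence_length=config.chrom_length,
        recombination_rate=config.rrate,
        random_seed=int(rng_seeds[0]),
    )
    mts = msprime.sim_mutations(
        ts, rate=config.mu, model=msprime.BinaryMutationModel(),
        discrete_genome=True, random_seed=int(rng_seeds[1]),
    )
    geno = mts.genotype_matrix()  # (n_sites, n_haps) of 0/1
    pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
    keep = np.concatenate([[True], np.diff(pos) > 0])  # drop position clashes
    geno, pos = geno[keep], pos[keep]
    seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < geno.shape[1])
    geno, pos = geno[seg], pos[seg]

    # sample order follows the SampleSet list: wild demes first, founders last
    n_wild_haps = 2 * config.n_sampled_wild
    wild = geno[:, :n_wild_haps].astype(np.int8)
    founders = geno[:, n_wild_haps:].astype(np.int8)
    return pos, wild, founders


def _make_gametes(haps: np.ndarray, pos: np.ndarray, parents: np.ndarray,
                  rng: np.random.Generator, rrate: float, length: int
                  ) -> np.ndarray:
    """One gamete per entry of ``parents`` (individual indices).

    haps has two consecutive rows per individual.  Crossovers are Poisson
    along the chromosome; with desk-scale map lengths most gametes are an
    uncrossed copy of one parental haplotype, which keeps this vectorized.
    """
    n = len(parents)
    phase = rng.integers(0, 2, size=n)
    out = haps[2 * parents + phase]
    n_x = rng.poisson(rrate * length, size=n)
    for g in np.nonzero(n_x)[0]:
        breaks = np.sort(rng.uniform(0, length, size=n_x[g]))
        seg = np.searchsorted(breaks, pos, side="right") % 2
        other = haps[2 * parents[g] + 1 - phase[g]]
        swap = seg == 1
        out[g, swap] = other[swap]
    return out


def _insert_mutations(haps: np.ndarray, pos: np.ndarray, rng: np.random.Generator,
                      mu: float, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Add de novo mutations: new singleton columns at fresh positions."""
    n_haps = haps.shape[0]
    n_new = rng.poisson(mu * length * n_haps)
    if n_new == 0:
        return haps, pos
    existing = set(pos.tolist())
    new_pos = []
    while len(new_pos) < n_new:
        cand = int(rng.integers(0, length))
        if cand not in existing:
            existing.add(cand)
            new_pos.append(cand)
    new_pos = np.array(sorted(new_pos), dtype=np.int64)
    cols = np.zeros((n_haps, len(new_pos)), dtype=np.int8)
    carriers = rng.integers(0, n_haps, size=len(new_pos))
    cols[carriers, np.arange(len(new_pos))] = 1
    all_pos = np.concatenate([pos, new_pos])
    order = np.argsort(all_pos, kind="stable")
    return np.concatenate([haps, cols], axis=1)[:, order], all_pos[order]


def _locus_dosage(haps_by_chrom, pos_by_chrom, loci) -> np.ndarray:
    """Dosage matrix (n_ind, n_loci) of the beneficial alleles."""
    n_ind = haps_by_chrom[0].shape[0] // 2
    dos = np.zeros((n_ind, len(loci)), dtype=float)
    for j, (c, p, _s) in enumerate(loci):
        col = np.searchsorted(pos_by_chrom[c], p)
        site = haps_by_chrom[c][:, col]
        dos[:, j] = site[0::2] + site[1::2]
    return dos


def _choose_parent_pairs(n_pairs: int, weights: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mother/father indices, distinct within each pair, weighted."""
    p = weights / weights.sum()
    mothers = rng.choice(len(weights), size=n_pairs, p=p)
    fathers = rng.choice(len(weights), size=n_pairs, p=p)
    clash = mothers == fathers
    while clash.any():
        fathers[clash] = rng.choice(len(weights), size=int(clash.sum()), p=p)
        clash = mothers == fathers
    return mothers, fathers


def _forward_domestication(config: SimConfig, founder_haps, founder_pos, rng):
    """Forward generations of mating + selection; returns final cohort."""
    haps = [h.copy() for h in founder_haps]
    pos = [p.copy() for p in founder_pos]
    loci = list(config.sweep_loci)

    if config.n_generations_dom == 0:
        return haps, pos

    n_ind = haps[0].shape[0] // 2
    for gen in range(config.n_generations_dom):
        if config.selection_mode == "fitness" and loci:
            dos = _locus_dosage(haps, pos, loci)
            w = np.ones(n_ind)
            for j, (_c, _p, s) in enumerate(loci):
                w *= 1.0 + s * dos[:, j] / 2.0
        else:
            w = np.ones(n_ind)
        mothers, fathers = _choose_parent_pairs(config.N_cult, w, rng)
        next_haps, next_pos = [], []
        for c in range(config.n_chrom):
            gm = _make_gametes(haps[c], pos[c], mothers, rng, config.rrate,
                               config.chrom_length)
            gp = _make_gametes(haps[c], pos[c], fathers, rng, config.rrate,
                               config.chrom_length)
            child = np.empty((2 * config.N_cult, gm.shape[1]), dtype=np.int8)
            child[0::2] = gm
            child[1::2] = gp
            child, cpos = _insert_mutations(child, pos[c], rng, config.mu,
                                            config.chrom_length)
            next_haps.append(child)
            next_pos.append(cpos)
        haps, pos = next_haps, next_pos
        n_ind = config.N_cult

        # the last cohort is the cultivar population itself (sampled below),
        # so truncation selection runs between generations, not after the last
        if config.selection_mode == "truncation" and gen < config.n_generations_dom - 1:
            dos = (_locus_dosage(haps, pos, loci) if loci
                   else np.zeros((n_ind, 0)))
            effects = np.array([s for (_c, _p, s) in loci])
            score = dos @ effects + rng.normal(0.0, config.score_noise_sd,
                                               size=n_ind)
            keep = np.argsort(-score, kind="stable")[:config.n_parents]
            haps = [h.reshape(n_ind, 2, -1)[keep].reshape(2 * len(keep), -1)
                    for h in haps]
            n_ind = config.n_parents
    return haps, pos


def simulate(config: SimConfig) -> SimResult:
    """Run the full two-population simulation; deterministic given the seed.

    The wild metapopulation and the founder haplotypes come from a neutral
    coalescent with the configured demography; beneficial alleles are seeded
    on one founder haplotype each (frequency 1/(2*n_founders)), and the
    domestication generations run forward.  If a beneficial allele is lost,
    the forward stage restarts (up to ``max_restarts``); exhaustion raises
    :class:`SweepLostError` naming the locus.
    """
    rng = np.random.default_rng(config.seed)
    chrom_seeds = rng.integers(1, 2**31 - 1, size=config.n_chrom)

    positions, wild, founders = [], [], []
    for c in range(config.n_chrom):
        pos, w, f = _wild_coalescent(config, int(chrom_seeds[c]))
        if len(pos) == 0:
            raise RuntimeError(
                f"no segregating sites on {config.chrom_names[c]}; "
                "increase mu, chrom_length or N_wild"
            )
        positions.append(pos)
        wild.append(w)
        founders.append(f)

    # seed beneficial alleles: one founder haplotype each, absent in the wild
    # matrices here are (n_sites, n_haplotypes)
    carrier = {}
    for (c, p, s) in config.sweep_loci:
        row = int(np.searchsorted(positions[c], p))
        if row < len(positions[c]) and positions[c][row] == p:
            founders[c][row, :] = 0
            wild[c][row, :] = 0
        else:
            founders[c] = np.insert(founders[c], row, 0, axis=0)
            wild[c] = np.insert(wild[c], row, 0, axis=0)
            positions[c] = np.insert(positions[c], row, p)
        hap = int(rng.integers(0, 2 * config.n_founders))
        founders[c][row, hap] = 1
        carrier[(c, p)] = hap

    founder_haps = [f.T.copy() for f in founders]  # rows = haplotypes

    n_restarts = 0
    while True:
        fwd_rng = np.random.default_rng([config.seed, 1, n_restarts])
        haps, pos = _forward_domestication(config, founder_haps, positions,
                                           fwd_rng)
        lost = None
        for (c, p, s) in config.sweep_loci:
            if s <= 0:
                continue
            col = np.searchsorted(pos[c], p)
            if haps[c][:, col].sum() == 0:
                lost = (c, p)
                break
        if lost is None:
            break
        n_restarts += 1
        if n_restarts > config.max_restarts:
            raise SweepLostError(
                f"beneficial allele at {config.chrom_names[lost[0]]}:"
                f"{lost[1]} lost in all {config.max_restarts} restarts"
            )

    # sample cultivars from the final cohort
    n_final = haps[0].shape[0] // 2
    if config.n_sampled_cult > n_final:
        raise ValueError(
            f"cannot sample {config.n_sampled_cult} cultivars from a final "
            f"population of {n_final}"
        )
    pick = np.sort(fwd_rng.choice(n_final, size=config.n_sampled_cult,
                                  replace=False))
    cult = []
    for c in range(config.n_chrom):
        rows = np.empty(2 * config.n_sampled_cult, dtype=int)
        rows[0::2] = 2 * pick
        rows[1::2] = 2 * pick + 1
        cult.append(haps[c][rows].T.copy())  # back to (n_sites, n_haps)

    # align wild to the cultivar site list (wild is 0 at forward-stage sites)
    out_pos, out_wild, out_cult = [], [], []
    sweeps = []
    for c in range(config.n_chrom):
        base_index = {int(p): i for i, p in enumerate(positions[c])}
        wild_full = np.zeros((len(pos[c]), wild[c].shape[1]), dtype=np.int8)
        for i, p in enumerate(pos[c]):
            j = base_index.get(int(p))
            if j is not None:
                wild_full[i] = wild[c][j]
        out_pos.append(pos[c])
        out_wild.append(wild_full)
        out_cult.append(cult[c])

    for (c, p, s) in config.sweep_loci:
        col = np.searchsorted(out_pos[c], p)
        freq = float(out_cult[c][col].mean())
        sweeps.append(SweepTruth(chrom=config.chrom_names[c], pos=int(p),
                                 s=float(s), final_freq=freq,
                                 carrier_hap=carrier[(c, p)]))

    # keep only sites segregating in the union of the two samples
    for c in range(config.n_chrom):
        total = out_wild[c].sum(axis=1) + out_cult[c].sum(axis=1)
        n_haps = out_wild[c].shape[1] + out_cult[c].shape[1]
        keep = (total > 0) & (total < n_haps)
        for (cc, p, _s) in config.sweep_loci:  # truth sites always kept
            if cc == c:
                keep[np.searchsorted(out_pos[c], p)] = True
        out_pos[c] = out_pos[c][keep]
        out_wild[c] = out_wild[c][keep]
        out_cult[c] = out_cult[c][keep]

    truth = SimTruth(
        sweeps=sweeps,
        founder_ids=[f"F{i + 1:03d}" for i in range(config.n_founders)],
        seed=config.seed, n_restarts=n_restarts,
        initializer="coalescent",
        config=asdict(config),
    )
    return SimResult(config=config, positions=out_pos, wild_haps=out_wild,
                     cult_haps=out_cult, truth=truth)


# ---------------------------------------------------------------------------
# emission: VCF + population map, GFF3, truth files, in-memory matrix
# ---------------------------------------------------------------------------

def genotype_matrix_from_sim(result: SimResult) -> GenotypeMatrix:
    """Assemble the simulated samples into a GenotypeMatrix (no noise model)."""
    cfg = result.config
    samples = result.wild_samples + result.cult_samples
    chroms, poss, haps = [], [], []
    for c, name in enumerate(cfg.chrom_names):
        n_sites = len(result.positions[c])
        if n_sites == 0:
            continue
        both = np.concatenate([result.wild_haps[c], result.cult_haps[c]], axis=1)
        chroms.append(np.full(n_sites, name, dtype=object))
        poss.append(result.positions[c])
        haps.append(both.reshape(n_sites, len(samples), 2))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    h = np.concatenate(haps).astype(np.int8)
    n_sites = len(pos)
    pops = {
        WILD_POP: list(range(cfg.n_sampled_wild)),
        CULT_POP: list(range(cfg.n_sampled_wild,
                             cfg.n_sampled_wild + cfg.n_sampled_cult)),
    }
    return GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, 60.0),
        haps=h,
        dp=np.full((n_sites, len(samples)), int(round(cfg.mean_depth)),
                   dtype=np.int32),
        biallelic=np.ones(n_sites, dtype=bool),
        pops=pops,
    )


def emit_vcf(result: SimResult, vcf_path: str, popmap_path: str) -> None:
    """Write the sampled genotypes as VCFv4.2 plus a population map.

    QUAL is drawn so that ``qual_fail_frac`` of sites fall below 30, per-call
    DP is Poisson around ``mean_depth``, and ``missing_frac`` of calls are
    masked to "./.".  Deterministic given the simulation seed.
    """
    cfg = result.config
    rng = np.random.default_rng([cfg.seed, 2])
    samples = result.wild_samples + result.cult_samples
    n_samples = len(samples)

    lines = [
        "##fileformat=VCFv4.2",
        "##source=sweepscan-simulate",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for name in cfg.chrom_names:
        lines.append(f"##contig=<ID={name},length={cfg.chrom_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))

    for c, name in enumerate(cfg.chrom_names):
        pos = result.positions[c]
        both = np.concatenate([result.wild_haps[c], result.cult_haps[c]], axis=1)
        n_sites = len(pos)
        fail = rng.random(n_sites) < cfg.qual_fail_frac
        qual = np.where(fail, rng.uniform(2.0, 29.9, n_sites),
                        rng.uniform(30.0, 99.0, n_sites))
        dp = rng.poisson(cfg.mean_depth, size=(n_sites, n_samples))
        miss = rng.random((n_sites, n_samples)) < cfg.missing_frac
        for i in range(n_sites):
            gts = []
            for j in range(n_samples):
                if miss[i, j]:
                    gts.append(f"./.:{dp[i, j]}")
                else:
                    gts.append(f"{both[i, 2 * j]}|{both[i, 2 * j + 1]}:{dp[i, j]}")
            lines.append(
                f"{name}\t{pos[i] + 1}\t.\tA\tT\t{qual[i]:.2f}\tPASS\t.\tGT:DP\t"
                + "\t".join(gts)
            )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    with open(popmap_path, "w") as fh:
        for s in result.wild_samples:
            fh.write(f"{s}\t{WILD_POP}\n")
        for s in result.cult_samples:
            fh.write(f"{s}\t{CULT_POP}\n")


def emit_annotation(config: SimConfig, path: str) -> None:
    """Tile non-overlapping genes along each chromosome as GFF3.

    Genes are ``gene_length`` bp every ``gene_spacing`` bp; a Bernoulli
    ``single_copy_frac`` of them carry single_copy=true.  Coordinates are
    1-based inclusive per GFF3.
    """
    rng = np.random.default_rng([config.seed, 3])
    lines = ["##gff-version 3"]
    for name in config.chrom_names:
        lines.append(f"##sequence-region {name} 1 {config.chrom_length}")
    for c, name in enumerate(config.chrom_names):
        n_fit = max(0, (config.chrom_length - config.gene_length)
                    // config.gene_spacing + 1) if config.gene_spacing > 0 else 0
        n_genes = min(config.genes_per_chrom, n_fit)
        flags = rng.random(n_genes) < config.single_copy_frac
        for g in range(n_genes):
            start0 = g * config.gene_spacing
            end0 = start0 + config.gene_length
            gid = f"gene_{name}_{g + 1:04d}"
            sc = "true" if flags[g] else "false"
            lines.append(
                f"{name}\tsweepscan\tgene\t{start0 + 1}\t{end0}\t.\t+\t.\t"
                f"ID={gid};single_copy={sc}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def emit_truth(result: SimResult, bed_path: str, json_path: str) -> None:
    """Truth sweeps as BED (0-based half-open) plus a JSON config snapshot."""
    with open(bed_path, "w") as fh:
        for sw in result.truth.sweeps:
            fh.write(f"{sw.chrom}\t{sw.pos}\t{sw.pos + 1}\t"
                     f"s={sw.s};final_freq={sw.final_freq:.4f}\n")
    with open(json_path, "w") as fh:
        fh.write(result.truth.to_json() + "\n")


def neutral_config(**overrides) -> SimConfig:
    """A convenience neutral (no sweep) configuration."""
    overrides.setdefault("sweep_loci", ())
    return SimConfig(**overrides)
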