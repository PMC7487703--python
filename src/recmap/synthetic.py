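"""Synthetic study generator.

Emulates the structure of a breed cohort segregating a fully penetrant
autosomal-recessive retinal-degeneration locus: a closed multi-generation
pedigree descending from a small founder set, SNP-array genotypes
gene-dropped through the pedigree with recombination, a causal locus that
rides on one ancestral haplotype (creating an LD block around it), disease
labels with a minority of phenocopy cases, a candidate-region variant set
(one mobile-element insertion plus linked SNVs with a couple of recombinant
dogs) typed also in a panel of unrelated control genomes, and read-pair
alignments over the insertion site in which carrier haplotypes produce
interchromosomal mates and soft-clipped reads.

A single master seed drives independent per-stage streams (pedigree,
gene-drop, phenotypes, region VCF, alignments), so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    MISSING,
    AlignmentRecord,
    GenotypeDataset,
    PedigreeTable,
    VariantTable,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults emulate the study design: a closed breed cohort with a
    case:control ratio near 15:27, full penetrance, a phenocopy rate sized
    so that roughly 4 in 17 cases carry a genetically different disease,
    an LD block of ~1.3 Mb around the causal locus whose marker alt
    alleles ride only the ancestral disease haplotype, two recombinant
    dogs among the candidate-region variants, and a 102-genome unrelated
    control panel in which the insertion is absent.
    """

    seed: int = 0
    # pedigree
    n_founders: int = 24
    n_generations: int = 4
    mean_litter_size: float = 1.5
    first_birth_year: int = 2009
    # SNP array
    n_snps: int = 1200
    n_chromosomes: int = 4
    chrom_length_bp: int = 20_000_000
    founder_maf_bounds: tuple[float, float] = (0.05, 0.5)
    # disease locus and LD block
    disease_chromosome: str = "33"
    disease_position_bp: int = 7_785_480
    ld_block_half_width_bp: int = 650_000
    # alt alleles of block markers are near-private to the ancestral
    # disease haplotype: rare on other haplotypes
    block_background_alt_bounds: tuple[float, float] = (0.0, 0.0)
    recombination_rate: float = 0.01  # Morgans per Mb, Haldane map function
    causal_founder_freq: float = 0.40
    penetrance: float = 1.0
    phenocopy_rate: float = 0.05
    # candidate-region variants
    linked_snv_offsets_bp: tuple[int, ...] = (-68_182, 60_000, 258_617)
    n_recombinants: int = 2
    n_panel_genomes: int = 102
    # alignment simulation
    read_length: int = 150
    insert_size_mean: float = 400.0
    insert_size_sd: float = 50.0
    depth: int = 30
    discordant_fraction: float = 0.5
    region_half_width_bp: int = 1_500

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "discordant_fraction",
                     "causal_founder_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.penetrance <= 0:
            raise ConfigError("penetrance must be in (0, 1]")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        lo, hi = self.founder_maf_bounds
        if not 0.0 <= lo <= hi <= 0.5:
            raise ConfigError("founder_maf_bounds must satisfy 0 <= lo <= hi <= 0.5")


@dataclass
class StudyTruth:
    """Ground truth recorded alongside the simulated data."""

    causal_chromosome: str
    causal_position_bp: int
    causal_genotype: dict[str, int]  # dog id -> 0/1/2 at the causal locus
    phenocopy_ids: list[str] = field(default_factory=list)
    recombinant_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    pedigree: PedigreeTable
    genotypes: GenotypeDataset
    variants: VariantTable
    alignments: list[AlignmentRecord]
    truth: StudyTruth


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ("pedigree", "gene_drop", "phenotypes", "region", "alignments")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Pedigree


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> PedigreeTable:
    """Random-mating closed pedigree: founders in generation 0, then
    ``n_generations - 1`` rounds of matings between dogs of any earlier
    generation, Poisson litter sizes (at least one pup per mating).
    Birth year is assigned by generation starting at ``first_birth_year``.
    """
    if rng is None:
        rng = _streams(config)["pedigree"]
    rows = []
    males: list[str] = []
    females: list[str] = []
    for i in range(config.n_founders):
        sex = "M" if i % 2 == 0 else "F"
        dog = f"F{i:03d}"
        (males if sex == "M" else females).append(dog)
        rows.append((dog, "", "", sex, config.first_birth_year))
    if not males or not females:
        raise ConfigError("need at least one founder of each sex")

    counter = 0
    for gen in range(1, config.n_generations):
        n_matings = max(1, config.n_founders // 2)
        new_m: list[str] = []
        new_f: list[str] = []
        for _ in range(n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            litter = max(1, int(rng.poisson(config.mean_litter_size)))
            for _ in range(litter):
                sex = "M" if rng.random() < 0.5 else "F"
                dog = f"D{counter:04d}"
                counter += 1
                rows.append((dog, sire, dam, sex, config.first_birth_year + gen))
                (new_m if sex == "M" else new_f).append(dog)
        males = males + new_m
        females = females + new_f

    records = pd.DataFrame(
        rows, columns=["dog_id", "sire_id", "dam_id", "sex", "birth_year"]
    )
    return PedigreeTable(records)


# ---------------------------------------------------------------------------
# SNP map and gene drop


def _snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNPs; the disease chromosome is one of n_chromosomes."""
    chroms = [str(c + 1) for c in range(config.n_chromosomes - 1)]
    chroms.append(config.disease_chromosome)
    per_chrom = config.n_snps // config.n_chromosomes
    rows = []
    for chrom in chroms:
        positions = np.linspace(
            50_000, config.chrom_length_bp, per_chrom, dtype=np.int64
        )
        for k, pos in enumerate(positions):
            rows.append(
                {
                    "snp_id": f"SNP_{chrom}_{k:04d}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": "A",
                    "alt": "G",
                }
            )
    return pd.DataFrame(rows)


def gene_drop(
    pedigree: PedigreeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeDataset, StudyTruth]:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder haplotype alleles are Bernoulli draws at per-SNP founder
    frequencies (uniform within ``founder_maf_bounds``). The causal locus
    is an extra, untyped locus at ``disease_position_bp``; founder
    haplotypes carry its alt allele with probability
    ``causal_founder_freq`` and, when they do, the SNPs inside the LD
    block are set to the shared ancestral alt haplotype. Transmission
    recombines between adjacent loci with Haldane's map function
    (``r = (1 - exp(-2d))/2``, d in Morgans); chromosomes assort
    independently; no interference.
    """
    if rng is None:
        rng = _streams(config)["gene_drop"]
    snps = _snp_map(config)

    # insert the causal locus into the ordered loci of the disease chromosome
    loci = snps[["chrom", "pos"]].copy()
    causal = pd.DataFrame(
        [{"chrom": config.disease_chromosome, "pos": config.disease_position_bp}]
    )
    loci = (
        pd.concat([loci.assign(is_causal=False), causal.assign(is_causal=True)])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    # drop a duplicated position if the causal site collides with a SNP
    dup = loci.duplicated(subset=["chrom", "pos"], keep="last")
    loci = loci[~dup].reset_index(drop=True)
    causal_idx = int(np.flatnonzero(loci["is_causal"])[0])
    n_loci = len(loci)

    maf = rng.uniform(*config.founder_maf_bounds, size=n_loci)
    in_block = (
        (loci["chrom"] == config.disease_chromosome)
        & (abs(loci["pos"] - config.disease_position_bp) <= config.ld_block_half_width_bp)
    ).to_numpy()
    # off the ancestral haplotype, block-marker alt alleles are rare
    maf[in_block] = rng.uniform(*config.block_background_alt_bounds,
                                size=int(in_block.sum()))
    maf[causal_idx] = 0.0  # the causal allele exists only on the ancestral haplotype

    # per-adjacent-locus recombination fraction (0.5 across chromosome breaks)
    r = np.zeros(max(n_loci - 1, 0))
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    for g in range(n_loci - 1):
        if chrom_arr[g] != chrom_arr[g + 1]:
            r[g] = 0.5
        else:
            d_morgans = config.recombination_rate * (pos_arr[g + 1] - pos_arr[g]) / 1e6
            r[g] = 0.5 * (1.0 - math.exp(-2.0 * d_morgans))

    haplos: dict[str, np.ndarray] = {}  # dog -> (2, n_loci) int8

    # fix the founder carrier-haplotype count at its expectation so the
    # causal frequency does not drift with the (small) founder pool
    n_founder_haps = 2 * sum(1 for d in pedigree.ids if pedigree.is_founder(d))
    carrier_flags = np.zeros(n_founder_haps, dtype=bool)
    carrier_flags[: int(round(config.causal_founder_freq * n_founder_haps))] = True
    rng.shuffle(carrier_flags)
    carrier_queue = list(carrier_flags)

    def founder_haplotype() -> np.ndarray:
        h = (rng.random(n_loci) < maf).astype(np.int8)
        carrier = (
            carrier_queue.pop()
            if carrier_queue
            else bool(rng.random() < config.causal_founder_freq)
        )
        if carrier:
            h[causal_idx] = 1
            h[in_block] = 1
        else:
            h[causal_idx] = 0
        return h

    def meiosis(parent: np.ndarray) -> np.ndarray:
        # crossover switches accumulated along the locus order
        switches = rng.random(n_loci - 1) < r
        strand = np.empty(n_loci, dtype=np.intp)
        strand[0] = rng.integers(2)
        strand[1:] = (strand[0] + np.cumsum(switches)) % 2
        return parent[strand, np.arange(n_loci)]

    order = _topological_order(pedigree)
    for dog in order:
        sire, dam = pedigree.parents(dog)
        paternal = founder_haplotype() if sire is None else meiosis(haplos[sire])
        maternal = founder_haplotype() if dam is None else meiosis(haplos[dam])
        haplos[dog] = np.stack([paternal, maternal])

    ids = pedigree.ids
    geno = np.stack([haplos[d].sum(axis=0) for d in ids]).astype(np.int16)
    causal_geno = {d: int(geno[i, causal_idx]) for i, d in enumerate(ids)}
    snp_cols = np.flatnonzero(~loci["is_causal"].to_numpy())
    calls = geno[:, snp_cols]

    # rebuild the SNP table in locus order minus the causal site
    kept = loci.loc[~loci["is_causal"]].reset_index(drop=True)
    kept = kept.merge(snps, on=["chrom", "pos"], how="left")
    snp_table = kept[["snp_id", "chrom", "pos", "ref", "alt"]]

    dataset = GenotypeDataset(ids, ["unknown"] * len(ids), snp_table, calls)
    truth = StudyTruth(
        causal_chromosome=config.disease_chromosome,
        causal_position_bp=config.disease_position_bp,
        causal_genotype=causal_geno,
    )
    return dataset, truth


def _topological_order(pedigree: PedigreeTable) -> list[str]:
    order: list[str] = []
    done: set[str] = set()

    def visit(d: str) -> None:
        if d in done:
            return
        for p in pedigree.parents(d):
            if p is not None and p in pedigree._parents:
                visit(p)
        done.add(d)
        order.append(d)

    for d in pedigree.ids:
        visit(d)
    return order


# ---------------------------------------------------------------------------
# Phenotypes


def assign_phenotypes(
    truth: StudyTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], StudyTruth]:
    """Label dogs case/control from the causal genotype.

    Hom-alt dogs become cases with probability ``penetrance``; all other
    dogs become phenocopy cases with probability ``phenocopy_rate``.
    Returns the labels and an updated truth carrying phenocopy ids.
    """
    if rng is None:
        rng = _streams(config)["phenotypes"]
    labels: dict[str, str] = {}
    phenocopies: list[str] = []
    for dog, g in truth.causal_genotype.items():
        if g == 2:
            labels[dog] = CASE if rng.random() < config.penetrance else CONTROL
        elif rng.random() < config.phenocopy_rate:
            labels[dog] = CASE
            phenocopies.append(dog)
        else:
            labels[dog] = CONTROL
    return labels, replace(truth, phenocopy_ids=phenocopies)


# ---------------------------------------------------------------------------
# Candidate-region VCF


def simulate_candidate_region_vcf(
    truth: StudyTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[VariantTable, StudyTruth]:
    """Insertion plus linked SNVs in near-perfect LD, typed in the study
    dogs and an unrelated control panel.

    Every linked SNV copies the causal genotype except in
    ``n_recombinants`` carrier dogs, where one flanking (outermost)
    variant loses one alt allele — the haplotype having recombined away.
    Panel genomes carry neither the insertion nor the linked alleles
    (the variant set is private to the study breed).
    """
    if rng is None:
        rng = _streams(config)["region"]
    dogs = list(truth.causal_genotype)
    n_rec = config.n_recombinants
    if n_rec > len(dogs):
        raise ConfigError("n_recombinants exceeds the number of study dogs")

    positions = sorted(
        [config.disease_position_bp]
        + [config.disease_position_bp + off for off in config.linked_snv_offsets_bp]
    )
    rows = []
    for pos in positions:
        if pos == config.disease_position_bp:
            rows.append(
                {
                    "chrom": config.disease_chromosome,
                    "pos": pos,
                    "ref": "A",
                    "alt": "<INS:ME:LINE1>",
                    "consequence": "upstream_insertion",
                }
            )
        else:
            rows.append(
                {
                    "chrom": config.disease_chromosome,
                    "pos": pos,
                    "ref": "G",
                    "alt": "T",
                    "consequence": "intron_variant",
                }
            )
    variants = pd.DataFrame(rows)

    causal_vec = np.array([truth.causal_genotype[d] for d in dogs], dtype=np.int16)
    geno = np.tile(causal_vec, (len(variants), 1))

    carriers = [i for i, g in enumerate(causal_vec) if g >= 1]
    pool = carriers if len(carriers) >= n_rec else list(range(len(dogs)))
    rec_idx = sorted(rng.choice(len(pool), size=n_rec, replace=False)) if n_rec else []
    recombinants = []
    flank_rows = [0, len(variants) - 1]  # outermost variants decouple
    for k, i in enumerate(rec_idx):
        dog_i = pool[i]
        v = flank_rows[k % len(flank_rows)]
        geno[v, dog_i] = max(0, geno[v, dog_i] - 1)
        recombinants.append(dogs[dog_i])

    panel_ids = [f"PANEL_{i:03d}" for i in range(config.n_panel_genomes)]
    panel = np.zeros((len(variants), len(panel_ids)), dtype=np.int16)
    table = VariantTable(
        dogs + panel_ids, variants, np.concatenate([geno, panel], axis=1)
    )
    return table, replace(truth, recombinant_ids=recombinants)


# ---------------------------------------------------------------------------
# Insertion-site alignments


def simulate_insertion_alignments(
    truth: StudyTruth,
    config: SimConfig,
    sample_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[AlignmentRecord]:
    """Read pairs over the insertion site.

    For fragments drawn from an insertion-carrying haplotype that span
    the breakpoint, a fraction ``discordant_fraction`` have their mate
    reassigned to a random other chromosome (the repetitive inserted
    sequence attracting the mate alignment); reads overlapping the
    breakpoint are soft-clipped at it. All other fragments yield proper
    pairs. Dogs without the insertion yield only proper pairs.

    Breakpoint-spanning carrier fragments carry ``:S`` in the pair id
    (synthetic ground truth for calibration; detection never reads ids).
    """
    if config.depth <= 0:
        raise ConfigError("depth must be positive")
    if rng is None:
        rng = _streams(config)["alignments"]
    if sample_ids is None:
        sample_ids = list(truth.causal_genotype)

    site = truth.causal_position_bp
    chrom = truth.causal_chromosome
    half = config.region_half_width_bp
    span = 2 * half
    read_len = config.read_length
    n_pairs = max(1, int(round(config.depth * span / (2 * read_len))))
    other_chroms = [c for c in ("1", "2", "3", "5", "12", "20") if c != chrom]

    records: list[AlignmentRecord] = []
    for dog in sample_ids:
        g = truth.causal_genotype.get(dog, 0)
        for k in range(n_pairs):
            frag = max(2 * read_len, int(rng.normal(config.insert_size_mean,
                                                    config.insert_size_sd)))
            start = int(site - half + rng.integers(span))
            end = start + frag - 1
            carrier_hap = rng.random() < (g / 2.0)
            spans_site = start < site < end

            if carrier_hap and spans_site:
                rid = f"{dog}:{k:05d}:S"
                discordant = rng.random() < config.discordant_fraction
                records.extend(
                    _breakpoint_pair(
                        rid, chrom, start, end, site, read_len, discordant,
                        other_chroms, rng,
                    )
                )
            else:
                rid = f"{dog}:{k:05d}:N"
                records.append(
                    AlignmentRecord(rid + "/1", chrom, start, read_len, 0, 0,
                                    chrom, end - read_len + 1, True)
                )
                records.append(
                    AlignmentRecord(rid + "/2", chrom, end - read_len + 1, read_len,
                                    0, 0, chrom, start, True)
                )
    return records


def _breakpoint_pair(
    rid: str,
    chrom: str,
    start: int,
    end: int,
    site: int,
    read_len: int,
    discordant: bool,
    other_chroms: list[str],
    rng: np.random.Generator,
) -> list[AlignmentRecord]:
    """Reads for one carrier fragment spanning the breakpoint.

    Discordant fragments keep only the anchoring left read locally (its
    mate aligned inside the element on another chromosome); either way a
    read overlapping the breakpoint is soft-clipped at it.
    """
    out = []
    r1_end = start + read_len - 1
    r2_start = end - read_len + 1

    if discordant:
        mate_chrom = str(rng.choice(other_chroms))
        mate_pos = int(rng.integers(1, 60_000_000))
        if start <= site <= r1_end and site > start:
            mapped = site - start
            out.append(
                AlignmentRecord(rid + "/1", chrom, start, mapped, 0,
                                read_len - mapped, mate_chrom, mate_pos, False)
            )
        else:
            out.append(
                AlignmentRecord(rid + "/1", chrom, start, read_len, 0, 0,
                                mate_chrom, mate_pos, False)
            )
        return out

    # concordant carrier fragment: clip any read overlapping the breakpoint
    if start <= site <= r1_end and site > start:
        mapped = site - start
        out.append(
            AlignmentRecord(rid + "/1", chrom, start, mapped, 0, read_len - mapped,
                            chrom, r2_start, False)
        )
    else:
        out.append(
            AlignmentRecord(rid + "/1", chrom, start, read_len, 0, 0,
                            chrom, r2_start, True)
        )
    if r2_start <= site <= end:
        clip_l = site - r2_start + 1
        mapped = read_len - clip_l
        if mapped > 0:
            out.append(
                AlignmentRecord(rid + "/2", chrom, site + 1, mapped, clip_l, 0,
                                chrom, start, False)
            )
    else:
        out.append(
            AlignmentRecord(rid + "/2", chrom, r2_start, read_len, 0, 0,
                            chrom, start, True)
        )
    return out


# ---------------------------------------------------------------------------
# Orchestration


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every stage with independent seeded streams; fully deterministic."""
    streams = _streams(config)
    pedigree = simulate_pedigree(config, streams["pedigree"])
    dataset, truth = gene_drop(pedigree, config, streams["gene_drop"])
    labels, truth = assign_phenotypes(truth, config, streams["phenotypes"])
    dataset = GenotypeDataset(
        dataset.sample_ids,
        [labels[d] for d in dataset.sample_ids],
        dataset.snps,
        dataset.calls,
    )
    variants, truth = simulate_candidate_region_vcf(truth, config, streams["region"])
    # the study sequences one homozygous case (falling back to the first
    # dog when no homozygote exists under an unusual configuration)
    sequenced = next(
        (d for d, g in truth.causal_genotype.items() if g == 2),
        dataset.sample_ids[0],
    )
    alignments = simulate_insertion_alignments(
        truth, config, sample_ids=[sequenced], rng=streams["alignments"]
    )
    return SimulatedStudy(pedigree, dataset, variants, alignments, truth)
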