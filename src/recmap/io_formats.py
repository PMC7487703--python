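"""Readers and writers for the external formats the pipeline touches.

Conventions fixed here and relied on everywhere else:

* Coordinates are 1-based inclusive internally (the VCF/MAP convention).
  BED output converts to 0-based half-open.
* Genotypes are stored as counts of the alternate allele: 0 = hom ref,
  1 = het, 2 = hom alt, with a dedicated :data:`MISSING` sentinel (never 0,
  which is a valid genotype). Phase is ignored.
* All variants are assumed reported on the reference forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

#: Sentinel for a missing genotype call.
MISSING: int = -9

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"

# PLINK phenotype column: 2 = affected, 1 = unaffected, 0/-9 = missing.
_PHENO_TO_LABEL = {"2": CASE, "1": CONTROL, "0": UNKNOWN, "-9": UNKNOWN}
_LABEL_TO_PHENO = {CASE: "2", CONTROL: "1", UNKNOWN: "0"}


class FormatError(ValueError):
    """A file does not conform to the dialect this package reads."""


@dataclass
class GenotypeDataset:
    """Samples x SNP genotype matrix with a chromosome map.

    ``calls[i, j]`` is the alt-allele count of sample ``i`` at SNP ``j``
    (0/1/2) or :data:`MISSING`. ``snps`` is a DataFrame with columns
    ``snp_id, chrom, pos, ref, alt`` ordered with strictly increasing
    positions within each chromosome.
    """

    sample_ids: list[str]
    phenotypes: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.snps)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def case_mask(self) -> np.ndarray:
        return np.asarray([p == CASE for p in self.phenotypes])

    def control_mask(self) -> np.ndarray:
        return np.asarray([p == CONTROL for p in self.phenotypes])

    def select_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            [s for s, k in zip(self.sample_ids, keep) if k],
            [p for p, k in zip(self.phenotypes, keep) if k],
            self.snps.reset_index(drop=True),
            self.calls[keep],
        )

    def select_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            list(self.sample_ids),
            list(self.phenotypes),
            self.snps.loc[keep].reset_index(drop=True),
            self.calls[:, keep],
        )


@dataclass
class PedigreeTable:
    """Parent links and birth years.

    ``records`` has columns ``dog_id, sire_id, dam_id, sex, birth_year``;
    an unknown parent is the empty string. The pedigree is verified acyclic
    on construction; a parent named but absent from the file is a
    founder-by-absence.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.records["dog_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate dog id {dup!r}")
        self._parents = {
            r.dog_id: (r.sire_id or None, r.dam_id or None)
            for r in self.records.itertuples()
        }
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(d: str, stack: list[str]) -> None:
            if state.get(d) == 1:
                return
            if state.get(d) == 0:
                raise ValueError(f"pedigree cycle involving {d!r}")
            state[d] = 0
            for p in self._parents.get(d, (None, None)):
                if p is not None:
                    visit(p, stack)
            state[d] = 1

        for d in self._parents:
            visit(d, [])

    @property
    def ids(self) -> list[str]:
        return list(self.records["dog_id"])

    def parents(self, dog_id: str) -> tuple[str | None, str | None]:
        """(sire, dam); an absent record or empty field is None (founder)."""
        return self._parents.get(dog_id, (None, None))

    def is_founder(self, dog_id: str) -> bool:
        sire, dam = self._parents.get(dog_id, (None, None))
        return sire is None and dam is None

    def founders(self) -> list[str]:
        """Dogs with no recorded parents, plus parents named but absent."""
        named = set()
        for s, d in self._parents.values():
            named.update(p for p in (s, d) if p is not None)
        absent = sorted(named - set(self._parents))
        in_file = [d for d in self.ids if self.is_founder(d)]
        return in_file + absent

    def birth_year(self, dog_id: str) -> int | None:
        row = self.records.loc[self.records["dog_id"] == dog_id, "birth_year"]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return int(row.iloc[0])


@dataclass
class VariantTable:
    """Ordered variant records with a per-sample genotype matrix.

    ``genotypes[v, s]`` is the alt-allele count of sample ``s`` at variant
    ``v``. Symbolic alternate alleles (e.g. ``<INS:ME:LINE1>``) carry
    zero-length ref-replacement semantics: the REF base is the breakpoint
    anchor, nothing is deleted.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # chrom, pos, ref, alt, consequence
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError("genotypes shape must be n_variants x n_samples")
        if not np.isin(self.genotypes, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in variant table") from None


@dataclass
class AlignmentRecord:
    """One aligned read with its mate's placement (the Fig-3-style evidence)."""

    read_id: str
    chromosome: str
    position_bp: int  # 1-based leftmost mapped base
    mapped_length: int
    soft_clip_left: int
    soft_clip_right: int
    mate_chromosome: str
    mate_position_bp: int
    proper_pair: bool

    def __post_init__(self) -> None:
        if self.mapped_length <= 0:
            raise ValueError("mapped_length must be positive")
        if self.soft_clip_left < 0 or self.soft_clip_right < 0:
            raise ValueError("soft-clip lengths must be non-negative")

    @property
    def end_bp(self) -> int:
        """1-based inclusive rightmost mapped base."""
        return self.position_bp + self.mapped_length - 1


@dataclass
class Interval:
    """Genomic interval, 1-based inclusive internally."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            self.start, self.end = self.end, self.start

    def contains(self, chromosome: str, pos: int) -> bool:
        return chromosome == self.chromosome and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed_row(self) -> tuple[str, int, int]:
        """Convert to BED3 (0-based half-open)."""
        return (self.chromosome, self.start - 1, self.end)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP


def read_genotype_dataset(ped_path: str, map_path: str) -> GenotypeDataset:
    """Read PLINK text PED + MAP into a :class:`GenotypeDataset`.

    The MAP file has columns ``chrom snp_id cM bp`` and optionally two
    extra columns ``ref alt`` (written by :func:`write_genotype_dataset`).
    Without them the reference allele is inferred as the major allele in
    the PED file (ties broken lexicographically). Genotype ``0 0`` becomes
    a missing call.
    """
    snps = _read_map(map_path)
    has_alleles = "ref" in snps.columns

    sample_ids: list[str] = []
    phenotypes: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(snps):
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * len(snps)} "
                    f"fields for {len(snps)} MAP SNPs, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            phenotypes.append(_PHENO_TO_LABEL.get(fields[5], UNKNOWN))
            allele_rows.append(fields[6:])

    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), len(snps), 2)

    refs, alts = [], []
    calls = np.full((len(sample_ids), len(snps)), MISSING, dtype=np.int16)
    for j in range(len(snps)):
        a = alleles[:, j, :]
        observed = a[a != "0"]
        if has_alleles:
            ref, alt = snps.at[j, "ref"], snps.at[j, "alt"]
        else:
            uniq, counts = np.unique(observed, return_counts=True)
            if len(uniq) == 0:
                ref, alt = ".", "."
            elif len(uniq) == 1:
                ref, alt = str(uniq[0]), "."
            else:
                order = np.lexsort((uniq, -counts))  # major first, ties lexicographic
                ref, alt = str(uniq[order[0]]), str(uniq[order[1]])
        refs.append(ref)
        alts.append(alt)
        typed = (a[:, 0] != "0") & (a[:, 1] != "0")
        calls[typed, j] = (a[typed, 0] == alt).astype(int) + (a[typed, 1] == alt).astype(int)

    snps = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "ref": refs,
            "alt": alts,
        }
    )
    return GenotypeDataset(sample_ids, phenotypes, snps, calls)


def _read_map(map_path: str) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (4, 6):
                raise FormatError(f"{map_path} line {lineno}: expected 4 or 6 columns")
            row = {"chrom": fields[0], "snp_id": fields[1], "pos": int(fields[3])}
            if len(fields) == 6:
                row["ref"], row["alt"] = fields[4], fields[5]
            rows.append(row)
    if not rows:
        raise FormatError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows)


def write_genotype_dataset(dataset: GenotypeDataset, ped_path: str, map_path: str) -> None:
    """Write PED + 6-column MAP (ref/alt recorded so reads round-trip)."""
    with open(map_path, "w") as fh:
        for row in dataset.snps.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.ref}\t{row.alt}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            fields = [sid, sid, "0", "0", "0", _LABEL_TO_PHENO[dataset.phenotypes[i]]]
            for j, row in enumerate(dataset.snps.itertuples()):
                code = dataset.calls[i, j]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [row.ref, row.ref]
                elif code == 1:
                    fields += [row.ref, row.alt]
                else:
                    fields += [row.alt, row.alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str) -> VariantTable:
    """Read a GT-only multi-sample VCF (v4.2 subset).

    Biallelic records only; the one symbolic alternate allele accepted is
    a mobile-element insertion tag such as ``<INS:ME:LINE1>``. A variant
    consequence label is taken from the INFO ``CSQ`` key when present.
    """
    with open(path) as fh:
        if not any(line.startswith("#CHROM") for line in fh if line.startswith("#")):
            raise FormatError(f"{path}: missing #CHROM header line")
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows = []
    genos = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} unsupported"
            )
        csq = rec.INFO.get("CSQ")
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "consequence": csq,
            }
        )
        codes = []
        for gt in rec.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                codes.append(MISSING)
            else:
                codes.append(int(a > 0) + int(b > 0))
        genos.append(codes)
    geno = (
        np.asarray(genos, dtype=np.int16)
        if genos
        else np.empty((0, len(sample_ids)), dtype=np.int16)
    )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "consequence"])
    return VariantTable(sample_ids, variants, geno)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str) -> None:
    chroms = list(dict.fromkeys(table.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##ALT=<ID=INS:ME:LINE1,Description="LINE-1 insertion">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for v, row in enumerate(table.variants.itertuples()):
            info = f"CSQ={row.consequence}" if row.consequence else "."
            gts = "\t".join(_GT_STR[int(g)] for g in table.genotypes[v])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def attach_consequences(table: VariantTable, tsv_path: str) -> VariantTable:
    """Fill the consequence column from a sidecar TSV (chrom, pos, consequence)."""
    side = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    lookup = {(r.chrom, r.pos): r.consequence for r in side.itertuples()}
    cons = [
        lookup.get((r.chrom, r.pos), r.consequence) for r in table.variants.itertuples()
    ]
    variants = table.variants.copy()
    variants["consequence"] = cons
    return VariantTable(table.sample_ids, variants, table.genotypes)


# ---------------------------------------------------------------------------
# Pedigree CSV


def read_pedigree(path: str) -> PedigreeTable:
    """Read the pedigree CSV (dog_id,sire_id,dam_id,sex,birth_year)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["dog_id", "sire_id", "dam_id", "sex", "birth_year"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {','.join(expected)}")
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
    return PedigreeTable(df)


def write_pedigree(table: PedigreeTable, path: str) -> None:
    out = table.records.copy()
    out["birth_year"] = out["birth_year"].map(
        lambda y: "" if pd.isna(y) else str(int(y))
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Alignments: headered TSV or SAM text (CIGAR restricted to M/S)

_TSV_COLUMNS = [
    "read_id",
    "chromosome",
    "position_bp",
    "mapped_length",
    "soft_clip_left",
    "soft_clip_right",
    "mate_chromosome",
    "mate_position_bp",
    "proper_pair",
]

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")


def read_alignments(path: str) -> list[AlignmentRecord]:
    """Read aligned read-pair records from a TSV or SAM text file."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@") or _looks_like_sam(first):
        return _read_sam(path)
    return _read_alignment_tsv(path)


def _looks_like_sam(line: str) -> bool:
    fields = line.rstrip("\n").split("\t")
    return len(fields) >= 11 and fields[1].isdigit() and fields[4].isdigit()


def _read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chromosome": str, "mate_chromosome": str}
    )
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        AlignmentRecord(
            read_id=str(r.read_id),
            chromosome=str(r.chromosome),
            position_bp=int(r.position_bp),
            mapped_length=int(r.mapped_length),
            soft_clip_left=int(r.soft_clip_left),
            soft_clip_right=int(r.soft_clip_right),
            mate_chromosome=str(r.mate_chromosome),
            mate_position_bp=int(r.mate_position_bp),
            proper_pair=bool(r.proper_pair),
        )
        for r in df.itertuples()
    ]


def _read_sam(path: str) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            left = right = 0
            mapped = 0
            for k, (op, length) in enumerate(read.cigartuples):
                if op == 0:  # M
                    mapped += length
                elif op == 4:  # S
                    if k == 0:
                        left = length
                    else:
                        right = length
                else:
                    raise FormatError(
                        f"{path}: read {read.query_name}: unsupported CIGAR opcode "
                        f"in {read.cigarstring} (only M/S handled)"
                    )
            mate_chrom = read.next_reference_name or "*"
            records.append(
                AlignmentRecord(
                    read_id=read.query_name,
                    chromosome=read.reference_name,
                    position_bp=read.reference_start + 1,
                    mapped_length=mapped,
                    soft_clip_left=left,
                    soft_clip_right=right,
                    mate_chromosome=mate_chrom,
                    mate_position_bp=(read.next_reference_start or 0) + 1,
                    proper_pair=read.is_proper_pair,
                )
            )
    return records


def write_alignments_tsv(records: list[AlignmentRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "chromosome": r.chromosome,
                "position_bp": r.position_bp,
                "mapped_length": r.mapped_length,
                "soft_clip_left": r.soft_clip_left,
                "soft_clip_right": r.soft_clip_right,
                "mate_chromosome": r.mate_chromosome,
                "mate_position_bp": r.mate_position_bp,
                "proper_pair": r.proper_pair,
            }
            for r in records
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: list[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv.to_bed_row()
            fh.write(f"{chrom}\t{start}\t{end}\n")
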