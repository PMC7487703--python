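"""Homozygosity mapping around the top associated SNP.

A recessive disease allele in a closed population rides a shared ancestral
haplotype, so affected dogs are expected to be homozygous across an
interval flanking the associated marker. The mapper anchors on the top
SNP, takes as the core set the cases homozygous for the risk allele
there, and extends marker-by-marker in both directions while the core
cases keep sharing a single homozygous allele. The resulting interval's
endpoints are the outermost passing SNP positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CASE, CONTROL, MISSING, GenotypeDataset, Interval


@dataclass
class CriticalRegion:
    """Shared homozygous interval with its supporting haplotype.

    ``shared_codes`` maps SNP index (column in the dataset used for
    mapping) to the shared homozygous genotype code (0 or 2) at that SNP.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    top_snp: str
    risk_allele: str
    core_case_ids: list[str]
    snp_indices: list[int] = field(default_factory=list)
    shared_codes: dict[int, int] = field(default_factory=dict)

    @property
    def interval(self) -> Interval:
        return Interval(self.chromosome, self.start_bp, self.end_bp)


def _snp_share_fraction(
    col: np.ndarray,
) -> tuple[float, int]:
    """Fraction of (non-missing) calls homozygous for the best single shared
    allele, and that allele's code. Missing calls do not break sharing but
    do not count as support; an all-missing column passes vacuously."""
    nonmiss = col != MISSING
    if not nonmiss.any():
        return 1.0, -1
    n0 = int((col[nonmiss] == 0).sum())
    n2 = int((col[nonmiss] == 2).sum())
    best, code = (n0, 0) if n0 >= n2 else (n2, 2)
    return best / int(nonmiss.sum()), code


def map_critical_region(
    dataset: GenotypeDataset,
    top_snp: str,
    min_share_fraction: float = 1.0,
) -> CriticalRegion:
    """Delimit the shared homozygous interval anchored at ``top_snp``.

    The risk allele is whichever allele has the higher frequency among
    cases at the top SNP; the core set is the cases homozygous for it
    there. Extension continues while the fraction of core cases
    homozygous for a single shared allele at each SNP is at least
    ``min_share_fraction``.
    """
    matches = np.flatnonzero(dataset.snps["snp_id"] == top_snp)
    if len(matches) == 0:
        raise KeyError(f"top SNP {top_snp!r} not in dataset")
    anchor = int(matches[0])
    chrom = dataset.snps.at[anchor, "chrom"]
    chrom_cols = np.flatnonzero(dataset.snps["chrom"] == chrom)

    cases = dataset.case_mask()
    col = dataset.calls[cases, anchor]
    nonmiss = col != MISSING
    if not nonmiss.any():
        raise ValueError("no case genotyped at the top SNP")
    alt_freq = col[nonmiss].sum() / (2 * nonmiss.sum())
    risk_code = 2 if alt_freq >= 0.5 else 0
    risk_allele = (
        dataset.snps.at[anchor, "alt"] if risk_code == 2 else dataset.snps.at[anchor, "ref"]
    )

    case_ids = np.asarray(dataset.sample_ids)[cases]
    core_mask = col == risk_code
    if not core_mask.any():
        raise ValueError("no case homozygous for the risk allele at the top SNP")
    core_ids = list(case_ids[core_mask])
    core_rows = np.flatnonzero(cases)[core_mask]

    anchor_in_chrom = int(np.flatnonzero(chrom_cols == anchor)[0])

    def passes(j_chrom: int) -> tuple[bool, int]:
        colj = dataset.calls[core_rows, chrom_cols[j_chrom]]
        frac, code = _snp_share_fraction(colj)
        return frac >= min_share_fraction, code

    shared_codes: dict[int, int] = {}
    ok, code = passes(anchor_in_chrom)
    if not ok:
        # the anchor itself always passes for the core set by construction
        # unless min_share_fraction demands more support than exists
        raise ValueError("anchor SNP fails the sharing criterion for the core set")
    shared_codes[int(chrom_cols[anchor_in_chrom])] = code

    left = anchor_in_chrom
    while left > 0:
        ok, code = passes(left - 1)
        if not ok:
            break
        left -= 1
        shared_codes[int(chrom_cols[left])] = code
    right = anchor_in_chrom
    while right < len(chrom_cols) - 1:
        ok, code = passes(right + 1)
        if not ok:
            break
        right += 1
        shared_codes[int(chrom_cols[right])] = code

    snp_indices = [int(c) for c in chrom_cols[left : right + 1]]
    return CriticalRegion(
        chromosome=chrom,
        start_bp=int(dataset.snps.at[snp_indices[0], "pos"]),
        end_bp=int(dataset.snps.at[snp_indices[-1], "pos"]),
        top_snp=top_snp,
        risk_allele=str(risk_allele),
        core_case_ids=core_ids,
        snp_indices=snp_indices,
        shared_codes=shared_codes,
    )


def classify_cases(
    dataset: GenotypeDataset, region: CriticalRegion
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Split cases into concordant/discordant and summarize controls.

    A case is concordant iff it is homozygous for the shared allele at
    every non-missing SNP inside the region. Controls are labeled
    ``homozygous`` (shared haplotype throughout), ``heterozygous`` (at
    least one het call in the region) or ``reference`` (homozygous for
    the non-shared allele somewhere, no het calls).
    """
    if not region.snp_indices:
        raise ValueError("empty region")
    for j in region.snp_indices:
        if j >= dataset.n_snps:
            raise ValueError("region outside dataset coordinates")

    def matches_shared(row: int) -> tuple[bool, bool]:
        any_het = False
        all_shared = True
        for j in region.snp_indices:
            g = dataset.calls[row, j]
            if g == MISSING:
                continue
            code = region.shared_codes.get(j, -1)
            if g == 1:
                any_het = True
            if code != -1 and g != code:
                all_shared = False
        return all_shared, any_het

    concordant, discordant = [], []
    control_rows = []
    for i, sid in enumerate(dataset.sample_ids):
        pheno = dataset.phenotypes[i]
        shared, any_het = matches_shared(i)
        if pheno == CASE:
            (concordant if shared else discordant).append(sid)
        elif pheno == CONTROL:
            status = "homozygous" if shared else ("heterozygous" if any_het else "reference")
            control_rows.append({"sample_id": sid, "status": status})
    return concordant, discordant, pd.DataFrame(control_rows, columns=["sample_id", "status"])
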