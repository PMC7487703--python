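"""Recessive segregation filtering, effect scoring and concordance tables.

For a fully penetrant recessive condition the causal variant must be
homozygous-alternate in every affected individual, while unaffected dogs
may be carriers (heterozygous) or homozygous reference but never
homozygous alternate. The filter applies exactly that pattern to a
multi-sample variant table, a rule-based scorer ranks consequence labels
by predicted severity, a privateness check counts carriers in an
unrelated genome panel, and the concordance table tabulates genotype
distributions by phenotype across a candidate variant set, flagging
discordant individuals and recombinants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CASE, CONTROL, MISSING, Interval, VariantTable

# Tier vocabulary. High-effect consequences are those altering protein
# sequence or splicing: premature start/stop codons, splice-site variants,
# nonsense and missense variants, frameshifts and in-frame deletions.
_TIERS: dict[str, str] = {
    "start_gained": "high",
    "start_lost": "high",
    "stop_gained": "high",
    "stop_lost": "high",
    "splice_donor_variant": "high",
    "splice_acceptor_variant": "high",
    "nonsense_variant": "high",
    "missense_variant": "high",
    "frameshift_variant": "high",
    "inframe_deletion": "high",
    "inframe_insertion": "moderate",
    "splice_region_variant": "moderate",
    "protein_altering_variant": "moderate",
    "synonymous_variant": "low",
    "stop_retained_variant": "low",
    "5_prime_UTR_variant": "low",
    "3_prime_UTR_variant": "low",
    "intron_variant": "modifier",
    "intergenic_variant": "modifier",
    "upstream_gene_variant": "modifier",
    "downstream_gene_variant": "modifier",
    "upstream_insertion": "modifier",
    "non_coding_transcript_variant": "modifier",
}

_TIER_SCORE = {"high": 4, "moderate": 3, "low": 2, "modifier": 1}


@dataclass(frozen=True)
class EffectScore:
    consequence: str
    tier: str
    score: int


@dataclass(frozen=True)
class SegregationConfig:
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    allow_control_het: bool = True
    allow_control_homalt: bool = False
    region: Interval | None = None

    def __post_init__(self) -> None:
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"case and control sets overlap: {sorted(overlap)}")
        if not self.case_ids:
            raise ValueError("at least one case must be configured")


def score_effect(consequence_label: str) -> EffectScore:
    """Map a consequence label to its severity tier and numeric score."""
    tier = _TIERS.get(consequence_label)
    if tier is None:
        raise ValueError(
            f"unknown consequence {consequence_label!r}; known labels: "
            f"{sorted(_TIERS)}"
        )
    return EffectScore(consequence_label, tier, _TIER_SCORE[tier])


def recessive_filter(
    variants: VariantTable, config: SegregationConfig
) -> tuple[VariantTable, pd.DataFrame]:
    """Keep variants segregating with a recessive model.

    A variant survives iff every case with a non-missing call is hom-alt
    and no control violates the allow flags. Missing calls neither support
    nor veto survival but are logged. Returns the surviving table and a
    per-variant reason log (chrom, pos, survives, reason, n_missing).
    """
    case_idx = [variants.sample_index(s) for s in config.case_ids]
    ctrl_idx = [variants.sample_index(s) for s in config.control_ids]

    keep = np.zeros(variants.n_variants, dtype=bool)
    rows = []
    for v in range(variants.n_variants):
        chrom = variants.variants.at[v, "chrom"]
        pos = int(variants.variants.at[v, "pos"])
        if config.region is not None and not config.region.contains(chrom, pos):
            rows.append((chrom, pos, False, "outside region", 0))
            continue
        case_g = variants.genotypes[v, case_idx]
        ctrl_g = variants.genotypes[v, ctrl_idx]
        n_missing = int((case_g == MISSING).sum() + (ctrl_g == MISSING).sum())
        reason = "pass"
        ok = True
        if ((case_g != MISSING) & (case_g != 2)).any():
            ok, reason = False, "case not hom-alt"
        elif not config.allow_control_homalt and (ctrl_g == 2).any():
            ok, reason = False, "control hom-alt"
        elif not config.allow_control_het and (ctrl_g == 1).any():
            ok, reason = False, "control het"
        keep[v] = ok
        rows.append((chrom, pos, ok, reason, n_missing))

    log = pd.DataFrame(
        rows, columns=["chrom", "pos", "survives", "reason", "n_missing"]
    )
    surviving = VariantTable(
        list(variants.sample_ids),
        variants.variants.loc[keep].reset_index(drop=True),
        variants.genotypes[keep],
    )
    return surviving, log


def private_check(
    variant_genotypes: np.ndarray, panel_ids: list[str] | None = None
) -> tuple[int, list[str], bool]:
    """Count insertion carriers in a control-genome panel.

    ``variant_genotypes`` holds the panel's 0/1/2/missing codes for one
    variant. Returns (carrier count, carrier ids, private), where private
    means no panel genome carries the alternate allele. An empty or
    all-missing panel is an error, distinct from a private variant.
    """
    g = np.asarray(variant_genotypes)
    if g.size == 0:
        raise ValueError("empty panel")
    nonmiss = g != MISSING
    if not nonmiss.any():
        raise ValueError("panel is entirely missing; privateness undetermined")
    carriers = np.flatnonzero(nonmiss & (g >= 1))
    if panel_ids is None:
        ids = [str(i) for i in carriers]
    else:
        ids = [panel_ids[i] for i in carriers]
    return len(carriers), ids, len(carriers) == 0


@dataclass
class ConcordanceTable:
    counts: pd.DataFrame  # per variant x phenotype class genotype counts
    discordant_ids: list[str]
    recombinant_ids: list[str]


def concordance_table(
    variants: VariantTable, phenotypes: dict[str, str]
) -> ConcordanceTable:
    """Genotype distributions per variant split by phenotype.

    Individuals without a phenotype are excluded (with a warning).
    Discordant individuals are cases not hom-alt, or controls hom-alt,
    at any variant; recombinants are individuals whose genotype differs
    across the variant set (ignoring missing calls).
    """
    if variants.n_variants == 0:
        raise ValueError("need at least one variant")
    known = [s for s in variants.sample_ids if phenotypes.get(s) in (CASE, CONTROL)]
    skipped = [s for s in variants.sample_ids if s not in known]
    if skipped:
        import warnings

        warnings.warn(f"{len(skipped)} genotyped individuals lack a phenotype; excluded")
    idx = [variants.sample_index(s) for s in known]
    labels = np.asarray([phenotypes[s] for s in known])

    rows = []
    for v in range(variants.n_variants):
        g = variants.genotypes[v, idx]
        for pheno in (CASE, CONTROL):
            sel = g[labels == pheno]
            rows.append(
                {
                    "chrom": variants.variants.at[v, "chrom"],
                    "pos": int(variants.variants.at[v, "pos"]),
                    "phenotype": pheno,
                    "hom_alt": int((sel == 2).sum()),
                    "het": int((sel == 1).sum()),
                    "hom_ref": int((sel == 0).sum()),
                    "missing": int((sel == MISSING).sum()),
                }
            )
    counts = pd.DataFrame(rows)

    discordant = []
    recombinant = []
    for s, lab in zip(known, labels):
        col = variants.genotypes[:, variants.sample_index(s)]
        nonmiss = col[col != MISSING]
        if lab == CASE and (nonmiss != 2).any():
            discordant.append(s)
        if lab == CONTROL and (nonmiss == 2).any():
            discordant.append(s)
        if len(nonmiss) > 1 and len(set(nonmiss.tolist())) > 1:
            recombinant.append(s)
    return ConcordanceTable(counts, discordant, recombinant)
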