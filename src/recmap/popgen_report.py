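"""Allele frequencies and Hardy-Weinberg expectations from DNA-test counts.

Given genotype counts (wild-type homozygotes, carriers, mutant
homozygotes) from a diagnostic DNA test, the mutant allele frequency is
q = (2 * n_mutant + n_carrier) / (2 * total), and under random mating the
expected carrier frequency is 2q(1-q) and the expected affected
frequency q^2. Report columns round half-up to the requested precision
through one guard digit (the convention of the source genotype tables);
raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_wild: int
    n_het: int
    n_hom_mutant: int

    def __post_init__(self) -> None:
        if min(self.n_hom_wild, self.n_het, self.n_hom_mutant) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_wild + self.n_het + self.n_hom_mutant

    def __sub__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_hom_wild - other.n_hom_wild,
            self.n_het - other.n_het,
            self.n_hom_mutant - other.n_hom_mutant,
        )


@dataclass(frozen=True)
class HWEReport:
    q: float  # mutant allele frequency
    p: float  # wild-type allele frequency
    carrier_frequency: float  # 2pq
    affected_frequency: float  # q^2


def _round_half_up(value: float, decimals: int) -> float:
    # staged half-up with one guard digit, the convention of the source
    # genotype tables (0.08046 -> 0.0805 -> 0.081)
    staged = Decimal(repr(value)).quantize(
        Decimal(1).scaleb(-(decimals + 1)), rounding=ROUND_HALF_UP
    )
    return float(staged.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def allele_frequency(counts: GenotypeCounts, decimals: int = 3) -> tuple[float, float]:
    """Mutant allele frequency, raw and rounded half-up to ``decimals``."""
    if counts.total == 0:
        raise ValueError("total genotype count must be positive")
    q = (2 * counts.n_hom_mutant + counts.n_het) / (2 * counts.total)
    return q, _round_half_up(q, decimals)


def hwe_expectations(q: float) -> HWEReport:
    """Hardy-Weinberg carrier and affected expectations for frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {q}")
    p = 1.0 - q
    return HWEReport(q=q, p=p, carrier_frequency=2 * p * q, affected_frequency=q * q)


def cohort_summary(
    cohorts: list[tuple[str, GenotypeCounts]],
    decimals: int = 3,
    exclusions: dict[str, GenotypeCounts] | None = None,
) -> pd.DataFrame:
    """Per-cohort genotype counts, allele frequency and HWE expectations.

    ``exclusions`` maps a cohort label to the genotype counts of excluded
    individuals (e.g. relatedness outliers); each such cohort gets a
    companion row with the exclusions subtracted. Zero exclusions give a
    companion row identical to the main row.
    """
    labels = [lab for lab, _ in cohorts]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate cohort labels")
    if not cohorts:
        raise ValueError("need at least one cohort")

    rows = []

    def add_row(label: str, counts: GenotypeCounts) -> None:
        q_raw, q_round = allele_frequency(counts, decimals)
        hwe = hwe_expectations(q_raw)
        rows.append(
            {
                "cohort": label,
                "n_hom_wild": counts.n_hom_wild,
                "n_het": counts.n_het,
                "n_hom_mutant": counts.n_hom_mutant,
                "total": counts.total,
                "allele_frequency_raw": q_raw,
                "allele_frequency": q_round,
                "expected_carrier_frequency": hwe.carrier_frequency,
                "expected_affected_frequency": hwe.affected_frequency,
            }
        )

    for label, counts in cohorts:
        add_row(label, counts)
        if exclusions is not None and label in exclusions:
            add_row(f"{label} (excluding outliers)", counts - exclusions[label])
    return pd.DataFrame(rows)
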