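"""Mobile-element insertion detection from read-pair evidence.

An inserted repetitive element leaves two local signatures in short-read
alignments against a reference lacking the element: read pairs whose mate
maps elsewhere in the genome (inside another copy of the element), and
reads soft-clipped at the breakpoint. The detector classifies records,
scans sliding windows for clustered support, and merges overlapping
candidate windows. Insertion length is estimated from amplicon-size
arithmetic (observed product minus the reference-allele product).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentRecord, Interval

CONCORDANT = "concordant"
INTERCHROM = "interchrom_discordant"
CLIPPED = "clipped"
OTHER = "other"


@dataclass
class InsertionCandidate:
    chromosome: str
    window_start: int
    window_end: int
    discordant_pairs: int
    soft_clips: int
    mate_chromosomes: list[str]
    depth: int
    support_fraction: float
    breakpoint: Interval

    @property
    def support(self) -> int:
        return self.discordant_pairs + self.soft_clips


def classify_pair(record: AlignmentRecord, clip_threshold: int = 10) -> str:
    """interchrom_discordant if the mate maps to a different chromosome,
    clipped if the larger soft clip reaches ``clip_threshold``, otherwise
    concordant when properly paired."""
    if record.mate_chromosome not in ("*", "") and record.mate_chromosome != record.chromosome:
        return INTERCHROM
    if max(record.soft_clip_left, record.soft_clip_right) >= clip_threshold:
        return CLIPPED
    return CONCORDANT if record.proper_pair else OTHER


def _clip_position(record: AlignmentRecord) -> int | None:
    """Breakpoint implied by the larger soft clip: the base after the last
    mapped base for a right clip, the first mapped base for a left clip."""
    if record.soft_clip_right >= record.soft_clip_left and record.soft_clip_right > 0:
        return record.end_bp + 1
    if record.soft_clip_left > 0:
        return record.position_bp
    return None


def detect_candidates(
    alignments: list[AlignmentRecord],
    window_bp: int = 200,
    step_bp: int = 50,
    min_support: int = 3,
    min_fraction: float = 0.2,
    clip_threshold: int = 10,
) -> list[InsertionCandidate]:
    """Scan for insertion candidates.

    Sliding windows of ``window_bp`` advanced by ``step_bp``; a window is a
    candidate iff (discordant + clipped) support >= ``min_support`` and
    support/depth >= ``min_fraction``. Overlapping candidate windows on one
    chromosome are merged; the reported breakpoint interval is the span of
    clip positions when clips exist, else the merged window. Results are
    invariant to input record order.
    """
    if not alignments:
        return []
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    candidates: list[InsertionCandidate] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.position_bp, r.read_id))
        classes = [classify_pair(r, clip_threshold) for r in recs]
        lo = min(r.position_bp for r in recs)
        hi = max(r.end_bp for r in recs)

        hits = []  # (start, end) of passing windows
        start = lo
        while start <= hi:
            end = start + window_bp - 1
            depth = support_d = support_c = 0
            for r, cls in zip(recs, classes):
                if r.position_bp <= end and r.end_bp >= start:
                    depth += 1
                    if cls == INTERCHROM:
                        support_d += 1
                    elif cls == CLIPPED:
                        support_c += 1
            support = support_d + support_c
            if depth > 0 and support >= min_support and support / depth >= min_fraction:
                hits.append((start, end))
            start += step_bp

        # merge overlapping/adjacent passing windows
        merged: list[list[int]] = []
        for s, e in hits:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])

        for s, e in merged:
            depth = support_d = support_c = 0
            mates: set[str] = set()
            clip_pos: list[int] = []
            for r, cls in zip(recs, classes):
                if r.position_bp <= e and r.end_bp >= s:
                    depth += 1
                    if cls == INTERCHROM:
                        support_d += 1
                        mates.add(r.mate_chromosome)
                    elif cls == CLIPPED:
                        support_c += 1
                        cp = _clip_position(r)
                        if cp is not None:
                            clip_pos.append(cp)
            if clip_pos:
                bkpt = Interval(chrom, min(clip_pos), max(clip_pos))
            else:
                bkpt = Interval(chrom, s, e)
            candidates.append(
                InsertionCandidate(
                    chromosome=chrom,
                    window_start=s,
                    window_end=e,
                    discordant_pairs=support_d,
                    soft_clips=support_c,
                    mate_chromosomes=sorted(mates),
                    depth=depth,
                    support_fraction=(support_d + support_c) / depth if depth else 0.0,
                    breakpoint=bkpt,
                )
            )
    return candidates


def estimate_insertion_length(
    observed_product_bp: float, expected_product_bp: float
) -> tuple[int, float]:
    """Insertion length from amplicon sizes: observed minus expected.

    Returns (length in bp, length in Kb rounded to one decimal). An
    observed product smaller than the reference-allele product supports
    no insertion and is an error.
    """
    if expected_product_bp <= 0:
        raise ValueError("expected product size must be positive")
    if observed_product_bp < expected_product_bp:
        raise ValueError("observed product smaller than expected: no insertion supported")
    length = int(round(observed_product_bp - expected_product_bp))
    return length, round(length / 1000.0, 1)
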