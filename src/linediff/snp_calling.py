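"""SNP-rate calling on pooled per-site base counts.

The central statistic is the SNP rate: the fraction of reads at a site
supporting the most frequent non-reference event (base substitution,
deletion, or insertion) out of the total base-supporting depth.  In a pool
of 2N haplotypes sequenced together, this fraction estimates the population
alternate-allele frequency, so fixed line-specific mutations appear as
sites with rates near 1.

Calling uses two permissive thresholds (minimum rate 5%, minimum variant
read count 2); the stringent >=75% rate and >=10 depth tiers applied later
in the cascade live in :mod:`linediff.line_differential`.  Base-quality
scores play no role anywhere: the design filters on pooled allele fractions
only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .io_formats import BASES, SiteCounts

__all__ = [
    "SnpCall",
    "VariantType",
    "snp_rate",
    "call_site",
    "render_called_base",
    "non_reference_events",
    "compute_coverage",
    "format_coverage",
]

DUAL_REF_FRAC = 0.20  # strict: dual call iff reference fraction > this


class VariantType(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"


@dataclass(frozen=True)
class SnpCall:
    """A called variant with its SNP rate and supporting counts.

    ``alt_allele`` is a base for substitutions, '-' for deletions, and the
    inserted sequence for insertions.  ``is_dual`` marks sites where the
    reference allele is retained at an appreciable fraction of the pool
    (rendered "REF|ALT").
    """

    contig: str
    pos: int
    ref_base: str
    alt_allele: str
    is_dual: bool
    snp_rate: float
    depth: int
    counts: SiteCounts
    variant_type: VariantType

    def __post_init__(self):
        if not 0.0 < self.snp_rate <= 1.0:
            raise ValueError(f"SNP rate {self.snp_rate} outside (0,1]")
        if (
            self.variant_type is VariantType.SUBSTITUTION
            and self.alt_allele == self.ref_base
        ):
            raise ValueError("substitution alt equals reference base")
        if self.depth != self.counts.depth:
            raise ValueError("call depth disagrees with counts depth")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    @property
    def allele_key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt_allele)


def non_reference_events(counts: SiteCounts) -> list[tuple[VariantType, str, int]]:
    """All candidate non-reference events, in fixed order A<C<G<T<del<ins.

    At an insertion anchor (reference '-') every observed inserted base is
    an insertion event and reads agreeing with the reference gap count as
    reference support.
    """
    events: list[tuple[VariantType, str, int]] = []
    if counts.ref_base == "-":
        base_counts = [(b, counts.base_count(b)) for b in BASES]
        if any(n for _, n in base_counts):
            for b, n in base_counts:
                events.append((VariantType.INSERTION, b, n))
        elif counts.count_ins > 0 or counts.ins_seq:
            events.append(
                (VariantType.INSERTION, counts.ins_seq or "N", counts.count_ins)
            )
        return events
    for b in BASES:
        if b != counts.ref_base:
            events.append((VariantType.SUBSTITUTION, b, counts.base_count(b)))
    events.append((VariantType.DELETION, "-", counts.count_del))
    if counts.count_ins > 0:
        events.append((VariantType.INSERTION, counts.ins_seq or "N", counts.count_ins))
    return events


def snp_rate(counts: SiteCounts) -> float:
    """Top non-reference event support divided by total depth.

    Ties between events break by the fixed order A<C<G<T<del<ins.  A site
    where all reads support the reference has rate 0.0; zero depth is an
    error.
    """
    if counts.depth < 1:
        raise ValueError(f"{counts.contig}:{counts.pos}: SNP rate undefined at depth 0")
    events = non_reference_events(counts)
    if not events:
        return 0.0
    top = max(n for _, _, n in events)
    return top / counts.depth


def call_site(
    counts: SiteCounts,
    min_rate: float = 0.05,
    min_count: int = 2,
    dual_ref_frac: float = DUAL_REF_FRAC,
) -> Optional[SnpCall]:
    """Call the top non-reference event, or no-call under the thresholds.

    No-call when the top event's read count is below ``min_count`` or the
    unrounded rate is below ``min_rate``.  The call is dual (reference
    retained) iff the reference-supporting fraction strictly exceeds
    ``dual_ref_frac``.
    """
    events = non_reference_events(counts)
    if not events or counts.depth < 1:
        return None
    vtype, alt, top = max(events, key=lambda ev: ev[2])  # first max wins ties
    rate = top / counts.depth
    if top < min_count or rate < min_rate:
        return None
    is_dual = (
        vtype is VariantType.SUBSTITUTION
        and counts.ref_support / counts.depth > dual_ref_frac
    )
    return SnpCall(
        contig=counts.contig, pos=counts.pos, ref_base=counts.ref_base,
        alt_allele=alt, is_dual=is_dual, snp_rate=rate, depth=counts.depth,
        counts=counts, variant_type=vtype,
    )


def render_called_base(call: SnpCall) -> str:
    """The marker table's "Called base": "T", dual "C|A", deletion "-"."""
    if call.variant_type is VariantType.DELETION:
        return "-"
    if call.variant_type is VariantType.INSERTION:
        return call.alt_allele
    if call.is_dual:
        return f"{call.ref_base}|{call.alt_allele}"
    return call.alt_allele


def compute_coverage(n_aligned_reads: int, read_length: int, genome_size: int) -> float:
    """Fold coverage: aligned reads x read length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_aligned_reads < 0 or read_length <= 0:
        raise ValueError("reads and read length must be non-negative / positive")
    return n_aligned_reads * read_length / genome_size


def format_coverage(fold: float) -> str:
    return f"{fold:.1f}x"
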