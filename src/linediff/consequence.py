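"""Coding-consequence annotation for pooled-line candidate SNPs.

Maps genomic variants onto spliced CDS coordinates of strand-aware gene
models, classifies the amino-acid-level impact (synonymous, non-synonymous,
nonsense, no-start, frameshift), and renders cDNA/protein change strings in
either standard HGVS-like notation ("c.368C>T", "T123I") or the spaced
dialect used in the source marker tables ("c.368C > T", stop rendered ".").

All genomic coordinates are 1-based and fully closed.  c. coordinates count
spliced CDS bases from the A of the initiator ATG, and all c. bases are
reported in CDS-strand orientation: for a minus-strand gene the genomic
reference and alternate bases are reverse-complemented before rendering.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

__all__ = [
    "Impact",
    "GeneModel",
    "CdsCoordinate",
    "Consequence",
    "ModelError",
    "map_to_cds",
    "classify_substitution",
    "classify_indel",
    "classify_region",
    "hgvs_cdna",
    "hgvs_protein",
    "cds_sequence",
    "codon_at",
    "translate_codon",
    "canonical_models",
    "annotate_site",
]

# Region labels (chromosomal feature classes used in the summaries).
REGION_CDS = "CDS"
REGION_UTR5 = "5'UTR"
REGION_UTR3 = "3'UTR"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"
REGION_FLANK = "upstream-downstream"

STOP = "."  # internal stop-codon symbol; '*' available via hgvs_protein dialect

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP
_START_CODON = "ATG"


class ModelError(ValueError):
    """Raised for malformed or inconsistent gene models."""


class Impact(str, enum.Enum):
    """Amino-acid-level impact class of a coding variant."""

    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    NONSENSE = "nonsense"
    NO_START = "no_start"
    FRAMESHIFT = "frameshift"

    @property
    def changes_protein(self) -> bool:
        return self is not Impact.SYNONYMOUS

    @classmethod
    def from_label(cls, label: str) -> "Impact":
        """Parse either the enum value or the marker-table label."""
        try:
            return cls(label)
        except ValueError:
            pass
        try:
            return _LABEL_TO_IMPACT[label]
        except KeyError:
            raise ValueError(f"unknown impact label {label!r}") from None

    @property
    def table_label(self) -> str:
        return _IMPACT_TO_LABEL[self]


_LABEL_TO_IMPACT = {
    "N-Syn": Impact.NON_SYNONYMOUS,
    "Syn": Impact.SYNONYMOUS,
    "Nonsense": Impact.NONSENSE,
    "No-start": Impact.NO_START,
    "Frameshift": Impact.FRAMESHIFT,
}
_IMPACT_TO_LABEL = {v: k for k, v in _LABEL_TO_IMPACT.items()}


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware transcript model: ordered CDS segments plus symbol.

    ``cds_segments`` are 1-based inclusive genomic intervals given in
    translation order: ascending coordinates on '+', descending on '-'.
    ``tx_start``/``tx_end`` bound the transcript (for UTR/intron calls);
    they default to the CDS span.
    """

    gene_symbol: str
    transcript_id: str
    contig: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    tx_start: int = 0
    tx_end: int = 0
    length_warning: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ModelError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.cds_segments:
            raise ModelError(f"{self.transcript_id}: no CDS segments")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ModelError(
                    f"{self.transcript_id}: overlapping CDS segments "
                    f"{(s1, e1)} and {(s2, e2)}"
                )
        expected = tuple(segs if self.strand == "+" else segs[::-1])
        if tuple(self.cds_segments) != expected:
            raise ModelError(
                f"{self.transcript_id}: CDS segments not in translation order"
            )
        if self.tx_start == 0:
            object.__setattr__(self, "tx_start", min(s for s, _ in segs))
        if self.tx_end == 0:
            object.__setattr__(self, "tx_end", max(e for _, e in segs))
        if self.cds_length % 3 != 0:
            object.__setattr__(self, "length_warning", True)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def cds_span(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.cds_segments),
            max(e for _, e in self.cds_segments),
        )

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end


@dataclass(frozen=True)
class CdsCoordinate:
    """Position within a spliced CDS, 1-based.

    ``codon_index`` is the 1-based residue number, ``codon_offset`` the
    1..3 position within that codon, so codon_index == ceil(cds_pos / 3)
    and codon_offset == cds_pos - 3 * (codon_index - 1).
    """

    cds_pos: int
    codon_index: int
    codon_offset: int

    @classmethod
    def from_cds_pos(cls, cds_pos: int) -> "CdsCoordinate":
        if cds_pos < 1:
            raise ValueError("cds_pos must be >= 1")
        codon_index = math.ceil(cds_pos / 3)
        return cls(cds_pos, codon_index, cds_pos - 3 * (codon_index - 1))


@dataclass(frozen=True)
class Consequence:
    """Classified impact plus rendered cDNA/protein change strings."""

    impact: Impact
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    inframe: bool = False


def translate_codon(codon: str) -> str:
    """Standard nuclear genetic code; stop rendered as '.'."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an ACGT trinucleotide: {codon!r}")
    return _CODON_TABLE[codon]


def map_to_cds(contig: str, pos: int, model: GeneModel) -> Union[CdsCoordinate, str]:
    """Map a genomic position onto a model's spliced CDS.

    Returns a :class:`CdsCoordinate` when the position falls inside a CDS
    segment; otherwise a region label (5'UTR / 3'UTR / intron /
    upstream-downstream) relative to this model.
    """
    if contig != model.contig:
        raise ValueError(
            f"contig mismatch: position on {contig!r}, model on {model.contig!r}"
        )
    acc = 0
    for s, e in model.cds_segments:
        if s <= pos <= e:
            if model.strand == "+":
                return CdsCoordinate.from_cds_pos(acc + (pos - s + 1))
            return CdsCoordinate.from_cds_pos(acc + (e - pos + 1))
        acc += e - s + 1
    if not model.contains(pos):
        return REGION_FLANK
    lo, hi = model.cds_span
    if pos < lo:
        return REGION_UTR5 if model.strand == "+" else REGION_UTR3
    if pos > hi:
        return REGION_UTR3 if model.strand == "+" else REGION_UTR5
    return REGION_INTRON


def cds_sequence(model: GeneModel, ref_map: Mapping[str, str]) -> str:
    """Spliced CDS sequence in translation orientation."""
    seq = ref_map[model.contig]
    parts = []
    for s, e in model.cds_segments:
        chunk = seq[s - 1 : e]
        parts.append(chunk if model.strand == "+" else reverse_complement(chunk))
    return "".join(parts)


def codon_at(model: GeneModel, ref_map: Mapping[str, str], codon_index: int) -> str:
    cds = cds_sequence(model, ref_map)
    start = 3 * (codon_index - 1)
    codon = cds[start : start + 3]
    if len(codon) != 3:
        raise ValueError(f"codon {codon_index} beyond CDS of {model.transcript_id}")
    return codon


def hgvs_cdna(
    cds_pos: int,
    ref_base: str,
    alt: str,
    variant_type: str,
    dialect: str = "standard",
) -> str:
    """Render a cDNA change string.

    ``variant_type`` is one of substitution / deletion / insertion; bases
    are in CDS-strand orientation.  The ``paper`` dialect reproduces the
    spaced marker-table forms ("c.368C > T", "c.388C > -", "c.105- > A").
    """
    if dialect == "paper":
        if variant_type == "substitution":
            return f"c.{cds_pos}{ref_base} > {alt}"
        if variant_type == "deletion":
            return f"c.{cds_pos}{ref_base} > -"
        if variant_type == "insertion":
            return f"c.{cds_pos}- > {alt}"
    elif dialect == "standard":
        if variant_type == "substitution":
            return f"c.{cds_pos}{ref_base}>{alt}"
        if variant_type == "deletion":
            return f"c.{cds_pos}del"
        if variant_type == "insertion":
            return f"c.{cds_pos}ins{alt}"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    raise ValueError(f"unknown variant type {variant_type!r}")


def hgvs_protein(
    ref_aa: str, alt_aa: str, codon_index: int, impact: Impact, stop_char: str = STOP
) -> str:
    """Render a protein change: "T123I", nonsense "Q51.", frameshift "Y130fs"."""
    ref_aa = stop_char if ref_aa == STOP else ref_aa
    alt_aa = stop_char if alt_aa == STOP else alt_aa
    if impact is Impact.FRAMESHIFT:
        return f"{ref_aa}{codon_index}fs"
    if impact is Impact.NONSENSE:
        return f"{ref_aa}{codon_index}{stop_char}"
    return f"{ref_aa}{codon_index}{alt_aa}"


def classify_substitution(
    ref_codon: str,
    alt_codon: str,
    codon_index: int,
    cds_pos: Optional[int] = None,
    dialect: str = "standard",
) -> Consequence:
    """Classify a single-base codon substitution.

    The no-start class takes precedence at codon 1 (any change away from an
    ATG initiator), then nonsense (sense codon to stop), then synonymous
    versus non-synonymous by the translated residue.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    if len(diffs) > 1:
        raise ValueError("codons differ at more than one position")
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if codon_index == 1 and alt_codon != _START_CODON:
        impact = Impact.NO_START
    elif alt_aa == STOP and ref_aa != STOP:
        impact = Impact.NONSENSE
    elif ref_aa == alt_aa:
        impact = Impact.SYNONYMOUS
    else:
        impact = Impact.NON_SYNONYMOUS
    cdna = ""
    if diffs:
        offset = diffs[0]
        pos = cds_pos if cds_pos is not None else 3 * (codon_index - 1) + offset + 1
        cdna = hgvs_cdna(pos, ref_codon[offset], alt_codon[offset], "substitution", dialect)
    return Consequence(
        impact=impact,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        cdna_change=cdna,
        protein_change=hgvs_protein(ref_aa, alt_aa, codon_index, impact),
    )


def classify_indel(
    event_length: int,
    is_insertion: bool,
    cds_coord: CdsCoordinate,
    ref_aa: str = "X",
) -> Consequence:
    """Classify a CDS indel: frameshift unless the length is a multiple of 3.

    ``ref_aa`` is the reference residue at the first affected codon (used in
    the "<refAA><codon>fs" rendering); in-frame indels are reported as
    non-synonymous with ``inframe`` set.
    """
    if event_length < 1:
        raise ValueError("indel event length must be >= 1")
    if event_length % 3 != 0:
        impact = Impact.FRAMESHIFT
        protein = hgvs_protein(ref_aa, "", cds_coord.codon_index, impact)
        return Consequence(impact=impact, ref_aa=ref_aa, protein_change=protein)
    return Consequence(impact=Impact.NON_SYNONYMOUS, ref_aa=ref_aa, inframe=True)


_REGION_PRECEDENCE = {
    REGION_CDS: 0,
    REGION_UTR5: 1,
    REGION_UTR3: 1,
    REGION_INTRON: 2,
    REGION_FLANK: 3,
}


def classify_region(contig: str, pos: int, models: Iterable[GeneModel]) -> str:
    """Feature class of a position over a set of gene models.

    Precedence when models overlap: CDS > UTR > intron > intergenic.
    Deterministic: ties resolve to the first model in input order.
    """
    best = REGION_INTERGENIC
    best_rank = 4
    for model in models:
        if model.contig != contig:
            continue
        hit = map_to_cds(contig, pos, model)
        label = REGION_CDS if isinstance(hit, CdsCoordinate) else hit
        rank = _REGION_PRECEDENCE[label]
        if rank < best_rank:
            best, best_rank = label, rank
    return REGION_INTERGENIC if best == REGION_FLANK else best


def canonical_models(models: Iterable[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: the longest CDS wins, ties by transcript id."""
    by_gene: dict[str, GeneModel] = {}
    for m in models:
        cur = by_gene.get(m.gene_symbol)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            by_gene[m.gene_symbol] = m
    return sorted(by_gene.values(), key=lambda m: (m.contig, m.cds_span[0]))


@dataclass(frozen=True)
class SiteAnnotation:
    """Consequence of one called variant against one chosen gene model."""

    region: str
    gene_symbol: str = ""
    consequence: Optional[Consequence] = None
    cds_coord: Optional[CdsCoordinate] = None


def annotate_site(
    contig: str,
    pos: int,
    ref_base: str,
    alt: str,
    variant_type: str,
    models: Sequence[GeneModel],
    ref_map: Mapping[str, str],
    dialect: str = "standard",
) -> SiteAnnotation:
    """Annotate one variant: pick the covering model and classify.

    ``alt`` is the genomic-strand alternate (a base for substitutions, the
    inserted sequence for insertions, ignored for deletions).  Model choice:
    the first model whose CDS contains the position; if none, the position's
    region class with the containing gene symbol when inside a transcript.
    """
    in_cds: Optional[tuple[GeneModel, CdsCoordinate]] = None
    region = REGION_INTERGENIC
    region_gene = ""
    best_rank = 4
    for model in models:
        if model.contig != contig:
            continue
        hit = map_to_cds(contig, pos, model)
        if isinstance(hit, CdsCoordinate):
            in_cds = (model, hit)
            break
        rank = _REGION_PRECEDENCE[hit]
        if rank < best_rank:
            best_rank = rank
            region = hit if hit != REGION_FLANK else REGION_INTERGENIC
            region_gene = model.gene_symbol if hit != REGION_FLANK else ""
    if in_cds is None:
        return SiteAnnotation(region=region, gene_symbol=region_gene)

    model, coord = in_cds
    if variant_type == "substitution":
        ref_codon = codon_at(model, ref_map, coord.codon_index)
        cds_ref = ref_codon[coord.codon_offset - 1]
        cds_alt = alt if model.strand == "+" else reverse_complement(alt)
        expected = ref_map[contig][pos - 1]
        if ref_base != expected:
            raise ValueError(
                f"reference mismatch at {contig}:{pos}: call says {ref_base!r}, "
                f"sequence has {expected!r}"
            )
        alt_codon = (
            ref_codon[: coord.codon_offset - 1]
            + cds_alt
            + ref_codon[coord.codon_offset :]
        )
        cons = classify_substitution(
            ref_codon, alt_codon, coord.codon_index, cds_pos=coord.cds_pos, dialect=dialect
        )
    else:
        is_ins = variant_type == "insertion"
        length = len(alt) if is_ins else max(len(ref_base.strip("-")), 1)
        try:
            ref_aa = translate_codon(codon_at(model, ref_map, coord.codon_index))
        except ValueError:
            ref_aa = "X"
        cons = classify_indel(length, is_ins, coord, ref_aa=ref_aa)
        if is_ins:
            cds_alt = alt if model.strand == "+" else reverse_complement(alt)
            cdna = hgvs_cdna(coord.cds_pos, "-", cds_alt, "insertion", dialect)
        else:
            cds_ref = codon_at(model, ref_map, coord.codon_index)[coord.codon_offset - 1]
            cdna = hgvs_cdna(coord.cds_pos, cds_ref, "-", "deletion", dialect)
        cons = Consequence(
            impact=cons.impact,
            ref_aa=cons.ref_aa,
            cdna_change=cdna,
            protein_change=cons.protein_change,
            inframe=cons.inframe,
        )
    return SiteAnnotation(
        region=REGION_CDS,
        gene_symbol=model.gene_symbol,
        consequence=cons,
        cds_coord=coord,
    )
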