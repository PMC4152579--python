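"""Readers and writers for every external format the pipeline touches.

Formats: FASTA reference, GFF3 gene models, VCF 4.2 call sets, the internal
per-site base-count TSV, the 16-column marker table, and the bird-panel
genotype TSV.  Coordinates are 1-based fully closed everywhere internally;
VCF emission follows VCF's own anchor-base conventions for indels.

The packaged fixtures under ``linediff/data`` transcribe the printed marker
table (156 amino-acid-changing candidate SNPs) and the 14-row Sanger
validation table of the source study, plus a contig-accession to chromosome
map for the galGal assembly accessions those tables use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO

from .consequence import GeneModel, Impact, ModelError

__all__ = [
    "SiteCounts",
    "MarkerSNP",
    "PanelRatio",
    "PanelObservation",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gff3",
    "read_site_counts",
    "write_site_counts",
    "read_marker_table",
    "write_marker_table",
    "read_panel",
    "write_vcf",
    "read_vcf",
    "VcfRecord",
    "load_marker_fixture",
    "load_validation_fixture",
    "load_contig_chrom_map",
]

IUPAC_NT = set("ACGTRYSWKMBDHVN")
BASES = "ACGT"


class FormatError(ValueError):
    """Malformed input file or row."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteCounts:
    """Per-site, per-line read support by event.

    For an ACGT reference base, ``depth == count_a + count_c + count_g +
    count_t + count_del`` (the marker table's Depth / A Cnt..Del columns).
    A reference base of '-' marks an insertion anchor: reads carrying the
    inserted sequence are in ``count_ins``/``ins_seq`` (single-base
    insertions may equivalently sit in the base columns, gapped-assembly
    style) and ``count_del`` counts reads agreeing with the reference gap.
    """

    contig: str
    pos: int
    ref_base: str
    count_a: int = 0
    count_c: int = 0
    count_g: int = 0
    count_t: int = 0
    count_del: int = 0
    count_ins: int = 0
    ins_seq: str = ""
    depth: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"{self.contig}:{self.pos}: pos must be >= 1")
        if self.ref_base not in ("A", "C", "G", "T", "-"):
            raise FormatError(
                f"{self.contig}:{self.pos}: ref base {self.ref_base!r} "
                "not in A,C,G,T,-"
            )
        for name in ("count_a", "count_c", "count_g", "count_t", "count_del",
                     "count_ins", "depth"):
            if getattr(self, name) < 0:
                raise FormatError(f"{self.contig}:{self.pos}: negative {name}")
        base_sum = (
            self.count_a + self.count_c + self.count_g + self.count_t + self.count_del
        )
        if self.ref_base == "-" and base_sum == self.count_del:
            # ins-column form: inserted reads recorded only in count_ins
            if self.depth != self.count_ins + self.count_del:
                raise FormatError(
                    f"{self.contig}:{self.pos}: depth {self.depth} != "
                    f"ins {self.count_ins} + del {self.count_del}"
                )
        elif self.depth != base_sum:
            raise FormatError(
                f"{self.contig}:{self.pos}: depth {self.depth} != "
                f"sum of base/del counts {base_sum}"
            )
        if self.ref_base == "-":
            # normalise: expose insertion support via count_ins/ins_seq
            if self.count_ins == 0:
                top, seq = max(
                    ((getattr(self, f"count_{b.lower()}"), b) for b in BASES),
                )
                if top > 0:
                    object.__setattr__(self, "count_ins", top)
                    object.__setattr__(self, "ins_seq", seq)

    def base_count(self, base: str) -> int:
        return getattr(self, f"count_{base.lower()}")

    @property
    def ref_support(self) -> int:
        """Reads agreeing with the reference at this site."""
        if self.ref_base == "-":
            return self.count_del
        return self.base_count(self.ref_base)


@dataclass(frozen=True)
class MarkerSNP:
    """One joined marker-table row: call, consequence and counts."""

    contig: str
    chrom: str
    pos: int
    ref_base: str
    called_base: str
    impact: Impact
    snp_rate: float
    gene_symbol: str
    dna_change: str
    aa_change: str
    depth: int
    counts: SiteCounts

    def __post_init__(self):
        if not 0.0 <= self.snp_rate <= 1.0:
            raise FormatError(
                f"{self.contig}:{self.pos}: SNP rate {self.snp_rate} outside [0,1]"
            )
        if self.depth < 1:
            raise FormatError(f"{self.contig}:{self.pos}: depth must be >= 1")


@dataclass(frozen=True)
class PanelRatio:
    """One validation-table row for one line at one marker position."""

    gene_symbol: str
    contig: str
    pos: int
    line_label: str
    ref_count: float
    alt_count: float
    ratio_text: str


@dataclass(frozen=True)
class PanelObservation:
    """A single bird's Sanger-style base call at one marker position."""

    bird_id: str
    line_label: str
    contig: str
    pos: int
    observed_bases: tuple[str, ...]

    def __post_init__(self):
        ok = {"A", "C", "G", "T", "-", "ins"}
        if not self.observed_bases or not set(self.observed_bases) <= ok:
            raise FormatError(
                f"{self.bird_id} at {self.contig}:{self.pos}: bad base call "
                f"{self.observed_bases!r}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into {accession: uppercase sequence}.

    IUPAC ambiguity codes are preserved; duplicate names, empty records and
    non-nucleotide characters are format errors (the latter naming the line).
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise FormatError(f"{path}: duplicate record name {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty record {rec.id!r}")
            bad = set(seq) - IUPAC_NT
            if bad:
                lineno = _locate_bad_line(path, bad)
                raise FormatError(
                    f"{path}:{lineno}: non-nucleotide character(s) "
                    f"{''.join(sorted(bad))!r} in record {rec.id!r}"
                )
            seqs[rec.id] = seq
    except FormatError:
        raise
    except ValueError:
        lineno, line = _first_content_line(path)
        raise FormatError(
            f"{path}:{lineno}: malformed header {str(line)[:30]!r}"
        ) from None
    if not seqs:
        lineno, line = _first_content_line(path)
        if line is None:
            raise FormatError(f"{path}: empty FASTA")
        raise FormatError(f"{path}:{lineno}: malformed header {line[:30]!r}")
    return seqs


def _locate_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def _first_content_line(path: Path):
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.strip():
                return i, line.strip()
    return 0, None


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: Union[str, Path]) -> list[GeneModel]:
    """Load transcript models (gene/mRNA/CDS) from GFF3.

    Per transcript the CDS segments are returned in translation order.
    A CDS length not divisible by 3 is tolerated (``length_warning`` set,
    warning emitted); orphan CDS features are model errors.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known_ids = {f.id for f in db.all_features()}
    models: list[GeneModel] = []
    orphans = [
        f.id
        for f in db.features_of_type("CDS")
        if not f.attributes.get("Parent")
        or f.attributes["Parent"][0] not in known_ids
    ]
    if orphans:
        raise ModelError(f"CDS feature(s) without parent transcript: {orphans}")
    for tx in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(
            db.children(tx, featuretype="CDS", order_by="start"),
            key=lambda f: f.start,
        )
        if not cds:
            continue
        segs = [(f.start, f.end) for f in cds]
        if tx.strand == "-":
            segs = segs[::-1]
        gene_symbol = tx.id
        parents = list(db.parents(tx, featuretype="gene"))
        src = parents[0] if parents else tx
        for key in ("gene_name", "Name", "gene", "ID"):
            if key in src.attributes:
                gene_symbol = src.attributes[key][0]
                break
        model = GeneModel(
            gene_symbol=gene_symbol,
            transcript_id=tx.id,
            contig=tx.seqid,
            strand=tx.strand,
            cds_segments=tuple(segs),
            tx_start=tx.start,
            tx_end=tx.end,
        )
        if model.length_warning:
            warnings.warn(
                f"{tx.id}: CDS length {model.cds_length} not divisible by 3",
                stacklevel=2,
            )
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: Union[str, Path]) -> None:
    """Emit gene/mRNA/CDS features (with phase) for a set of models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.contig, m.tx_start)):
            gid, tid = f"gene-{m.gene_symbol}", m.transcript_id
            fh.write(
                f"{m.contig}\tlinediff\tgene\t{m.tx_start}\t{m.tx_end}\t.\t"
                f"{m.strand}\t.\tID={gid};Name={m.gene_symbol}\n"
            )
            fh.write(
                f"{m.contig}\tlinediff\tmRNA\t{m.tx_start}\t{m.tx_end}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={gid}\n"
            )
            acc = 0
            for i, (s, e) in enumerate(m.cds_segments):
                phase = (3 - acc % 3) % 3
                fh.write(
                    f"{m.contig}\tlinediff\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds-{tid}-{i};Parent={tid}\n"
                )
                acc += e - s + 1


# ---------------------------------------------------------------------------
# per-site counts TSV
# ---------------------------------------------------------------------------

_COUNTS_COLS = ["contig", "pos", "ref", "A", "C", "G", "T", "del", "ins", "ins_seq"]


def read_site_counts(path: Union[str, Path]) -> Iterator[SiteCounts]:
    """Stream SiteCounts from the internal counts TSV (header mandatory)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "ins_seq": str})
    missing = [c for c in _COUNTS_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.rename(columns={"del": "del_"})
    for row in df.itertuples(index=False):
        ins_seq = "" if pd.isna(row.ins_seq) or row.ins_seq == "." else str(row.ins_seq)
        counts = {
            "count_a": int(row.A),
            "count_c": int(row.C),
            "count_g": int(row.G),
            "count_t": int(row.T),
            "count_del": int(row.del_),
            "count_ins": int(row.ins),
        }
        depth = sum(v for k, v in counts.items() if k != "count_ins")
        if str(row.ref) == "-" and depth == counts["count_del"]:
            depth = counts["count_ins"] + counts["count_del"]
        try:
            yield SiteCounts(
                contig=str(row.contig),
                pos=int(row.pos),
                ref_base=str(row.ref),
                ins_seq=ins_seq,
                depth=depth,
                **counts,
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None


def write_site_counts(counts: Iterable[SiteCounts], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COUNTS_COLS) + "\n")
        for c in counts:
            fh.write(
                f"{c.contig}\t{c.pos}\t{c.ref_base}\t{c.count_a}\t{c.count_c}\t"
                f"{c.count_g}\t{c.count_t}\t{c.count_del}\t{c.count_ins}\t"
                f"{c.ins_seq or '.'}\n"
            )


# ---------------------------------------------------------------------------
# marker table (16 columns mirroring the printed candidate-SNP table)
# ---------------------------------------------------------------------------

_MARKER_COLS = [
    "contig", "chrom", "pos", "ref_base", "called_base", "impact", "snp_rate",
    "gene_symbol", "dna_change", "aa_change", "depth",
    "a_cnt", "c_cnt", "g_cnt", "t_cnt", "del_cnt",
]


def read_marker_table(path: Union[str, Path]) -> list[MarkerSNP]:
    """Load a marker TSV.

    The packaged fixture resolves the printed table's "-" placeholder (the
    reference base's own count) to depth minus the other counts; the column
    that held it is kept in ``raw_ref_col`` for provenance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty marker table", stacklevel=2)
        return []
    missing = [c for c in _MARKER_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    markers = []
    for row in df.itertuples(index=False):
        depth = int(row.depth)
        raw = {b: row_val for b, row_val in zip(
            "ACGTD", (row.a_cnt, row.c_cnt, row.g_cnt, row.t_cnt, row.del_cnt))}
        nums: dict[str, Optional[int]] = {}
        hole = None
        for b, v in raw.items():
            if v == "-":
                if hole is not None:
                    raise FormatError(
                        f"{path}: {row.contig}:{row.pos}: multiple '-' placeholders"
                    )
                hole, nums[b] = b, None
            else:
                nums[b] = int(v)
        if hole is not None:
            nums[hole] = depth - sum(v for v in nums.values() if v is not None)
            if nums[hole] < 0:
                raise FormatError(
                    f"{path}: {row.contig}:{row.pos}: counts exceed depth"
                )
        ref, called = str(row.ref_base), str(row.called_base)
        if "|" in called:
            parts = called.split("|")
            if len(parts) != 2 or not all(p in set(BASES) for p in parts):
                raise FormatError(
                    f"{path}: {row.contig}:{row.pos}: unparsable dual allele {called!r}"
                )
        kwargs = dict(
            contig=str(row.contig), pos=int(row.pos), ref_base=ref,
            count_a=nums["A"], count_c=nums["C"], count_g=nums["G"],
            count_t=nums["T"], count_del=nums["D"], depth=depth,
        )
        counts = SiteCounts(**kwargs)
        rate = float(row.snp_rate)
        markers.append(
            MarkerSNP(
                contig=str(row.contig), chrom=str(row.chrom), pos=int(row.pos),
                ref_base=ref, called_base=called,
                impact=Impact.from_label(str(row.impact)), snp_rate=rate,
                gene_symbol=str(row.gene_symbol), dna_change=str(row.dna_change),
                aa_change=str(row.aa_change), depth=depth, counts=counts,
            )
        )
    return markers


def write_marker_table(markers: Iterable[MarkerSNP], path: Union[str, Path]) -> None:
    rows = []
    for m in markers:
        c = m.counts
        base_cols = {b: c.base_count(b) for b in BASES}
        # insertion anchors store inserted-read support in the inserted
        # base's column (gapped-assembly style), as the printed table does
        if m.ref_base == "-" and c.count_ins and not any(base_cols.values()):
            base_cols[c.ins_seq[0] if c.ins_seq else "A"] = c.count_ins
        m = replace(m, counts=replace(
            c, count_a=base_cols["A"], count_c=base_cols["C"],
            count_g=base_cols["G"], count_t=base_cols["T"],
        ))
        rows.append({
            "contig": m.contig, "chrom": m.chrom, "pos": m.pos,
            "ref_base": m.ref_base, "called_base": m.called_base,
            "impact": m.impact.table_label, "snp_rate": f"{m.snp_rate:.2f}",
            "gene_symbol": m.gene_symbol, "dna_change": m.dna_change,
            "aa_change": m.aa_change, "depth": m.depth,
            "a_cnt": m.counts.count_a, "c_cnt": m.counts.count_c,
            "g_cnt": m.counts.count_g, "t_cnt": m.counts.count_t,
            "del_cnt": m.counts.count_del, "raw_ref_col": ".",
        })
    pd.DataFrame(rows, columns=_MARKER_COLS + ["raw_ref_col"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bird panel TSV
# ---------------------------------------------------------------------------


def read_panel(path: Union[str, Path]) -> list[PanelObservation]:
    """Panel TSV: bird_id, line, contig, pos, base1, base2 ('.' if absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["bird_id", "line", "contig", "pos", "base1", "base2"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    obs = []
    for row in df.itertuples(index=False):
        bases = tuple(
            b for b in (row.base1, row.base2) if isinstance(b, str) and b != "."
        )
        obs.append(
            PanelObservation(
                bird_id=str(row.bird_id), line_label=str(row.line),
                contig=str(row.contig), pos=int(row.pos), observed_bases=bases,
            )
        )
    return obs


def write_panel(obs: Iterable[PanelObservation], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("bird_id\tline\tcontig\tpos\tbase1\tbase2\n")
        for o in obs:
            b = list(o.observed_bases) + ["."] * (2 - len(o.observed_bases))
            fh.write(
                f"{o.bird_id}\t{o.line_label}\t{o.contig}\t{o.pos}\t{b[0]}\t{b[1]}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VcfRecord:
    """A re-read VCF line in the terms the writer emits."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depth: int
    snp_rate: float
    is_dual: bool


def write_vcf(calls: Sequence, ref_map: Mapping[str, str], path: Union[str, Path]) -> None:
    """Write calls to VCF 4.2 with INFO DP (depth) and SR (SNP rate).

    Dual calls (reference retained at appreciable fraction) are emitted as a
    single record with the non-reference ALT and FILTER tag ``DUAL``.
    Indels are left-normalised with an anchor base: a deletion of base X at
    pos P becomes (P-1, REF=aX, ALT=a); an insertion of S after pos P
    becomes (P, REF=b, ALT=bS), a and b being reference bases.
    """
    header = pysam.VariantHeader()
    for contig, seq in ref_map.items():
        header.contigs.add(contig, length=len(seq))
    header.info.add("DP", 1, "Integer", "Total base-supporting read depth")
    header.info.add("SR", 1, "Float", "SNP rate (top non-reference support / depth)")
    header.filters.add("DUAL", None, None, "Reference allele retained (dual call)")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
            seq = ref_map[call.contig]
            vtype = getattr(call.variant_type, "value", call.variant_type)
            if vtype == "substitution":
                ref_here = seq[call.pos - 1]
                if ref_here != call.ref_base:
                    raise FormatError(
                        f"{call.contig}:{call.pos}: call ref {call.ref_base!r} "
                        f"disagrees with reference {ref_here!r}"
                    )
                pos, ref, alt = call.pos, call.ref_base, call.alt_allele
            elif vtype == "deletion":
                ref_here = seq[call.pos - 1]
                if ref_here != call.ref_base:
                    raise FormatError(
                        f"{call.contig}:{call.pos}: call ref {call.ref_base!r} "
                        f"disagrees with reference {ref_here!r}"
                    )
                if call.pos == 1:
                    pos, ref, alt = 1, seq[0:2], seq[1]
                else:
                    anchor = seq[call.pos - 2]
                    pos, ref, alt = call.pos - 1, anchor + call.ref_base, anchor
            elif vtype == "insertion":
                anchor = seq[call.pos - 1]
                pos, ref, alt = call.pos, anchor, anchor + call.alt_allele
            else:
                raise FormatError(f"unknown variant type {vtype!r}")
            rec = vf.new_record(
                contig=call.contig, start=pos - 1, stop=pos + len(ref) - 1,
                alleles=(ref, alt),
            )
            rec.info["DP"] = int(call.depth)
            rec.info["SR"] = round(float(call.snp_rate), 4)
            if getattr(call, "is_dual", False):
                rec.filter.add("DUAL")
            else:
                rec.filter.add("PASS")
            vf.write(rec)


def read_vcf(path: Union[str, Path]) -> list[VcfRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            out.append(
                VcfRecord(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref,
                    alts=tuple(rec.alts or ()), depth=int(rec.info["DP"]),
                    snp_rate=float(rec.info["SR"]),
                    is_dual="DUAL" in rec.filter.keys(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("linediff") / "data" / name)


def load_marker_fixture() -> list[MarkerSNP]:
    """The 156 printed amino-acid-changing candidate marker SNPs."""
    return read_marker_table(_data_path("table2_markers.tsv"))


def load_validation_fixture() -> pd.DataFrame:
    """The 14-row Sanger validation table (per-line ratio strings)."""
    return pd.read_csv(_data_path("table3_validation.tsv"), sep="\t", dtype=str)


def load_contig_chrom_map() -> dict[str, str]:
    """Contig accession -> chromosome label for the assembly the tables use."""
    df = pd.read_csv(_data_path("contig_chrom_map.tsv"), sep="\t", dtype=str)
    return dict(zip(df["contig"], df["chrom"]))
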