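"""Two-line pooled sequencing simulator with known ground truth.

Emulates the study design the pipeline targets: two pools of ``pool_size``
diploid birds (default 10 per line), sequenced together so per-site read
fractions estimate population allele frequencies.  The generator builds a
random reference with strand-mixed multi-exon gene models, plants shared
and line-specific variants at configurable allele frequencies (frequency
1.0 gives the fixed, homozygous line-specific mutations the discovery
cascade is designed to catch), samples per-bird genotypes binomially, and
simulates per-site base counts with Poisson depth and a uniform miscall
error.

Ground-truth impact classes are computed here by direct codon translation
against an inline genetic-code table — deliberately independent of
:mod:`linediff.consequence`, so recovery evaluation cross-checks the
annotator rather than echoing it.

Default scale (2 contigs x 100 kb, 20 genes, 200 planted variants) runs the
full pipeline in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .consequence import GeneModel
from .io_formats import PanelObservation, SiteCounts

__all__ = [
    "SimConfig",
    "TruthRecord",
    "StudyData",
    "RecoveryReport",
    "generate_reference",
    "plant_variants",
    "simulate_counts",
    "simulate_panel",
    "simulate_study",
    "evaluate_recovery",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")

# Standard nuclear genetic code, transcribed here by hand (positions ordered
# A,C,G,T) so truth impacts never route through the annotator's table.
_AA_BY_INDEX = (
    "KNKN" "TTTT" "RSRS" "IIMI"   # AA* AC* AG* AT*
    "QHQH" "PPPP" "RRRR" "LLLL"   # CA* CC* CG* CT*
    "EDED" "AAAA" "GGGG" "VVVV"   # GA* GC* GG* GT*
    ".Y.Y" "SSSS" ".CWC" "LFLF"   # TA* TC* TG* TT*
)
CODON_TABLE = {
    b1 + b2 + b3: _AA_BY_INDEX[16 * i + 4 * j + k]
    for i, b1 in enumerate(BASES)
    for j, b2 in enumerate(BASES)
    for k, b3 in enumerate(BASES)
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the simulator.

    Defaults mirror the emulated design: 10-bird diploid pools per line,
    mean per-site depth in the 5-7x band of the real libraries (6.0), a
    small uniform miscall rate, and line-specific variants fixed at allele
    frequency 1.0 while shared polymorphisms segregate at 0.5.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    gc_fraction: float = 0.42
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 4)
    pool_size: int = 10
    depth_mean: float = 6.0
    error_rate: float = 0.005
    n_shared: int = 80
    n_case_only: int = 80
    n_control_only: int = 40
    coding_fraction: float = 0.5
    indel_fraction: float = 0.1
    case_allele_freq: float = 1.0
    control_allele_freq: float = 1.0
    shared_allele_freq: float = 0.5
    case_label: str = "SL"
    control_label: str = "BL"

    def __post_init__(self):
        for name in ("gc_fraction", "error_rate", "coding_fraction",
                     "indel_fraction", "case_allele_freq",
                     "control_allele_freq", "shared_allele_freq"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """One planted variant with its per-line frequencies and true impact."""

    contig: str
    pos: int
    ref: str
    alt: str
    variant_type: str  # substitution / deletion / insertion
    line_specificity: str  # shared / case_only / control_only
    allele_freq_case: float
    allele_freq_control: float
    impact: str  # noncoding, synonymous, non_synonymous, nonsense, no_start, frameshift
    gene_symbol: str = ""

    def __post_init__(self):
        if not (0.0 <= self.allele_freq_case <= 1.0
                and 0.0 <= self.allele_freq_control <= 1.0):
            raise ValueError("allele frequencies outside [0,1]")
        if self.line_specificity == "case_only" and self.allele_freq_control > 0:
            raise ValueError("case-only variant with nonzero control frequency")
        if self.line_specificity == "control_only" and self.allele_freq_case > 0:
            raise ValueError("control-only variant with nonzero case frequency")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus strand-mixed multi-exon gene models.

    Every CDS starts with ATG, ends with a stop codon, has length divisible
    by 3 and no internal in-frame stop.  Deterministic given the config
    seed.  Raises if the requested genes cannot fit on the contigs.
    """
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ref: dict[str, str] = {}
    for i in range(config.n_contigs):
        arr = rng.choice(list(BASES), size=config.contig_length, p=probs)
        ref[f"ctg{i + 1}"] = "".join(arr)

    models: list[GeneModel] = []
    if config.n_genes == 0:
        return ref, models
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1
    gene_no = 0
    for ci, (contig, n_here) in enumerate(zip(ref, per_contig)):
        if n_here == 0:
            continue
        slot = config.contig_length // n_here
        if slot < 2500:
            raise ValueError(
                f"infeasible geometry: {n_here} genes do not fit on a "
                f"{config.contig_length} bp contig"
            )
        for g in range(n_here):
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            n_codons = int(rng.integers(60, 201))
            cds_len = 3 * n_codons
            body = "".join(
                _CODONS_NONSTOP[j]
                for j in rng.integers(0, len(_CODONS_NONSTOP), size=n_codons - 2)
            )
            stop = _STOPS[int(rng.integers(0, 3))]
            cds_seq = "ATG" + body + stop
            # split CDS into exon chunks (each >= 10 bp)
            cuts = sorted(rng.choice(
                np.arange(10, cds_len - 9), size=n_exons - 1, replace=False
            )) if n_exons > 1 else []
            chunk_lens = np.diff([0, *cuts, cds_len]).astype(int)
            introns = rng.integers(60, 301, size=n_exons - 1)
            gene_span = int(chunk_lens.sum() + introns.sum())
            utr5, utr3 = int(rng.integers(20, 80)), int(rng.integers(20, 80))
            max_start = slot * g + slot - gene_span - utr3 - 10
            min_start = slot * g + utr5 + 10
            if max_start <= min_start:
                raise ValueError("infeasible geometry: gene does not fit in slot")
            start = int(rng.integers(min_start, max_start))
            # genomic segments left to right
            segs = []
            at = start
            for k, ln in enumerate(chunk_lens):
                segs.append((at + 1, at + int(ln)))  # 1-based inclusive
                at += int(ln)
                if k < n_exons - 1:
                    at += int(introns[k])
            # write CDS into the genome
            seq = ref[contig]
            if strand == "+":
                offset = 0
                for (s, e) in segs:
                    ln = e - s + 1
                    seq = seq[: s - 1] + cds_seq[offset : offset + ln] + seq[e:]
                    offset += ln
                order = tuple(segs)
            else:
                rc = _revcomp(cds_seq)
                offset = 0
                for (s, e) in segs:
                    ln = e - s + 1
                    seq = seq[: s - 1] + rc[offset : offset + ln] + seq[e:]
                    offset += ln
                order = tuple(segs[::-1])
            ref[contig] = seq
            symbol = f"GENE{gene_no:03d}"
            models.append(
                GeneModel(
                    gene_symbol=symbol, transcript_id=f"{symbol}.t1",
                    contig=contig, strand=strand, cds_segments=order,
                    tx_start=max(1, segs[0][0] - utr5),
                    tx_end=min(len(seq), segs[-1][1] + utr3),
                )
            )
    return ref, models


_CODONS_NONSTOP = [c for c in (a + b + d for a in BASES for b in BASES for d in BASES)
                   if c not in _STOPS]


def _spliced_cds(model: GeneModel, ref: Mapping[str, str]) -> str:
    seq = ref[model.contig]
    parts = []
    for s, e in model.cds_segments:
        chunk = seq[s - 1 : e]
        parts.append(chunk if model.strand == "+" else _revcomp(chunk))
    return "".join(parts)


def _genomic_pos_of_cds(model: GeneModel, cds_pos: int) -> int:
    acc = 0
    for s, e in model.cds_segments:
        ln = e - s + 1
        if cds_pos <= acc + ln:
            within = cds_pos - acc
            return s + within - 1 if model.strand == "+" else e - within + 1
        acc += ln
    raise ValueError("cds_pos beyond CDS")


def _truth_impact_substitution(cds: str, cds_pos: int, cds_alt: str) -> str:
    """Direct-translation impact check, independent of the annotator."""
    idx = (cds_pos - 1) // 3
    off = (cds_pos - 1) % 3
    ref_codon = cds[3 * idx : 3 * idx + 3]
    alt_codon = ref_codon[:off] + cds_alt + ref_codon[off + 1 :]
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if idx == 0 and alt_codon != "ATG":
        return "no_start"
    if alt_aa == "." and ref_aa != ".":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "non_synonymous"


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


@dataclass
class Genotypes:
    """Per-line, per-variant, per-bird alternate-allele counts (0/1/2)."""

    case: np.ndarray  # shape (n_variants, pool_size)
    control: np.ndarray


def plant_variants(
    ref: Mapping[str, str],
    models: Sequence[GeneModel],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[TruthRecord], Genotypes]:
    """Plant shared / case-only / control-only variants and draw genotypes.

    Coding variants are placed inside CDS segments; substitutions are
    resampled until amino-acid-changing (the discovery target), so the true
    impact of every planted coding variant is protein-altering by
    construction.  Each bird's genotype at a variant is Binomial(2, f) in
    the line(s) carrying it: f = 1.0 plants fixed homozygous differences.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    classes = (
        [("shared", config.shared_allele_freq, config.shared_allele_freq)]
        * config.n_shared
        + [("case_only", config.case_allele_freq, 0.0)] * config.n_case_only
        + [("control_only", 0.0, config.control_allele_freq)] * config.n_control_only
    )
    coding_capacity = sum(m.cds_length for m in models)
    n_coding_wanted = round(len(classes) * config.coding_fraction)
    if n_coding_wanted > coding_capacity // 10:
        raise ValueError(
            f"requested ~{n_coding_wanted} coding variants exceed available "
            f"CDS space ({coding_capacity} bp)"
        )
    used: set[tuple[str, int]] = set()
    cds_cache = {m.gene_symbol: _spliced_cds(m, ref) for m in models}
    truth: list[TruthRecord] = []

    for i, (spec, f_case, f_control) in enumerate(classes):
        coding = models and (i % 2 == 0 if config.coding_fraction == 0.5
                             else rng.random() < config.coding_fraction)
        is_indel = rng.random() < config.indel_fraction
        for _ in range(200):  # rejection-sample a placement
            if coding:
                m = models[int(rng.integers(0, len(models)))]
                cds = cds_cache[m.gene_symbol]
                # avoid the stop codon; keep indels off codon 1
                lo = 4 if is_indel else 1
                cds_pos = int(rng.integers(lo, len(cds) - 2))
                pos = _genomic_pos_of_cds(m, cds_pos)
                contig = m.contig
                if (contig, pos) in used:
                    continue
                ref_base = ref[contig][pos - 1]
                if is_indel:
                    if rng.random() < 0.5:
                        vtype, alt = "deletion", "-"
                        impact = "frameshift"
                    else:
                        vtype = "insertion"
                        alt = BASES[int(rng.integers(0, 4))]
                        impact = "frameshift"
                else:
                    cds_ref = cds[cds_pos - 1]
                    choices = [b for b in BASES if b != cds_ref]
                    cds_alt = choices[int(rng.integers(0, 3))]
                    impact = _truth_impact_substitution(cds, cds_pos, cds_alt)
                    if impact == "synonymous":
                        continue
                    vtype = "substitution"
                    alt = cds_alt if m.strand == "+" else _revcomp(cds_alt)
                gene = m.gene_symbol
            else:
                contig = list(ref)[int(rng.integers(0, len(ref)))]
                pos = int(rng.integers(1, len(ref[contig]) + 1))
                if (contig, pos) in used:
                    continue
                if any(m2.contig == contig and m2.contains(pos) for m2 in models):
                    continue  # keep non-coding variants outside transcripts
                ref_base = ref[contig][pos - 1]
                if is_indel:
                    vtype, alt = ("deletion", "-") if rng.random() < 0.5 else (
                        "insertion", BASES[int(rng.integers(0, 4))])
                else:
                    vtype = "substitution"
                    choices = [b for b in BASES if b != ref_base]
                    alt = choices[int(rng.integers(0, 3))]
                impact, gene = "noncoding", ""
            used.add((contig, pos))
            truth.append(
                TruthRecord(
                    contig=contig, pos=pos,
                    ref="-" if vtype == "insertion" else ref_base, alt=alt,
                    variant_type=vtype, line_specificity=spec,
                    allele_freq_case=f_case, allele_freq_control=f_control,
                    impact=impact, gene_symbol=gene,
                )
            )
            break
        else:
            raise ValueError("could not place a planted variant (genome too small?)")

    n = len(truth)
    fc = np.array([t.allele_freq_case for t in truth])[:, None]
    fb = np.array([t.allele_freq_control for t in truth])[:, None]
    geno = Genotypes(
        case=rng.binomial(2, np.broadcast_to(fc, (n, config.pool_size))),
        control=rng.binomial(2, np.broadcast_to(fb, (n, config.pool_size))),
    )
    return truth, geno


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    truth: Sequence[TruthRecord],
    genotypes: np.ndarray,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SiteCounts]:
    """Per-site base counts for one line at every planted position.

    Depth is Poisson(``depth_mean``); each read samples a haplotype from a
    uniformly chosen bird (alternate with probability genotype/2) and is
    miscalled to a uniform different base with probability ``error_rate``.
    Insertion anchors are emitted as reference-'-' rows with the inserted
    reads in ``count_ins``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    out: list[SiteCounts] = []
    for i, t in enumerate(truth):
        depth = int(rng.poisson(config.depth_mean))
        if depth == 0:
            continue
        birds = rng.integers(0, config.pool_size, size=depth)
        hap_alt = rng.random(depth) < genotypes[i, birds] / 2.0
        tallies = {b: 0 for b in BASES}
        n_del = n_ins = 0
        for alt_read in hap_alt:
            if alt_read and t.variant_type == "deletion":
                n_del += 1
                continue
            if alt_read and t.variant_type == "insertion":
                n_ins += 1
                continue
            base = t.alt if alt_read else (
                t.ref if t.ref != "-" else None
            )
            if base is None:  # ref read at an insertion anchor: agrees with gap
                n_del += 1
                continue
            if config.error_rate and rng.random() < config.error_rate:
                others = [b for b in BASES if b != base]
                base = others[int(rng.integers(0, 3))]
            tallies[base] += 1
        if t.variant_type == "insertion":
            out.append(
                SiteCounts(
                    contig=t.contig, pos=t.pos, ref_base="-",
                    count_ins=n_ins, ins_seq=t.alt, count_del=depth - n_ins,
                    depth=depth,
                )
            )
        else:
            out.append(
                SiteCounts(
                    contig=t.contig, pos=t.pos, ref_base=t.ref,
                    count_a=tallies["A"], count_c=tallies["C"],
                    count_g=tallies["G"], count_t=tallies["T"],
                    count_del=n_del, depth=depth,
                )
            )
    return out


def simulate_panel(
    truth: Sequence[TruthRecord],
    config: SimConfig,
    n_case_birds: int = 70,
    n_control_birds: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> list[PanelObservation]:
    """Per-bird Sanger-style genotype calls at every planted position."""
    rng = rng or np.random.default_rng(config.seed + 3)
    obs: list[PanelObservation] = []
    for t in truth:
        alt_symbol = "ins" if t.variant_type == "insertion" else (
            "-" if t.variant_type == "deletion" else t.alt
        )
        ref_symbol = t.ref if t.ref != "-" else "-"
        for line, freq, n_birds in (
            (config.case_label, t.allele_freq_case, n_case_birds),
            (config.control_label, t.allele_freq_control, n_control_birds),
        ):
            g = rng.binomial(2, freq, size=n_birds)
            for b, gi in enumerate(g):
                if gi == 0:
                    bases: tuple[str, ...] = (ref_symbol,)
                elif gi == 2:
                    bases = (alt_symbol,)
                else:
                    bases = (ref_symbol, alt_symbol)
                obs.append(
                    PanelObservation(
                        bird_id=f"{line}{b + 1:03d}", line_label=line,
                        contig=t.contig, pos=t.pos, observed_bases=bases,
                    )
                )
    return obs


# ---------------------------------------------------------------------------
# study bundle + recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Everything one simulated two-line study produces."""

    config: SimConfig
    reference: dict[str, str]
    models: list[GeneModel]
    truth: list[TruthRecord]
    genotypes: Genotypes
    case_counts: list[SiteCounts]
    control_counts: list[SiteCounts]

    def counts_by_pos(self, line: str = "case") -> dict[tuple[str, int], SiteCounts]:
        counts = self.case_counts if line == "case" else self.control_counts
        return {(c.contig, c.pos): c for c in counts}


def simulate_study(config: SimConfig) -> StudyData:
    """Run the full generator: reference, models, truth, per-line counts.

    All randomness flows from one generator seeded by ``config.seed``, so a
    study is exactly reproducible.
    """
    rng = np.random.default_rng(config.seed)
    reference, models = generate_reference(config, rng)
    truth, geno = plant_variants(reference, models, config, rng)
    case_counts = simulate_counts(truth, geno.case, config, rng)
    control_counts = simulate_counts(truth, geno.control, config, rng)
    return StudyData(config, reference, models, truth, geno,
                     case_counts, control_counts)


_AA_CHANGING = {"non_synonymous", "nonsense", "no_start", "frameshift"}


@dataclass
class RecoveryReport:
    """Precision/recall of marker discovery against the planted truth."""

    precision: float
    recall: float
    n_eligible: int
    n_reported: int
    n_true_positive: int
    confusion: dict[tuple[str, str], int]
    false_positives: list[tuple[str, int]] = field(default_factory=list)
    false_negatives: list[tuple[str, int]] = field(default_factory=list)


def evaluate_recovery(
    markers: Sequence,
    truth: Sequence[TruthRecord],
    case_counts: Optional[Mapping[tuple[str, int], SiteCounts]] = None,
    min_rate: float = 0.75,
    min_depth: int = 10,
) -> RecoveryReport:
    """Score reported markers against planted case-only coding variants.

    Eligible truth = case-only, amino-acid-changing variants that pass the
    design thresholds in the simulated case counts (depth >= ``min_depth``
    and true-allele support fraction >= ``min_rate``); recall is the
    recovered fraction of those, precision the fraction of reported markers
    matching one.  The confusion table maps (true impact, called impact)
    over the true positives.
    """
    eligible: dict[tuple[str, int], TruthRecord] = {}
    for t in truth:
        if t.line_specificity != "case_only" or t.impact not in _AA_CHANGING:
            continue
        if case_counts is not None:
            c = case_counts.get(t.key)
            if c is None or c.depth < min_depth:
                continue
            if t.variant_type == "insertion":
                support = c.count_ins or max(c.base_count(b) for b in BASES)
            elif t.variant_type == "deletion":
                support = c.count_del
            else:
                support = c.base_count(t.alt)
            if support / c.depth < min_rate:
                continue
        eligible[t.key] = t

    reported = {(m.contig, m.pos): m for m in markers}
    tp_keys = set(reported) & set(eligible)
    confusion: dict[tuple[str, str], int] = {}
    for key in tp_keys:
        true_imp = eligible[key].impact
        called = reported[key].impact
        called_imp = getattr(called, "value", str(called))
        confusion[(true_imp, called_imp)] = confusion.get((true_imp, called_imp), 0) + 1
    precision = len(tp_keys) / len(reported) if reported else 1.0
    recall = len(tp_keys) / len(eligible) if eligible else 1.0
    return RecoveryReport(
        precision=precision, recall=recall, n_eligible=len(eligible),
        n_reported=len(reported), n_true_positive=len(tp_keys),
        confusion=confusion,
        false_positives=sorted(set(reported) - tp_keys),
        false_negatives=sorted(set(eligible) - tp_keys),
    )
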