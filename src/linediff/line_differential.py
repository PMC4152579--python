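"""The case/control filtering cascade for line-specific marker discovery.

Two inbred-line pools (case = vitiligo-prone, control = parental) are called
independently; variants present in both lines are subtracted, and the
survivors pass through fixed cutoffs — SNP rate >= 0.75, read depth >= 10 —
followed by an automated recount confirmation that re-derives rate, depth
and top allele from the raw per-site counts.  Every stage appends to an
ordered filter log so the cascade's attrition is auditable.

No association statistic is computed: the design is deliberately a pair of
fixed thresholds on pooled allele fractions, chosen to catch near-fixed,
homozygous line-specific mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .consequence import Impact
from .io_formats import SiteCounts
from .snp_calling import SnpCall, non_reference_events

__all__ = [
    "LineComparison",
    "SummaryTables",
    "subtract_shared",
    "apply_rate_filter",
    "apply_depth_filter",
    "apply_impact_filter",
    "confirm_by_recount",
    "summarize",
]

FilterLog = list[tuple[str, int, int]]
CountsSource = Union[Mapping[tuple[str, int], SiteCounts],
                     Callable[[str, int], Optional[SiteCounts]]]


@dataclass
class LineComparison:
    """Result of subtracting the control line's calls from the case line's."""

    case_label: str
    control_label: str
    case_calls: list[SnpCall]
    control_calls: list[SnpCall]
    unique_calls: list[SnpCall]
    match_key: str = "position_allele"
    filter_log: FilterLog = field(default_factory=list)

    def log(self, name: str, n_in: int, n_out: int) -> None:
        if self.filter_log and n_in > self.filter_log[-1][2]:
            raise ValueError("filter log counts must be non-increasing")
        self.filter_log.append((name, n_in, n_out))


def _check_unique_positions(calls: Sequence[SnpCall], label: str) -> None:
    seen: set[tuple[str, int]] = set()
    for c in calls:
        if c.key in seen:
            raise ValueError(
                f"{label}: duplicate call at {c.contig}:{c.pos} "
                "(upstream caller must emit one call per site)"
            )
        seen.add(c.key)


def subtract_shared(
    case_calls: Sequence[SnpCall],
    control_calls: Sequence[SnpCall],
    match_key: str = "position_allele",
    case_label: str = "case",
    control_label: str = "control",
) -> LineComparison:
    """Remove case calls that also occur in the control line.

    ``match_key`` decides what "also occurs" means: ``position`` drops any
    case call whose site is variant in the control line at all;
    ``position_allele`` (default) drops it only when the control carries the
    same alternate allele, so a site variant in both lines with different
    alleles stays line-informative.
    """
    if match_key not in ("position", "position_allele"):
        raise ValueError(f"unknown match key {match_key!r}")
    _check_unique_positions(case_calls, case_label)
    _check_unique_positions(control_calls, control_label)
    if match_key == "position":
        control_keys = {c.key for c in control_calls}
        unique = [c for c in case_calls if c.key not in control_keys]
    else:
        control_keys = {c.allele_key for c in control_calls}
        unique = [c for c in case_calls if c.allele_key not in control_keys]
    unique.sort(key=lambda c: (c.contig, c.pos))
    cmp = LineComparison(
        case_label=case_label, control_label=control_label,
        case_calls=list(case_calls), control_calls=list(control_calls),
        unique_calls=unique, match_key=match_key,
    )
    cmp.log("subtract_shared", len(case_calls), len(unique))
    return cmp


def _logged(name, calls, kept, log):
    if log is not None:
        if isinstance(log, LineComparison):
            log.unique_calls = kept
            log.log(name, len(calls), len(kept))
        else:
            log.append((name, len(calls), len(kept)))
    return kept


def apply_rate_filter(
    calls: Sequence[SnpCall],
    min_rate: float = 0.75,
    log: Union[FilterLog, LineComparison, None] = None,
) -> list[SnpCall]:
    """Keep calls whose unrounded SNP rate is >= ``min_rate``.

    The comparison uses exact arithmetic, never the 2-decimal display
    rendering: 9/12 = 0.75 passes the default cutoff, 0.7499 does not.
    """
    kept = [c for c in calls if c.snp_rate >= min_rate]
    return _logged(f"rate>={min_rate}", calls, kept, log)


def apply_depth_filter(
    calls: Sequence[SnpCall],
    min_depth: int = 10,
    log: Union[FilterLog, LineComparison, None] = None,
) -> list[SnpCall]:
    """Keep calls with read depth >= ``min_depth`` (reliability tier)."""
    kept = [c for c in calls if c.depth >= min_depth]
    return _logged(f"depth>={min_depth}", calls, kept, log)


def apply_impact_filter(
    calls: Sequence[SnpCall],
    impacts: Mapping[tuple[str, int], Impact],
    log: Union[FilterLog, LineComparison, None] = None,
) -> list[SnpCall]:
    """Keep calls whose annotated impact changes the protein."""
    kept = [
        c for c in calls
        if c.key in impacts and impacts[c.key].changes_protein
    ]
    return _logged("amino-acid-changing", calls, kept, log)


def confirm_by_recount(
    calls: Sequence[SnpCall],
    counts_source: CountsSource,
    min_rate: float = 0.75,
    min_depth: int = 10,
    log: Union[FilterLog, LineComparison, None] = None,
) -> tuple[list[SnpCall], list[tuple[SnpCall, str]]]:
    """Automated re-scan: re-derive each call from the raw counts.

    A call is confirmed only if the recomputed depth is >= ``min_depth``,
    the recomputed rate of its alternate allele is >= ``min_rate``, and that
    allele is still the top non-reference event.  Dropped calls are returned
    with a reason: "no-data", "depth", "rate", or "allele".
    """
    lookup: Callable[[str, int], Optional[SiteCounts]]
    if callable(counts_source):
        lookup = counts_source
    else:
        lookup = lambda contig, pos: counts_source.get((contig, pos))
    confirmed: list[SnpCall] = []
    dropped: list[tuple[SnpCall, str]] = []
    for call in calls:
        counts = lookup(call.contig, call.pos)
        if counts is None or counts.depth < 1:
            dropped.append((call, "no-data"))
            continue
        events = non_reference_events(counts)
        by_alt = {alt: n for _, alt, n in events}
        alt_count = by_alt.get(call.alt_allele, 0)
        top = max((n for _, _, n in events), default=0)
        if counts.depth < min_depth:
            dropped.append((call, "depth"))
        elif alt_count / counts.depth < min_rate:
            dropped.append((call, "rate"))
        elif alt_count < top:
            dropped.append((call, "allele"))
        else:
            confirmed.append(call)
    _logged("recount", calls, confirmed, log)
    return confirmed, dropped


@dataclass
class SummaryTables:
    """Per-chromosome, per-region and per-impact tallies of unique calls."""

    per_chromosome: dict[str, int]
    per_region: dict[str, int]
    per_impact: dict[Impact, int]

    def __post_init__(self):
        total = sum(self.per_chromosome.values())
        if total != sum(self.per_region.values()):
            raise ValueError("per-chromosome and per-region totals disagree")


def summarize(
    unique_calls: Sequence[SnpCall],
    gene_models: Sequence,
    consequences: Optional[Mapping[tuple[str, int], Impact]] = None,
    contig_chrom_map: Optional[Mapping[str, str]] = None,
    chromosomes: Optional[Iterable[str]] = None,
) -> SummaryTables:
    """Build the summary tables for a unique-call set.

    Chromosome labels come from ``contig_chrom_map`` (contigs map to
    themselves by default).  ``chromosomes`` lists labels to report even at
    zero count, so chromosomes with no unique SNPs stay visible.  The
    per-impact table covers only calls present in ``consequences``.
    """
    from .consequence import classify_region

    cmap = contig_chrom_map or {}
    per_chrom: dict[str, int] = {str(c): 0 for c in (chromosomes or [])}
    per_region: dict[str, int] = {}
    per_impact: dict[Impact, int] = {}
    for call in unique_calls:
        chrom = cmap.get(call.contig, call.contig)
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
        region = classify_region(call.contig, call.pos, gene_models)
        per_region[region] = per_region.get(region, 0) + 1
        if consequences and call.key in consequences:
            imp = consequences[call.key]
            per_impact[imp] = per_impact.get(imp, 0) + 1
    return SummaryTables(per_chrom, per_region, per_impact)
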