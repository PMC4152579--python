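"""End-to-end marker discovery: counts in, candidate marker table out.

Cascade order: per-line calling -> shared-SNP subtraction -> >=75% rate
filter -> coding-consequence annotation (keeping amino-acid-changing
variants) -> >=10 depth filter -> recount confirmation.  Each stage logs
its attrition in the returned comparison's filter log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .consequence import (
    REGION_CDS,
    GeneModel,
    SiteAnnotation,
    annotate_site,
    canonical_models,
)
from .io_formats import MarkerSNP, SiteCounts
from .line_differential import (
    LineComparison,
    apply_depth_filter,
    apply_rate_filter,
    confirm_by_recount,
    subtract_shared,
)
from .snp_calling import SnpCall, call_site, render_called_base

__all__ = ["DiscoveryResult", "call_all_sites", "run_discovery"]


@dataclass
class DiscoveryResult:
    """Markers surviving the full cascade plus the audit trail."""

    markers: list[MarkerSNP]
    comparison: LineComparison
    annotations: dict[tuple[str, int], SiteAnnotation]
    dropped_by_recount: list


def call_all_sites(
    counts: Sequence[SiteCounts],
    min_rate: float = 0.05,
    min_count: int = 2,
    dual_ref_frac: float = 0.20,
) -> list[SnpCall]:
    calls = []
    for c in counts:
        call = call_site(c, min_rate=min_rate, min_count=min_count,
                         dual_ref_frac=dual_ref_frac)
        if call is not None:
            calls.append(call)
    return calls


def run_discovery(
    case_counts: Sequence[SiteCounts],
    control_counts: Sequence[SiteCounts],
    reference: Mapping[str, str],
    models: Sequence[GeneModel],
    contig_chrom_map: Optional[Mapping[str, str]] = None,
    match_key: str = "position_allele",
    min_call_rate: float = 0.05,
    min_call_count: int = 2,
    dual_ref_frac: float = 0.20,
    min_rate: float = 0.75,
    min_depth: int = 10,
    recount: bool = True,
    dialect: str = "paper",
    case_label: str = "SL",
    control_label: str = "BL",
) -> DiscoveryResult:
    """Run the full two-line discovery cascade.

    ``case_counts``/``control_counts`` are the per-site pooled base counts
    of the two lines; ``models`` the transcript models used for consequence
    annotation (reduced to one canonical transcript per gene).
    """
    canon = canonical_models(models)
    case_calls = call_all_sites(case_counts, min_call_rate, min_call_count,
                                dual_ref_frac)
    control_calls = call_all_sites(control_counts, min_call_rate,
                                   min_call_count, dual_ref_frac)
    cmp = subtract_shared(case_calls, control_calls, match_key=match_key,
                          case_label=case_label, control_label=control_label)
    kept = apply_rate_filter(cmp.unique_calls, min_rate=min_rate, log=cmp)

    annotations: dict[tuple[str, int], SiteAnnotation] = {}
    coding = []
    for call in kept:
        vtype = call.variant_type.value
        ann = annotate_site(
            call.contig, call.pos, call.ref_base, call.alt_allele, vtype,
            canon, reference, dialect=dialect,
        )
        annotations[call.key] = ann
        if (
            ann.region == REGION_CDS
            and ann.consequence is not None
            and ann.consequence.impact.changes_protein
        ):
            coding.append(call)
    cmp.log("amino-acid-changing", len(kept), len(coding))

    deep = apply_depth_filter(coding, min_depth=min_depth, log=cmp)
    dropped = []
    if recount:
        by_pos = {(c.contig, c.pos): c for c in case_counts}
        confirmed, dropped = confirm_by_recount(
            deep, by_pos, min_rate=min_rate, min_depth=min_depth, log=cmp
        )
    else:
        confirmed = deep

    cmap = contig_chrom_map or {}
    markers = []
    for call in confirmed:
        ann = annotations[call.key]
        cons = ann.consequence
        markers.append(
            MarkerSNP(
                contig=call.contig,
                chrom=cmap.get(call.contig, call.contig),
                pos=call.pos,
                ref_base=call.ref_base,
                called_base=render_called_base(call),
                impact=cons.impact,
                snp_rate=call.snp_rate,
                gene_symbol=ann.gene_symbol,
                dna_change=cons.cdna_change,
                aa_change=cons.protein_change,
                depth=call.depth,
                counts=call.counts,
            )
        )
    cmp.unique_calls = confirmed
    return DiscoveryResult(
        markers=markers, comparison=cmp, annotations=annotations,
        dropped_by_recount=dropped,
    )
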