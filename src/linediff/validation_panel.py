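"""Per-line allele-ratio comparison for marker validation panels.

Candidate markers discovered from two pooled libraries are re-typed in
larger per-bird panels (Sanger-style base calls).  This module tallies
reference versus alternate support per line, renders the study's ratio
strings ("C:T = 10:1", "All_C", "Ins_A_30%"), and flags markers whose
alternate-allele frequency differs between lines by more than a margin.

Heterozygous per-bird calls contribute 0.5 to each allele before ratio
reduction — pooled-trace reading cannot phase, and the printed ratios are
approximate by construction.  For insertion markers the rendered percentage
is the fraction of birds carrying the insertion (allele-level phasing of an
insertion from a mixed trace is not attempted).
"""

from __future__ import annotations

from math import gcd
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import MarkerSNP, PanelObservation, PanelRatio

__all__ = ["tally_line", "render_ratio", "render_insertion", "compare_lines"]


def tally_line(
    observations: Sequence[PanelObservation],
    ref_base: str,
    alt_base: str,
) -> tuple[float, float, float]:
    """Tally (reference, alternate, other) support for one site and line.

    A homozygous bird contributes 1 to its allele, a heterozygous bird 0.5
    to each, so the three counts sum to the number of birds observed.
    """
    if not observations:
        return (0.0, 0.0, 0.0)
    site = {(o.contig, o.pos) for o in observations}
    lines = {o.line_label for o in observations}
    if len(site) != 1 or len(lines) != 1:
        raise ValueError(
            f"observations span multiple sites/lines: {sorted(site)}, {sorted(lines)}"
        )
    ref = alt = other = 0.0
    for o in observations:
        w = 1.0 / len(o.observed_bases)
        for b in o.observed_bases:
            if b == ref_base:
                ref += w
            elif b == alt_base or (alt_base not in "ACGT-" and b == "ins"):
                alt += w
            else:
                other += w
    return (ref, alt, other)


def _reduced(r: float, a: float) -> tuple[int, int]:
    # het calls make half-integer counts; double first, then reduce
    ri, ai = round(2 * r), round(2 * a)
    g = gcd(ri, ai)
    ri, ai = ri // g, ai // g
    if ri % 2 == 0 and ai % 2 == 0:
        ri, ai = ri // 2, ai // 2
    return ri, ai


def render_ratio(ref_base: str, alt_base: str, ref_count: float, alt_count: float) -> str:
    """Render a per-line ratio string.

    "All_<base>" when one side is absent (a deletion allele renders as
    "Del"); otherwise "<ref>:<alt> = <r>:<a>" with the pair reduced by their
    greatest common divisor.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if ref_count == 0 and alt_count == 0:
        raise ValueError("both counts zero: nothing to render")
    alt_label = "Del" if alt_base == "-" else alt_base
    if alt_count == 0:
        return f"All_{ref_base}"
    if ref_count == 0:
        return f"All_{alt_label}"
    r, a = _reduced(ref_count, alt_count)
    return f"{ref_base}:{alt_label} = {r}:{a}"


def render_insertion(ins_seq: str, carrier_fraction: float) -> str:
    """Insertion panels render "Ins_<seq>_<percent>%" (nearest integer)."""
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier fraction outside [0,1]")
    return f"Ins_{ins_seq}_{round(100 * carrier_fraction)}%"


def _insertion_stats(obs: Sequence[PanelObservation]) -> tuple[float, float]:
    """(carrier fraction, allele-level alt frequency) for an insertion site."""
    if not obs:
        return (0.0, 0.0)
    carriers = sum(1 for o in obs if "ins" in o.observed_bases)
    alt, total = 0.0, 0.0
    for o in obs:
        w = 1.0 / len(o.observed_bases)
        for b in o.observed_bases:
            total += w
            if b == "ins":
                alt += w
    return (carriers / len(obs), alt / total if total else 0.0)


def compare_lines(
    panel: Iterable[PanelObservation],
    markers: Sequence[MarkerSNP],
    case_label: str = "SL",
    control_label: str = "BL",
    margin: float = 0.25,
    fisher: bool = False,
) -> pd.DataFrame:
    """One row per marker: per-line ratio strings and a differential flag.

    The flag is set when the alternate-allele frequency differs between the
    two lines by more than ``margin`` (default 0.25); it is an artifact of
    this implementation — the original study reported the ratios
    qualitatively with no test statistic.  ``fisher=True`` adds a two-sided
    Fisher exact p-value on the pooled per-line allele counts.
    """
    by_key: dict[tuple[str, int, str], list[PanelObservation]] = {}
    for o in panel:
        by_key.setdefault((o.contig, o.pos, o.line_label), []).append(o)
    rows = []
    for m in markers:
        alt = m.called_base.split("|")[-1] if "|" in m.called_base else m.called_base
        is_ins = m.ref_base == "-"
        row: dict = {
            "gene_symbol": m.gene_symbol, "contig": m.contig, "pos": m.pos,
            "impact": m.impact.value, "ref_base": m.ref_base, "called_base": alt,
        }
        freqs: dict[str, Optional[float]] = {}
        counts: dict[str, tuple[float, float]] = {}
        for line in (control_label, case_label):
            obs = by_key.get((m.contig, m.pos, line), [])
            if not obs:
                row[f"ratio_{line}"] = "no-data"
                freqs[line] = None
                continue
            if is_ins:
                carrier_frac, allele_freq = _insertion_stats(obs)
                row[f"ratio_{line}"] = render_insertion(alt, carrier_frac)
                freqs[line] = allele_freq
                counts[line] = ((1 - allele_freq) * 2 * len(obs), allele_freq * 2 * len(obs))
            else:
                ref_n, alt_n, _ = tally_line(obs, m.ref_base, alt)
                row[f"ratio_{line}"] = (
                    "no-data" if ref_n + alt_n == 0
                    else render_ratio(m.ref_base, alt, ref_n, alt_n)
                )
                freqs[line] = alt_n / (ref_n + alt_n) if ref_n + alt_n else None
                counts[line] = (ref_n, alt_n)
            row[f"alt_freq_{line}"] = freqs[line]
        fa, fb = freqs.get(case_label), freqs.get(control_label)
        row["differential"] = (
            fa is not None and fb is not None and abs(fa - fb) > margin
        )
        if fisher:
            if case_label in counts and control_label in counts:
                table = [
                    [round(2 * counts[control_label][0]), round(2 * counts[control_label][1])],
                    [round(2 * counts[case_label][0]), round(2 * counts[case_label][1])],
                ]
                row["fisher_p"] = fisher_exact(table, alternative="two-sided")[1]
            else:
                row["fisher_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
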