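"""Detection of amo operon architectures on annotated contigs.

Ammonia monooxygenase is encoded by a cluster of subunit genes — the
well-recognized amoC, amoA and amoB, plus accessory subunits (amoX, and
the downstream amoD/amoE pair of beta-proteobacterial ammonia oxidizers).
A cluster of amo-family gene calls on one contig separated by at most
``max_gap`` bases becomes an operon call. Completeness is co-occurrence
on the contig: strand agreement and the canonical C-A-B order are
recorded as flags but not required, because several ammonia-oxidizer
lineages scatter the subunits around the genome or rearrange the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core_io import GeneCall, OperonCall

AMO_SUBUNITS = frozenset({"amoA", "amoB", "amoC", "amoD", "amoE", "amoX"})
CORE = frozenset({"amoA", "amoB", "amoC"})


@dataclass
class OperonParams:
    max_gap: int = 500
    neighbor_window: int = 2000


def _completeness(families: set[str]) -> str:
    if CORE <= families:
        if "amoD" in families or "amoE" in families:
            return "extended_DE"
        if "amoX" in families:
            return "complete_ABCX"
        return "complete_CAB"
    subset = ",".join(sorted(f[-1] for f in families & AMO_SUBUNITS))
    return f"partial:{subset}"


def _canonical_order(genes: list[GeneCall]) -> bool:
    """True iff the subunit order along the coding strand starts C,A,B."""
    core = [g for g in genes if g.family in ("amoA", "amoB", "amoC")]
    if len(core) < 3:
        return False
    core_sorted = sorted(core, key=lambda g: g.start)
    strands = {g.strand for g in core_sorted}
    if len(strands) > 1:
        return False
    fams = [g.family[-1] for g in core_sorted]
    if strands == {"-"}:
        fams = fams[::-1]
    return fams[:3] == ["C", "A", "B"]


def detect_operons(gene_calls: list[GeneCall],
                   params: Optional[OperonParams] = None) -> list[OperonCall]:
    """Cluster amo-family calls per contig into operon calls.

    Calls are grouped when the gap between consecutive genes (end of one
    to start of the next along the contig) is at most ``max_gap``.
    Overlapping calls of the same family across reading frames are
    collapsed to the best-supported one before clustering so the subunit
    list reflects distinct loci. Operons never span contigs.
    """
    params = params or OperonParams()
    out: list[OperonCall] = []
    by_contig: dict[str, list[GeneCall]] = {}
    for g in gene_calls:
        if g.family in AMO_SUBUNITS:
            by_contig.setdefault(g.contig_id, []).append(g)
    for contig_id in sorted(by_contig):
        genes = _collapse_overlaps(by_contig[contig_id])
        genes.sort(key=lambda g: (g.start, g.end))
        cluster: list[GeneCall] = []
        for g in genes:
            if cluster and g.start - max(x.end for x in cluster) > params.max_gap:
                out.append(_make_call(contig_id, cluster))
                cluster = []
            cluster.append(g)
        if cluster:
            out.append(_make_call(contig_id, cluster))
    return out


def _collapse_overlaps(genes: list[GeneCall]) -> list[GeneCall]:
    """Among same-locus calls (overlapping over at least half of the
    shorter call) keep the best supported one. Slight overlaps between
    adjacent genes, common in operons, are left alone."""
    def support(g: GeneCall):
        bits = g.best_hit.bitscore if g.best_hit is not None else 0.0
        return (-bits, -(g.end - g.start), g.start)

    kept: list[GeneCall] = []
    for g in sorted(genes, key=support):
        same_locus = False
        for h in kept:
            ov = min(g.end, h.end) - max(g.start, h.start)
            shorter = min(g.end - g.start, h.end - h.start)
            if ov > 0.5 * shorter:
                same_locus = True
                break
        if not same_locus:
            kept.append(g)
    return kept


def _make_call(contig_id: str, genes: list[GeneCall]) -> OperonCall:
    families = {g.family for g in genes}
    gaps = [b.start - a.end for a, b in zip(genes, genes[1:])]
    return OperonCall(
        contig_id=contig_id,
        genes=list(genes),
        completeness_class=_completeness(families),
        same_strand=len({g.strand for g in genes}) == 1,
        max_gap_bp=max(gaps) if gaps else 0,
        canonical_order=_canonical_order(genes),
    )


def annotate_neighbors(operon_call: OperonCall, gene_calls: list[GeneCall],
                       window_bp: int = 2000) -> list[GeneCall]:
    """Non-amo calls overlapping the window around the operon span.

    Any overlap with the window counts, including a single base. The
    neighbors are whatever the stringent annotation labeled them against
    the panel's non-target entries (family ``other``), or unassigned.
    """
    lo = operon_call.start - window_bp
    hi = operon_call.end + window_bp
    member_ids = {g.id for g in operon_call.genes}
    neighbors = [
        g for g in gene_calls
        if g.contig_id == operon_call.contig_id
        and g.id not in member_ids
        and g.family not in AMO_SUBUNITS
        and g.end > lo and g.start < hi
    ]
    neighbors.sort(key=lambda g: (g.start, g.end))
    operon_call.neighbors = neighbors
    return neighbors


def operon_summary(operon_calls: list[OperonCall],
                   label: str = "targeted") -> pd.DataFrame:
    """Counts per completeness class, with a strict variant restricted to
    same-strand canonical-order calls, in deterministic order."""
    rows = []
    classes = sorted({c.completeness_class for c in operon_calls})
    for cls in classes:
        group = [c for c in operon_calls if c.completeness_class == cls]
        rows.append({
            "assembly": label,
            "completeness_class": cls,
            "count": len(group),
            "count_strict": sum(1 for c in group
                                if c.same_strand and c.canonical_order),
        })
    return pd.DataFrame(rows,
                        columns=["assembly", "completeness_class",
                                 "count", "count_strict"])
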