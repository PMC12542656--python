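"""Gene prediction on contigs, stringent re-annotation, and dereplication.

Contigs produced by targeted assembly are expected to be near-complete
genes or operons, so gene prediction is a six-frame stop-to-stop ORF scan
with start-codon preference rather than a trained gene-finder HMM. Each
predicted protein is then re-searched against the reference panel at the
stringent threshold (e-value <= 1e-5, identity >= 0.3) so that only
well-supported target-family genes survive, and redundant variants are
collapsed by greedy incremental clustering in the CD-HIT style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib

from .core_io import Contig, GeneCall, ReferencePanel, TARGET_FAMILIES, revcomp
from .recruit import (PanelIndex, STRINGENT_EVALUE, MIN_IDENTITY,
                      best_protein_hit, translate)

START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class AnnotationConfig:
    min_orf_aa: int = 60
    stringent_evalue: float = STRINGENT_EVALUE
    stringent_identity: float = MIN_IDENTITY
    derep_identity: float = 0.95
    derep_coverage: float = 0.9


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def call_orfs(contig: Contig, config: Optional[AnnotationConfig] = None
              ) -> list[GeneCall]:
    """Predict ORFs in all six frames of a contig.

    Within each maximal stop-to-stop interval the call starts at the first
    ATG/GTG/TTG when one exists, otherwise at the interval start (flagged
    partial). Calls shorter than ``min_orf_aa`` are dropped. Coordinates
    are reported 0-based half-open on the forward strand; overlapping
    calls across frames are all kept (annotation disambiguates).
    """
    config = config or AnnotationConfig()
    calls: list[GeneCall] = []
    L = len(contig.sequence)
    for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
        for offset in range(3):
            aa = translate(seq[offset:])
            for a0, a1, stop_before, stop_after in _stop_to_stop(aa):
                start_aa, no_start = _pick_start(seq, offset, a0, a1)
                if no_start and not stop_before and not stop_after:
                    # completely open frame with no start codon: no
                    # evidence of a gene at all
                    continue
                if a1 - start_aa < config.min_orf_aa:
                    continue
                nt_start = offset + 3 * start_aa
                nt_end = offset + 3 * a1
                if strand == "+":
                    f_start, f_end = nt_start, nt_end
                else:
                    f_start, f_end = L - nt_end, L - nt_start
                calls.append(GeneCall(
                    contig_id=contig.id, start=f_start, end=f_end,
                    strand=strand,
                    aa_sequence=aa[start_aa:a1],
                    partial=no_start or not stop_after,
                ))
    calls.sort(key=lambda g: (g.start, g.end, g.strand))
    return calls


def _stop_to_stop(aa: str):
    """Yield (start, end, stop_before, stop_after) intervals between
    stop codons."""
    start = 0
    for i, res in enumerate(aa):
        if res == "*":
            if i > start:
                yield start, i, start > 0, True
            start = i + 1
    if len(aa) > start:
        yield start, len(aa), start > 0, False


def _pick_start(seq: str, offset: int, a0: int, a1: int) -> tuple[int, bool]:
    """First start codon within the interval, else the interval start."""
    for a in range(a0, a1):
        codon = seq[offset + 3 * a: offset + 3 * a + 3]
        if codon in START_CODONS:
            return a, False
    return a0, True


# ---------------------------------------------------------------------------
# stringent re-annotation
# ---------------------------------------------------------------------------

def annotate_stringent(gene_calls: list[GeneCall], panel: ReferencePanel,
                       config: Optional[AnnotationConfig] = None,
                       index: Optional[PanelIndex] = None) -> list[GeneCall]:
    """Assign a family to each call by its best panel hit at the stringent
    threshold; calls failing it stay ``unassigned``. Returns all calls."""
    config = config or AnnotationConfig()
    if index is None:
        index = PanelIndex(panel)
    db_residues = panel.total_residues
    for call in gene_calls:
        best = best_protein_hit(call.id, call.aa_sequence, index,
                                db_residues)
        if best is not None and best.evalue <= config.stringent_evalue \
                and best.identity >= config.stringent_identity:
            call.family = best.family
            call.best_hit = best
        else:
            call.family = "unassigned"
            call.best_hit = best
    return gene_calls


def filter_targeted(gene_calls: list[GeneCall]) -> list[GeneCall]:
    """Keep only calls annotated to an amo/pmo family."""
    return [g for g in gene_calls if g.family in TARGET_FAMILIES]


# ---------------------------------------------------------------------------
# dereplication (greedy incremental clustering)
# ---------------------------------------------------------------------------

def dereplicate(sequences: dict[str, str],
                config: Optional[AnnotationConfig] = None
                ) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy incremental clustering of sequences.

    Sequences are sorted by length descending (ties broken by id); each
    sequence joins the first existing representative it matches at
    >= ``derep_identity`` over the full length of the shorter sequence
    (the shorter is aligned within the longer, so its coverage is
    complete), else it founds a new cluster. Returns the representative
    ids in order and the cluster map representative -> members
    (each representative is a member of its own cluster).
    """
    config = config or AnnotationConfig()
    if not sequences:
        return [], {}
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        home = None
        for rep in reps:
            if _identity_over_shorter(seq, sequences[rep]) >= config.derep_identity:
                home = rep
                break
        if home is None:
            reps.append(sid)
            clusters[sid] = [sid]
        else:
            clusters[home].append(sid)
    return reps, clusters


def _identity_over_shorter(a: str, b: str) -> float:
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    if not shorter:
        return 0.0
    is_dna = set(shorter + longer) <= set("ACGTN")
    probes = [shorter, revcomp(shorter)] if is_dna else [shorter]
    best = 0.0
    for probe in probes:
        res = edlib.align(probe, longer, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            ident = 1.0 - res["editDistance"] / len(shorter)
            best = max(best, ident)
    return best
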