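"""Shared domain types and readers/writers for the toolkit's file formats.

All coordinates held in memory are 0-based half-open on the forward strand
of the contig; conversion to the 1-based inclusive convention happens only
when writing GFF3. Sequences are stored uppercase. ``N`` is a legal
character in DNA but never matches any base during alignment or k-mer
operations.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger("genetarget")

FAMILIES = (
    "amoA", "amoB", "amoC", "amoD", "amoE", "amoX",
    "pmoA", "pmoB", "pmoC", "other",
)
#: families counted as recruitment / annotation targets
TARGET_FAMILIES = frozenset(f for f in FAMILIES if f != "other")
DOMAINS = ("archaea", "bacteria", "unknown")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ACGTN."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceRecord:
    """One labeled protein in the reference panel.

    The panel stands in for a curated functional-gene database: each record
    carries its gene family (amo/pmo subunit or ``other``), the domain of
    life of its source organism, and, for archaeal amoA, an optional
    phylogenetic clade label (NP-*/NT-* vocabulary).
    """

    id: str
    family: str
    domain_label: str = "unknown"
    clade_label: Optional[str] = None
    aa_sequence: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FormatError(f"unknown family {self.family!r} for {self.id}")
        if self.domain_label not in DOMAINS:
            raise FormatError(
                f"unknown domain {self.domain_label!r} for {self.id}")
        self.aa_sequence = self.aa_sequence.upper()
        if len(self.aa_sequence) < 30:
            raise FormatError(
                f"reference {self.id}: protein shorter than 30 aa")
        bad = set(self.aa_sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"reference {self.id}: illegal residues {sorted(bad)}")


@dataclass
class ReferencePanel:
    """An ordered collection of :class:`ReferenceRecord` with unique ids."""

    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate panel ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    @property
    def total_residues(self) -> int:
        return sum(len(r.aa_sequence) for r in self.records)

    def by_family(self, family: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.family == family]


@dataclass
class Read:
    """A shotgun read with its sample of origin."""

    id: str
    sample_id: str
    sequence: str
    mate: str = "unpaired"  # {"1", "2", "unpaired"}
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}")


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.reads})


@dataclass
class SampleDesign:
    """Spatial layout of the samples: coordinates in meters from a central
    point, plus the radius of the sampling ring each sample sits on (0 for
    the central sample)."""

    table: pd.DataFrame  # columns: sample_id, x, y, ring_radius

    REQUIRED = ("sample_id", "x", "y", "ring_radius")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample design missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in design")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def coords(self) -> "pd.DataFrame":
        return self.table.set_index("sample_id")[["x", "y"]]

    def pairwise_distances(self) -> pd.DataFrame:
        """Euclidean distance matrix between samples (meters)."""
        import numpy as np
        xy = self.table[["x", "y"]].to_numpy(float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        ids = self.sample_ids
        return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Contig:
    id: str
    sequence: str
    k_origin: object = "consensus"  # int or "consensus"
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(f"contig {self.id}: illegal characters {sorted(bad)}")
        if self.mean_coverage < 0:
            raise FormatError(f"contig {self.id}: negative coverage")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """A predicted coding region on a contig.

    ``start``/``end`` are 0-based half-open on the contig forward strand
    regardless of ``strand``; ``aa_sequence`` is the translation read in the
    coding direction (stop codon excluded).
    """

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    aa_sequence: str
    family: str = "unassigned"
    best_hit: Optional[object] = None  # recruit.Hit
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene on {self.contig_id}: bad interval {self.start}..{self.end}")
        if (self.end - self.start) % 3 != 0:
            raise FormatError(
                f"gene on {self.contig_id}: span not divisible by 3")
        if self.strand not in "+-":
            raise FormatError(f"gene on {self.contig_id}: bad strand {self.strand}")

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


@dataclass
class OperonCall:
    """A cluster of amo-family gene calls on one contig."""

    contig_id: str
    genes: list[GeneCall]
    completeness_class: str
    same_strand: bool
    max_gap_bp: int
    canonical_order: bool
    neighbors: list[GeneCall] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def id(self) -> str:
        return f"{self.contig_id}:operon:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    # gzip transparency by magic bytes
    if "r" in mode:
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[FastaRecord]:
    """Parse a FASTA file into records, in file order.

    The header token before the first whitespace becomes the id; sequences
    are uppercased. An empty file yields an empty list (with a warning).
    """
    records: list[FastaRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_make_fasta_record(header, chunks))
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before first header "
                        f"at line {lineno}")
                chunks.append(line)
    if header is not None:
        records.append(_make_fasta_record(header, chunks))
    if not records:
        logger.warning("read_fasta: %s contains no records", path)
    return records


def _make_fasta_record(header: str, chunks: list[str]) -> FastaRecord:
    parts = header.split(None, 1)
    rec_id = parts[0] if parts else ""
    desc = parts[1] if len(parts) > 1 else ""
    return FastaRecord(id=rec_id, sequence="".join(chunks).upper(),
                       description=desc)


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    """Write records (anything with .id and .sequence, or (id, seq) pairs)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec_id, seq, desc = rec[0], rec[1], ""
            else:
                rec_id, seq = rec.id, rec.sequence
                desc = getattr(rec, "description", "")
            head = f">{rec_id}" + (f" {desc}" if desc else "")
            fh.write(head + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path, sample_id: str = "sample") -> ReadSet:
    """Parse 4-line FASTQ (plain or gzip) into a :class:`ReadSet`.

    Mate suffixes ``/1``-``/2`` on the id, or `` 1:``-`` 2:`` in the
    description, are parsed into the ``mate`` field (the suffix is kept on
    the id so round-trips are byte-exact).
    """
    reads: list[Read] = []
    with _open_text(path) as fh:
        idx = 0
        while True:
            head = fh.readline()
            if not head:
                break
            head = head.rstrip("\n")
            if not head:
                continue
            idx += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not head.startswith("@") or not plus.startswith("+") or not qual:
                raise FormatError(
                    f"{path}: truncated or malformed FASTQ record {idx}")
            full_id = head[1:]
            token = full_id.split()[0]
            mate = "unpaired"
            if token.endswith("/1"):
                mate = "1"
            elif token.endswith("/2"):
                mate = "2"
            else:
                rest = full_id[len(token):].lstrip()
                if rest.startswith("1:"):
                    mate = "1"
                elif rest.startswith("2:"):
                    mate = "2"
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {token}: sequence and quality lengths differ")
            reads.append(Read(id=full_id, sample_id=sample_id,
                              sequence=seq, mate=mate, quality=qual))
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in readset:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# reference panel FASTA  (header convention: id|family|domain|clade)
# ---------------------------------------------------------------------------

def read_panel(path) -> ReferencePanel:
    """Read a labeled reference panel from FASTA.

    The header carries the labels as ``id|family|domain|clade`` with ``NA``
    placeholders for absent labels, so the panel file is self-describing.
    """
    records = []
    for rec in read_fasta(path):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"panel header {rec.id!r}: expected id|family|domain|clade")
        rid, family, domain, clade = parts
        records.append(ReferenceRecord(
            id=rid,
            family=family,
            domain_label=domain if domain != "NA" else "unknown",
            clade_label=None if clade == "NA" else clade,
            aa_sequence=rec.sequence,
        ))
    return ReferencePanel(records)


def write_panel(panel: ReferencePanel, path) -> None:
    recs = []
    for r in panel:
        domain = r.domain_label if r.domain_label != "unknown" else "NA"
        clade = r.clade_label if r.clade_label else "NA"
        recs.append((f"{r.id}|{r.family}|{domain}|{clade}", r.aa_sequence))
    write_fasta(recs, path)


# ---------------------------------------------------------------------------
# sample design TSV
# ---------------------------------------------------------------------------

def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(gene_calls: list[GeneCall], operon_calls: list[OperonCall],
               path) -> None:
    """Write gene and operon calls to GFF3.

    Internal 0-based half-open intervals are converted to the GFF3 1-based
    inclusive convention here and nowhere else. Operons become ``operon``
    features whose genes carry ``Parent`` attributes.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        operon_child_ids = set()
        for op in operon_calls:
            fh.write("\t".join([
                op.contig_id, "genetarget", "operon",
                str(op.start + 1), str(op.end),
                ".", "+" if op.same_strand else ".", ".",
                f"ID={op.id};completeness={op.completeness_class};"
                f"canonical_order={str(op.canonical_order).lower()}",
            ]) + "\n")
            for g in op.genes:
                operon_child_ids.add(g.id)
                fh.write(_gene_line(g, parent=op.id))
        for g in gene_calls:
            if g.id in operon_child_ids:
                continue
            fh.write(_gene_line(g))


def _gene_line(g: GeneCall, parent: Optional[str] = None) -> str:
    attrs = [f"ID={g.id}", f"family={g.family}"]
    if parent:
        attrs.append(f"Parent={parent}")
    if g.partial:
        attrs.append("partial=true")
    return "\t".join([
        g.contig_id, "genetarget", "gene",
        str(g.start + 1), str(g.end), ".", g.strand, "0",
        ";".join(attrs),
    ]) + "\n"


def read_gff3(path) -> tuple[list[GeneCall], list[dict]]:
    """Minimal GFF3 import for round-tripping this package's own output.

    Returns gene calls (coordinates converted back to 0-based half-open)
    and raw operon feature dicts.
    """
    genes: list[GeneCall] = []
    operons: list[dict] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: bad GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attr_str = cols
            attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
            if ftype == "gene":
                start0, end0 = int(start) - 1, int(end)
                n_aa = (end0 - start0) // 3
                genes.append(GeneCall(
                    contig_id=seqid, start=start0, end=end0,
                    strand=strand if strand in "+-" else "+",
                    aa_sequence="X" * max(n_aa - 1, 1),
                    family=attrs.get("family", "unassigned"),
                    partial=attrs.get("partial") == "true",
                ))
            elif ftype == "operon":
                operons.append({
                    "contig_id": seqid, "start": int(start) - 1,
                    "end": int(end), "attributes": attrs,
                })
    return genes, operons


# ---------------------------------------------------------------------------
# hit tables (12-column tabular alignment convention)
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query", "subject", "identity", "aln_len", "mismatches", "gap_opens",
    "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


def write_hits_tsv(hits: Iterable, path) -> None:
    """Write hits in the conventional 12-column tabular layout.

    Coordinates are emitted 1-based inclusive on the query/subject as in
    that convention; identity as a percentage.
    """
    rows = []
    for h in hits:
        rows.append({
            "query": h.query_id, "subject": h.subject_id,
            "identity": round(100.0 * h.identity, 2),
            "aln_len": h.aln_len, "mismatches": h.mismatches,
            "gap_opens": h.gap_opens,
            "q_start": h.q_start + 1, "q_end": h.q_end,
            "s_start": h.s_start + 1, "s_end": h.s_end,
            "evalue": f"{h.evalue:.3g}", "bitscore": round(h.bitscore, 1),
        })
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
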