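"""Multi-k de Bruijn assembly of recruited reads with cross-k consensus.

The assembler follows the iterative multi-k strategy of the MEGAHIT family:
a de Bruijn graph over canonical k-mers is built and compacted into unitigs
for each k in an ascending list, each k additionally seeded with the
contigs of the previous k, and the pooled contigs are merged into a
consensus set by removing exact duplicates and contigs contained in a
longer contig at high identity.

No k-mer abundance cutoff is applied: every observed k-mer enters the
graph with its count. Graph cleaning is limited to clipping short,
weakly supported dead-end unitigs (tips) that have a branching
alternative; bubbles are deliberately left intact so allelic variants of
a gene survive as separate contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import edlib

from .core_io import ConfigError, Contig, Read, ReadSet, revcomp

logger = logging.getLogger("genetarget")


@dataclass
class AssemblyConfig:
    """Parameters of the multi-k assembly.

    ``k_list`` defaults to a desk-scale ladder; the full-scale equivalent
    of the replaced assembler family would run 29..141. ``tip_len_factor``
    and ``tip_max_count`` bound which dead-end unitigs count as clippable
    tips: shorter than ``tip_len_factor * k`` and mean k-mer count at most
    ``tip_max_count``, with a branching alternative present.
    """

    k_list: tuple = (21, 33, 55, 77)
    min_contig_len: int = 200
    tip_len_factor: int = 3
    tip_max_count: float = 3.0
    merge_identity: float = 0.99

    def __post_init__(self) -> None:
        ks = list(self.k_list)
        if any(k % 2 == 0 for k in ks):
            raise ConfigError("all k must be odd")
        if ks != sorted(ks) or len(set(ks)) != len(ks):
            raise ConfigError("k_list must be strictly ascending")


# ---------------------------------------------------------------------------
# paired-end merging
# ---------------------------------------------------------------------------

def merge_pairs(read1: Read, read2: Read, min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> list[Read]:
    """Overlap-merge a mate pair into a single fragment when possible.

    The suffix of ``read1`` is compared with the prefix of the reverse
    complement of ``read2``; the longest overlap of at least
    ``min_overlap`` bases with a mismatch fraction at most
    ``max_mismatch_frac`` wins. Mismatching bases inside the overlap are
    resolved toward the higher-quality call, ties to ``read1``. When no
    acceptable overlap exists both reads are returned unchanged.
    """
    s1 = read1.sequence
    s2 = revcomp(read2.sequence)
    q1 = read1.quality
    q2 = read2.quality[::-1] if read2.quality else None
    best: Optional[tuple[int, int]] = None  # (overlap_len, mismatches)
    max_ov = min(len(s1), len(s2))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = s1[len(s1) - ov:]
        head = s2[:ov]
        mism = sum(1 for a, b in zip(tail, head) if a != b)
        if mism <= max_mismatch_frac * ov:
            best = (ov, mism)
            break
    if best is None:
        return [read1, read2]
    ov, _ = best
    off = len(s1) - ov
    merged = list(s1[:off])
    mqual = list(q1[:off]) if q1 and q2 else None
    for i in range(ov):
        a, b = s1[off + i], s2[i]
        if a == b:
            merged.append(a)
        else:
            qa = ord(q1[off + i]) if q1 else 0
            qb = ord(q2[i]) if q2 else 0
            merged.append(b if qb > qa else a)
        if mqual is not None:
            mqual.append(max(q1[off + i], q2[i]))
    merged.append(s2[ov:])
    seq = "".join(merged[:-1]) + merged[-1]
    qual = None
    if mqual is not None:
        qual = "".join(mqual) + q2[ov:]
    return [Read(id=read1.id.split("/")[0] + "_merged",
                 sample_id=read1.sample_id, sequence=seq, mate="unpaired",
                 quality=qual)]


def merge_readset(reads: ReadSet, min_overlap: int = 10,
                  max_mismatch_frac: float = 0.1) -> ReadSet:
    """Merge all /1-/2 pairs in a read set; unpaired reads pass through."""
    by_key: dict[tuple[str, str], dict[str, Read]] = {}
    singles: list[Read] = []
    for r in reads:
        if r.mate in ("1", "2"):
            stem = r.id.split()[0]
            for suffix in ("/1", "/2"):
                if stem.endswith(suffix):
                    stem = stem[: -2]
            by_key.setdefault((r.sample_id, stem), {})[r.mate] = r
        else:
            singles.append(r)
    out: list[Read] = []
    for (_, _), pair in sorted(by_key.items()):
        if "1" in pair and "2" in pair:
            out.extend(merge_pairs(pair["1"], pair["2"], min_overlap,
                                   max_mismatch_frac))
        else:
            out.extend(pair.values())
    out.extend(singles)
    return ReadSet(out)


# ---------------------------------------------------------------------------
# de Bruijn graph over canonical k-mers
# ---------------------------------------------------------------------------

def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DBG:
    """De Bruijn graph over canonical k-mers with multiplicities."""

    k: int
    counts: dict = field(default_factory=dict)  # canonical kmer -> count

    def __len__(self) -> int:
        return len(self.counts)

    def has(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def count(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def successors(self, kmer: str) -> list[str]:
        """Oriented k-mers reachable by shifting one base to the right."""
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if self.has(suffix + b)]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in "ACGT" if self.has(b + prefix)]


def build_dbg(sequences, k: int) -> DBG:
    """Count every k-mer free of N (canonicalized) in the input sequences.

    Accepts an iterable of strings, Reads or Contigs.
    """
    if k % 2 == 0:
        raise ConfigError("k must be odd")
    counts: dict[str, int] = {}
    for item in sequences:
        seq = getattr(item, "sequence", item)
        n = len(seq)
        if n < k:
            continue
        for i in range(n - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return DBG(k=k, counts=counts)


def _walk(dbg: DBG, start: str, visited: set) -> tuple[str, list[int]]:
    """Maximal non-branching path through ``start`` (oriented); returns the
    unitig sequence and the counts of its k-mers. Marks canonicals visited."""

    def extend(kmer: str) -> list[str]:
        path = []
        current = kmer
        while True:
            succ = dbg.successors(current)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(dbg.predecessors(nxt)) != 1:
                break
            cn = canonical(nxt)
            if cn in visited or cn == canonical(kmer):
                break
            visited.add(cn)
            path.append(nxt)
            current = nxt
        return path

    visited.add(canonical(start))
    fwd = extend(start)
    bwd = [revcomp(x) for x in extend(revcomp(start))]
    chain = list(reversed(bwd)) + [start] + fwd
    seq = chain[0] + "".join(x[-1] for x in chain[1:])
    counts = [dbg.count(x) for x in chain]
    return seq, counts


def unitigs(dbg: DBG, config: Optional[AssemblyConfig] = None,
            min_len: int = 0) -> list[Contig]:
    """Compact the graph into maximal non-branching paths.

    Weak short tips are clipped first (see :class:`AssemblyConfig`), then
    paths are emitted once each in canonical orientation (lexicographic
    minimum of the sequence and its reverse complement), with
    ``mean_coverage`` the mean k-mer count along the path.
    """
    config = config or AssemblyConfig()
    _clip_tips(dbg, config)
    out: list[Contig] = []
    visited: set[str] = set()
    for kmer in sorted(dbg.counts):
        if kmer in visited:
            continue
        seq, counts = _walk(dbg, kmer, visited)
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
        if len(seq) >= min_len:
            out.append(Contig(
                id="", sequence=seq, k_origin=dbg.k,
                mean_coverage=sum(counts) / len(counts)))
    out.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(out):
        c.id = f"k{dbg.k}_{i}"
    return out


def _clip_tips(dbg: DBG, config: AssemblyConfig, rounds: int = 3) -> None:
    """Remove weakly supported error structures from the graph.

    Two kinds of unitig are clipped, both only when their mean k-mer
    count is at most ``tip_max_count`` (sequencing-error support; real
    variants at reasonable coverage stay well above it):

    * tips — dead-ended on one side, shorter than ``tip_len_factor * k``,
      with a branching alternative at the attachment node;
    * weak bubble arms — attached on both sides to branching nodes and
      shorter than ``3 * k``; these arise when an error is re-threaded
      inside a longer contig from a smaller k. Balanced allelic bubbles
      are untouched because both arms carry real coverage.

    Candidates are removed weakest-first, and each removal is re-checked
    against the current graph so parallel weak arms cannot delete each
    other's only alternative.
    """
    k = dbg.k
    tip_max_len = config.tip_len_factor * k
    arm_max_len = 3 * k
    for _ in range(rounds):
        visited: set[str] = set()
        cands: list[tuple[float, str, str]] = []
        for kmer in sorted(dbg.counts):
            if kmer in visited:
                continue
            seq, counts = _walk(dbg, kmer, visited)
            mean = sum(counts) / len(counts)
            if mean > config.tip_max_count:
                continue
            kind = _weak_kind(dbg, seq, tip_max_len, arm_max_len)
            if kind:
                cands.append((mean, seq, kind))
        removed = 0
        for mean, seq, kind in sorted(cands):
            kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
            if not all(dbg.has(km) for km in kmers):
                continue
            if _weak_kind(dbg, seq, tip_max_len, arm_max_len) != kind:
                continue
            for km in kmers:
                dbg.counts.pop(canonical(km), None)
            removed += 1
        if removed == 0:
            return


def _weak_kind(dbg: DBG, seq: str, tip_max_len: int,
               arm_max_len: int) -> Optional[str]:
    """Classify a unitig as a clippable 'tip' or 'arm' (else None),
    based on its attachments in the current graph."""
    k = dbg.k
    first, last = seq[:k], seq[-k:]
    preds = dbg.predecessors(first)
    succs = dbg.successors(last)
    dead_start = len(preds) == 0
    dead_end = len(succs) == 0
    if dead_start != dead_end and len(seq) < tip_max_len:
        anchor = succs[0] if dead_start else preds[0]
        alt = (dbg.predecessors(anchor) if dead_start
               else dbg.successors(anchor))
        if len(alt) >= 2:
            return "tip"
        return None
    if len(preds) == 1 and len(succs) == 1 and len(seq) < arm_max_len:
        if len(dbg.successors(preds[0])) >= 2 \
                and len(dbg.predecessors(succs[0])) >= 2:
            return "arm"
    return None


# ---------------------------------------------------------------------------
# multi-k consensus
# ---------------------------------------------------------------------------

def _contained(shorter: str, longer: str, min_identity: float) -> bool:
    """True when ``shorter`` aligns within ``longer`` (either strand) over
    its full length at >= min_identity."""
    max_dist = int((1.0 - min_identity) * len(shorter))
    for probe in (shorter, revcomp(shorter)):
        res = edlib.align(probe, longer, mode="HW", task="distance",
                          k=max_dist)
        if res["editDistance"] != -1:
            return True
    return False


def merge_contig_sets(pooled: list[Contig], config: AssemblyConfig
                      ) -> list[Contig]:
    """Consensus merging of contigs pooled across k values.

    Exact duplicates (reverse-complement aware) collapse; a contig fully
    contained in a longer contig at >= ``merge_identity`` is dropped;
    survivors shorter than ``min_contig_len`` are discarded.
    """
    seen: dict[str, Contig] = {}
    for c in sorted(pooled, key=lambda c: (-len(c.sequence), c.sequence)):
        key = min(c.sequence, revcomp(c.sequence))
        if key not in seen:
            seen[key] = c
    uniq = sorted(seen.values(), key=lambda c: (-len(c.sequence), c.sequence))
    kept: list[Contig] = []
    for c in uniq:
        contained = any(
            len(longer.sequence) > len(c.sequence) and
            _contained(c.sequence, longer.sequence, config.merge_identity)
            for longer in kept)
        if not contained and len(c.sequence) >= config.min_contig_len:
            kept.append(c)
    for i, c in enumerate(kept):
        c.id = f"contig_{i}"
        c.k_origin = "consensus"
    return kept


def assemble_multi_k(reads, config: Optional[AssemblyConfig] = None
                     ) -> list[Contig]:
    """Run the full multi-k assembly on a read set (or sequence iterable).

    Each k is seeded with the previous k's contigs as additional input
    sequences; all per-k contigs are pooled and consensus-merged.
    """
    config = config or AssemblyConfig()
    seqs = [getattr(r, "sequence", r) for r in reads]
    max_read = max((len(s) for s in seqs), default=0)
    pooled: list[Contig] = []
    prev: list[Contig] = []
    for k in config.k_list:
        inputs = list(seqs)
        inputs.extend(c.sequence for c in prev)
        if k > max(max_read, max((len(c.sequence) for c in prev), default=0)):
            logger.warning("k=%d exceeds all input lengths; skipped", k)
            continue
        dbg = build_dbg(inputs, k)
        prev = unitigs(dbg, config)
        pooled.extend(prev)
    return merge_contig_sets(pooled, config)
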