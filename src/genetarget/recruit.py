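"""Translated homology search of reads against the reference panel.

This stage recruits shotgun reads homologous to the target gene families
before assembly. Each read is translated in all six frames and searched
against the panel proteins with a seed-and-extend local aligner
(exact amino-acid seeds chained into banded Smith-Waterman extensions under
BLOSUM62 with affine gaps). Significance uses Karlin-Altschul statistics
with the standard gapped BLOSUM62 constants, so the conventional e-value
thresholds (1 for relaxed recruitment, 1e-5 for stringent re-annotation)
keep their usual meaning.

Scoring model
-------------
* substitution matrix: BLOSUM62 (X and ``*`` scored as in the matrix)
* gap of length L costs ``gap_open + L * gap_extend`` = 11 + L
* bitscore = (lambda * S - ln K) / ln 2 with lambda = 0.267, K = 0.041
* evalue  = m * n * 2**(-bitscore), n = total residues in the panel
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .core_io import (ConfigError, Read, ReadSet, ReferencePanel,
                      TARGET_FAMILIES, revcomp)

# Karlin-Altschul constants for gapped BLOSUM62 (11/1)
LAMBDA = 0.267
K_CONST = 0.041

GAP_OPEN = 11
GAP_EXTEND = 1
SEED_K = 5
BAND = 16

RELAXED_EVALUE = 1.0
STRINGENT_EVALUE = 1e-5
MIN_IDENTITY = 0.3

FRAMES = (1, 2, 3, -1, -2, -3)

# ---------------------------------------------------------------------------
# genetic code (translation table 11; identical residues to the standard code)
# ---------------------------------------------------------------------------

_table = CodonTable.unambiguous_dna_by_id[11]
_CODON = dict(_table.forward_table)
for _stop in _table.stop_codons:
    _CODON[_stop] = "*"


def translate(dna: str) -> str:
    """Translate a DNA string in frame +1; codons containing N give 'X',
    stops give '*', trailing partial codons are dropped."""
    aa = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        aa.append(_CODON.get(codon, "X"))
    return "".join(aa)


def translate_six_frames(dna: str) -> dict[int, str]:
    """All six translation frames of a DNA string.

    Frames +1/+2/+3 start at offsets 0/1/2 of the forward strand; frames
    -1/-2/-3 at offsets 0/1/2 of the reverse complement.
    """
    rc = revcomp(dna)
    return {
        1: translate(dna), 2: translate(dna[1:]), 3: translate(dna[2:]),
        -1: translate(rc), -2: translate(rc[1:]), -3: translate(rc[2:]),
    }


# ---------------------------------------------------------------------------
# substitution matrix as a flat lookup
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet
_IDX = {c: i for i, c in enumerate(_ALPHA)}
_SCORE = np.array(_BLOSUM, dtype=np.int32)
# extended float matrix with a padding sentinel that can never align
_PAD = len(_ALPHA)
_SCOREF = np.full((_PAD + 1, _PAD + 1), -1.0e4)
_SCOREF[:_PAD, :_PAD] = _SCORE


def _encode(aa: str) -> np.ndarray:
    # unknown residues score as X
    x = _IDX["X"]
    return np.fromiter((_IDX.get(c, x) for c in aa), dtype=np.int64,
                       count=len(aa))


def score_pair(a: str, b: str) -> int:
    """BLOSUM62 score of two residues."""
    x = _IDX["X"]
    return int(_SCORE[_IDX.get(a, x), _IDX.get(b, x)])


# ---------------------------------------------------------------------------
# hit record
# ---------------------------------------------------------------------------

@dataclass
class Hit:
    """A translated local alignment of a query to a panel protein.

    Coordinates are 0-based half-open; ``q_start``/``q_end`` index the
    amino-acid string of the reported frame.
    """

    query_id: str
    subject_id: str
    frame: int
    aln_len: int
    identity: float
    matches: int
    mismatches: int
    gap_opens: int
    raw_score: int
    bitscore: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    family: str = "other"
    domain_label: str = "unknown"

    def sort_key(self):
        # higher bitscore first, then higher identity, then lexicographic id
        return (-self.bitscore, -self.identity, self.subject_id)


def evalue(raw_score: float, query_len: int, db_residues: int
           ) -> tuple[float, float]:
    """Karlin-Altschul bitscore and e-value for a raw alignment score.

    ``query_len`` counts residues of the translated query frame and
    ``db_residues`` the total residues of the panel (the search space the
    e-value refers to).
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    bits = (LAMBDA * raw_score - math.log(K_CONST)) / math.log(2.0)
    ev = float(query_len) * float(db_residues) * 2.0 ** (-bits)
    return bits, ev


# ---------------------------------------------------------------------------
# seed-and-extend banded Smith-Waterman
# ---------------------------------------------------------------------------

class PanelIndex:
    """Exact k-mer seed index over the panel proteins."""

    def __init__(self, panel: ReferencePanel, k: int = SEED_K):
        if len(panel) == 0:
            raise ConfigError("reference panel is empty")
        self.panel = panel
        self.k = k
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        self.subjects = [r.aa_sequence for r in panel]
        self.encoded = [_encode(s) for s in self.subjects]
        nmax = max(len(e) for e in self.encoded)
        self.padded = np.full((len(self.encoded), nmax), _PAD,
                              dtype=np.int64)
        for i, e in enumerate(self.encoded):
            self.padded[i, :len(e)] = e
        for si, seq in enumerate(self.subjects):
            for p in range(len(seq) - k + 1):
                kmer = seq[p:p + k]
                if "X" in kmer or "*" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((si, p))

    def seed_diagonals(self, query_aa: str) -> dict[int, set[int]]:
        """Map subject index -> set of seed diagonals (s_pos - q_pos)."""
        out: dict[int, set[int]] = {}
        k = self.kmers
        for qp in range(len(query_aa) - self.k + 1):
            kmer = query_aa[qp:qp + self.k]
            hits = k.get(kmer)
            if hits:
                for si, sp in hits:
                    out.setdefault(si, set()).add(sp - qp)
        return out


@dataclass
class _Alignment:
    score: int
    matches: int
    mismatches: int
    gap_opens: int
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


def _banded_sw(q: str, s: str, dlo: int, dhi: int) -> Optional[_Alignment]:
    """Local Gotoh alignment restricted to diagonals dlo <= j-i <= dhi
    (i indexes query, j subject, both 1-based in the DP). Returns the best
    local alignment with traceback, or None when no positive score exists.

    Match cells outside the band (or with non-positive score) act as the
    zero floor, so alignments may start anywhere inside the band.
    """
    m, n = len(q), len(s)
    qi = _encode(q)
    si = _encode(s)
    NEG = -10 ** 9
    open_cost = GAP_OPEN + GAP_EXTEND
    M: dict[tuple[int, int], int] = {}
    Ix: dict[tuple[int, int], int] = {}  # gap in subject (consumes query)
    Iy: dict[tuple[int, int], int] = {}  # gap in query (consumes subject)
    mptr: dict[tuple[int, int], str] = {}
    xptr: dict[tuple[int, int], str] = {}
    yptr: dict[tuple[int, int], str] = {}
    best_score, best_cell = 0, None
    for i in range(1, m + 1):
        jlo = max(1, i + dlo)
        jhi = min(n, i + dhi)
        for j in range(jlo, jhi + 1):
            sub = int(_SCORE[qi[i - 1], si[j - 1]])
            pm = M.get((i - 1, j - 1), 0)
            px = Ix.get((i - 1, j - 1), NEG)
            py = Iy.get((i - 1, j - 1), NEG)
            prev, src = pm, "M"
            if px > prev:
                prev, src = px, "X"
            if py > prev:
                prev, src = py, "Y"
            if prev <= 0:
                prev, src = 0, "0"
            mval = prev + sub
            if mval > 0:
                M[(i, j)] = mval
                mptr[(i, j)] = src
                if mval > best_score:
                    best_score, best_cell = mval, (i, j)
            xm = M.get((i - 1, j), NEG) - open_cost
            xx = Ix.get((i - 1, j), NEG) - GAP_EXTEND
            if max(xm, xx) > NEG // 2:
                Ix[(i, j)] = max(xm, xx)
                xptr[(i, j)] = "M" if xm >= xx else "X"
            ym = M.get((i, j - 1), NEG) - open_cost
            yy = Iy.get((i, j - 1), NEG) - GAP_EXTEND
            if max(ym, yy) > NEG // 2:
                Iy[(i, j)] = max(ym, yy)
                yptr[(i, j)] = "M" if ym >= yy else "Y"
    if best_cell is None:
        return None
    i, j = best_cell
    q_end, s_end = i, j
    state = "M"
    matches = mismatches = gap_opens = aln_len = 0
    while True:
        if state == "M":
            aln_len += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            else:
                mismatches += 1
            src = mptr[(i, j)]
            i, j = i - 1, j - 1
            if src == "0":
                break
            state = src
        elif state == "X":
            aln_len += 1
            src = xptr[(i, j)]
            if src == "M":
                gap_opens += 1
            i -= 1
            state = src
        else:
            aln_len += 1
            src = yptr[(i, j)]
            if src == "M":
                gap_opens += 1
            j -= 1
            state = src
    return _Alignment(score=best_score, matches=matches,
                      mismatches=mismatches, gap_opens=gap_opens,
                      aln_len=aln_len, q_start=i, q_end=q_end,
                      s_start=j, s_end=s_end)


def sw_score_batch(q_enc: np.ndarray, s_batch: np.ndarray) -> np.ndarray:
    """Best local-alignment score of one query against a batch of
    subjects (full Smith-Waterman, affine gaps, score only).

    ``s_batch`` is a (subjects, n) integer matrix of encoded residues,
    short subjects padded with the sentinel code. The dynamic program is
    vectorized along subjects and columns; used to rank candidate
    subjects so the banded traceback runs on the winner only.
    """
    S, n = s_batch.shape
    NEG = -1.0e9
    ext = float(GAP_EXTEND)
    oc = float(GAP_OPEN + GAP_EXTEND)
    jext = ext * np.arange(n + 1)
    M_prev = np.zeros((S, n + 1))
    Ix_prev = np.full((S, n + 1), NEG)
    H_prev = np.zeros((S, n + 1))
    best = np.zeros(S)
    for i in range(len(q_enc)):
        subrow = _SCOREF[q_enc[i]][s_batch]
        M_cur = np.zeros((S, n + 1))
        np.maximum(H_prev[:, :-1] + subrow, 0.0, out=M_cur[:, 1:])
        Ix_cur = np.maximum(M_prev - oc, Ix_prev - ext)
        run = np.maximum.accumulate(M_cur + jext, axis=1)
        Iy_cur = np.full((S, n + 1), NEG)
        Iy_cur[:, 1:] = run[:, :-1] - oc - jext[1:] + ext
        H_prev = np.maximum(np.maximum(M_cur, Ix_cur), Iy_cur)
        np.maximum(best, M_cur.max(axis=1), out=best)
        M_prev, Ix_prev = M_cur, Ix_cur
    return np.rint(best).astype(np.int64)


def sw_score(q, s) -> int:
    """Score of the best local alignment of two proteins (exact full
    Smith-Waterman with affine gaps, no traceback)."""
    qi = q if isinstance(q, np.ndarray) else _encode(q)
    si = s if isinstance(s, np.ndarray) else _encode(s)
    return int(sw_score_batch(qi, si[None, :])[0])


def _diagonal_windows(diags: set[int], band: int = BAND) -> list[tuple[int, int]]:
    """Merge seed diagonals into banded windows [dlo, dhi]."""
    ds = sorted(diags)
    windows = []
    lo = hi = ds[0]
    for d in ds[1:]:
        if d - hi <= 2 * band:
            hi = d
        else:
            windows.append((lo - band, hi + band))
            lo = hi = d
    windows.append((lo - band, hi + band))
    return windows


def seed_and_extend(query_aa: str, subject_aa: str, k: int = SEED_K,
                    band: int = BAND) -> Optional[_Alignment]:
    """Best local alignment of two proteins found by exact-seed banded
    extension. Returns None when no seed (hence no alignment) exists."""
    if not query_aa or not subject_aa:
        return None
    diags: set[int] = set()
    index: dict[str, list[int]] = {}
    for p in range(len(subject_aa) - k + 1):
        index.setdefault(subject_aa[p:p + k], []).append(p)
    for qp in range(len(query_aa) - k + 1):
        for sp in index.get(query_aa[qp:qp + k], ()):
            diags.add(sp - qp)
    if not diags:
        return None
    best: Optional[_Alignment] = None
    for dlo, dhi in _diagonal_windows(diags, band):
        aln = _banded_sw(query_aa, subject_aa, dlo, dhi)
        if aln and (best is None or aln.score > best.score):
            best = aln
    return best


# ---------------------------------------------------------------------------
# read recruitment
# ---------------------------------------------------------------------------

@dataclass
class RecruitResult:
    """Outcome of best-hit recruitment: the retained reads, their single
    best hit each, and the family that hit assigns. Mates pulled in by
    rescue carry no hit and are kept apart in ``rescued``."""

    reads: ReadSet
    best_hits: dict[str, Hit] = field(default_factory=dict)
    rescued: ReadSet = field(default_factory=lambda: ReadSet([]))

    def family_of(self, read_id: str) -> str:
        return self.best_hits[read_id].family

    def __len__(self) -> int:
        return len(self.reads)


def _trace_hit(query_id: str, aa: str, frame: int, si: int,
               diags: set[int], index: PanelIndex,
               db_residues: int) -> Optional[Hit]:
    """Full banded alignment with traceback against one subject."""
    subject = index.subjects[si]
    best = None
    for dlo, dhi in _diagonal_windows(diags):
        aln = _banded_sw(aa, subject, dlo, dhi)
        if aln and (best is None or aln.score > best.score):
            best = aln
    if best is None:
        return None
    rec = index.panel.records[si]
    bits, ev = evalue(best.score, len(aa), db_residues)
    return Hit(
        query_id=query_id, subject_id=rec.id, frame=frame,
        aln_len=best.aln_len, identity=best.matches / best.aln_len,
        matches=best.matches, mismatches=best.mismatches,
        gap_opens=best.gap_opens, raw_score=best.score,
        bitscore=bits, evalue=ev,
        q_start=best.q_start, q_end=best.q_end,
        s_start=best.s_start, s_end=best.s_end,
        family=rec.family, domain_label=rec.domain_label,
    )


def _pick_best(query_id: str, framed: list, index: PanelIndex,
               db_residues: int) -> Optional[Hit]:
    """Rank seeded (frame, subject) candidates by score-only SW; run the
    traceback on the top scorers only and break ties by identity, then
    subject id."""
    scored = []
    for frame, aa, seeds in framed:
        q_enc = _encode(aa)
        sis = sorted(seeds)
        scores = sw_score_batch(q_enc, index.padded[sis])
        for si, s in zip(sis, scores):
            if s > 0:
                scored.append((int(s), frame, aa, si, seeds[si]))
    if not scored:
        return None
    smax = max(x[0] for x in scored)
    hits = []
    for s, frame, aa, si, diags in scored:
        if s < smax:
            continue
        hit = _trace_hit(query_id, aa, frame, si, diags, index, db_residues)
        if hit is not None:
            hits.append(hit)
    if not hits:
        return None
    hits.sort(key=Hit.sort_key)
    return hits[0]


def best_hit(query_id: str, query_dna: str, index: PanelIndex,
             db_residues: Optional[int] = None) -> Optional[Hit]:
    """Best translated hit of a DNA query over all frames and subjects.

    Ties on bitscore are broken by higher identity, then lexicographically
    smaller subject id, so the outcome is deterministic.
    """
    if db_residues is None:
        db_residues = index.panel.total_residues
    frames = translate_six_frames(query_dna)
    framed = []
    for frame in FRAMES:
        aa = frames[frame]
        if len(aa) < index.k:
            continue
        seeds = index.seed_diagonals(aa)
        if seeds:
            framed.append((frame, aa, seeds))
    return _pick_best(query_id, framed, index, db_residues)


def best_protein_hit(query_id: str, aa: str, index: PanelIndex,
                     db_residues: Optional[int] = None) -> Optional[Hit]:
    """Best panel hit of a protein query (frame reported as +1)."""
    if db_residues is None:
        db_residues = index.panel.total_residues
    if len(aa) < index.k:
        return None
    seeds = index.seed_diagonals(aa)
    if not seeds:
        return None
    return _pick_best(query_id, [(1, aa, seeds)], index, db_residues)


def recruit_reads(reads: ReadSet, panel: ReferencePanel,
                  mode: str = "relaxed", min_identity: float = MIN_IDENTITY,
                  index: Optional[PanelIndex] = None,
                  mate_rescue: bool = False) -> RecruitResult:
    """Extract reads whose single best translated hit falls in a target
    family and passes the mode's thresholds.

    ``relaxed`` mode (e-value <= 1) casts the wide recruitment net before
    assembly; ``stringent`` mode (e-value <= 1e-5) is the re-annotation
    setting. Identity must reach ``min_identity`` in both modes. Mates
    are searched independently; with ``mate_rescue`` the unrecruited
    partner of a recruited mate is additionally returned (off by
    default).
    """
    if mode not in ("relaxed", "stringent"):
        raise ConfigError(f"unknown recruitment mode {mode!r}")
    if len(panel) == 0:
        raise ConfigError("reference panel is empty")
    emax = RELAXED_EVALUE if mode == "relaxed" else STRINGENT_EVALUE
    if index is None:
        index = PanelIndex(panel)
    kept: list[Read] = []
    hits: dict[str, Hit] = {}
    for read in reads:
        h = best_hit(read.id, read.sequence, index)
        if h is None:
            continue
        if h.evalue <= emax and h.identity >= min_identity \
                and h.family in TARGET_FAMILIES:
            kept.append(read)
            hits[read.id] = h
    rescued: list[Read] = []
    if mate_rescue:
        recruited_stems = {_mate_stem(r) for r in kept if r.mate != "unpaired"}
        taken = {r.id for r in kept}
        for read in reads:
            if read.mate == "unpaired" or read.id in taken:
                continue
            if _mate_stem(read) in recruited_stems:
                rescued.append(read)
    return RecruitResult(reads=ReadSet(kept), best_hits=hits,
                         rescued=ReadSet(rescued))


def _mate_stem(read: Read) -> tuple[str, str]:
    stem = read.id.split()[0]
    for suffix in ("/1", "/2"):
        if stem.endswith(suffix):
            stem = stem[:-2]
    return (read.sample_id, stem)
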