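"""Assembly-quality metrics and spatial diversity statistics.

This module carries the downstream statistics of the targeted-assembly
route: contig contiguity metrics (N50/N90, L50/L90), a read-to-variant
community matrix built by shared-k-mer assignment, Bray-Curtis community
similarity, the distance-decay relationship (DDR; the linear least-squares
slope d of community similarity on log10 geographic distance), the
taxa-area relationship (TAR; the log-log slope z of pooled richness on
sampled area), nearest-reference clade assignment for archaeal amoA, and
Poisson-corrected neighbor-joining trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .core_io import ReadSet, ReferencePanel, SampleDesign, revcomp


# ---------------------------------------------------------------------------
# assembly contiguity statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    n_contigs: int
    total_len: int
    N50: int
    N90: int
    L50: int
    L90: int


def assembly_stats(contig_lengths) -> AssemblyStats:
    """N50/N90 and L50/L90 of a set of contig lengths.

    Lengths are sorted descending; N50 is the length of the contig at
    which the cumulative length first reaches 50% of the total, and L50
    the number of contigs up to and including it (analogously at 90%).
    """
    lengths = sorted(int(x) for x in contig_lengths)
    if not lengths or lengths[0] <= 0:
        raise ValueError("contig lengths must be positive and non-empty")
    lengths = lengths[::-1]
    total = sum(lengths)
    cum = 0
    n50 = n90 = l50 = l90 = 0
    for i, ln in enumerate(lengths, 1):
        cum += ln
        if not n50 and cum >= 0.5 * total:
            n50, l50 = ln, i
        if not n90 and cum >= 0.9 * total:
            n90, l90 = ln, i
            break
    return AssemblyStats(n_contigs=len(lengths), total_len=total,
                         N50=n50, N90=n90, L50=l50, L90=l90)


# ---------------------------------------------------------------------------
# read mapping -> community matrix
# ---------------------------------------------------------------------------

def map_reads(reads: ReadSet, representatives: dict[str, str],
              k: int = 31) -> pd.DataFrame:
    """Assign reads to dereplicated gene representatives by shared k-mers.

    Each read goes to the representative sharing the most distinct
    canonical k-mers; ties are dropped as ambiguous and reads sharing no
    k-mer stay unmapped. Returns a samples x variants count matrix whose
    row sums equal the per-sample mapped-read counts.
    """
    def kmer_set(seq: str) -> frozenset:
        return frozenset(
            min(seq[i:i + k], revcomp(seq[i:i + k]))
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k])

    rep_ids = sorted(representatives)
    rep_kmers = {rid: kmer_set(representatives[rid]) for rid in rep_ids}
    counts: dict[tuple[str, str], int] = {}
    samples = set()
    for read in reads:
        samples.add(read.sample_id)
        rk = kmer_set(read.sequence)
        if not rk:
            continue
        shared = [(len(rk & rep_kmers[rid]), rid) for rid in rep_ids]
        shared.sort(reverse=True)
        if shared[0][0] == 0:
            continue
        if len(shared) > 1 and shared[1][0] == shared[0][0]:
            continue  # ambiguous
        key = (read.sample_id, shared[0][1])
        counts[key] = counts.get(key, 0) + 1
    matrix = pd.DataFrame(0, index=sorted(samples), columns=rep_ids,
                          dtype=int)
    for (sid, rid), n in counts.items():
        matrix.loc[sid, rid] = n
    return matrix


# ---------------------------------------------------------------------------
# Bray-Curtis and slope fits
# ---------------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|xi-yi| / sum(xi+yi), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if not x.any() and not y.any():
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(x, y))


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_points: int
    mantel_p: Optional[float] = None


def fit_decay(similarities, distances) -> SlopeFit:
    """OLS of community similarity on log10 distance (the DDR core)."""
    sims = np.asarray(similarities, dtype=float)
    dists = np.asarray(distances, dtype=float)
    keep = dists > 0
    sims, dists = sims[keep], dists[keep]
    if len(sims) < 3:
        raise ValueError("need at least 3 pairs with positive distance")
    res = stats.linregress(np.log10(dists), sims)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                    n_points=len(sims))


def fit_ddr(matrix: pd.DataFrame, design: SampleDesign,
            relative: bool = True, mantel_permutations: int = 0,
            seed: int = 0) -> SlopeFit:
    """Distance-decay slope of Bray-Curtis similarity (1 - dissimilarity)
    on log10 pairwise distance.

    Zero-distance pairs are excluded (the log is undefined there).
    Abundances default to relative (rows normalized to 1). An optional
    Mantel permutation p-value (permuting sample identities) supplements
    the parametric OLS p-value.
    """
    ids = [s for s in design.sample_ids if s in matrix.index]
    m = matrix.loc[ids].to_numpy(dtype=float)
    if relative:
        rowsum = m.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        m = m / rowsum
    dmat = design.pairwise_distances().loc[ids, ids].to_numpy()
    sims, dists = [], []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= 0:
                continue
            if not m[i].any() and not m[j].any():
                continue
            sims.append(1.0 - bray_curtis(m[i], m[j]))
            dists.append(dmat[i, j])
    fit = fit_decay(sims, dists)
    if mantel_permutations > 0:
        fit.mantel_p = _mantel_p(np.array(sims), np.array(dists),
                                 n, mantel_permutations, seed)
    return fit


def _mantel_p(sims: np.ndarray, dists: np.ndarray, n: int,
              permutations: int, seed: int) -> float:
    # permute sample labels; recompute the correlation of the two
    # condensed matrices under each permutation
    rng = np.random.default_rng(seed)
    pair_index = {}
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            pair_index[(i, j)] = idx
            idx += 1
    if len(sims) != idx:
        # some pairs were excluded; fall back to permuting the vectors
        obs = stats.pearsonr(sims, np.log10(dists)).statistic
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(len(sims))
            r = stats.pearsonr(sims[perm], np.log10(dists)).statistic
            if abs(r) >= abs(obs):
                count += 1
        return (count + 1) / (permutations + 1)
    obs = stats.pearsonr(sims, np.log10(dists)).statistic
    logd = np.log10(dists)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        perm_sims = np.empty_like(sims)
        for (i, j), pi in pair_index.items():
            a, b = min(p[i], p[j]), max(p[i], p[j])
            perm_sims[pair_index[(a, b)]] = sims[pi]
        r = stats.pearsonr(perm_sims, logd).statistic
        if abs(r) >= abs(obs):
            count += 1
    return (count + 1) / (permutations + 1)


def fit_tar(matrix: pd.DataFrame, design: SampleDesign,
            cumulative: bool = True) -> SlopeFit:
    """Taxa-area slope z: OLS of log10 pooled richness on log10 area.

    For each ring radius r the samples within radius r (cumulative
    pooling, the default) or exactly on ring r are pooled; richness is
    the number of variants with at least one count in the pool; the area
    is pi * r**2.
    """
    ids = [s for s in design.sample_ids if s in matrix.index]
    tab = design.table[design.table["sample_id"].isin(ids)]
    radii = sorted(r for r in tab["ring_radius"].unique() if r > 0)
    if len(radii) < 3:
        raise ValueError("need at least 3 ring radii for a TAR fit")
    log_area, log_rich = [], []
    for r in radii:
        if cumulative:
            pool_ids = tab.loc[tab["ring_radius"] <= r, "sample_id"]
        else:
            pool_ids = tab.loc[tab["ring_radius"] == r, "sample_id"]
        pooled = matrix.loc[list(pool_ids)].sum(axis=0)
        richness = int((pooled > 0).sum())
        if richness <= 0:
            continue
        log_area.append(math.log10(math.pi * r * r))
        log_rich.append(math.log10(richness))
    if len(log_area) < 3:
        raise ValueError("fewer than 3 usable ring pools")
    res = stats.linregress(log_area, log_rich)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                    n_points=len(log_area))


# ---------------------------------------------------------------------------
# clade assignment and trees
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Identity of the global (end-to-end) alignment of two sequences:
    matching columns over alignment columns."""
    import edlib
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(n) for n, ch in _cigar_items(res["cigar"]))
    return 1.0 - res["editDistance"] / aln_len


def _cigar_items(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


@dataclass
class CladeAssignment:
    label: str
    identity: float
    reference_id: Optional[str] = None
    ambiguous: bool = False


def assign_clade(query_aa: str, panel: ReferencePanel,
                 min_identity: float = 0.5) -> CladeAssignment:
    """Nearest-reference clade label for an archaeal amoA protein.

    The query is compared by global identity to every clade-labeled
    reference; the nearest label wins if its identity reaches
    ``min_identity``, ties go to the lexicographically smallest label
    (flagged ambiguous), otherwise the query is unclassified.
    """
    labeled = [r for r in panel if r.clade_label]
    best: dict[str, tuple[float, str]] = {}
    for r in labeled:
        ident = global_identity(query_aa, r.aa_sequence)
        cur = best.get(r.clade_label)
        if cur is None or ident > cur[0]:
            best[r.clade_label] = (ident, r.id)
    if not best:
        return CladeAssignment(label="unclassified", identity=0.0)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    (label, (ident, rid)) = ranked[0]
    if ident < min_identity:
        return CladeAssignment(label="unclassified", identity=ident)
    ambiguous = len(ranked) > 1 and ranked[1][1][0] == ident
    return CladeAssignment(label=label, identity=ident, reference_id=rid,
                           ambiguous=ambiguous)


def poisson_distance(a: str, b: str, cap: float = 0.95) -> float:
    """Poisson-corrected distance d = -ln(1 - p) from the global-alignment
    p-distance (capped to avoid the logarithm's singularity)."""
    p = 1.0 - global_identity(a, b)
    p = min(p, cap)
    return -math.log(1.0 - p)


def nj_from_distances(ids: list[str], matrix: np.ndarray) -> str:
    """Neighbor-joining (Saitou-Nei) on a distance matrix; negative
    branch lengths are clamped to zero. Returns Newick."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    tree = nj(DistanceMatrix(matrix, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def nj_tree(sequences: dict[str, str]) -> str:
    """Neighbor-joining tree on Poisson-corrected pairwise distances of
    the input sequences. Returns Newick with the input ids."""
    ids = sorted(sequences)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = poisson_distance(sequences[ids[i]], sequences[ids[j]])
            mat[i, j] = mat[j, i] = d
    return nj_from_distances(ids, mat)
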