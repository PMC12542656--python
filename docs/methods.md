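# Methods

This note documents the models, parameters and numerical choices behind
each stage of the toolkit, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Translated read recruitment

Reads are translated in all six frames under translation table 11
(codons containing N translate to X, stops to `*`, trailing partial
codons are dropped) and searched against the reference panel.

**Seeding and extension.** Exact amino-acid 5-mers shared between a
frame and a panel protein define candidate diagonals; diagonals within
2×16 of each other merge into a window, and a banded Gotoh local
alignment (half-band 16 around the seeded diagonals) with traceback
produces the reported alignment. Candidate subjects are first ranked
with a full-matrix, score-only Smith–Waterman (vectorized across
subjects); the banded traceback then runs only on the top scorer(s).
Reported scores equal the exhaustive Smith–Waterman score whenever the
optimal alignment lies within the seeded band — verified against an
independent Biopython `PairwiseAligner` oracle on hundreds of random
pairs. The documented sensitivity contract is that an alignment is only
found if query and subject share at least one exact 5-mer; homologs
below ~35% identity without conserved motifs can be missed, which is the
usual operating regime of seed-based translated search.

**Scoring.** BLOSUM62; a gap of length L costs 11 + L. Karlin–Altschul
statistics with the standard gapped constants λ = 0.267, K = 0.041:
`bitscore = (λS − ln K)/ln 2`, `E = m·n·2^(−bitscore)` where m is the
translated query length and n the total panel residues. The scoring
system is a deliberate, community-standard choice; the thresholds
(relaxed E ≤ 1, stringent E ≤ 10⁻⁵, identity ≥ 0.3, best-hit-only)
are the route's semantics and are exposed in configuration.

**Ties.** Best hits tie-break by higher identity, then lexicographically
smaller subject id, making hit tables deterministic.

## Multi-k assembly

A de Bruijn graph over canonical k-mers (lexicographic minimum of k-mer
and reverse complement; k odd so palindromes cannot occur) is built per
k in an ascending ladder, by default 21, 33, 55, 77 — a desk-scale
stand-in for the 29…141 ladder a full-scale assembler would run. Every
observed k-mer enters the graph with its count; there is no abundance
cutoff. Each k after the first is additionally seeded with the previous
k's contigs, and all per-k unitigs are pooled, deduplicated
(reverse-complement aware), purged of contigs contained in a longer
contig at ≥ 99% identity over their full length (edlib infix
alignment), and filtered at 200 bp.

**Graph cleaning.** Unitig compaction alone is unusable at realistic
error rates, so two weakly supported structures are clipped, both only
when their mean k-mer count is ≤ 3 (default `tip_max_count`):

* *tips*: dead-ended unitigs shorter than 3k with a branching
  alternative at their attachment node — the signature of a substitution
  error near a read end;
* *weak bubble arms*: unitigs shorter than 3k attached on both sides to
  branching nodes. These arise specifically from the multi-k seeding:
  an error absorbed into a smaller-k contig re-enters the larger-k graph
  with long flanks and forms a bubble rather than a tip.

Candidates are removed weakest-first with re-checks against the current
graph, so two parallel weak arms cannot delete each other's only
alternative path. Bubbles whose arms both carry real coverage — allelic
variants of a gene — are untouched; keeping sequence variants separate
is the point of the route. The count threshold is absolute, so genuine
variants at coverage ≤ 3 can be clipped; at the coverages the route is
designed for (≥ 10×) this does not occur.

**Pair merging.** Overlapping mate pairs are merged before assembly when
the suffix of read 1 matches the prefix of the reverse-complemented
read 2 over ≥ 10 bases at ≤ 10% mismatches (longest acceptable overlap
wins; disagreements resolve toward the higher-quality base, ties to
read 1).

## Gene calling, annotation, dereplication

Contigs from targeted assembly are near-complete genes, so gene
prediction is a six-frame stop-to-stop ORF scan rather than a trained
gene-finder model. Within each stop-bounded interval the call starts at
the first ATG/GTG/TTG, else at the interval start (flagged partial);
intervals with no start codon and no bounding stop on either side are
discarded as evidence-free. Calls shorter than 60 aa are dropped;
overlapping calls across frames are all reported and disambiguated by
annotation. A consequence of the first-start rule is that a call may
extend a few codons upstream of the true start when the flank contains
an in-frame start codon; stringent annotation is robust to this.

Stringent re-annotation assigns each call the family of its best panel
hit when `E ≤ 10⁻⁵` and identity ≥ 0.3; only amo/pmo families survive
into the targeted output. Dereplication is greedy incremental
clustering: sequences sorted by length (ties by id) join the first
representative they match at ≥ 95% identity over the full length of the
shorter sequence (the shorter is aligned within the longer, so its
coverage is complete), else found a new cluster.

## Chimera detection

For a query and a pool of candidate parents, per-parent match vectors
come from global (edlib) alignment projected onto query columns
(query-gap columns count as mismatches, parent-only columns are
skipped; nucleotide parents are tried in both orientations). For every
ordered parent pair (A, B) and crossover column x the two-parent model
scores `M(A,B,x) = cumA(x) + totB − cumB(x)`; the verdict follows the
gain `d = max M − best single parent`:

* `d ≤ 0` → non-chimeric;
* `d ≥ 3` with both segments ≥ 20% of columns and ≥ 80% identity to
  their parent → chimeric;
* anything else → unclassified (weak or conflicting evidence).

The d ∈ [1, 3) band is this detector's analog of the "unknown" category
the classic tools report; it is an operating-characteristic choice, not
a replica of any published score. Candidate parents in reference mode
are the top 4 panel hits of the whole query plus the top 2 hits of each
query quarter (capped at 8): without the chunked candidates, a splice of
two distant families would populate the pool entirely from the
better-matching family and the second segment would be unexplainable.
De novo mode draws candidates from the other queries with coverage
≥ 2× the query's own (a chimera formed during assembly cannot out-number
its parents), processing queries in decreasing coverage order. When the
maximum of M is flat over a run of columns on which both parents agree,
the reported crossover is the first column of the run; mirrored inputs
can therefore report crossovers differing by the run length.

## Operon detection

Amo-family calls on one contig cluster when consecutive genes are
≤ 500 bp apart. Completeness is co-occurrence: {C,A,B} → `complete_CAB`,
plus amoX → `complete_ABCX`, plus amoD/amoE → `extended_DE`, anything
less → `partial:<subset>`. Strand agreement and canonical C-A-B order
along the coding strand are recorded as flags but not required, because
several ammonia-oxidizer lineages scatter or rearrange the subunits; the
summary also reports a strict count restricted to same-strand canonical
calls. Same-locus duplicates (ORFs overlapping ≥ 50% of the shorter
call) collapse to the best-supported call before clustering; the small
overlaps of adjacent genes in real operons are preserved. Neighbors are
the non-amo calls overlapping a ±2 kb window around the operon span by
at least one base.

## Diversity statistics

* **Contiguity**: lengths sorted descending; N50 is the length of the
  contig at which the cumulative length first reaches half the total,
  L50 the number of contigs to that point; N90/L90 analogously.
* **Community matrix**: each read is assigned to the dereplicated gene
  representative sharing the most distinct canonical 31-mers; ties are
  dropped as ambiguous, zero-sharers unmapped. Row sums equal mapped
  reads per sample.
* **Distance–decay (DDR)**: ordinary least squares of Bray–Curtis
  similarity (1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), on relative abundances by default)
  against log₁₀ pairwise distance; zero-distance pairs are excluded
  because the logarithm is undefined there. An optional Mantel
  permutation p-value (seeded) supplements the parametric one.
* **Taxa–area (TAR)**: for each ring radius r, samples within r pool
  cumulatively; richness is the number of variants with ≥ 1 count in the
  pool (no rarefaction — the simplest defensible definition; rarefaction
  can be added upstream of the fit); the slope of log₁₀ richness on
  log₁₀(πr²) is z. Archaeal and bacterial genes are analyzed separately,
  split by the domain label of each variant's best panel hit.
* **Clades**: archaeal amoA queries take the clade label (NP-α/γ/ζ/η,
  NT-α/γ vocabulary) of their nearest clade-labeled reference by global
  identity, threshold 0.5, ties to the lexicographically smallest label
  and flagged. This is nearest-reference classification, not placement
  on a curated phylogeny — adequate for a labeled in-package panel,
  not a substitute for the published multi-level taxonomy.
* **Trees**: Poisson-corrected distances d = −ln(1 − p) (p-distance from
  global alignment, capped at 0.95) under Saitou–Nei neighbor-joining
  (scikit-bio), negative branch lengths clamped to zero.

## The synthetic world

The generator provides every input with planted ground truth. Its
defaults are the study conditions of the package's tests.

**Panel.** Family ancestors are uniform-random proteins (A-subunits
250 ± 30 aa, others 200 ± 30, all starting with M); members arise by
per-site substitution at 5–20%, so within-family identity stays ≥ 60%.
Each pmo subunit ancestor is a 55%-mutated copy of its amo paralog
(40–50% residual identity), making amo/pmo discrimination a real task.
Archaeal amoA members descend from six clade sub-ancestors and carry
NP-*/NT-* labels; amoD/E are bacterial, amoX archaeal, and a few
unrelated "other" proteins (LlaDCHIA/ATPase stand-ins) support neighbor
annotation and decoy tests.

**Genomes.** Random background DNA (i.i.d. uniform ACGT) with one operon
planted: panel proteins reverse-translated with uniform synonymous codon
choice (no codon-bias model), stop codons appended, layouts cycling
through CAB / CABX / CAB+DE, intergenic gaps 20–120 bp, 150 bp flanks.
Genomes are regenerated until no canonical 21-mer repeats, so
reconstruction failures cannot hide behind repeats.

**Spatial design.** One central sample plus four samples on each of six
rings (1, 5, 10, 20, 50, 100 m), 25 samples total, ring angles
staggered.

**Community abundances.** Each variant v has an epicenter e_v and
abundance `a_v(s) = A_v · exp(−‖pos_s − e_v‖²/2σ²)` (σ = 50 m;
A_v log-normal) — log-abundance decays quadratically around the
epicenter. For uniformly scattered epicenters the expected Bray–Curtis
similarity is `S(d) = 1 − γ·erf(d / 2√2 σ)`, with γ the mass fraction of
spatially structured variants; the remaining mass sits in cosmopolitan
core variants (20% of the 500-variant pool). Calibration is by
construction: γ is first solved so the OLS slope of the expected S(d)
on log₁₀ d over the design's actual pair distances equals the planted
slope (−0.045 by default), then corrected once multiplicatively for the
finite-pool bias that relative-abundance normalization introduces,
measured on internal fixed-seed replicates. The taxa–area law is planted
exactly: each ring receives the computed number of rare ring-endemic
variants so cumulative pooled richness follows `N = N₁ (A/A₁)^z`
(z = 0.016 by default). Verified over 20 seeded replicates: mean fitted
DDR slope −0.0453 (planted −0.045), TAR slope 0.0160.

**Reads.** Uniform positions, random strand, substitution errors only
(0.5% default; indels are deliberately out of scope — the assembler's
cleaning contract is defined for substitution noise), optional
fixed-length-fragment mate pairs (290 bp), background reads at a
configured fraction. Every read's origin and template span are recorded.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: quality-score structure, PCR and GC bias,
codon usage, indel errors, strain microdiversity within a variant,
repeats shared between target genes and background, and real mudflat
community complexity (the tests run at 10²–10³ reads per sample, not
10⁸). The spatial model produces the planted slopes in expectation but
is far simpler than real biogeography.

## Problem sizes in tests and acceptance runs

The default test suite and `scripts/acceptance.py` use desk-scale
worlds chosen to finish in minutes on one CPU: single-operon genomes of
~2.5 kb, 20 fixtures per reconstruction arm (10× error-free merged
pairs; 20× single-end with 0.5% errors), 20-replicate slope sweeps on
the 25-sample design with 500-variant pools, 100 alignment-oracle
instances, 1000 contiguity-metric multisets, and 50 six-taxon NJ cases.

## Known limitations

* Seed-based recruitment misses homologs below ~35% identity lacking
  exact 5-mer matches; profile/HMM search is out of scope.
* The assembler does not scaffold with pair information, correct reads,
  or model indels; k values above the read length are skipped.
* Gene calls may over-extend to an upstream in-frame start codon.
* Chimera verdicts depend on candidate-pool composition; a panel with
  no relative of one parent segment leaves a splice unclassified.
* The TAR definition (cumulative ring pooling, presence richness) is one
  of several defensible choices; per-ring pooling is available behind a
  flag.
* Clade assignment is nearest-reference only and inherits the panel's
  label quality.
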