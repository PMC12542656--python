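"""Orchestration of the full targeted-assembly route.

The route mirrors the targeted arm of a gene-family recovery study:
reads are recruited against the panel at the relaxed threshold, the
recruited reads are co-assembled across a ladder of k values, genes are
called on the consensus contigs and re-annotated at the stringent
threshold, redundant variants are collapsed, chimeras are screened in
reference and de novo mode, operons are detected, and the diversity
statistics (contiguity metrics, community matrix, distance-decay and
taxa-area slopes, clades, tree) are computed.

Every stage's outputs are written under the run directory and listed in
a manifest together with the parameters and content hashes, so a rerun
under the same seed is byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .core_io import (ConfigError, Contig, GeneCall, ReadSet,
                      ReferencePanel, SampleDesign, write_fasta, write_gff3,
                      write_hits_tsv)
from . import assemble as asm
from . import chimera as chi
from . import ecodiv
from . import genecall as gc
from . import operon as op
from . import recruit as rec

logger = logging.getLogger("genetarget")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    panel: ReferencePanel
    reads: ReadSet
    design: Optional[SampleDesign] = None
    outdir: Optional[Path] = None
    seed: int = 0
    merge_pairs: bool = True
    per_sample: bool = False
    assembly: asm.AssemblyConfig = field(default_factory=asm.AssemblyConfig)
    annotation: gc.AnnotationConfig = field(default_factory=gc.AnnotationConfig)
    chimera: chi.ChimeraParams = field(default_factory=chi.ChimeraParams)
    operon: op.OperonParams = field(default_factory=op.OperonParams)


@dataclass
class GeneRecord:
    """A dereplicated, stringently annotated gene variant."""

    id: str
    contig_id: str
    family: str
    domain_label: str
    sequence: str       # nucleotide, coding orientation
    aa_sequence: str
    mean_coverage: float
    call: GeneCall


@dataclass
class PipelineResult:
    recruit: rec.RecruitResult = None
    contigs: list = field(default_factory=list)
    gene_calls: list = field(default_factory=list)
    genes: list = field(default_factory=list)          # list[GeneRecord]
    clusters: dict = field(default_factory=dict)
    verdicts_ref: list = field(default_factory=list)
    verdicts_denovo: list = field(default_factory=list)
    operons: list = field(default_factory=list)
    stats: Optional[ecodiv.AssemblyStats] = None
    matrix: Optional[pd.DataFrame] = None
    ddr: dict = field(default_factory=dict)            # domain -> SlopeFit
    tar: dict = field(default_factory=dict)
    clades: dict = field(default_factory=dict)         # gene id -> label
    tree: Optional[str] = None
    manifest: dict = field(default_factory=dict)

    @property
    def manifest_hash(self) -> str:
        payload = {k: v for k, v in self.manifest.items()
                   if k != "stage_seconds"}
        return hashlib.md5(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_targeted(config: PipelineConfig) -> PipelineResult:
    """Run the targeted-assembly route end to end."""
    if len(config.panel) == 0:
        raise ConfigError("pipeline needs a non-empty reference panel")
    result = PipelineResult()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - report the stage
                _write_manifest(result, config, stages, timings, outdir)
                raise StageError(name, exc) from exc
            stages.append(name)
            timings[name] = round(time.perf_counter() - t0, 3)
        return wrap

    index = rec.PanelIndex(config.panel)

    @stage("recruit")
    def _recruit():
        result.recruit = rec.recruit_reads(config.reads, config.panel,
                                           mode="relaxed", index=index)
        if outdir:
            write_hits_tsv(sorted(result.recruit.best_hits.values(),
                                  key=lambda h: h.query_id),
                           outdir / "hits.tsv")

    @stage("assemble")
    def _assemble():
        recruited = result.recruit.reads
        if config.merge_pairs:
            recruited = asm.merge_readset(recruited)
        if config.per_sample:
            contigs = []
            for sid in recruited.sample_ids():
                sub = ReadSet([r for r in recruited if r.sample_id == sid])
                for c in asm.assemble_multi_k(sub, config.assembly):
                    c.id = f"{sid}_{c.id}"
                    contigs.append(c)
            result.contigs = contigs
        else:
            result.contigs = asm.assemble_multi_k(recruited, config.assembly)
        if outdir:
            write_fasta(
                [(f"{c.id} k_origin={c.k_origin} cov={c.mean_coverage:.2f}",
                  c.sequence) for c in result.contigs],
                outdir / "contigs.fasta")

    @stage("genecall")
    def _genecall():
        calls = []
        for c in result.contigs:
            calls.extend(gc.call_orfs(c, config.annotation))
        result.gene_calls = gc.annotate_stringent(calls, config.panel,
                                                  config.annotation, index)

    @stage("dereplicate")
    def _derep():
        targeted = gc.filter_targeted(result.gene_calls)
        cov = {c.id: c.mean_coverage for c in result.contigs}
        seqs, meta = {}, {}
        by_contig = {c.id: c for c in result.contigs}
        for call in targeted:
            contig = by_contig[call.contig_id]
            nt = contig.sequence[call.start:call.end]
            if call.strand == "-":
                from .core_io import revcomp
                nt = revcomp(nt)
            seqs[call.id] = nt
            meta[call.id] = call
        reps, clusters = gc.dereplicate(seqs, config.annotation)
        result.clusters = clusters
        genes = []
        for i, rep in enumerate(reps):
            call = meta[rep]
            genes.append(GeneRecord(
                id=f"gene_{i:03d}", contig_id=call.contig_id,
                family=call.family,
                domain_label=(call.best_hit.domain_label
                              if call.best_hit else "unknown"),
                sequence=seqs[rep], aa_sequence=call.aa_sequence,
                mean_coverage=cov.get(call.contig_id, 0.0), call=call))
        result.genes = genes
        if outdir:
            write_fasta([(f"{g.id} family={g.family}", g.sequence)
                         for g in genes], outdir / "genes.fasta")
            write_fasta([(f"{g.id} family={g.family}", g.aa_sequence)
                         for g in genes], outdir / "genes.faa")

    @stage("chimera")
    def _chimera():
        result.verdicts_ref = []
        for g in result.genes:
            v = chi.detect_ref(g.id, g.aa_sequence, config.panel,
                               config.chimera, index)
            v.family = g.family
            result.verdicts_ref.append(v)
        queries = [Contig(id=g.id, sequence=g.sequence,
                          mean_coverage=g.mean_coverage)
                   for g in result.genes]
        result.verdicts_denovo = chi.detect_denovo(queries, config.chimera)
        fam = {g.id: g.family for g in result.genes}
        for v in result.verdicts_denovo:
            v.family = fam.get(v.query_id, "unassigned")
        if outdir:
            rows = [{
                "query": v.query_id, "mode": mode,
                "classification": v.classification,
                "parent_a": v.parent_a or "", "parent_b": v.parent_b or "",
                "crossover": v.crossover if v.crossover is not None else "",
                "d_score": v.d_score,
            } for mode, group in (("ref", result.verdicts_ref),
                                  ("denovo", result.verdicts_denovo))
                for v in group]
            pd.DataFrame(rows).to_csv(outdir / "chimera.tsv", sep="\t",
                                      index=False)

    @stage("operon")
    def _operon():
        targeted = gc.filter_targeted(result.gene_calls)
        result.operons = op.detect_operons(targeted, config.operon)
        for call in result.operons:
            op.annotate_neighbors(call, result.gene_calls,
                                  config.operon.neighbor_window)
        if outdir:
            op.operon_summary(result.operons).to_csv(
                outdir / "operons.tsv", sep="\t", index=False)
            write_gff3(targeted, result.operons, outdir / "calls.gff3")

    @stage("stats")
    def _stats():
        if result.contigs:
            result.stats = ecodiv.assembly_stats(
                [len(c.sequence) for c in result.contigs])

    @stage("diversity")
    def _diversity():
        if not result.genes or config.design is None:
            return
        representatives = {g.id: g.sequence for g in result.genes}
        result.matrix = ecodiv.map_reads(config.reads, representatives)
        domain_of = {g.id: g.domain_label for g in result.genes}
        for domain in ("archaea", "bacteria"):
            cols = [g for g in result.matrix.columns
                    if domain_of.get(g) == domain]
            if len(cols) < 1:
                continue
            sub = result.matrix[cols]
            try:
                result.ddr[domain] = ecodiv.fit_ddr(sub, config.design,
                                                    seed=config.seed)
            except ValueError:
                pass
            try:
                result.tar[domain] = ecodiv.fit_tar(sub, config.design)
            except ValueError:
                pass
        for g in result.genes:
            if g.family == "amoA" and g.domain_label == "archaea":
                result.clades[g.id] = ecodiv.assign_clade(
                    g.aa_sequence, config.panel).label
        if len(result.genes) >= 3:
            result.tree = ecodiv.nj_tree(
                {g.id: g.aa_sequence for g in result.genes})
        if outdir:
            result.matrix.to_csv(outdir / "matrix.tsv", sep="\t")
            if result.tree:
                (outdir / "tree.nwk").write_text(result.tree + "\n")

    _write_manifest(result, config, stages, timings, outdir)
    return result


def _write_manifest(result: PipelineResult, config: PipelineConfig,
                    stages: list[str], timings: dict,
                    outdir: Optional[Path]) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "parameters": {
            "k_list": list(config.assembly.k_list),
            "min_contig_len": config.assembly.min_contig_len,
            "merge_identity": config.assembly.merge_identity,
            "min_orf_aa": config.annotation.min_orf_aa,
            "derep_identity": config.annotation.derep_identity,
            "chimera_d_min": config.chimera.d_min,
            "operon_max_gap": config.operon.max_gap,
            "per_sample": config.per_sample,
        },
        "n_reads": len(config.reads),
        "n_recruited": len(result.recruit) if result.recruit else 0,
        "n_contigs": len(result.contigs),
        "n_genes": len(result.genes),
        "n_operons": len(result.operons),
        "output_md5": {},
        "stage_seconds": timings,
    }
    if outdir:
        for f in sorted(outdir.glob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["output_md5"][f.name] = hashlib.md5(
                    f.read_bytes()).hexdigest()
    result.manifest = manifest
    if outdir:
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult, truth) -> dict:
    """Compare a pipeline run with the generator's ground truth.

    Reports recruiter recall/precision over read origins, the fraction of
    planted operons recovered with the correct completeness class,
    chimera recall and false-positive rate when chimeras were planted,
    and per-family gene counts.
    """
    report: dict = {}
    origin = truth.read_origin
    if origin and result.recruit is not None:
        recruited = {r.id for r in result.recruit.reads}
        target_reads = {rid for rid, o in origin.items()
                        if o != "background"}
        back_reads = set(origin) - target_reads
        tp = len(recruited & target_reads)
        fp = len(recruited & back_reads)
        report["recruit_recall"] = tp / len(target_reads) if target_reads else None
        report["recruit_precision"] = tp / (tp + fp) if (tp + fp) else None
        inside = truth.reads_inside_cds()
        if inside:
            report["recruit_recall_cds"] = len(recruited & inside) / len(inside)
    if truth.operons:
        expected = []
        for planted in truth.operons.values():
            fams = {p.family for p in planted if p.family != "other"}
            expected.append(_expected_class(fams))
        found = [o.completeness_class for o in result.operons]
        recovered = 0
        pool = list(found)
        for cls in expected:
            if cls in pool:
                pool.remove(cls)
                recovered += 1
        report["operon_expected"] = len(expected)
        report["operon_recovered_complete"] = recovered
        report["operon_recovery"] = recovered / len(expected) if expected else None
    fam_counts: dict[str, int] = {}
    for g in result.genes:
        fam_counts[g.family] = fam_counts.get(g.family, 0) + 1
    report["gene_counts"] = fam_counts
    if truth.chimeras:
        planted_ids = {c.id for c in truth.chimeras}
        flagged = {v.query_id for v in result.verdicts_ref
                   if v.classification == "chimeric"}
        report["chimera_recall"] = (len(flagged & planted_ids)
                                    / len(planted_ids))
        clean = {v.query_id for v in result.verdicts_ref} - planted_ids
        report["chimera_fpr"] = (len(flagged - planted_ids) / len(clean)
                                 if clean else 0.0)
    return report


def _expected_class(families: set) -> str:
    from .operon import _completeness
    return _completeness(set(families))
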