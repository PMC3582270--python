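"""High-level per-dataset pipeline steps over the library modules.

Each function takes a :class:`~spliceflow.engine.ProjectConfig` plus a dataset
name, reads what it needs, and writes tabular results into the project's
file-backed stores.  The rule-graph engine (and the CLI) wire these into the
default qc -> map -> quant -> discover pipeline; they are equally usable
straight from Python.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import discovery, formats, postmap, qc, quant
from .annotation import JunctionContig, JunctionLibrary, build_junction_library, extract_transcriptome
from .core import AlignmentRecord, Junction, ReadRecord
from .engine import (
    DatasetConfig,
    ProjectConfig,
    ResultsStore,
    RuleGraph,
    StateStore,
    run as engine_run,
)
from .mapping import MappingParams, iterative_map, merge_mappings

log = logging.getLogger("spliceflow")


def mapping_params(cfg: ProjectConfig) -> MappingParams:
    p = cfg.params
    return MappingParams(
        initial_mismatches=p.get("mismatches", 2),
        mismatch_per_nt=p.get("mismatch_per_nt", 25),
        trim_step=p.get("trim_step", 10),
        min_length=p.get("min_length", 25),
        min_span=p.get("min_span", 4),
        min_segment=p.get("min_segment", 10),
        intron_range=tuple(p.get("intron_range", (40, 500_000))),
        allow_gc_ag=p.get("allow_gc_ag", False),
    )


def load_reads(ds: DatasetConfig) -> Tuple[List[ReadRecord], List[tuple]]:
    """Read a dataset's library; returns (all reads, mate pairs)."""
    if ds.paired and len(ds.reads) == 2:
        pairs = list(formats.read_paired_sequences(ds.reads[0], ds.reads[1], ds.format))
        reads = [r for p in pairs for r in p]
        return reads, pairs
    reads = []
    for path in ds.reads:
        reads.extend(formats.read_sequences(path, ds.format))
    if ds.paired:  # interleaved
        by_stem: Dict[str, dict] = {}
        for r in reads:
            by_stem.setdefault(r.read_id, {})[r.mate_index] = r
        pairs = [(m[1], m[2]) for m in by_stem.values() if 1 in m and 2 in m]
        return reads, pairs
    return reads, []


def _peek_read_length(ds: DatasetConfig, n: int = 100) -> int:
    longest = 0
    count = 0
    for path in ds.reads:
        for r in formats.read_sequences(path, ds.format):
            longest = max(longest, len(r))
            count += 1
            if count >= n:
                return longest
    return longest


# ---------------------------------------------------------------------------
# Junction-library cache (the shared, annotation-derived store)


def _library_to_table(lib: JunctionLibrary) -> pd.DataFrame:
    rows = []
    for j in lib:
        contig = lib.contigs.get(j.junction_id)
        lb = contig.left_block if contig else (j.donor_end, j.donor_end)
        rb = contig.right_block if contig else (j.acceptor_start, j.acceptor_start)
        rows.append(
            (j.chrom, j.donor_end, j.acceptor_start, j.strand, j.origin_class,
             lb[0], rb[1])
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "donor_end", "acceptor_start", "strand", "origin",
                 "left_start", "right_end"],
    )


def _library_from_table(table: pd.DataFrame, genome: dict, flank: int) -> JunctionLibrary:
    lib = JunctionLibrary(flank=flank)
    for row in table.itertuples(index=False):
        j = Junction(row.chrom, int(row.donor_end), int(row.acceptor_start),
                     row.strand, row.origin)
        lib.junctions[j.key] = j
        seq = genome[row.chrom]
        lb = (int(row.left_start), j.donor_end)
        rb = (j.acceptor_start, int(row.right_end))
        lib.contigs[j.junction_id] = JunctionContig(
            junction=j,
            sequence=seq[lb[0] : lb[1]] + seq[rb[0] : rb[1]],
            left_block=lb,
            right_block=rb,
            truncated=(lb[1] - lb[0] < flank) or (rb[1] - rb[0] < flank),
        )
    return lib


def get_junction_library(
    store: ResultsStore, model, genome: dict, flank: int, min_intron: int = 40
) -> JunctionLibrary:
    """Build the junction library, or reuse the cached copy in the common
    store (one build serves every dataset of the project)."""
    table_name = f"junction_library_flank{flank}"
    if store.has(table_name):
        log.info("junction library cache hit (%s)", table_name)
        return _library_from_table(store.get(table_name), genome, flank)
    lib = build_junction_library(model, genome, flank=flank, min_intron=min_intron)
    store.put(table_name, _library_to_table(lib))
    return lib


# ---------------------------------------------------------------------------
# Steps


def run_qc(cfg: ProjectConfig, dataset: str) -> qc.QCReport:
    ds = cfg.datasets[dataset]
    store = ResultsStore(cfg.results_dir)
    store.add_dataset(dataset)
    reads, _ = load_reads(ds)
    report = qc.compute_qc(reads)
    store.put("qc_summary", report.summary_table(), dataset=dataset)
    store.put("qc_per_cycle", report.per_cycle_table(), dataset=dataset)
    return report


def run_mapping(cfg: ProjectConfig, dataset: str):
    """Map a dataset (or ingest its prealigned file) and write the merged SAM
    plus the mapping summary."""
    ds = cfg.datasets[dataset]
    store = ResultsStore(cfg.results_dir)
    out_dir = store.add_dataset(dataset)
    genome = formats.read_genome(cfg.genome)
    merged_path = out_dir / "merged.sam"

    if ds.alignments:
        records = formats.read_alignments(ds.alignments, format=ds.alignments.rsplit(".", 1)[-1])
        formats.write_alignments(
            records, str(merged_path), {k: len(v) for k, v in genome.items()}
        )
        grouped: Dict[tuple, list] = {}
        for r in records:
            grouped.setdefault((r.read_id, r.mate_index), []).append(r)
        classified = postmap.classify_uniqueness(grouped)
        summary = postmap.classification_summary(classified, total_reads=len(grouped))
        store.put(
            "mapping_summary",
            pd.DataFrame(
                [("total", summary.total_reads), ("unique", summary.mapped_unique),
                 ("multi", summary.mapped_multi), ("unmapped", summary.unmapped),
                 ("provenance", "external")],
                columns=["metric", "value"],
            ),
            dataset=dataset,
        )
        return summary

    model = formats.read_annotation(cfg.annotation, genome=genome)
    params = mapping_params(cfg)
    flank = cfg.params.get("flank") or max(_peek_read_length(ds) - 1, 1)
    library = get_junction_library(store, model, genome, flank,
                                   cfg.params.get("min_intron", 40))
    reads, _ = load_reads(ds)
    result = iterative_map(reads, genome, library, params)
    summary = merge_mappings(
        result, {k: len(v) for k, v in genome.items()}, str(merged_path)
    )
    rows = [("total", summary.total_reads), ("unique", summary.mapped_unique),
            ("multi", summary.mapped_multi), ("unmapped", summary.unmapped)]
    rows += [(f"stage:{k}", v) for k, v in sorted(summary.per_stage.items())]
    store.put("mapping_summary", pd.DataFrame(rows, columns=["metric", "value"]),
              dataset=dataset)
    return result


def _load_merged(cfg: ProjectConfig, dataset: str):
    store = ResultsStore(cfg.results_dir)
    merged = store.dataset_dir(dataset) / "merged.sam"
    records = formats.read_alignments(str(merged))
    grouped: Dict[tuple, list] = {}
    for r in records:
        grouped.setdefault((r.read_id, r.mate_index), []).append(r)
    return store, grouped


def run_quant(cfg: ProjectConfig, dataset: str, use_rescued: bool = False) -> dict:
    """Classify the merged mapping and quantify genes/exons/junctions/
    transcripts, exon inclusion, and the read-position bias profile."""
    ds = cfg.datasets[dataset]
    store, grouped = _load_merged(cfg, dataset)
    genome = formats.read_genome(cfg.genome)
    model = formats.read_annotation(cfg.annotation, genome=genome)
    flank = cfg.params.get("flank") or (max(_peek_read_length(ds) - 1, 1) if ds.reads else 74)
    library = get_junction_library(store, model, genome, flank,
                                   cfg.params.get("min_intron", 40))

    classified = postmap.classify_uniqueness(grouped)
    if ds.paired:
        postmap.rescue_mates(classified)
    uniq = postmap.unique_records(classified, use_rescued=use_rescued)
    total_mapped = len(classified)

    gene_exon = quant.quantify_overlap(uniq, model, total_mapped)
    junctions = quant.quantify_junctions(uniq, library, genome=genome)
    inclusion = quant.exon_inclusion(uniq, model)
    transcripts = quant.deconvolve_transcripts(uniq, model, total_mapped)
    bias = quant.position_bias(uniq, model)

    store.put("quant_genes", quant.quant_table([q for q in gene_exon if q.feature_type == "gene"]), dataset=dataset)
    store.put("quant_exons", quant.quant_table([q for q in gene_exon if q.feature_type == "exon"]), dataset=dataset)
    store.put("quant_transcripts", quant.quant_table(transcripts), dataset=dataset)
    store.put("quant_junctions", quant.junction_table(junctions), dataset=dataset)
    store.put("exon_inclusion", quant.inclusion_table(inclusion), dataset=dataset)
    bias_rows = [
        (label, i, int(n)) for label, hist in bias.items() for i, n in enumerate(hist)
    ]
    store.put("position_bias", pd.DataFrame(bias_rows, columns=["length_bin", "bin", "reads"]), dataset=dataset)
    return {
        "classified": classified,
        "gene_exon": gene_exon,
        "junctions": junctions,
        "inclusion": inclusion,
        "transcripts": transcripts,
        "bias": bias,
    }


def run_discovery(cfg: ProjectConfig, dataset: str) -> dict:
    ds = cfg.datasets[dataset]
    store, grouped = _load_merged(cfg, dataset)
    genome = formats.read_genome(cfg.genome)
    model = formats.read_annotation(cfg.annotation, genome=genome)
    flank = cfg.params.get("flank") or (max(_peek_read_length(ds) - 1, 1) if ds.reads else 74)
    library = get_junction_library(store, model, genome, flank,
                                   cfg.params.get("min_intron", 40))
    classified = postmap.classify_uniqueness(grouped)
    uniq = postmap.unique_records(classified)

    clusters = discovery.build_clusters(uniq, stranded=ds.stranded)
    novel = discovery.collect_novel_junctions(uniq, library, genome=genome)
    store.put("read_clusters", discovery.cluster_table(clusters), dataset=dataset)
    store.put("novel_junctions", quant.junction_table(novel), dataset=dataset)

    chimeras = []
    if ds.paired and ds.reads:
        _, pairs = load_reads(ds)
        transcriptome = extract_transcriptome(model, genome)
        chimeras = discovery.detect_chimeras(
            pairs, model, transcriptome=transcriptome,
            max_mismatches=cfg.params.get("mismatches", 2),
        )
        store.put("chimeras", discovery.chimera_table(chimeras), dataset=dataset)
    return {"clusters": clusters, "novel_junctions": novel, "chimeras": chimeras}


# ---------------------------------------------------------------------------
# Rule graph wiring


def build_pipeline_graph(cfg: ProjectConfig, dataset: str) -> RuleGraph:
    """The default dependency graph with Python-callable steps."""
    g = RuleGraph()
    g.add("start", [], [])
    g.add("qc", ["start"], [lambda: run_qc(cfg, dataset)])
    g.add("map", ["qc"], [lambda: run_mapping(cfg, dataset)])
    g.add("quant", ["map"], [lambda: run_quant(cfg, dataset)])
    g.add("discover", ["quant"], [lambda: run_discovery(cfg, dataset)])
    g.validate()
    return g


def run_project(cfg: ProjectConfig, dataset: str, target: str = "discover",
                graph: Optional[RuleGraph] = None):
    """Run one dataset's pipeline to ``target`` with resumable state.

    Prealigned datasets (an ``alignments`` entry in the config) keep the map
    step, but it ingests the external file instead of mapping."""
    cfg.validate()
    store = ResultsStore(cfg.results_dir)
    ds_dir = store.add_dataset(dataset)
    state = StateStore(str(ds_dir / "state.json"))
    if graph is None:
        graph = build_pipeline_graph(cfg, dataset)
    return engine_run(graph, target, state, workdir=str(ds_dir),
                      log_dir=str(ds_dir / "logs"))
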