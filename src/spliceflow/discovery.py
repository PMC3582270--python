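"""Discovery of novel transcribed elements.

Read clusters are connected components of uniquely mapping reads under
segment-wise genomic overlap — the two exonic blocks of a split read anchor it
to both flanks, but the intron gap itself covers nothing, so unrelated reads
inside an intron never fuse clusters.  There is no minimum read count; each
cluster reports its read count and the number of staggered reads (distinct 5'
start positions).

Chimeric RNA candidates come from paired ends mapped to the transcriptome:
pairs where both mates map uniquely (after collapsing hits with an identical
genomic projection, so isoforms sharing an exon do not destroy uniqueness)
and to different transcripts are classified as unannotated splice variants
when the two transcripts belong to the same gene, and putative chimeras or
fusions otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .annotation import JunctionLibrary, extract_transcriptome
from .core import AlignmentRecord, GeneModel, ReadRecord
from .mapping import ExhaustiveAligner, best_stratum, is_split_stage, stage_base
from .quant import JunctionQuant, quantify_junctions

SPLICE_VARIANT = "unannotated_splice_variant"
PUTATIVE_CHIMERA = "putative_chimera"


@dataclass
class ReadCluster:
    chrom: str
    start: int
    end: int
    strand: str  # '.' for unstranded clustering
    read_count: int
    staggered_count: int
    source: str  # genomic | junction | split | all

    def __post_init__(self):
        if not (self.read_count >= self.staggered_count >= 1):
            raise ValueError("cluster must satisfy read_count >= staggered_count >= 1")
        if self.end <= self.start:
            raise ValueError("empty cluster interval")


@dataclass(frozen=True)
class ChimeraCandidate:
    read_pair_id: str
    transcript_a: str
    transcript_b: str
    gene_a: str
    gene_b: str
    classification: str


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


_SOURCE_STAGES = {"genomic": "genome", "junction": "junction", "split": "split"}


def build_clusters(
    alignments: List[AlignmentRecord],
    source: Optional[str] = None,
    stranded: bool = False,
) -> List[ReadCluster]:
    """Cluster uniquely mapping reads by genomic overlap.

    ``source`` restricts the input to one mapping stage ('genomic',
    'junction' or 'split'); ``stranded`` keeps strands apart.  Overlap is
    segment-wise; components are found by a sweep over sorted segments (the
    brute-force union-find over pairwise overlaps is the test oracle).
    """
    if source is not None:
        if source not in _SOURCE_STAGES:
            raise ValueError(f"unknown cluster source {source!r}")
        wanted = _SOURCE_STAGES[source]
        alignments = [r for r in alignments if stage_base(r.stage) == wanted]
    if not alignments:
        return []

    uf = _UnionFind(len(alignments))
    groups: Dict[tuple, List[Tuple[int, int, int]]] = {}
    for i, rec in enumerate(alignments):
        gkey = (rec.chrom, rec.strand) if stranded else (rec.chrom,)
        for s, e in rec.segments:
            groups.setdefault(gkey, []).append((s, e, i))
    for segs in groups.values():
        segs.sort()
        chain_end = -1
        chain_rep = -1
        for s, e, i in segs:
            if s < chain_end:
                uf.union(chain_rep, i)
                chain_end = max(chain_end, e)
            else:
                chain_rep, chain_end = i, e

    members: Dict[int, List[AlignmentRecord]] = {}
    for i, rec in enumerate(alignments):
        members.setdefault(uf.find(i), []).append(rec)

    clusters = []
    for recs in members.values():
        starts = [s for r in recs for s, _ in r.segments]
        ends = [e for r in recs for _, e in r.segments]
        five_prime = {(r.strand, r.start if r.strand != "-" else r.end) for r in recs}
        clusters.append(
            ReadCluster(
                chrom=recs[0].chrom,
                start=min(starts),
                end=max(ends),
                strand=recs[0].strand if stranded else ".",
                read_count=len(recs),
                staggered_count=len(five_prime),
                source=source or "all",
            )
        )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end))
    return clusters


def _transcript_genomic_projection(model: GeneModel, tx_id: str, hit_pos: int,
                                   length: int) -> Optional[tuple]:
    tx = model.transcript(tx_id)
    if hit_pos + length > tx.length:
        return None
    return (tx.chrom, tuple(tx.genomic_blocks_for(hit_pos, hit_pos + length)))


def _unique_transcript_hits(
    read: ReadRecord,
    aligner: ExhaustiveAligner,
    model: GeneModel,
    max_mismatches: int,
) -> Optional[set]:
    """Set of transcript ids at the mate's single best-stratum genomic locus,
    or None if the mate is unmapped or multi-mapping across loci."""
    hits = best_stratum(aligner.search(read.sequence, max_mismatches))
    if not hits:
        return None
    loci: Dict[tuple, set] = {}
    for h in hits:
        proj = _transcript_genomic_projection(model, h.ref, h.pos, len(read.sequence))
        loci.setdefault(proj, set()).add(h.ref)
    if len(loci) != 1:
        return None
    return next(iter(loci.values()))


def detect_chimeras(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]],
    model: GeneModel,
    transcriptome: Optional[Dict[str, str]] = None,
    genome: Optional[dict] = None,
    max_mismatches: int = 2,
) -> List[ChimeraCandidate]:
    """Classify read pairs whose mates map uniquely to different transcripts.

    Requires paired-end input.  Mates on the same transcript (or whose unique
    loci share a transcript) emit nothing.
    """
    if transcriptome is None:
        if genome is None:
            raise ValueError("need either a transcriptome or a genome to extract it")
        transcriptome = extract_transcriptome(model, genome)
    aligner = ExhaustiveAligner(transcriptome)
    out = []
    for pair in pairs:
        if not isinstance(pair, tuple) or len(pair) != 2:
            raise ValueError("chimera detection requires paired ends")
        r1, r2 = pair
        txs1 = _unique_transcript_hits(r1, aligner, model, max_mismatches)
        txs2 = _unique_transcript_hits(r2, aligner, model, max_mismatches)
        if txs1 is None or txs2 is None:
            continue
        if txs1 & txs2:
            continue  # compatible with one transcript: not a candidate
        genes1 = {model.gene_of_transcript(t).gene_id for t in txs1}
        genes2 = {model.gene_of_transcript(t).gene_id for t in txs2}
        ta, tb = sorted(txs1)[0], sorted(txs2)[0]
        if genes1 & genes2:
            shared = sorted(genes1 & genes2)[0]
            out.append(
                ChimeraCandidate(r1.read_id, ta, tb, shared, shared, SPLICE_VARIANT)
            )
        else:
            out.append(
                ChimeraCandidate(
                    r1.read_id, ta, tb, sorted(genes1)[0], sorted(genes2)[0],
                    PUTATIVE_CHIMERA,
                )
            )
    return out


def collect_novel_junctions(
    alignments: List[AlignmentRecord],
    library: JunctionLibrary,
    genome: Optional[dict] = None,
) -> List[JunctionQuant]:
    """Deduplicated split-map junctions absent from the library, with
    spanning read counts (the novel-from-unannotated-exons class)."""
    split_recs = [r for r in alignments if is_split_stage(r.stage)]
    quants = quantify_junctions(split_recs, library, genome=genome)
    return [q for q in quants if q.novelty == "novel_unannotated"]


def cluster_table(clusters: List[ReadCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, f"cluster_{i}", c.read_count, c.strand,
             c.staggered_count, c.source)
            for i, c in enumerate(clusters, start=1)
        ],
        columns=["chrom", "start", "end", "name", "reads", "strand", "staggered", "source"],
    )


def chimera_table(candidates: List[ChimeraCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.read_pair_id, c.transcript_a, c.transcript_b, c.gene_a, c.gene_b,
             c.classification)
            for c in candidates
        ],
        columns=["read_pair_id", "transcript_a", "transcript_b", "gene_a", "gene_b",
                 "classification"],
    )
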