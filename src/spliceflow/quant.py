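"""Quantification of exons, genes, junctions and transcripts.

Exons and genes are quantified by simple overlap: a uniquely mapping read
counts for a feature iff every aligned base lies within the feature's span
(for genes, the union of exon intervals).  A read inside two overlapping
exons counts for each, so overlapping-exon quantifications are deliberately
overestimates.  Values are reported as raw counts and RPKM (reads per
kilobase of feature per million mapped reads).

Junctions are counted by reads whose split boundary matches the donor and
acceptor exactly — no length normalization is needed — and classified as
known (in the annotation), novel (a junction between annotated exons of one
gene that is not annotated itself) or novel-from-unannotated (split-map
junctions with at least one unannotated side, including anything joining two
different genes).

Per-transcript abundances come from a splicing-graph linear system: exonic
segments and junctions of a locus give one equation each, relating observed
read evidence to the per-transcript read densities, solved by non-negative
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.optimize import nnls

from .annotation import JunctionLibrary
from .core import (
    AlignmentRecord,
    Gene,
    GeneModel,
    Junction,
    NOVELTY_KNOWN,
    NOVELTY_NOVEL,
    NOVELTY_UNANNOTATED,
    ORIGIN_KNOWN,
    ORIGIN_LEGAL,
)
from .mapping import splice_strand


@dataclass(frozen=True)
class QuantRecord:
    feature_id: str
    feature_type: str  # exon | gene | junction | transcript
    raw_count: float
    rpkm: float


@dataclass(frozen=True)
class InclusionRecord:
    """Evidence for an internal exon's inclusion.

    ``inclusion_index`` is inclusion/(inclusion+exclusion), in [0,1]; the raw
    counts are kept so the unbounded inclusion/exclusion ratio is recoverable.
    Absent (None) when there is no evidence either way.
    """

    exon_id: str
    inclusion_reads: int
    exclusion_reads: int
    inclusion_index: Optional[float]


@dataclass(frozen=True)
class JunctionQuant:
    junction: Junction
    spanning_read_count: int
    novelty: str


def rpkm(raw_count: float, feature_length: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return raw_count / ((feature_length / 1000.0) * (total_mapped / 1_000_000.0))


def exon_feature_id(gene_id: str, exon) -> str:
    return f"{gene_id}:{exon.chrom}:{exon.start}-{exon.end}"


def _contained_in_interval(rec: AlignmentRecord, start: int, end: int) -> bool:
    return all(start <= s and e <= end for s, e in rec.segments)


def _contained_in_union(rec: AlignmentRecord, merged: List[Tuple[int, int]]) -> bool:
    """Every aligned base within the union of (sorted, merged) intervals."""
    for s, e in rec.segments:
        ok = any(ms <= s and e <= me for ms, me in merged)
        if not ok:
            return False
    return True


def quantify_overlap(
    alignments: List[AlignmentRecord],
    model: GeneModel,
    total_mapped: int,
) -> List[QuantRecord]:
    """Simple-overlap quantification of exons and genes from unique reads."""
    exon_trees: Dict[str, IntervalTree] = {}
    gene_trees: Dict[str, IntervalTree] = {}
    exon_info = {}  # feature_id -> (start, end, length)
    gene_info = {}  # gene_id -> (merged intervals, union length)
    for gene in model:
        span = gene.span
        gene_trees.setdefault(gene.chrom, IntervalTree()).addi(span[0], span[1], gene.gene_id)
        merged = gene.merged_exon_intervals()
        gene_info[gene.gene_id] = (merged, sum(e - s for s, e in merged))
        for exon in gene.exons:
            fid = exon_feature_id(gene.gene_id, exon)
            exon_trees.setdefault(gene.chrom, IntervalTree()).addi(exon.start, exon.end, fid)
            exon_info[fid] = (exon.start, exon.end, len(exon))

    exon_counts = {fid: 0 for fid in exon_info}
    gene_counts = {gid: 0 for gid in gene_info}
    for rec in alignments:
        lo, hi = rec.start, rec.end
        for iv in exon_trees.get(rec.chrom, IntervalTree()).overlap(lo, hi):
            s, e, _ = exon_info[iv.data]
            if _contained_in_interval(rec, s, e):
                exon_counts[iv.data] += 1
        for iv in gene_trees.get(rec.chrom, IntervalTree()).overlap(lo, hi):
            merged, _ = gene_info[iv.data]
            if _contained_in_union(rec, merged):
                gene_counts[iv.data] += 1

    out = [
        QuantRecord(fid, "exon", exon_counts[fid], rpkm(exon_counts[fid], info[2], total_mapped))
        for fid, info in exon_info.items()
    ]
    out += [
        QuantRecord(gid, "gene", gene_counts[gid], rpkm(gene_counts[gid], info[1], total_mapped))
        for gid, info in gene_info.items()
    ]
    return out


def quantify_junctions(
    alignments: List[AlignmentRecord],
    library: JunctionLibrary,
    genome: Optional[dict] = None,
) -> List[JunctionQuant]:
    """Count reads spanning each observed junction (exact donor/acceptor
    boundary match) and classify its novelty."""
    counts: Dict[Tuple[str, int, int], int] = {}
    strands: Dict[Tuple[str, int, int], str] = {}
    for rec in alignments:
        for donor, acceptor in rec.junctions():
            key = (rec.chrom, donor, acceptor)
            counts[key] = counts.get(key, 0) + 1
            strands.setdefault(key, rec.strand)

    by_coord = {(j.chrom, j.donor_end, j.acceptor_start): j for j in library}
    out = []
    for (chrom, donor, acceptor), n in sorted(counts.items()):
        lib_j = by_coord.get((chrom, donor, acceptor))
        if lib_j is not None:
            novelty = NOVELTY_KNOWN if lib_j.origin_class == ORIGIN_KNOWN else NOVELTY_NOVEL
            junction = lib_j
        else:
            novelty = NOVELTY_UNANNOTATED
            strand = None
            if genome is not None:
                strand = splice_strand(genome, chrom, donor, acceptor)
            junction = Junction(
                chrom, donor, acceptor, strand or strands[(chrom, donor, acceptor)], "novel_split"
            )
        out.append(JunctionQuant(junction, n, novelty))
    return out


def exon_inclusion(
    alignments: List[AlignmentRecord],
    model: GeneModel,
) -> List[InclusionRecord]:
    """Inclusion evidence for every annotated internal exon.

    Inclusion reads: unique reads fully inside the exon body, plus reads on
    junctions joining the exon to another exon of its gene.  Exclusion reads:
    reads on junctions of the same gene that link an exon upstream of this one
    to an exon downstream of it, skipping it entirely.
    """
    jcounts: Dict[Tuple[str, int, int], int] = {}
    by_chrom: Dict[str, List[AlignmentRecord]] = {}
    for rec in alignments:
        by_chrom.setdefault(rec.chrom, []).append(rec)
        for donor, acceptor in rec.junctions():
            key = (rec.chrom, donor, acceptor)
            jcounts[key] = jcounts.get(key, 0) + 1

    out = []
    for gene in model:
        exons = gene.exons
        starts = {e.start for e in exons}
        ends = {e.end for e in exons}
        gene_junctions = [
            (d, a, n)
            for (chrom, d, a), n in jcounts.items()
            if chrom == gene.chrom and d in ends and a in starts
        ]
        recs = by_chrom.get(gene.chrom, [])
        for exon in model.internal_exons(gene):
            body = sum(
                1 for r in recs if _contained_in_interval(r, exon.start, exon.end)
            )
            inc_junc = sum(
                n for d, a, n in gene_junctions if d == exon.end or a == exon.start
            )
            exc = sum(
                n for d, a, n in gene_junctions if d <= exon.start and a >= exon.end
            )
            inc = body + inc_junc
            index = inc / (inc + exc) if (inc + exc) > 0 else None
            out.append(
                InclusionRecord(exon_feature_id(gene.gene_id, exon), inc, exc, index)
            )
    return out


DEFAULT_LENGTH_BINS = (0, 500, 1000, 2000, 5000)


def _compatible_transcript_position(rec: AlignmentRecord, tx) -> Optional[int]:
    """Transcript coordinate of the read's 5' end if the read lies fully on
    the transcript's exon structure (split boundaries must match its introns),
    else None."""
    gpos = rec.start if tx.strand != "-" else rec.end - 1
    tpos = tx.genomic_to_transcript(gpos)
    if tpos is None or tpos + rec.effective_read_length > tx.length:
        return None
    expected = tx.genomic_blocks_for(tpos, tpos + rec.effective_read_length)
    if tuple(expected) != tuple(rec.segments):
        return None
    return tpos


def position_bias(
    alignments: List[AlignmentRecord],
    model: GeneModel,
    length_bins: Tuple[int, ...] = DEFAULT_LENGTH_BINS,
    n_bins: int = 20,
) -> Dict[str, np.ndarray]:
    """Histogram of relative read start positions (5'->3', strand-aware) along
    transcripts, one histogram per transcript-length bin.

    A read compatible with several transcripts contributes once to each.
    Returns bin label -> integer histogram of ``n_bins`` cells.
    """
    edges = list(length_bins) + [np.inf]
    labels = [
        f"{edges[i]}-{edges[i+1] if np.isfinite(edges[i+1]) else 'inf'}"
        for i in range(len(edges) - 1)
    ]
    hists = {lab: np.zeros(n_bins, dtype=int) for lab in labels}

    tx_list = []
    for gene in model:
        for tx in gene.transcripts:
            idx = np.searchsorted(edges, tx.length, side="right") - 1
            tx_list.append((tx, labels[max(0, min(idx, len(labels) - 1))]))

    for rec in alignments:
        for tx, label in tx_list:
            if tx.chrom != rec.chrom:
                continue
            tpos = _compatible_transcript_position(rec, tx)
            if tpos is None:
                continue
            denom = tx.length - rec.effective_read_length
            rel = tpos / denom if denom > 0 else 0.0
            hists[label][min(int(rel * n_bins), n_bins - 1)] += 1
    return hists


def _gene_segments(gene: Gene) -> List[Tuple[int, int]]:
    """Exon projection: split the gene's exonic space at every exon boundary,
    yielding the minimal segments each transcript either fully contains or
    fully lacks."""
    bounds = sorted({p for e in gene.exons for p in (e.start, e.end)})
    merged = gene.merged_exon_intervals()
    segs = []
    for lo, hi in zip(bounds, bounds[1:]):
        if any(ms <= lo and hi <= me for ms, me in merged):
            segs.append((lo, hi))
    return segs


def _segment_coefficient(tstart: int, tend: int, M: int, L: int) -> float:
    """Expected aligned bases in transcript interval [tstart, tend), per unit
    read density (reads per valid start position), divided by L.

    Under uniform starts over [0, M-L], coverage depth at position p is
    min(p+1, L, M-L+1, M-p) — full depth L in the interior, tapering at the
    transcript ends.  Exact, so short transcripts are handled without bias.
    """
    if M < L:
        return 0.0
    p = np.arange(tstart, tend)
    depth = np.minimum.reduce([p + 1, np.full_like(p, L), np.full_like(p, M - L + 1), M - p])
    return float(np.clip(depth, 0, None).sum()) / L


def _junction_coefficient(c: int, M: int, L: int, min_span: int) -> float:
    """Number of valid start positions placing a read across the junction at
    transcript coordinate ``c`` with at least ``min_span`` nt on each side
    (the junction-mapping filter)."""
    if M < L:
        return 0.0
    lo = max(0, c - L + min_span)
    hi = min(M - L, c - min_span)
    return float(max(0, hi - lo + 1))


def deconvolve_transcripts(
    alignments: List[AlignmentRecord],
    model: GeneModel,
    total_mapped: int,
    read_length: Optional[int] = None,
    min_span: int = 4,
) -> List[QuantRecord]:
    """Estimate per-transcript abundances locus by locus.

    Each locus' transcript structures are projected onto exonic segments and
    junctions; observed base counts per segment and spanning counts per
    junction give the linear system A·y = b over per-transcript read densities
    y >= 0 (reads per valid start position), solved by non-negative least
    squares.  The coefficients follow the uniform fragment-start model exactly
    (coverage tapers at transcript ends; junction rows honor the ``min_span``
    overhang filter of the mapping stage), so short transcripts are estimated
    without length bias.  Transcript read counts are y_t × (length − L + 1),
    capped so a locus never receives more reads than were assigned to it, and
    reported as RPKM.  A locus with no reads gets all-zero abundances.
    """
    if read_length is None:
        lengths = [r.effective_read_length for r in alignments]
        read_length = int(np.median(lengths)) if lengths else 0

    out = []
    for gene in model:
        txs = gene.transcripts
        merged = gene.merged_exon_intervals()
        gene_reads = [
            r
            for r in alignments
            if r.chrom == gene.chrom and _contained_in_union(r, merged)
        ]
        if not gene_reads or read_length == 0:
            out.extend(
                QuantRecord(t.transcript_id, "transcript", 0.0, 0.0) for t in txs
            )
            continue

        segments = _gene_segments(gene)
        junctions = sorted(
            {
                (a.end, b.start)
                for t in txs
                for a, b in zip(t.exons, t.exons[1:])
            }
        )
        def seg_coeff(t, lo, hi):
            if not any(e.start <= lo and hi <= e.end for e in t.exons):
                return 0.0
            a = t.genomic_to_transcript(lo)
            b = t.genomic_to_transcript(hi - 1)
            tlo, thi = min(a, b), max(a, b) + 1
            return _segment_coefficient(tlo, thi, t.length, read_length)

        def junc_coeff(t, d, a):
            pairs = {(x.end, y.start) for x, y in zip(t.exons, t.exons[1:])}
            if (d, a) not in pairs:
                return 0.0
            # transcript coordinate of the first base after the splice
            c = t.genomic_to_transcript(a if t.strand != "-" else d - 1)
            return _junction_coefficient(c, t.length, read_length, min_span)

        seg_bases = np.zeros(len(segments))
        junc_counts = np.zeros(len(junctions))
        jindex = {j: i for i, j in enumerate(junctions)}
        for rec in gene_reads:
            for s, e in rec.segments:
                for i, (lo, hi) in enumerate(segments):
                    ov = min(e, hi) - max(s, lo)
                    if ov > 0:
                        seg_bases[i] += ov
            for j in rec.junctions():
                if j in jindex:
                    junc_counts[jindex[j]] += 1

        nt, ns, nj = len(txs), len(segments), len(junctions)
        A = np.zeros((ns + nj, nt))
        b = np.zeros(ns + nj)
        for i, (lo, hi) in enumerate(segments):
            b[i] = seg_bases[i] / read_length
            for t in range(nt):
                A[i, t] = seg_coeff(txs[t], lo, hi)
        for i, (d, a) in enumerate(junctions):
            b[ns + i] = junc_counts[i]
            for t in range(nt):
                A[ns + i, t] = junc_coeff(txs[t], d, a)

        y, _ = nnls(A, b)
        # y is reads per valid start position; a transcript of length M has
        # M - L + 1 of them under the uniform fragment-start model
        counts = y * np.array([max(t.length - read_length + 1, 1) for t in txs])
        assigned = len(gene_reads)
        if counts.sum() > assigned > 0:
            counts *= assigned / counts.sum()
        for t, c in zip(txs, counts):
            out.append(
                QuantRecord(
                    t.transcript_id, "transcript", float(c),
                    rpkm(float(c), t.length, total_mapped),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Tabular export


def quant_table(records: List[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.feature_type, r.raw_count, r.rpkm) for r in records],
        columns=["feature_id", "feature_type", "raw_count", "rpkm"],
    )


def junction_table(records: List[JunctionQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.junction.junction_id,
                r.junction.chrom,
                r.junction.donor_end,
                r.junction.acceptor_start,
                r.junction.strand,
                r.spanning_read_count,
                r.novelty,
            )
            for r in records
        ],
        columns=["junction_id", "chrom", "donor_end", "acceptor_start", "strand", "reads", "novelty"],
    )


def inclusion_table(records: List[InclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.exon_id, r.inclusion_reads, r.exclusion_reads, r.inclusion_index)
            for r in records
        ],
        columns=["exon_id", "inclusion_reads", "exclusion_reads", "inclusion_index"],
    )
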