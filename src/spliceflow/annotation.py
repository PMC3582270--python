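"""Derived annotation structures: the splice-junction library and the
transcriptome sequence set.

The junction library contains every junction present in an annotated
transcript (origin ``known``) plus every junction obtainable by joining an
ordered pair of non-overlapping exons of the same gene that is not itself
annotated (origin ``legal_combination``).  Junctions never join exons of
different genes.  Each library junction carries a reference contig — the last
``flank`` nt of the upstream exon concatenated with the first ``flank`` nt of
the downstream exon — so that any read spanning the splice site can be aligned
to a contiguous reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import (
    GeneModel,
    Junction,
    ORIGIN_KNOWN,
    ORIGIN_LEGAL,
    revcomp,
)

DEFAULT_MIN_INTRON = 40


@dataclass(frozen=True)
class JunctionContig:
    """Reference contig for one junction.

    ``left_block``/``right_block`` give the genomic intervals of the two
    flanks; ``boundary`` is the contig offset of the splice site (== length of
    the left flank).  ``truncated`` marks contigs where an exon was shorter
    than the requested flank and the full exon was used instead.
    """

    junction: Junction
    sequence: str
    left_block: tuple
    right_block: tuple
    truncated: bool = False

    @property
    def boundary(self) -> int:
        return self.left_block[1] - self.left_block[0]

    @property
    def contig_id(self) -> str:
        return self.junction.junction_id


@dataclass
class JunctionLibrary:
    """The junction set plus per-junction reference contigs."""

    junctions: dict = field(default_factory=dict)  # key -> Junction
    contigs: dict = field(default_factory=dict)  # contig_id -> JunctionContig
    flank: int = 0

    def __contains__(self, key) -> bool:
        return key in self.junctions

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions.values())

    def coordinate_set(self) -> set:
        """(chrom, donor_end, acceptor_start) triples, strand-blind, for
        checking whether an observed junction is in the library."""
        return {(j.chrom, j.donor_end, j.acceptor_start) for j in self}

    def by_origin(self, origin: str) -> list:
        return [j for j in self if j.origin_class == origin]

    def contig_sequences(self) -> Iterable[tuple]:
        for cid, contig in self.contigs.items():
            yield cid, contig.sequence


def build_junction_library(
    model: GeneModel,
    genome: Optional[dict] = None,
    flank: int = 74,
    min_intron: int = DEFAULT_MIN_INTRON,
) -> JunctionLibrary:
    """Build the splice-junction library from a gene model.

    Known junctions come from consecutive exon pairs of annotated transcripts;
    legal combinations are all remaining ordered pairs of distinct,
    non-overlapping exons within one gene whose implied intron is at least
    ``min_intron`` nt.  Exons identical in coordinates are deduplicated per
    gene before pairing.  When ``genome`` is given, each junction gets a
    reference contig of up to ``flank`` nt per side (a flank longer than its
    exon is truncated to the full exon, flagged, never an error).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    lib = JunctionLibrary(flank=flank)

    for gene in model:
        known_pairs = set()
        for tx in gene.transcripts:
            exons = tx.exons  # genomic order
            for a, b in zip(exons, exons[1:]):
                known_pairs.add(((a.start, a.end), (b.start, b.end)))
        dedup = gene.exons
        for i, a in enumerate(dedup):
            for b in dedup[i + 1 :]:
                if b.start < a.end:
                    continue  # overlapping exons cannot be spliced together
                if b.start - a.end < min_intron:
                    continue
                pair = ((a.start, a.end), (b.start, b.end))
                origin = ORIGIN_KNOWN if pair in known_pairs else ORIGIN_LEGAL
                j = Junction(gene.chrom, a.end, b.start, gene.strand, origin)
                if j.key in lib.junctions:
                    continue
                lib.junctions[j.key] = j
                if genome is not None:
                    chrom_seq = genome[gene.chrom]
                    l_start = max(a.start, a.end - flank)
                    r_end = min(b.end, b.start + flank)
                    seq = chrom_seq[l_start : a.end] + chrom_seq[b.start : r_end]
                    lib.contigs[j.junction_id] = JunctionContig(
                        junction=j,
                        sequence=seq,
                        left_block=(l_start, a.end),
                        right_block=(b.start, r_end),
                        truncated=(a.end - l_start < flank) or (r_end - b.start < flank),
                    )
    return lib


def extract_transcriptome(model: GeneModel, genome: dict) -> dict:
    """Spliced sequence of every transcript: exon sequences concatenated in
    genomic order, reverse-complemented for minus-strand transcripts.

    Returns transcript_id -> sequence.  An exon outside its chromosome raises
    an error naming the transcript.
    """
    out = {}
    for gene in model:
        for tx in gene.transcripts:
            parts = []
            for exon in tx.exons:
                chrom_seq = genome.get(exon.chrom)
                if chrom_seq is None or exon.end > len(chrom_seq) or exon.start < 0:
                    raise ValueError(
                        f"transcript {tx.transcript_id}: exon "
                        f"{exon.chrom}:{exon.start}-{exon.end} outside chromosome bounds"
                    )
                parts.append(chrom_seq[exon.start : exon.end])
            seq = "".join(parts)
            if tx.strand == "-":
                seq = revcomp(seq)
            out[tx.transcript_id] = seq
    return out
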