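"""Core domain types shared across the pipeline.

All internal coordinates are 0-based, half-open ``[start, end)``.  Conversion
to and from 1-based inclusive conventions (GTF, SAM, GFF) happens only at I/O
boundaries in :mod:`spliceflow.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# A genome is simply a mapping chromosome name -> uppercase DNA string.
GenomeSequence = dict


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    ``mate_index`` is 0 for unpaired reads, 1 or 2 for paired ends.
    ``qualities`` holds per-base Phred scores and is ``None`` for FASTA input.
    """

    read_id: str
    sequence: str
    qualities: Optional[tuple] = None
    mate_index: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"zero/negative length exon {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class Transcript:
    transcript_id: str
    exons: list  # of Exon, sorted by genomic start

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self):
        return self.exons[0].start, self.exons[-1].end

    def exons_5to3(self) -> list:
        """Exons in transcription order."""
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def genomic_blocks_for(self, tstart: int, tend: int) -> list:
        """Project a transcript-coordinate interval [tstart, tend) onto the
        genome, returning a sorted list of (start, end) genomic blocks.

        Transcript coordinates run 5'->3'; on the minus strand they walk the
        genomic exons right to left.
        """
        if not (0 <= tstart < tend <= self.length):
            raise ValueError(
                f"interval [{tstart},{tend}) outside transcript {self.transcript_id} "
                f"of length {self.length}"
            )
        blocks = []
        offset = 0
        for exon in self.exons_5to3():
            elen = len(exon)
            lo = max(tstart, offset)
            hi = min(tend, offset + elen)
            if lo < hi:
                if self.strand == "-":
                    # transcript position p maps to genomic exon.end - 1 - (p - offset)
                    g_hi = exon.end - (lo - offset)
                    g_lo = exon.end - (hi - offset)
                else:
                    g_lo = exon.start + (lo - offset)
                    g_hi = exon.start + (hi - offset)
                blocks.append((g_lo, g_hi))
            offset += elen
        return sorted(blocks)

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript coordinate of genomic position ``gpos`` (None if intronic)."""
        offset = 0
        for exon in self.exons_5to3():
            if exon.start <= gpos < exon.end:
                if self.strand == "-":
                    return offset + (exon.end - 1 - gpos)
                return offset + (gpos - exon.start)
            offset += len(exon)
        return None


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list  # of Transcript

    @property
    def exons(self) -> list:
        """Distinct exons of the gene (deduplicated by coordinates)."""
        seen = {}
        for t in self.transcripts:
            for e in t.exons:
                seen.setdefault(e.key, e)
        return sorted(seen.values(), key=lambda e: e.start)

    @property
    def span(self):
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    def merged_exon_intervals(self) -> list:
        """Union of exon intervals, merged and sorted."""
        merged = []
        for e in self.exons:
            if merged and e.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e.end))
            else:
                merged.append((e.start, e.end))
        return merged


@dataclass
class GeneModel:
    """Hierarchical gene annotation: genes -> transcripts -> exons."""

    genes: list = field(default_factory=list)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes:
            yield from g.transcripts

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts():
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def gene_of_transcript(self, transcript_id: str) -> Gene:
        for g in self.genes:
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return g
        raise KeyError(transcript_id)

    def internal_exons(self, gene: Gene) -> list:
        """Exons of ``gene`` with at least one annotated exon strictly on each
        genomic side within the gene — the exons for which an inclusion index
        is defined."""
        exons = gene.exons
        out = []
        for e in exons:
            has_up = any(o.end <= e.start for o in exons)
            has_down = any(o.start >= e.end for o in exons)
            if has_up and has_down:
                out.append(e)
        return out


# Junction origin classes (library construction) and novelty classes (observed).
ORIGIN_KNOWN = "known"
ORIGIN_LEGAL = "legal_combination"
ORIGIN_SPLIT = "novel_split"

NOVELTY_KNOWN = "known"
NOVELTY_NOVEL = "novel"
NOVELTY_UNANNOTATED = "novel_unannotated"


@dataclass(frozen=True)
class Junction:
    """A splice junction: donor = end of the upstream exon (0-based exclusive),
    acceptor = start of the downstream exon (0-based), on forward coordinates.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    origin_class: str = ORIGIN_KNOWN

    def __post_init__(self):
        if self.acceptor_start <= self.donor_end:
            raise ValueError(
                f"junction {self.chrom}:{self.donor_end}-{self.acceptor_start}: "
                "acceptor must lie downstream of donor"
            )

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end

    @property
    def key(self):
        """Identity: coordinates and strand, ignoring provenance."""
        return (self.chrom, self.donor_end, self.acceptor_start, self.strand)

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.donor_end}_{self.acceptor_start}:{self.strand}"


# Mapping stages, in ownership priority order (earlier stages own reads first).
STAGE_GENOME = "genome"
STAGE_JUNCTION = "junction"
STAGE_SPLIT = "split"


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of a (possibly split) read on the genome.

    ``segments`` are the aligned genomic blocks, increasing and non-overlapping;
    their total length equals ``effective_read_length`` (the read length after
    any 3' trimming).  ``n_hits`` is the number of equally good placements the
    aligner found for this read at this stage.
    """

    read_id: str
    mate_index: int
    chrom: str
    segments: tuple  # of (start, end)
    strand: str
    mismatches: int
    stage: str
    effective_read_length: int
    n_hits: int = 1

    def __post_init__(self):
        prev_end = -1
        total = 0
        for s, e in self.segments:
            if e <= s:
                raise ValueError(f"empty segment ({s},{e}) in read {self.read_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted segments in read {self.read_id}")
            prev_end = e
            total += e - s
        if total != self.effective_read_length:
            raise ValueError(
                f"read {self.read_id}: segment lengths sum to {total}, "
                f"expected effective length {self.effective_read_length}"
            )

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def projection(self):
        """Genomic footprint used to decide whether two placements are the
        same locus."""
        return (self.chrom, self.segments, self.strand)

    def junctions(self) -> list:
        """(donor_end, acceptor_start) pairs between adjacent segments."""
        return [
            (self.segments[i][1], self.segments[i + 1][0])
            for i in range(len(self.segments) - 1)
        ]


@dataclass
class MappingSummary:
    total_reads: int
    mapped_unique: int
    mapped_multi: int
    unmapped: int
    per_stage: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mapped_unique + self.mapped_multi + self.unmapped != self.total_reads:
            raise ValueError(
                "mapping summary does not conserve reads: "
                f"{self.mapped_unique}+{self.mapped_multi}+{self.unmapped} "
                f"!= {self.total_reads}"
            )

    @property
    def mapped(self) -> int:
        return self.mapped_unique + self.mapped_multi
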