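"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GTF/GFF/SAM conversion
(1-based inclusive) happens only here.  The Phred offset is fixed at 33;
offset-64 encodings are rejected with a clear message rather than silently
misread.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    AlignmentRecord,
    Exon,
    Gene,
    GeneModel,
    ReadRecord,
    Transcript,
)

PHRED_OFFSET = 33
# Phred+64 FASTQ uses ';'..'h'-ish ranges; chars below '!' + 26 never occur in
# offset-33 data from modern instruments, while chars >= 'K' (Q>=42) plus no
# char < ';' is the classic offset-64 signature.
_OFFSET64_MIN = ord(";")


def _decode_qualities(read_id: str, qual_str: str, record_no: int) -> tuple:
    quals = tuple(ord(c) - PHRED_OFFSET for c in qual_str)
    if any(q < 0 for q in quals):
        raise ValueError(
            f"record {record_no} ({read_id!r}): quality character below '!' — not Phred+33"
        )
    return quals


def sniff_format(path: str) -> str:
    """Detect FASTA vs FASTQ from the first non-blank byte."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: unrecognized sequence format (first line {line[:20]!r})")
    raise ValueError(f"{path}: empty file, cannot detect format")


def _mate_index_from_id(read_id: str) -> tuple:
    """Split a trailing /1 or /2 mate suffix off a read id."""
    m = re.match(r"^(.*)/([12])$", read_id)
    if m:
        return m.group(1), int(m.group(2))
    return read_id, 0


def read_sequences(
    path: str, format: str = "auto", mate_index: Optional[int] = None
) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a FASTA or FASTQ file.

    ``mate_index`` forces the mate label (used when paired data come as two
    files with _1/_2 suffixes); otherwise a trailing ``/1`` or ``/2`` on the
    read id is honoured.

    Raises ``ValueError`` naming the offending record for malformed input,
    including sequence/quality length mismatches.
    """
    fmt = sniff_format(path) if format == "auto" else format
    if fmt == "fasta":
        with open(path) as fh:
            for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
                rid = title.split()[0]
                stem, mi = _mate_index_from_id(rid)
                if not seq:
                    raise ValueError(f"{path}: record {i} ({rid!r}): empty sequence")
                yield ReadRecord(
                    stem, seq.upper(), None, mate_index if mate_index is not None else mi
                )
    elif fmt == "fastq":
        with open(path) as fh:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                i += 1
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    return
                except ValueError as exc:
                    raise ValueError(f"{path}: record {i}: {exc}") from exc
                rid = title.split()[0]
                stem, mi = _mate_index_from_id(rid)
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record {i} ({rid!r}): sequence length {len(seq)} "
                        f"!= quality length {len(qual)}"
                    )
                quals = _decode_qualities(rid, qual, i)
                yield ReadRecord(
                    stem, seq.upper(), quals, mate_index if mate_index is not None else mi
                )
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")


def read_paired_sequences(path1: str, path2: str, format: str = "auto") -> Iterator[tuple]:
    """Iterate (mate1, mate2) ReadRecord pairs from two parallel files."""
    it1 = read_sequences(path1, format, mate_index=1)
    it2 = read_sequences(path2, format, mate_index=2)
    for r1, r2 in zip(it1, it2):
        if r1.read_id != r2.read_id:
            raise ValueError(
                f"paired files out of sync: {r1.read_id!r} vs {r2.read_id!r}"
            )
        yield r1, r2


def read_genome(path: str) -> dict:
    """Load a genome FASTA into a chrom -> uppercase sequence dict."""
    genome = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in genome:
                raise ValueError(f"{path}: duplicate chromosome name {name!r}")
            if not seq:
                raise ValueError(f"{path}: chromosome {name!r} has empty sequence")
            genome[name] = seq.upper()
    return genome


def write_fasta(sequences: Iterable[tuple], path: str, width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else (30,) * len(r.sequence)
            suffix = f"/{r.mate_index}" if r.mate_index else ""
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# GTF annotation


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def read_annotation(path: str, genome: Optional[dict] = None) -> GeneModel:
    """Parse a GTF file into a :class:`GeneModel`.

    Only ``exon`` features are used to build transcripts.  GTF's 1-based
    inclusive coordinates are converted to internal 0-based half-open ones.
    Input line order is irrelevant: exons are grouped by transcript and genes
    assembled from their transcripts, so a shuffled file yields the same model.
    """
    tx_exons: dict = {}
    tx_gene: dict = {}
    tx_order: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            attributes = _parse_attributes(attrs)
            if "gene_id" not in attributes or "transcript_id" not in attributes:
                raise ValueError(
                    f"{path}:{lineno}: exon line missing gene_id or transcript_id"
                )
            start0 = int(start) - 1  # GTF is 1-based inclusive
            end0 = int(end)
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end0 > len(genome[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: exon end {end0} beyond chromosome "
                        f"{chrom!r} length {len(genome[chrom])}"
                    )
            tid = attributes["transcript_id"]
            gid = attributes["gene_id"]
            if tid in tx_gene and tx_gene[tid] != gid:
                raise ValueError(f"{path}:{lineno}: transcript {tid!r} under two genes")
            if tid not in tx_gene:
                tx_gene[tid] = gid
                tx_order.append(tid)
            tx_exons.setdefault(tid, []).append(Exon(chrom, start0, end0, strand))

    genes: dict = {}
    gene_order: list = []
    for tid in sorted(tx_order):
        gid = tx_gene[tid]
        exons = sorted(tx_exons[tid], key=lambda e: e.start)
        tx = Transcript(tid, exons)
        if gid not in genes:
            genes[gid] = Gene(gid, exons[0].chrom, exons[0].strand, [])
            gene_order.append(gid)
        genes[gid].transcripts.append(tx)
    return GeneModel([genes[g] for g in sorted(gene_order)])


def write_annotation(model: GeneModel, path: str, source: str = "spliceflow") -> None:
    """Write a GeneModel as GTF (exon features only)."""
    with open(path, "w") as fh:
        for gene in model:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{exon.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Alignment output: SAM/BAM (CIGAR with N for introns), BED12, GFF2


def _sam_header(genome_lengths: dict) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in genome_lengths.items()],
        }
    )


def _to_aligned_segment(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = rec.read_id if not rec.mate_index else f"{rec.read_id}/{rec.mate_index}"
    a.reference_id = header.get_tid(rec.chrom)
    if a.reference_id < 0:
        raise ValueError(f"unknown chromosome {rec.chrom!r} for read {rec.read_id}")
    a.reference_start = rec.start
    a.flag = 16 if rec.strand == "-" else 0
    cigar = []
    for i, (s, e) in enumerate(rec.segments):
        if i > 0:
            gap = s - rec.segments[i - 1][1]
            cigar.append((3, gap))  # N: skipped region (intron)
        cigar.append((0, e - s))  # M
    a.cigartuples = cigar
    a.mapping_quality = 255
    a.query_sequence = None
    a.set_tag("NM", rec.mismatches)
    a.set_tag("NH", rec.n_hits)
    a.set_tag("XS", rec.stage)  # stage of origin
    return a


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str,
    genome_lengths: dict,
    format: str = "sam",
) -> None:
    """Write alignments as SAM/BAM (CIGAR N across introns), BED12 or GFF2.

    SAM/GFF are 1-based on disk; BED is 0-based half-open.  Round-tripping a
    SAM file through :func:`read_alignments` reproduces coordinates exactly.
    """
    if format in ("sam", "bam"):
        header = _sam_header(genome_lengths)
        mode = "wb" if format == "bam" else "w"
        with pysam.AlignmentFile(path, mode, header=header) as out:
            for rec in records:
                out.write(_to_aligned_segment(rec, header))
    elif format == "bed":
        with open(path, "w") as fh:
            for rec in records:
                if rec.chrom not in genome_lengths:
                    raise ValueError(f"unknown chromosome {rec.chrom!r}")
                sizes = ",".join(str(e - s) for s, e in rec.segments)
                starts = ",".join(str(s - rec.start) for s, _ in rec.segments)
                name = rec.read_id if not rec.mate_index else f"{rec.read_id}/{rec.mate_index}"
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t{rec.mismatches}\t"
                    f"{rec.strand}\t{rec.start}\t{rec.end}\t0\t{len(rec.segments)}\t"
                    f"{sizes}\t{starts}\n"
                )
    elif format == "gff":
        # GFF2, one feature line per aligned block.
        with open(path, "w") as fh:
            fh.write("##gff-version 2\n")
            for rec in records:
                if rec.chrom not in genome_lengths:
                    raise ValueError(f"unknown chromosome {rec.chrom!r}")
                name = rec.read_id if not rec.mate_index else f"{rec.read_id}/{rec.mate_index}"
                for s, e in rec.segments:
                    fh.write(
                        f"{rec.chrom}\tspliceflow\tmatch\t{s + 1}\t{e}\t"
                        f"{rec.mismatches}\t{rec.strand}\t.\tread \"{name}\"; stage \"{rec.stage}\"\n"
                    )
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def read_alignments(path: str, format: str = "sam") -> list:
    """Read SAM/BAM (or spliceflow BED12/GFF2) back into AlignmentRecords."""
    records = []
    if format in ("sam", "bam"):
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for a in fh:
                if a.is_unmapped:
                    continue
                segments = []
                pos = a.reference_start
                for op, length in a.cigartuples:
                    if op == 0:  # M
                        segments.append((pos, pos + length))
                        pos += length
                    elif op == 3:  # N
                        pos += length
                    else:
                        raise ValueError(f"unsupported CIGAR op {op} in {path}")
                stem, mi = _mate_index_from_id(a.query_name)
                records.append(
                    AlignmentRecord(
                        read_id=stem,
                        mate_index=mi,
                        chrom=a.reference_name,
                        segments=tuple(segments),
                        strand="-" if a.is_reverse else "+",
                        mismatches=a.get_tag("NM") if a.has_tag("NM") else 0,
                        stage=a.get_tag("XS") if a.has_tag("XS") else "genome",
                        effective_read_length=sum(e - s for s, e in segments),
                        n_hits=a.get_tag("NH") if a.has_tag("NH") else 1,
                    )
                )
    elif format == "bed":
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                chrom, start = f[0], int(f[1])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                segments = tuple(
                    (start + o, start + o + s) for o, s in zip(offsets, sizes)
                )
                stem, mi = _mate_index_from_id(f[3])
                records.append(
                    AlignmentRecord(
                        read_id=stem,
                        mate_index=mi,
                        chrom=chrom,
                        segments=segments,
                        strand=f[5],
                        mismatches=int(f[4]),
                        stage="genome",
                        effective_read_length=sum(sizes),
                    )
                )
    elif format == "gff":
        blocks: dict = {}
        order: list = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = _parse_attributes(f[8])
                key = (attrs["read"], f[0], f[6], attrs.get("stage", "genome"))
                if key not in blocks:
                    order.append(key)
                blocks.setdefault(key, []).append((int(f[3]) - 1, int(f[4]), int(f[5])))
        for name, chrom, strand, stage in order:
            segs = sorted(blocks[(name, chrom, strand, stage)])
            stem, mi = _mate_index_from_id(name)
            records.append(
                AlignmentRecord(
                    read_id=stem,
                    mate_index=mi,
                    chrom=chrom,
                    segments=tuple((s, e) for s, e, _ in segs),
                    strand=strand,
                    mismatches=segs[0][2],
                    stage=stage,
                    effective_read_length=sum(e - s for s, e, _ in segs),
                )
            )
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return records


def write_junction_bed(junctions, counts: Optional[dict], path: str, flank: int = 20) -> None:
    """Export junctions as BED12 with two blocks (the flanking exonic anchors)."""
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda j: (j.chrom, j.donor_end, j.acceptor_start)):
            score = counts.get(j.key, 0) if counts else 0
            start = max(0, j.donor_end - flank)
            end = j.acceptor_start + flank
            b1 = j.donor_end - start
            b2 = end - j.acceptor_start
            fh.write(
                f"{j.chrom}\t{start}\t{end}\t{j.junction_id}\t{score}\t{j.strand}\t"
                f"{start}\t{end}\t0\t2\t{b1},{b2}\t0,{j.acceptor_start - start}\n"
            )
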