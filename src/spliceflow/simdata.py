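"""Synthetic genomes, annotations and read libraries with known truth.

Everything here is deterministic under its seed.  The generators emulate the
structure RNA-seq analysis cares about — multi-exon genes with GT..AG introns
(CT..AC on the minus strand), cassette exons for inclusion analysis, hidden
genes whose junctions are absent from the annotation (novel-junction truth),
fusion transcripts joining two genes (chimera truth), substitution errors,
N injection and 3' quality decay — not the error chemistry of any real
instrument.

Defaults follow the study conditions the pipeline targets: 100 nt reads,
uniform fragment starts (an optional 3' bias mode exercises the position-bias
detector), error-free unless asked otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import extract_transcriptome
from .core import Exon, Gene, GeneModel, Junction, ReadRecord, Transcript, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(
    n_chrom: int = 1,
    length: int = 100_000,
    gc: float = 0.5,
    seed: int = 0,
    repeat_free_k: Optional[int] = None,
) -> Dict[str, str]:
    """Random genome with the requested GC content.

    With ``repeat_free_k`` set, no k-mer occurs twice within or across
    chromosomes (duplicate windows are re-randomized), which makes toy-aligner
    uniqueness controllable.
    """
    if length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {}
    for c in range(n_chrom):
        arr = rng.choice(_BASES, size=length, p=p)
        chroms[f"chr{c + 1}"] = arr
    if repeat_free_k:
        k = repeat_free_k
        for _ in range(100):
            seen: Dict[bytes, tuple] = {}
            dup = []
            for name, arr in chroms.items():
                data = arr.tobytes()
                for i in range(len(data) - k + 1):
                    km = data[i : i + k]
                    if km in seen and seen[km] != (name, i):
                        dup.append((name, i))
                        break
                    seen.setdefault(km, (name, i))
            if not dup:
                break
            for name, i in dup:
                chroms[name][i : i + k] = rng.choice(_BASES, size=k, p=p)
        else:
            raise RuntimeError("could not achieve repeat-free genome")
    return {name: arr.tobytes().decode("ascii") for name, arr in chroms.items()}


@dataclass
class AnnotationTruth:
    """A generated gene model plus the ground truth the pipeline should find.

    ``model`` is what gets written to GTF (the pipeline's view);
    ``source_model`` additionally contains hidden genes whose transcripts
    produce reads but whose junctions are absent from the annotation —
    the implanted novel junctions listed in ``hidden_junctions``.
    """

    genome: Dict[str, str]
    model: GeneModel
    source_model: GeneModel
    hidden_junctions: List[Junction] = field(default_factory=list)
    cassette_exons: Dict[str, tuple] = field(default_factory=dict)  # gene_id -> exon key


def _write_motif(seq: list, donor: int, acceptor: int, strand: str) -> None:
    if strand == "+":
        seq[donor], seq[donor + 1] = "G", "T"
        seq[acceptor - 2], seq[acceptor - 1] = "A", "G"
    else:
        seq[donor], seq[donor + 1] = "C", "T"
        seq[acceptor - 2], seq[acceptor - 1] = "A", "C"


def make_annotation(
    genome: Dict[str, str],
    n_genes: int = 6,
    exons_per_gene: Tuple[int, int] = (3, 5),
    exon_length: Tuple[int, int] = (150, 300),
    intron_length: Tuple[int, int] = (60, 400),
    cassette_genes: int = 2,
    hidden_genes: int = 0,
    intergenic: Tuple[int, int] = (300, 600),
    both_strands: bool = True,
    seed: int = 0,
) -> AnnotationTruth:
    """Lay out multi-exon genes along the genome, writing splice motifs into
    the sequence at every implanted intron.

    The first ``cassette_genes`` genes (needing >= 3 exons) get a second
    transcript that skips one internal exon; the last ``hidden_genes`` genes
    are kept out of the annotated model and contribute implanted novel
    junctions.  Raises when the genome cannot hold the request.
    """
    rng = np.random.default_rng(seed)
    chrom_seqs = {name: list(seq) for name, seq in genome.items()}
    chrom_names = list(genome)
    cursors = {name: rng.integers(*intergenic) for name in chrom_names}

    genes: List[Gene] = []
    cassettes: Dict[str, tuple] = {}
    chrom_i = 0
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_lens = rng.integers(exon_length[0], exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_length[0], intron_length[1] + 1, size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        placed = False
        for _ in range(len(chrom_names)):
            name = chrom_names[chrom_i % len(chrom_names)]
            start = int(cursors[name])
            if start + span <= len(chrom_seqs[name]):
                placed = True
                break
            chrom_i += 1
        if not placed:
            raise ValueError(
                f"insufficient genome space for gene {g + 1} of {n_genes} (span {span})"
            )
        strand = "+" if (not both_strands or rng.random() < 0.5) else "-"
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append(Exon(name, pos, pos + int(el), strand))
            pos += int(el)
            if i < n_ex - 1:
                intron_start, intron_end = pos, pos + int(in_lens[i])
                _write_motif(chrom_seqs[name], intron_start, intron_end, strand)
                pos = intron_end
        cursors[name] = pos + int(rng.integers(*intergenic))
        chrom_i += 1

        gid = f"g{g + 1:03d}"
        transcripts = [Transcript(f"{gid}.t1", exons)]
        if g < cassette_genes and n_ex >= 3:
            skip_idx = int(rng.integers(1, n_ex - 1))
            skipped = [e for i, e in enumerate(exons) if i != skip_idx]
            transcripts.append(Transcript(f"{gid}.t2", skipped))
            cassettes[gid] = exons[skip_idx].key
        genes.append(Gene(gid, name, strand, transcripts))

    genome_out = {name: "".join(seq) for name, seq in chrom_seqs.items()}
    visible = genes[: n_genes - hidden_genes] if hidden_genes else genes
    hidden = genes[n_genes - hidden_genes :] if hidden_genes else []
    hidden_junctions = [
        Junction(a.chrom, a.end, b.start, gene.strand, "novel_split")
        for gene in hidden
        for tx in gene.transcripts
        for a, b in zip(tx.exons, tx.exons[1:])
    ]
    return AnnotationTruth(
        genome=genome_out,
        model=GeneModel(list(visible)),
        source_model=GeneModel(list(genes)),
        hidden_junctions=hidden_junctions,
        cassette_exons=cassettes,
    )


@dataclass
class ReadTruth:
    reads: List[ReadRecord]
    pairs: List[Tuple[ReadRecord, ReadRecord]]
    table: pd.DataFrame  # read_id, transcript_id, tstart, tend, mate


def _default_quality(read_length: int, decay: float = 8.0, q0: int = 38) -> np.ndarray:
    """Linear 3' quality decay from q0 to q0-decay."""
    if read_length == 1:
        return np.array([q0])
    return np.round(q0 - decay * np.arange(read_length) / (read_length - 1)).astype(int)


def _mutate(seq: np.ndarray, rng, error_rate: float) -> Tuple[np.ndarray, int]:
    if error_rate <= 0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != seq[i]]
        seq[i] = rng.choice(choices)
    return seq, len(hits)


def simulate_reads(
    model: GeneModel,
    genome: Dict[str, str],
    n_reads: int = 10_000,
    read_length: int = 100,
    seed: int = 0,
    weights: Optional[Dict[str, float]] = None,
    paired: bool = False,
    insert: int = 250,
    error_rate: float = 0.0,
    n_profile: Optional[np.ndarray] = None,
    quality_decay: float = 8.0,
    bias: str = "uniform",
    extra_transcripts: Optional[Dict[str, str]] = None,
) -> ReadTruth:
    """Draw reads from spliced transcripts with known truth.

    Transcripts are sampled proportionally to ``weights`` (uniform when
    absent), start positions uniformly (``bias='3p'`` skews mass to the 3'
    half), substitutions at ``error_rate`` per base, Ns injected per-cycle at
    the probabilities in ``n_profile``.  ``extra_transcripts`` (id -> spliced
    sequence) join the pool — implanted fusion transcripts go here.  The truth
    table records each read's source transcript and transcript coordinates.
    """
    rng = np.random.default_rng(seed)
    seqs = extract_transcriptome(model, genome)
    if extra_transcripts:
        seqs = {**seqs, **extra_transcripts}
    tx_ids = sorted(seqs)
    fragment = insert if paired else read_length
    too_short = [t for t in tx_ids if len(seqs[t]) < fragment]
    if too_short:
        raise ValueError(
            f"fragment length {fragment} exceeds transcript(s) {too_short[:3]}"
        )
    if weights is None:
        w = np.ones(len(tx_ids))
    else:
        w = np.array([weights.get(t, 0.0) for t in tx_ids], dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero")
    w = w / w.sum()
    arrs = {t: np.frombuffer(seqs[t].encode(), dtype=np.uint8) for t in tx_ids}

    choices = rng.choice(len(tx_ids), size=n_reads, p=w)
    reads: List[ReadRecord] = []
    pairs: List[Tuple[ReadRecord, ReadRecord]] = []
    rows = []
    quals = _default_quality(read_length, decay=quality_decay)
    nprof = np.zeros(read_length) if n_profile is None else np.asarray(n_profile)

    def finish(arr: np.ndarray) -> str:
        arr, _ = _mutate(arr, rng, error_rate)
        if nprof.any():
            nhits = np.nonzero(rng.random(len(arr)) < nprof[: len(arr)])[0]
            arr[nhits] = ord("N")
        return arr.tobytes().decode("ascii")

    for i, ti in enumerate(choices):
        tid = tx_ids[ti]
        arr = arrs[tid]
        max_start = len(arr) - fragment
        if bias == "3p":
            rel = np.sqrt(rng.random())
            start = int(rel * max_start) if max_start > 0 else 0
        else:
            start = int(rng.integers(0, max_start + 1))
        rid = f"r{i:07d}"
        if paired:
            frag = arr[start : start + insert]
            m1 = finish(frag[:read_length].copy())
            m2 = finish(
                np.frombuffer(revcomp(frag[-read_length:].tobytes().decode()).encode(), np.uint8).copy()
            )
            r1 = ReadRecord(rid, m1, tuple(quals), 1)
            r2 = ReadRecord(rid, m2, tuple(quals), 2)
            pairs.append((r1, r2))
            reads.extend([r1, r2])
            rows.append((rid, tid, start, start + read_length, 1))
            rows.append((rid, tid, start + insert - read_length, start + insert, 2))
        else:
            m = finish(arr[start : start + read_length].copy())
            reads.append(ReadRecord(rid, m, tuple(quals), 0))
            rows.append((rid, tid, start, start + read_length, 0))

    table = pd.DataFrame(rows, columns=["read_id", "transcript_id", "tstart", "tend", "mate"])
    return ReadTruth(reads=reads, pairs=pairs, table=table)


def make_fusion_transcript(
    model: GeneModel, genome: Dict[str, str], gene_a: str, gene_b: str
) -> Tuple[str, str, int]:
    """Join the first transcript of two genes into one chimeric sequence.

    Returns (fusion_id, sequence, boundary offset of the A/B junction).
    """
    seqs = extract_transcriptome(model, genome)
    ta = model.gene(gene_a).transcripts[0]
    tb = model.gene(gene_b).transcripts[0]
    sa, sb = seqs[ta.transcript_id], seqs[tb.transcript_id]
    return f"fusion_{gene_a}_{gene_b}", sa + sb, len(sa)


def simulate_fusion_pairs(
    fusion_seq: str,
    boundary: int,
    n_pairs: int,
    read_length: int = 100,
    insert: int = 250,
    seed: int = 0,
    id_prefix: str = "fus",
) -> List[Tuple[ReadRecord, ReadRecord]]:
    """Paired reads straddling a fusion boundary: mate 1 entirely in the A
    part, mate 2 entirely in the B part.  Requires insert >= 2*read_length."""
    if insert < 2 * read_length:
        raise ValueError("insert must be >= 2 * read_length to straddle the boundary")
    lo = max(0, boundary - insert + read_length)
    hi = min(boundary - read_length, len(fusion_seq) - insert)
    if hi < lo:
        raise ValueError("fusion parts too short for straddling pairs")
    rng = np.random.default_rng(seed)
    quals = tuple(_default_quality(read_length))
    pairs = []
    for i in range(n_pairs):
        s = int(rng.integers(lo, hi + 1))
        frag = fusion_seq[s : s + insert]
        rid = f"{id_prefix}{i:05d}"
        pairs.append(
            (
                ReadRecord(rid, frag[:read_length], quals, 1),
                ReadRecord(rid, revcomp(frag[-read_length:]), quals, 2),
            )
        )
    return pairs


def write_truth(truth: ReadTruth, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
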