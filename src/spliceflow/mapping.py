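"""Iterative splice-aware mapping.

The strategy: align every read against the genome and the junction-contig
references; reads left unmapped go through split mapping (two fragments, the
intervening gap required to be intron-sized and bounded by consensus splice
motifs).  Reads still unmapped are retried with one extra mismatch at a time
up to a cap proportional to read length (one mismatch per 25 nt by default),
then iteratively trimmed from the 3' end (10 nt at a time by default) until a
minimum length (25 nt by default) is reached.  The outputs of all stages are
merged; each read is owned by the first stage that mapped it.

Alignment itself is behind a pluggable contract: any aligner returning ALL
placements of a read at or below a substitution budget can be used.  The
bundled :class:`ExhaustiveAligner` satisfies the contract with pigeonhole
seeding — a read aligned with at most m substitutions must contain at least
one of m+1 disjoint exact seed segments — and numpy Hamming verification, so
it is exhaustive for substitutions.  :func:`brute_force_scan` is a separate
all-positions scan kept as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import numpy as np

from .annotation import JunctionLibrary
from .core import (
    AlignmentRecord,
    Junction,
    MappingSummary,
    ORIGIN_SPLIT,
    ReadRecord,
    STAGE_GENOME,
    STAGE_JUNCTION,
    STAGE_SPLIT,
    revcomp,
)

# Below this seed length the k-mer index degenerates; fall back to a full scan
# (only very short fragments at high mismatch budgets ever hit this).
_MIN_SEED = 6

# Splice-site consensus dinucleotides on the forward genome and the junction
# strand they imply.  GC-AG is a rarer donor variant, off by default.
_MOTIFS = {("GT", "AG"): "+", ("CT", "AC"): "-"}
_MOTIFS_GC = {("GT", "AG"): "+", ("CT", "AC"): "-", ("GC", "AG"): "+", ("CT", "GC"): "-"}


class Hit(NamedTuple):
    """A raw aligner placement: reference name, 0-based start, query strand,
    substitution count."""

    ref: str
    pos: int
    strand: str
    mismatches: int


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_CODE = np.zeros(256, dtype=np.uint64)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i + 1


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-8 Horner hash of every k-mer (uint64, wraparound is fine:
    equal k-mers always hash equal; rare collisions only add candidates that
    verification discards)."""
    n = len(codes) - k + 1
    h = np.zeros(n, dtype=np.uint64)
    eight = np.uint64(8)
    for i in range(k):
        h = h * eight + codes[i : i + n]
    return h


class ExhaustiveAligner:
    """Substitution-only aligner returning every placement within a mismatch
    budget, on both strands, against a set of reference sequences.

    Pigeonhole seeding: a placement with <= m substitutions contains at least
    one of m+1 disjoint exact seed segments, so exact-seed lookup plus full
    verification finds every placement.  Seed indices (sorted k-mer hashes
    over a concatenated reference) are built lazily per seed length and
    cached, so one instance serves successive mismatch strata cheaply.
    """

    def __init__(self, references: Dict[str, str]):
        self.names = list(references)
        self.arrays = {n: _seq_to_array(s) for n, s in references.items()}
        self._indices: Dict[int, tuple] = {}
        # concatenated codes with zero-gap separators so windows never span
        # two references (a zero code never matches any query base)
        self._offsets = {}
        parts = []
        pos = 0
        self._max_sep = 64
        for n in self.names:
            codes = _CODE[self.arrays[n]]
            self._offsets[n] = pos
            parts.append(codes)
            parts.append(np.zeros(self._max_sep, dtype=np.uint64))
            pos += len(codes) + self._max_sep
        self._concat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint64)
        self._bounds = np.array([self._offsets[n] for n in self.names])
        self._lens = np.array([len(self.arrays[n]) for n in self.names])

    def _index(self, k: int):
        if k > self._max_sep:
            raise ValueError(f"seed length {k} exceeds separator width")
        cached = self._indices.get(k)
        if cached is None:
            if len(self._concat) >= k:
                h = _kmer_hashes(self._concat, k)
                order = np.argsort(h, kind="stable")
                cached = (h[order], order.astype(np.int64))
            else:
                cached = (np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64))
            self._indices[k] = cached
        return cached

    def _locate(self, global_pos: int) -> Tuple[str, int]:
        i = int(np.searchsorted(self._bounds, global_pos, side="right")) - 1
        return self.names[i], global_pos - int(self._bounds[i])

    def _verify(self, name: str, start: int, qarr: np.ndarray) -> Optional[int]:
        ref = self.arrays[name]
        L = len(qarr)
        if start < 0 or start + L > len(ref):
            return None
        return int(np.count_nonzero(ref[start : start + L] != qarr))

    def _search_oriented(self, seq: str, max_mismatches: int) -> List[Tuple[str, int, int]]:
        L = len(seq)
        qarr = _seq_to_array(seq)
        # shorter seeds than the pigeonhole maximum are still exhaustive;
        # 32 keeps candidate lists specific without giant hash windows
        seed_len = min(L // (max_mismatches + 1), 32)
        out = []
        if seed_len < _MIN_SEED:
            # full scan: still exhaustive, used only for tiny queries
            for name, ref in self.arrays.items():
                if len(ref) < L:
                    continue
                n = len(ref) - L + 1
                counts = np.zeros(n, dtype=np.uint16)
                for i in range(L):
                    counts += ref[i : i + n] != qarr[i]
                for pos in np.nonzero(counts <= max_mismatches)[0]:
                    out.append((name, int(pos), int(counts[pos])))
            return out
        hashes, positions = self._index(seed_len)
        qcodes = _CODE[qarr]
        seen = set()
        mask64 = (1 << 64) - 1
        for i in range(max_mismatches + 1):
            off = i * seed_len
            qh = 0
            for c in qcodes[off : off + seed_len].tolist():
                qh = ((qh << 3) + c) & mask64
            qh = np.uint64(qh)
            lo = int(np.searchsorted(hashes, qh, side="left"))
            hi = int(np.searchsorted(hashes, qh, side="right"))
            for gpos in positions[lo:hi]:
                name, local = self._locate(int(gpos))
                cand = (name, local - off)
                if cand in seen:
                    continue
                seen.add(cand)
                mm = self._verify(name, local - off, qarr)
                if mm is not None and mm <= max_mismatches:
                    out.append((name, local - off, mm))
        return out

    def search(
        self, seq: str, max_mismatches: int, both_strands: bool = True
    ) -> List[Hit]:
        """All placements of ``seq`` with at most ``max_mismatches``
        substitutions.  Minus-strand hits are placements of the reverse
        complement on the forward reference."""
        hits = [
            Hit(ref, pos, "+", mm)
            for ref, pos, mm in self._search_oriented(seq, max_mismatches)
        ]
        if both_strands:
            hits += [
                Hit(ref, pos, "-", mm)
                for ref, pos, mm in self._search_oriented(revcomp(seq), max_mismatches)
            ]
        return hits


def brute_force_scan(
    seq: str, references: Dict[str, str], max_mismatches: int, both_strands: bool = True
) -> List[Hit]:
    """Independent all-positions Hamming scan (test oracle for the aligner)."""
    hits = []
    queries = [(seq, "+")]
    if both_strands:
        queries.append((revcomp(seq), "-"))
    for q, strand in queries:
        qarr = _seq_to_array(q)
        L = len(qarr)
        for name, ref in references.items():
            rarr = _seq_to_array(ref)
            if len(rarr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(rarr, L)
            counts = (windows != qarr).sum(axis=1)
            for pos in np.nonzero(counts <= max_mismatches)[0]:
                hits.append(Hit(name, int(pos), strand, int(counts[pos])))
    return hits


def best_stratum(hits: List[Hit]) -> List[Hit]:
    """Keep only the placements with the minimum mismatch count."""
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


# ---------------------------------------------------------------------------
# Mapping parameters


@dataclass(frozen=True)
class MappingParams:
    """Knobs of the iterative strategy.

    ``initial_mismatches`` is the phase-1 budget; escalation adds
    ``mismatch_step`` at a time up to floor(length / ``mismatch_per_nt``).
    Trimming removes ``trim_step`` nt from the 3' end per round and stops when
    the next trim would drop the read below ``min_length``; setting
    ``min_length`` equal to the read length disables trimming entirely.
    """

    initial_mismatches: int = 2
    mismatch_step: int = 1
    mismatch_per_nt: int = 25
    trim_step: int = 10
    min_length: int = 25
    min_span: int = 4
    min_segment: int = 10
    intron_range: Tuple[int, int] = (40, 500_000)
    allow_gc_ag: bool = False
    trim_from: str = "3p"  # or "5p"

    def __post_init__(self):
        if self.trim_step <= 0:
            raise ValueError("trim_step must be positive")
        if self.mismatch_per_nt <= 0:
            raise ValueError("mismatch_per_nt must be positive")

    def max_mismatches_for(self, length: int) -> int:
        """Mismatch cap for a read: floor(length / mismatch_per_nt)."""
        return length // self.mismatch_per_nt

    def trim_schedule(self, read_length: int) -> List[int]:
        """Effective lengths after each trimming round, e.g. 100 nt with step
        10 and floor 25 -> [90, 80, ..., 30].  Empty when min_length equals
        the read length (no trimming)."""
        if self.min_length >= read_length:
            return []
        lengths = []
        L = read_length - self.trim_step
        while L >= self.min_length:
            lengths.append(L)
            L -= self.trim_step
        return lengths


# ---------------------------------------------------------------------------
# Stage aligners


ReadKey = Tuple[str, int]  # (read_id, mate_index)


def _read_key(read: ReadRecord) -> ReadKey:
    return (read.read_id, read.mate_index)


def align_genome(
    reads: Iterable[ReadRecord],
    genome: Dict[str, str],
    max_mismatches: int,
    aligner: Optional[ExhaustiveAligner] = None,
    stage: str = STAGE_GENOME,
) -> Dict[ReadKey, List[AlignmentRecord]]:
    """Contiguous genome alignment.  Returns, per read, ALL placements at the
    best mismatch stratum within the budget, with ``n_hits`` set; reads with
    no placement are absent from the result."""
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if aligner is None:
        aligner = ExhaustiveAligner(genome)
    out: Dict[ReadKey, List[AlignmentRecord]] = {}
    for read in reads:
        hits = best_stratum(aligner.search(read.sequence, max_mismatches))
        if not hits:
            continue
        L = len(read.sequence)
        out[_read_key(read)] = [
            AlignmentRecord(
                read_id=read.read_id,
                mate_index=read.mate_index,
                chrom=h.ref,
                segments=((h.pos, h.pos + L),),
                strand=h.strand,
                mismatches=h.mismatches,
                stage=stage,
                effective_read_length=L,
                n_hits=len(hits),
            )
            for h in hits
        ]
    return out


def _junction_hit_to_record(
    read: ReadRecord, hit: Hit, library: JunctionLibrary, min_span: int, stage: str
) -> Optional[AlignmentRecord]:
    contig = library.contigs[hit.ref]
    L = len(read.sequence)
    left_len = contig.boundary - hit.pos
    right_len = (hit.pos + L) - contig.boundary
    if left_len < min_span or right_len < min_span:
        return None  # does not span the splice site
    lb, rb = contig.left_block, contig.right_block
    segments = ((lb[1] - left_len, lb[1]), (rb[0], rb[0] + right_len))
    return AlignmentRecord(
        read_id=read.read_id,
        mate_index=read.mate_index,
        chrom=contig.junction.chrom,
        segments=segments,
        strand=hit.strand,
        mismatches=hit.mismatches,
        stage=stage,
        effective_read_length=L,
    )


def align_junctions(
    reads: Iterable[ReadRecord],
    library: JunctionLibrary,
    max_mismatches: int,
    min_span: int = 4,
    aligner: Optional[ExhaustiveAligner] = None,
    stage: str = STAGE_JUNCTION,
) -> Dict[ReadKey, List[AlignmentRecord]]:
    """Align reads to the junction contigs and lift the surviving hits to
    two-segment genomic records.

    Hits covering fewer than ``min_span`` nt on either side of the splice site
    are discarded; hits from different contigs that project to the same
    genomic segments (shared flanks) are collapsed to one placement."""
    if aligner is None:
        aligner = ExhaustiveAligner(dict(library.contig_sequences()))
    out: Dict[ReadKey, List[AlignmentRecord]] = {}
    for read in reads:
        hits = aligner.search(read.sequence, max_mismatches)
        records = []
        for h in hits:
            rec = _junction_hit_to_record(read, h, library, min_span, stage)
            if rec is not None:
                records.append(rec)
        if not records:
            continue
        best = min(r.mismatches for r in records)
        dedup = {}
        for r in records:
            if r.mismatches == best:
                dedup.setdefault(r.projection, r)
        final = [replace(r, n_hits=len(dedup)) for r in dedup.values()]
        out[_read_key(read)] = final
    return out


def split_map(
    reads: Iterable[ReadRecord],
    genome: Dict[str, str],
    max_mismatches: int,
    min_segment: int = 10,
    intron_range: Tuple[int, int] = (40, 500_000),
    library: Optional[JunctionLibrary] = None,
    aligner: Optional[ExhaustiveAligner] = None,
    allow_gc_ag: bool = False,
    stage: str = STAGE_SPLIT,
) -> Dict[ReadKey, List[AlignmentRecord]]:
    """Two-fragment spliced alignment at consensus splice sites.

    Every breakpoint leaving at least ``min_segment`` nt on each side is
    tried, in both read orientations; a candidate needs both fragments on the
    same chromosome in order, a gap within ``intron_range``, and GT..AG (or
    CT..AC read on the reverse strand) at the intron edges.  The best
    candidate wins by (total mismatches, junction already in the library,
    smallest intron, leftmost donor); ``n_hits`` counts candidates tied before
    the leftmost-donor break.
    """
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    if aligner is None:
        aligner = ExhaustiveAligner(genome)
    motifs = _MOTIFS_GC if allow_gc_ag else _MOTIFS
    known = library.coordinate_set() if library is not None else set()
    min_intron, max_intron = intron_range
    out: Dict[ReadKey, List[AlignmentRecord]] = {}

    # Anchor trick: a valid two-fragment alignment with <= mm total mismatches
    # must place the read's first and last min_segment nt with <= mm each, so
    # all candidate (prefix start p, suffix end e) anchor pairs come from two
    # cheap scans.  For a fixed pair the intron length e - p - L is the same
    # for every breakpoint; per-breakpoint mismatch totals fall out of prefix/
    # suffix mismatch cumulative sums against the anchored genomic windows.
    for read in reads:
        L = len(read.sequence)
        if L < 2 * min_segment:
            continue
        candidates = []  # (mm_total, not_known, intron_len, donor, record)
        for oriented, read_strand in ((read.sequence, "+"), (revcomp(read.sequence), "-")):
            qarr = _seq_to_array(oriented)
            lefts = aligner.search(oriented[:min_segment], max_mismatches, both_strands=False)
            if not lefts:
                continue
            rights = aligner.search(oriented[-min_segment:], max_mismatches, both_strands=False)
            if not rights:
                continue
            lefts_by_ref: Dict[str, list] = {}
            for h in lefts:
                lefts_by_ref.setdefault(h.ref, []).append(h.pos)
            rights_by_ref: Dict[str, list] = {}
            for h in rights:
                rights_by_ref.setdefault(h.ref, []).append(h.pos + min_segment)  # end pos
            bs = np.arange(min_segment, L - min_segment + 1)
            for ref in lefts_by_ref:
                if ref not in rights_by_ref:
                    continue
                ref_arr = aligner.arrays[ref]
                chrom_seq = genome[ref]
                ps = np.array(sorted(set(lefts_by_ref[ref])))
                es = np.array(sorted(set(rights_by_ref[ref])))
                # prefix mismatch cumsums anchored at each p (out-of-bounds
                # bases count as mismatches), CL[i, b-1] = mism of first b nt
                pidx = ps[:, None] + np.arange(L)[None, :]
                pok = pidx < len(ref_arr)
                CL = np.cumsum(
                    np.where(pok, ref_arr[np.minimum(pidx, len(ref_arr) - 1)], 255)
                    != qarr[None, :],
                    axis=1,
                )
                # suffix mismatch reverse-cumsums anchored at each end e
                eidx = es[:, None] - L + np.arange(L)[None, :]
                eok = eidx >= 0
                CR = np.cumsum(
                    (np.where(eok, ref_arr[np.maximum(eidx, 0)], 255) != qarr[None, :])[:, ::-1],
                    axis=1,
                )
                gaps = es[None, :] - ps[:, None] - L
                gap_ok = (gaps >= min_intron) & (gaps <= max_intron)
                # total mismatches >= anchor mismatches of each side, so most
                # pairs are rejected before any breakpoint is evaluated
                pair_ok = gap_ok & (
                    CL[:, min_segment - 1][:, None] + CR[:, min_segment - 1][None, :]
                    <= max_mismatches
                )
                CLb = CL[:, bs - 1]
                CRb = CR[:, L - bs - 1]
                I, J = np.nonzero(pair_ok)
                chunk = 65536
                for c0 in range(0, len(I), chunk):
                    Ic, Jc = I[c0 : c0 + chunk], J[c0 : c0 + chunk]
                    T = CLb[Ic] + CRb[Jc]
                    for r, bi in np.argwhere(T <= max_mismatches):
                        i, j, b = int(Ic[r]), int(Jc[r]), int(bs[bi])
                        p, e = int(ps[i]), int(es[j])
                        donor = p + b
                        acceptor = e - (L - b)
                        motif = (chrom_seq[donor : donor + 2], chrom_seq[acceptor - 2 : acceptor])
                        if motif not in motifs:
                            continue
                        rec = AlignmentRecord(
                            read_id=read.read_id,
                            mate_index=read.mate_index,
                            chrom=ref,
                            segments=((p, donor), (acceptor, e)),
                            strand=read_strand,
                            mismatches=int(T[r, bi]),
                            stage=stage,
                            effective_read_length=L,
                        )
                        in_lib = (ref, donor, acceptor) in known
                        candidates.append(
                            (rec.mismatches, 0 if in_lib else 1, int(gaps[i, j]), donor, rec)
                        )
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[:4])
        top = candidates[0]
        ties = {c[4].projection for c in candidates if c[:3] == top[:3]}
        out[_read_key(read)] = [replace(top[4], n_hits=len(ties))]
    return out


def splice_strand(genome: Dict[str, str], chrom: str, donor: int, acceptor: int) -> Optional[str]:
    """Strand implied by the intron motif at (donor, acceptor), or None."""
    seq = genome[chrom]
    return _MOTIFS_GC.get((seq[donor : donor + 2], seq[acceptor - 2 : acceptor]))


# ---------------------------------------------------------------------------
# Iterative strategy


def stage_base(stage: str) -> str:
    """'trimmed@80:split' -> 'split'; plain stages unchanged."""
    return stage.rsplit(":", 1)[-1] if ":" in stage else stage


def is_split_stage(stage: str) -> bool:
    return stage_base(stage) == STAGE_SPLIT


@dataclass
class MappingResult:
    """Merged output of the iterative strategy.

    ``records`` holds, per read key, every best-stratum placement from the
    stage that owns the read; ``owner_stage`` names that stage;
    ``phase_summaries`` snapshots the unique/multi/unmapped partition at each
    phase boundary (phase 1 budget, each escalated budget, each trim round).
    """

    total_reads: int
    records: Dict[ReadKey, List[AlignmentRecord]] = field(default_factory=dict)
    owner_stage: Dict[ReadKey, str] = field(default_factory=dict)
    unmapped: set = field(default_factory=set)
    phase_summaries: List[MappingSummary] = field(default_factory=list)

    def all_records(self) -> List[AlignmentRecord]:
        return [r for recs in self.records.values() for r in recs]

    @property
    def summary(self) -> MappingSummary:
        return self.phase_summaries[-1]


def _combine_rounds(
    genome_hits: Dict[ReadKey, List[AlignmentRecord]],
    junction_hits: Dict[ReadKey, List[AlignmentRecord]],
) -> Dict[ReadKey, List[AlignmentRecord]]:
    """Merge genome and junction placements per read, keep the joint best
    stratum, dedupe identical genomic projections, and recompute n_hits."""
    combined: Dict[ReadKey, List[AlignmentRecord]] = {}
    for key in set(genome_hits) | set(junction_hits):
        records = genome_hits.get(key, []) + junction_hits.get(key, [])
        best = min(r.mismatches for r in records)
        dedup = {}
        for r in records:
            if r.mismatches == best:
                dedup.setdefault(r.projection, r)
        n = len(dedup)
        combined[key] = [replace(r, n_hits=n) for r in dedup.values()]
    return combined


def _summarize(result_records, owner_stage, unmapped, total) -> MappingSummary:
    unique = sum(1 for recs in result_records.values() if recs[0].n_hits == 1)
    multi = len(result_records) - unique
    per_stage: Dict[str, int] = {}
    for stage in owner_stage.values():
        per_stage[stage] = per_stage.get(stage, 0) + 1
    return MappingSummary(
        total_reads=total,
        mapped_unique=unique,
        mapped_multi=multi,
        unmapped=len(unmapped),
        per_stage=per_stage,
    )


def iterative_map(
    reads: List[ReadRecord],
    genome: Dict[str, str],
    library: JunctionLibrary,
    params: MappingParams = MappingParams(),
) -> MappingResult:
    """Run the full iterative strategy over a read set.

    Phase 1: genome + junction alignment at the initial budget, then split
    mapping of the leftovers.  Phase 2: re-run the round with the budget
    raised one step at a time up to floor(L/25).  Phase 3: trim the still
    unmapped reads from the 3' end in 10 nt steps (genome + split only,
    budget floor(L'/25)) until the length floor.  Each read is owned by the
    first stage that placed it; the unique+multi+unmapped partition is
    recorded at every phase boundary.
    """
    reads = list(reads)
    total = len(reads)
    genome_aligner = ExhaustiveAligner(genome)
    junction_aligner = ExhaustiveAligner(dict(library.contig_sequences()))

    result = MappingResult(total_reads=total)
    pending: Dict[ReadKey, ReadRecord] = {_read_key(r): r for r in reads}
    if len(pending) != total:
        raise ValueError("duplicate (read_id, mate_index) keys in input")

    def adopt(hits: Dict[ReadKey, List[AlignmentRecord]], label: str, per_record_stage=False):
        for key, recs in hits.items():
            if key not in pending:
                continue
            result.records[key] = recs
            result.owner_stage[key] = recs[0].stage if per_record_stage else label
            del pending[key]

    def checkpoint():
        result.unmapped = set(pending)
        result.phase_summaries.append(
            _summarize(result.records, result.owner_stage, result.unmapped, total)
        )

    def round_genome_junction_split(current: List[ReadRecord], mm: int, prefix: str = "",
                                    with_junctions: bool = True):
        g_stage = f"{prefix}{STAGE_GENOME}" if prefix else STAGE_GENOME
        j_stage = f"{prefix}{STAGE_JUNCTION}" if prefix else STAGE_JUNCTION
        s_stage = f"{prefix}{STAGE_SPLIT}" if prefix else STAGE_SPLIT
        g = align_genome(current, genome, mm, aligner=genome_aligner, stage=g_stage)
        j = (
            align_junctions(current, library, mm, params.min_span,
                            aligner=junction_aligner, stage=j_stage)
            if with_junctions
            else {}
        )
        combined = _combine_rounds(g, j)
        # owner stage: genome if any genome placement survived, else junction
        for key, recs in combined.items():
            label = g_stage if any(r.stage == g_stage for r in recs) else j_stage
            if key in pending:
                result.records[key] = recs
                result.owner_stage[key] = label
                del pending[key]
        leftovers = [r for r in current if _read_key(r) in pending]
        s = split_map(
            leftovers, genome, mm, params.min_segment, params.intron_range,
            library=library, aligner=genome_aligner, allow_gc_ag=params.allow_gc_ag,
            stage=s_stage,
        )
        adopt(s, s_stage)

    # Phase 1
    m0 = params.initial_mismatches
    round_genome_junction_split(list(pending.values()), m0)
    checkpoint()

    # Phase 2: mismatch escalation up to floor(L/25) per read
    if pending:
        max_cap = max(params.max_mismatches_for(len(r)) for r in pending.values())
        m = m0
        while pending and m < max_cap:
            m += params.mismatch_step
            eligible = [r for r in pending.values() if params.max_mismatches_for(len(r)) >= m]
            if not eligible:
                break
            round_genome_junction_split(eligible, m, prefix=f"mm{m}:")
            checkpoint()

    # Phase 3: iterative 3' trimming, genome + split only
    if pending:
        round_no = 0
        while True:
            round_no += 1
            trimmed: List[ReadRecord] = []
            trim_of: Dict[ReadKey, int] = {}
            for r in pending.values():
                cut = round_no * params.trim_step
                new_len = len(r) - cut
                if params.min_length >= len(r):
                    continue  # no trimming for this read
                if new_len < params.min_length:
                    continue
                seq = r.sequence[:new_len] if params.trim_from == "3p" else r.sequence[-new_len:]
                quals = r.qualities
                if quals is not None:
                    quals = quals[:new_len] if params.trim_from == "3p" else quals[-new_len:]
                trimmed.append(ReadRecord(r.read_id, seq, quals, r.mate_index))
                trim_of[_read_key(r)] = new_len
            if not trimmed:
                break
            lengths = {len(r) for r in trimmed}
            for L in sorted(lengths, reverse=True):
                subset = [r for r in trimmed if len(r) == L]
                mm = params.max_mismatches_for(L)
                round_genome_junction_split(
                    subset, mm, prefix=f"trimmed@{L}:", with_junctions=False
                )
            checkpoint()
    if not result.phase_summaries:
        checkpoint()
    result.unmapped = set(pending)
    return result


def merge_mappings(result: MappingResult, genome_lengths: Dict[str, int], path: str,
                   format: str = "sam") -> MappingSummary:
    """Write the merged mapping to one SAM/BAM file, the stage of origin in
    the XS tag, and return a summary recomputed from the written file.

    Each read must be owned by exactly one stage (guaranteed by
    :func:`iterative_map`; duplicated ownership raises)."""
    from . import formats

    seen = set()
    for key in result.records:
        if key in seen:
            raise ValueError(f"read {key} owned by more than one stage")
        seen.add(key)
    formats.write_alignments(result.all_records(), path, genome_lengths, format=format)
    recs = formats.read_alignments(path, format=format)
    grouped: Dict[ReadKey, List[AlignmentRecord]] = {}
    for r in recs:
        grouped.setdefault((r.read_id, r.mate_index), []).append(r)
    unique = sum(1 for v in grouped.values() if v[0].n_hits == 1)
    per_stage: Dict[str, int] = {}
    for key, v in grouped.items():
        per_stage[result.owner_stage[key]] = per_stage.get(result.owner_stage[key], 0) + 1
    return MappingSummary(
        total_reads=result.total_reads,
        mapped_unique=unique,
        mapped_multi=len(grouped) - unique,
        unmapped=result.total_reads - len(grouped),
        per_stage=per_stage,
    )
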