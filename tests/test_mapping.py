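"""The iterative mapping strategy and its aligner contract."""

import numpy as np
import pytest

from spliceflow import simdata
from spliceflow.annotation import build_junction_library
from spliceflow.core import ReadRecord, revcomp
from spliceflow.mapping import (
    ExhaustiveAligner,
    MappingParams,
    align_genome,
    align_junctions,
    best_stratum,
    brute_force_scan,
    iterative_map,
    merge_mappings,
    split_map,
)


def _reads(*seqs):
    return [ReadRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def test_unique_exact_hit(sim):
    truth, _, _ = sim
    chrom = truth.genome["chr1"]
    read = _reads(chrom[5000:5030])
    hits = align_genome(read, truth.genome, 0)
    ((rec,),) = [hits[("r0", 0)]]
    assert (rec.chrom, rec.segments, rec.strand, rec.mismatches, rec.n_hits) == (
        "chr1", ((5000, 5030),), "+", 0, 1,
    )


def test_duplicated_sequence_counts_two_hits():
    genome = {"c": "TTTT" + "ACGTACGTACGTACGTACGTACGTACGTACGT" + "CCCC"
                   + "ACGTACGTACGTACGTACGTACGTACGTACGT" + "GGGG"}
    read = _reads(genome["c"][4:36])
    hits = align_genome(read, genome, 0)
    recs = hits[("r0", 0)]
    # the 32-mer is also internally periodic; all placements are equally good
    assert all(r.n_hits == len(recs) for r in recs)
    assert len(recs) >= 2


def test_mismatch_budget_is_a_hamming_threshold(sim):
    truth, _, _ = sim
    src = truth.genome["chr1"][8000:8040]
    mutated = src[:10] + ("A" if src[10] != "A" else "C") + src[11:]
    mutated = mutated[:25] + ("G" if mutated[25] != "G" else "T") + mutated[26:]
    read = _reads(mutated)
    assert ("r0", 0) not in align_genome(read, truth.genome, 1)
    rec = align_genome(read, truth.genome, 2)[("r0", 0)][0]
    assert rec.mismatches == 2 and rec.segments == ((8000, 8040),)


def test_minus_strand_hit(sim):
    truth, _, _ = sim
    read = _reads(revcomp(truth.genome["chr1"][7000:7050]))
    rec = align_genome(read, truth.genome, 0)[("r0", 0)][0]
    assert rec.strand == "-" and rec.segments == ((7000, 7050),)


def test_read_longer_than_chromosome_is_unmapped():
    assert align_genome(_reads("A" * 50), {"c": "ACGT" * 10}, 2) == {}


@pytest.mark.parametrize("mm", [0, 1, 2])
def test_aligner_equals_brute_force_oracle(mm):
    """Exhaustiveness: seeded search == all-positions Hamming scan."""
    rng = np.random.default_rng(20)
    genome = {"c": "".join(rng.choice(list("ACGT"), size=5000))}
    aligner = ExhaustiveAligner(genome)
    for i in range(40):
        start = int(rng.integers(0, 4950))
        seq = list(genome["c"][start : start + 50])
        for pos in rng.choice(50, size=rng.integers(0, 4), replace=False):
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        seq = "".join(seq)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        got = {tuple(h) for h in aligner.search(seq, mm)}
        expect = {tuple(h) for h in brute_force_scan(seq, genome, mm)}
        assert got == expect


def _junction_setup():
    rng = np.random.default_rng(8)
    seq = list(rng.choice(list("ACGT"), size=2000))
    seq[500:502] = list("GT")
    seq[898:900] = list("AG")
    genome = {"c": "".join(seq)}
    from spliceflow.core import Exon, Gene, GeneModel, Transcript

    exons = [Exon("c", 300, 500, "+"), Exon("c", 900, 1100, "+")]
    model = GeneModel([Gene("g", "c", "+", [Transcript("g.t1", exons)])])
    lib = build_junction_library(model, genome, flank=50)
    return genome, model, lib


def test_junction_spanning_read_lifts_to_two_segments():
    genome, _, lib = _junction_setup()
    read_seq = genome["c"][475:500] + genome["c"][900:925]  # 25/25 across
    recs = align_junctions(_reads(read_seq), lib, 0, min_span=4)[("r0", 0)]
    assert recs[0].segments == ((475, 500), (900, 925))


def test_read_inside_flank_does_not_span():
    genome, _, lib = _junction_setup()
    read_seq = genome["c"][455:495]  # entirely in the upstream flank
    assert align_junctions(_reads(read_seq), lib, 0, min_span=4) == {}


@pytest.mark.parametrize("overhang,kept", [(4, True), (3, False)])
def test_min_span_boundary(overhang, kept):
    genome, _, lib = _junction_setup()
    read_seq = genome["c"][500 - (40 - overhang) : 500] + genome["c"][900 : 900 + overhang]
    out = align_junctions(_reads(read_seq), lib, 0, min_span=4)
    assert (("r0", 0) in out) is kept


def test_split_map_recovers_unannotated_intron():
    genome, _, _ = _junction_setup()
    read_seq = genome["c"][470:500] + genome["c"][900:920]  # GT..AG intron
    (rec,) = split_map(_reads(read_seq), genome, 0, min_segment=10)[("r0", 0)]
    assert rec.segments == ((470, 500), (900, 920))
    assert rec.junctions() == [(500, 900)]


def test_split_map_rejects_non_consensus_motif():
    genome, _, _ = _junction_setup()
    broken = dict(genome)
    broken["c"] = genome["c"][:898] + "AC" + genome["c"][900:]  # GT..AC
    read_seq = broken["c"][470:500] + broken["c"][900:920]
    assert split_map(_reads(read_seq), broken, 0, min_segment=10) == {}


def test_exonic_read_yields_no_split():
    genome, _, _ = _junction_setup()
    read_seq = genome["c"][350:400]
    assert split_map(_reads(read_seq), genome, 0, min_segment=10) == {}


def test_mismatch_cap_and_trim_schedule_defaults():
    p = MappingParams()
    assert p.max_mismatches_for(100) == 4  # 1 mismatch per 25 nt
    assert p.max_mismatches_for(99) == 3  # floor, not ceiling
    assert p.trim_schedule(100) == [90, 80, 70, 60, 50, 40, 30]
    # min_length equal to the read length: no trimming at all
    assert MappingParams(min_length=100).trim_schedule(100) == []


def test_error_free_reads_all_map_in_phase_one(sim):
    """Error-free reads from annotated transcripts map completely in the
    first round (a read overhanging a splice site by less than min_span is
    the documented exception, so such reads are excluded here)."""
    truth, _, library = sim
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=900,
                                read_length=100, seed=21)
    params = MappingParams()
    keep = []
    tx = {t.transcript_id: t for g in truth.model for t in g.transcripts}
    for read, row in zip(rt.reads, rt.table.itertuples(index=False)):
        blocks = tx[row.transcript_id].genomic_blocks_for(row.tstart, row.tend)
        if min(e - s for s, e in blocks) >= params.min_span:
            keep.append(read)
    assert len(keep) > 800
    result = iterative_map(keep, truth.genome, library, params)
    first = result.phase_summaries[0]
    assert first.unmapped == 0
    assert len(result.phase_summaries) == 1  # later phases never ran
    assert set(result.owner_stage.values()) <= {"genome", "junction", "split"}


def test_conservation_and_monotonicity(sim):
    truth, _, library = sim
    rt = simdata.simulate_reads(
        truth.source_model, truth.genome, n_reads=1500, read_length=100,
        error_rate=0.01, seed=33,
    )
    result = iterative_map(rt.reads, truth.genome, library, MappingParams())
    mapped = []
    for s in result.phase_summaries:
        assert s.mapped_unique + s.mapped_multi + s.unmapped == s.total_reads
        mapped.append(s.mapped)
    assert mapped == sorted(mapped)


def test_merge_recount_matches_summary(sim, tmp_path):
    truth, reads, library = sim
    result = iterative_map(reads.reads[:500], truth.genome, library, MappingParams())
    lengths = {k: len(v) for k, v in truth.genome.items()}
    recount = merge_mappings(result, lengths, str(tmp_path / "m.sam"))
    s = result.summary
    assert (recount.total_reads, recount.mapped_unique, recount.mapped_multi,
            recount.unmapped) == (s.total_reads, s.mapped_unique, s.mapped_multi,
                                  s.unmapped)
    assert sum(recount.per_stage.values()) == recount.mapped_unique + recount.mapped_multi


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        MappingParams(trim_step=0)
    with pytest.raises(ValueError):
        align_genome(_reads("ACGT"), {"c": "ACGTACGT"}, -1)
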