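"""Read clusters, chimera classification, novel-junction collection."""

import numpy as np
import pytest

from spliceflow import simdata
from spliceflow.annotation import build_junction_library, extract_transcriptome
from spliceflow.core import AlignmentRecord
from spliceflow.discovery import (
    PUTATIVE_CHIMERA,
    SPLICE_VARIANT,
    build_clusters,
    collect_novel_junctions,
    detect_chimeras,
)


def _rec(rid, segments, chrom="chr1", strand="+", stage="genome"):
    return AlignmentRecord(rid, 0, chrom, tuple(segments), strand, 0, stage,
                           sum(e - s for s, e in segments))


def test_cluster_counts_and_staggered():
    reads = [
        _rec("a", [(100, 150)]),
        _rec("b", [(100, 150)]),
        _rec("c", [(120, 170)]),
        _rec("d", [(120, 170)]),
        _rec("e", [(140, 190)]),
    ]
    (cluster,) = build_clusters(reads)
    assert (cluster.read_count, cluster.staggered_count) == (5, 3)
    assert (cluster.start, cluster.end) == (100, 190)


def test_one_nt_gap_separates_clusters():
    reads = [_rec("a", [(100, 150)]), _rec("b", [(151, 200)])]
    assert len(build_clusters(reads)) == 2
    # touching half-open intervals share no base either
    reads = [_rec("a", [(100, 150)]), _rec("b", [(150, 200)])]
    assert len(build_clusters(reads)) == 2


def test_split_read_bridges_its_flanks_but_intron_covers_nothing():
    split = _rec("s", [(100, 130), (500, 520)], stage="split")
    left = _rec("l", [(90, 120)])
    right = _rec("r", [(505, 540)])
    middle = _rec("m", [(300, 340)])  # inside the intron
    clusters = build_clusters([split, left, right, middle])
    sizes = sorted(c.read_count for c in clusters)
    assert sizes == [1, 3]  # split+flanks fused; intron read alone


def test_clusters_match_union_find_oracle():
    rng = np.random.default_rng(14)
    reads = []
    for i in range(400):
        s = int(rng.integers(0, 5000))
        reads.append(_rec(f"r{i}", [(s, s + int(rng.integers(10, 80)))]))
    clusters = build_clusters(reads)
    # brute-force union-find over pairwise segment overlaps
    parent = list(range(len(reads)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            a, b = reads[i].segments[0], reads[j].segments[0]
            if a[0] < b[1] and b[0] < a[1]:
                parent[find(i)] = find(j)
    from collections import Counter

    brute = sorted(Counter(find(i) for i in range(len(reads))).values())
    assert sorted(c.read_count for c in clusters) == brute
    assert sum(c.read_count for c in clusters) == len(reads)
    assert all(c.read_count >= c.staggered_count >= 1 for c in clusters)


def test_stranded_clustering_separates_strands():
    reads = [_rec("a", [(100, 150)], strand="+"), _rec("b", [(120, 170)], strand="-")]
    assert len(build_clusters(reads, stranded=True)) == 2
    assert len(build_clusters(reads, stranded=False)) == 1


def test_source_filter():
    reads = [_rec("a", [(0, 50)], stage="genome"), _rec("b", [(0, 50)], stage="split")]
    assert sum(c.read_count for c in build_clusters(reads, source="genomic")) == 1
    with pytest.raises(ValueError):
        build_clusters(reads, source="bogus")


@pytest.fixture(scope="module")
def chimera_setup():
    genome = simdata.make_genome(length=30_000, seed=40, repeat_free_k=20)
    truth = simdata.make_annotation(genome, n_genes=3, cassette_genes=1,
                                    hidden_genes=0, seed=40)
    transcriptome = extract_transcriptome(truth.model, truth.genome)
    return truth, transcriptome


def test_single_end_input_rejected(chimera_setup):
    truth, transcriptome = chimera_setup
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=2,
                                read_length=50, seed=1)
    with pytest.raises(ValueError, match="paired"):
        detect_chimeras(rt.reads, truth.model, transcriptome)


def test_fusion_pairs_all_called_chimera(chimera_setup):
    truth, transcriptome = chimera_setup
    fid, fseq, boundary = simdata.make_fusion_transcript(
        truth.model, truth.genome, "g001", "g003")
    pairs = simdata.simulate_fusion_pairs(fseq, boundary, 60, read_length=60,
                                          insert=160, seed=2)
    calls = detect_chimeras(pairs, truth.model, transcriptome)
    assert len(calls) == 60
    assert all(c.classification == PUTATIVE_CHIMERA for c in calls)
    assert all({c.gene_a, c.gene_b} == {"g001", "g003"} for c in calls)


def test_normal_pairs_produce_no_chimeras(chimera_setup):
    truth, transcriptome = chimera_setup
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=800,
                                read_length=60, paired=True, insert=200, seed=3)
    calls = detect_chimeras(rt.pairs, truth.model, transcriptome)
    assert all(c.classification != PUTATIVE_CHIMERA for c in calls)


def test_same_gene_different_isoforms_is_splice_variant(chimera_setup):
    truth, transcriptome = chimera_setup
    # cassette gene: mate1 unique to the skipped isoform's junction region,
    # mate2 unique to the cassette exon (inclusion isoform only)
    gene = truth.model.genes[0]
    t_in, t_skip = gene.transcripts[0], gene.transcripts[1]
    in_exons = {e.key for e in t_in.exons}
    skip_exons = {e.key for e in t_skip.exons}
    (cassette,) = [k for k in in_exons - skip_exons]
    seq_in = transcriptome[t_in.transcript_id]
    seq_skip = transcriptome[t_skip.transcript_id]
    # a mate inside the cassette exon: substring of t_in absent from t_skip
    cass_exon = next(e for e in t_in.exons if e.key == cassette)
    offset = sum(len(e) for e in t_in.exons_5to3()
                 if t_in.exons_5to3().index(e) < t_in.exons_5to3().index(cass_exon))
    mate1 = seq_in[offset + 5 : offset + 55]
    # a mate spanning the skip junction: substring of t_skip absent from t_in
    upstream_len = len(t_skip.exons_5to3()[0])
    mate2 = seq_skip[upstream_len - 25 : upstream_len + 25]
    from spliceflow.core import ReadRecord, revcomp

    pair = (ReadRecord("pX", mate1, None, 1), ReadRecord("pX", revcomp(mate2), None, 2))
    calls = detect_chimeras([pair], truth.model, transcriptome)
    assert len(calls) == 1
    assert calls[0].classification == SPLICE_VARIANT
    assert calls[0].gene_a == calls[0].gene_b == gene.gene_id


def test_collect_novel_junctions(sim):
    truth, reads, library = sim
    from spliceflow.mapping import MappingParams, iterative_map
    from spliceflow.postmap import classify_uniqueness, unique_records

    result = iterative_map(reads.reads, truth.genome, library, MappingParams())
    uniq = unique_records(classify_uniqueness(result.records))
    novel = collect_novel_junctions(uniq, library, genome=truth.genome)
    found = {(q.junction.chrom, q.junction.donor_end, q.junction.acceptor_start)
             for q in novel}
    for j in truth.hidden_junctions:
        assert (j.chrom, j.donor_end, j.acceptor_start) in found
    # an annotated junction is never reported here
    annotated = library.coordinate_set()
    assert not (found & annotated)


def test_no_split_reads_no_novel_junctions(sim):
    _, _, library = sim
    assert collect_novel_junctions([], library) == []
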