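"""The synthetic-data generators and their determinism guarantees."""

import numpy as np
import pytest

from spliceflow import simdata
from spliceflow.annotation import extract_transcriptome
from spliceflow.core import revcomp


def test_same_seed_identical_genome():
    a = simdata.make_genome(length=5000, seed=9)
    b = simdata.make_genome(length=5000, seed=9)
    assert a == b
    c = simdata.make_genome(length=5000, seed=10)
    assert a != c


def test_gc_fraction_binomial_oracle():
    g = simdata.make_genome(length=100_000, gc=0.5, seed=1)
    seq = g["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(0.5, abs=0.01)


def test_repeat_free_mode_has_no_duplicate_kmer():
    g = simdata.make_genome(length=50_000, seed=2, repeat_free_k=20)
    seq = g["chr1"]
    k = 20
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    assert len(kmers) == len(seq) - k + 1


def test_annotation_structure_and_motifs():
    g = simdata.make_genome(length=60_000, seed=5)
    truth = simdata.make_annotation(g, n_genes=4, cassette_genes=1,
                                    hidden_genes=1, seed=5)
    assert len(truth.model) == 3 and len(truth.source_model) == 4
    for gene in truth.source_model:
        seq = truth.genome[gene.chrom]
        for tx in gene.transcripts:
            for a, b in zip(tx.exons, tx.exons[1:]):
                donor, acceptor = a.end, b.start
                motif = seq[donor : donor + 2] + seq[acceptor - 2 : acceptor]
                assert motif == ("GTAG" if gene.strand == "+" else "CTAC")


def test_cassette_gene_has_two_transcripts_differing_by_one_exon():
    g = simdata.make_genome(length=60_000, seed=6)
    truth = simdata.make_annotation(g, n_genes=2, cassette_genes=1, seed=6)
    gene = truth.model.genes[0]
    assert len(gene.transcripts) == 2
    keys = [{e.key for e in t.exons} for t in gene.transcripts]
    assert len(keys[0] - keys[1]) == 1 and not (keys[1] - keys[0])


def test_insufficient_space_errors():
    g = simdata.make_genome(length=1000, seed=7)
    with pytest.raises(ValueError, match="insufficient"):
        simdata.make_annotation(g, n_genes=10, seed=7)


def test_error_free_reads_are_exact_transcript_substrings():
    g = simdata.make_genome(length=40_000, seed=8)
    truth = simdata.make_annotation(g, n_genes=3, seed=8)
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=200,
                                read_length=80, seed=8)
    seqs = extract_transcriptome(truth.model, truth.genome)
    for read, row in zip(rt.reads, rt.table.itertuples(index=False)):
        assert read.sequence == seqs[row.transcript_id][row.tstart : row.tend]


def test_isoform_mix_follows_binomial_oracle():
    g = simdata.make_genome(length=40_000, seed=13)
    truth = simdata.make_annotation(g, n_genes=1, cassette_genes=1, seed=13)
    t1, t2 = [t.transcript_id for t in truth.model.genes[0].transcripts]
    rt = simdata.simulate_reads(
        truth.model, truth.genome, n_reads=10_000, read_length=80,
        weights={t1: 0.7, t2: 0.3}, seed=14,
    )
    n1 = (rt.table.transcript_id == t1).sum()
    sd = np.sqrt(10_000 * 0.7 * 0.3)
    assert abs(n1 - 7000) <= 3 * sd


def test_paired_mates_differ_by_insert_minus_read_length():
    g = simdata.make_genome(length=40_000, seed=15)
    truth = simdata.make_annotation(g, n_genes=2, seed=15)
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=500,
                                read_length=60, paired=True, insert=200, seed=15)
    t = rt.table
    m1 = t[t.mate == 1].set_index("read_id")
    m2 = t[t.mate == 2].set_index("read_id")
    diffs = (m2.tstart - m1.tstart).values
    assert (diffs == 200 - 60).all()
    # mate 2 is the reverse complement of the fragment's far end
    seqs = extract_transcriptome(truth.model, truth.genome)
    r1, r2 = rt.pairs[0]
    row = m2.loc[r1.read_id]
    assert r2.sequence == revcomp(seqs[row.transcript_id][row.tstart : row.tend])


def test_fragment_longer_than_transcript_rejected():
    g = simdata.make_genome(length=40_000, seed=16)
    truth = simdata.make_annotation(g, n_genes=2, exon_length=(80, 120),
                                    exons_per_gene=(2, 2), seed=16)
    with pytest.raises(ValueError, match="exceeds"):
        simdata.simulate_reads(truth.model, truth.genome, n_reads=10,
                               read_length=100, paired=True, insert=5000, seed=1)


def test_error_rate_injects_substitutions():
    g = simdata.make_genome(length=40_000, seed=17)
    truth = simdata.make_annotation(g, n_genes=2, seed=17)
    rt = simdata.simulate_reads(truth.model, truth.genome, n_reads=1000,
                                read_length=100, error_rate=0.01, seed=18)
    seqs = extract_transcriptome(truth.model, truth.genome)
    mismatches = sum(
        sum(a != b for a, b in zip(read.sequence,
                                   seqs[row.transcript_id][row.tstart:row.tend]))
        for read, row in zip(rt.reads, rt.table.itertuples(index=False))
    )
    # 100,000 bases at 1%: ~1000 substitutions
    assert 700 <= mismatches <= 1300


def test_three_prime_bias_mode_skews_start_positions():
    g = simdata.make_genome(length=40_000, seed=19)
    truth = simdata.make_annotation(g, n_genes=2, seed=19)
    uni = simdata.simulate_reads(truth.model, truth.genome, n_reads=3000,
                                 read_length=60, bias="uniform", seed=20)
    biased = simdata.simulate_reads(truth.model, truth.genome, n_reads=3000,
                                    read_length=60, bias="3p", seed=20)
    assert biased.table.tstart.mean() > uni.table.tstart.mean()
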