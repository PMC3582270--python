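"""Shared fixtures: a tiny hand-crafted gene model (exact coordinates known)
and a small simulated dataset (seeded, generated at test time)."""

import numpy as np
import pytest

from spliceflow.core import Exon, Gene, GeneModel, Transcript
from spliceflow import simdata
from spliceflow.annotation import build_junction_library


def _place(seq: list, pos: int, s: str) -> None:
    seq[pos : pos + len(s)] = list(s)


@pytest.fixture(scope="session")
def tiny():
    """One plus-strand 3-exon gene on a 400 nt chromosome.

    Exons [10,30), [90,110), [170,190); introns [30,90) and [110,170) carry
    GT..AG.  A second transcript skips the middle exon (cassette).
    """
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=400))
    _place(seq, 30, "GT")
    _place(seq, 88, "AG")
    _place(seq, 110, "GT")
    _place(seq, 168, "AG")
    genome = {"chr1": "".join(seq)}
    exons = [
        Exon("chr1", 10, 30, "+"),
        Exon("chr1", 90, 110, "+"),
        Exon("chr1", 170, 190, "+"),
    ]
    gene = Gene(
        "gA",
        "chr1",
        "+",
        [
            Transcript("gA.t1", exons),
            Transcript("gA.t2", [exons[0], exons[2]]),
        ],
    )
    return genome, GeneModel([gene])


@pytest.fixture(scope="session")
def sim():
    """Simulated project: 100 kb repeat-free genome, 6 genes (2 cassette,
    1 hidden), 4,000 error-free 100 nt reads, plus the junction library."""
    genome = simdata.make_genome(length=100_000, seed=11, repeat_free_k=20)
    truth = simdata.make_annotation(
        genome, n_genes=6, cassette_genes=2, hidden_genes=1, seed=11
    )
    reads = simdata.simulate_reads(
        truth.source_model, truth.genome, n_reads=4000, read_length=100, seed=12
    )
    library = build_junction_library(truth.model, truth.genome, flank=99)
    return truth, reads, library
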