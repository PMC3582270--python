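"""Build the splice-junction library from a gene annotation.

The library contains every annotated junction plus every junction formed by
an ordered pair of non-overlapping exons of the same gene ("legal
combinations" — the extra junctions alternative splicing could produce).  A
single-transcript gene of n exons therefore yields n(n-1)/2 junctions.  Each
junction gets a reference contig of flanking exonic sequence so that reads
spanning the splice site can be aligned contiguously.
"""

from spliceflow import build_junction_library, simdata
from spliceflow.core import ORIGIN_KNOWN, ORIGIN_LEGAL

genome = simdata.make_genome(length=50_000, seed=5, repeat_free_k=20)
truth = simdata.make_annotation(genome, n_genes=4, cassette_genes=2, seed=5)

library = build_junction_library(truth.model, truth.genome, flank=74)
print(f"genes: {len(truth.model)}; junctions in library: {len(library)}")
print(f"  annotated (known):     {len(library.by_origin(ORIGIN_KNOWN))}")
print(f"  legal combinations:    {len(library.by_origin(ORIGIN_LEGAL))}")

j = next(iter(library))
contig = library.contigs[j.junction_id]
print(f"example junction {j.junction_id}: intron {j.intron_length} nt, "
      f"contig {len(contig.sequence)} nt, splice site at offset {contig.boundary}")

# Reading: a 4-exon single-transcript gene contributes 3 known junctions
# (consecutive exon pairs) and 3 legal combinations (exon skips); a read
# needs to overhang the contig's splice-site offset on both sides to count
# as spanning the junction.
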