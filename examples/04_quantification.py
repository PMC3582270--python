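"""Quantify genes, junctions, exon inclusion and isoform abundances.

A one-gene genome with a cassette exon is simulated at a 70/30 isoform mix;
after mapping and uniqueness classification, simple-overlap counting gives
gene/exon RPKM, junction spanning counts split into novelty classes, the
cassette exon's inclusion index, and non-negative least squares on the
splicing-graph system recovers the isoform proportions.
"""

from spliceflow import (
    MappingParams,
    build_junction_library,
    classify_uniqueness,
    deconvolve_transcripts,
    exon_inclusion,
    iterative_map,
    quantify_junctions,
    quantify_overlap,
    simdata,
)
from spliceflow.postmap import unique_records

genome = simdata.make_genome(length=20_000, seed=70, repeat_free_k=20)
truth = simdata.make_annotation(genome, n_genes=1, cassette_genes=1,
                                exons_per_gene=(3, 3), seed=70)
gene = truth.model.genes[0]
t_in, t_skip = gene.transcripts
library = build_junction_library(truth.model, truth.genome, flank=99)
reads = simdata.simulate_reads(
    truth.model, truth.genome, n_reads=10_000, read_length=100,
    weights={t_in.transcript_id: 0.7, t_skip.transcript_id: 0.3}, seed=71)

result = iterative_map(reads.reads, truth.genome, library, MappingParams())
uniq = unique_records(classify_uniqueness(result.records))
total = len(uniq)

for q in quantify_overlap(uniq, truth.model, total):
    if q.feature_type == "gene":
        print(f"gene {q.feature_id}: {q.raw_count:.0f} reads, RPKM {q.rpkm:.0f}")
for jq in quantify_junctions(uniq, library, genome=truth.genome):
    print(f"junction {jq.junction.junction_id}: {jq.spanning_read_count} reads "
          f"({jq.novelty})")
for rec in exon_inclusion(uniq, truth.model):
    print(f"exon {rec.exon_id}: inclusion {rec.inclusion_reads}, "
          f"exclusion {rec.exclusion_reads}, index "
          f"{'-' if rec.inclusion_index is None else f'{rec.inclusion_index:.3f}'}")
out = {q.feature_id: q.raw_count
       for q in deconvolve_transcripts(uniq, truth.model, total)}
share = out[t_in.transcript_id] / (out[t_in.transcript_id] + out[t_skip.transcript_id])
print(f"deconvolved major-isoform proportion: {share:.3f} (simulated 0.700)")

# Reading: the cassette exon's inclusion index sits near the evidence ratio
# implied by the 70/30 mix; the skip junction is 'known' here because the
# skipping isoform is annotated; the NNLS estimate recovers the mix within
# sampling error.
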