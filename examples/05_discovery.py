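"""Discover novel elements: read clusters, unannotated junctions, chimeras.

One gene is hidden from the annotation (its junctions exist only in the
genome sequence) and a fusion transcript joining two genes is implanted into
the paired-end library.  Split mapping recovers the hidden introns; the
transcriptome mapping of mate pairs flags the fusion.
"""

from spliceflow import (
    MappingParams,
    build_clusters,
    build_junction_library,
    classify_uniqueness,
    collect_novel_junctions,
    detect_chimeras,
    extract_transcriptome,
    iterative_map,
    simdata,
)
from spliceflow.postmap import unique_records

genome = simdata.make_genome(length=60_000, seed=50, repeat_free_k=20)
truth = simdata.make_annotation(genome, n_genes=5, cassette_genes=1,
                                hidden_genes=1, seed=50)
library = build_junction_library(truth.model, truth.genome, flank=99)
reads = simdata.simulate_reads(truth.source_model, truth.genome, n_reads=8000,
                               read_length=100, seed=51)
result = iterative_map(reads.reads, truth.genome, library, MappingParams())
uniq = unique_records(classify_uniqueness(result.records))

clusters = build_clusters(uniq)
print(f"{len(clusters)} read clusters; largest: "
      f"{max(c.read_count for c in clusters)} reads "
      f"({max(c.staggered_count for c in clusters)} staggered)")

novel = collect_novel_junctions(uniq, library, genome=truth.genome)
print(f"implanted unannotated junctions: "
      f"{[(j.chrom, j.donor_end, j.acceptor_start) for j in truth.hidden_junctions]}")
print(f"recovered (>=5 spanning reads): "
      f"{[(q.junction.donor_end, q.junction.acceptor_start, q.spanning_read_count) for q in novel if q.spanning_read_count >= 5]}")

transcriptome = extract_transcriptome(truth.model, truth.genome)
_, fseq, boundary = simdata.make_fusion_transcript(truth.model, truth.genome,
                                                   "g001", "g003")
pairs = simdata.simulate_fusion_pairs(fseq, boundary, 50, read_length=75,
                                      insert=180, seed=52)
calls = detect_chimeras(pairs, truth.model, transcriptome)
kinds = {c.classification for c in calls}
print(f"fusion pairs called: {len(calls)}/50, classes {kinds}")

# Reading: clusters re-draw the transcribed regions with no read-count
# threshold; the hidden gene's introns come back with exact coordinates and
# two orders of magnitude more spanning reads than the low-count artifacts
# (reads overhanging a hidden junction too little to split there settle on
# an alternative consensus split); every implanted fusion pair is classified
# putative_chimera because its mates map uniquely to transcripts of two
# different genes.
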