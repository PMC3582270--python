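# Methods

This note records the models, defaults and numerical choices behind
spliceflow, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to 1-based
inclusive conventions happens only at I/O boundaries (GTF, SAM, GFF out;
BED stays 0-based).  FASTQ qualities are fixed at Phred+33; a quality
character below `!` is rejected outright rather than guessed at — offset-64
data must be re-encoded upstream.  Paired reads arrive as two parallel files
(`_1`/`_2`) or interleaved with `/1`,`/2` suffixes; the layout is declared in
the project config, never sniffed.

## Junction library

"Legal combinations" are interpreted as ordered pairs of distinct,
coordinate-deduplicated, non-overlapping exons within one gene, using each
exon's annotated boundaries as donor and acceptor; any within-gene pair
qualifies, not only pairs co-occurring in transcript order.  Junctions never
join exons of different genes.  Pairs whose implied intron is shorter than
`min_intron` (default 40 nt) are dropped — shorter gaps are indistinguishable
from small deletions at these scales.  The contig flank defaults to
`read_length − 1` so any read overhanging the splice site by one base fits on
the contig; a flank longer than its exon is truncated to the exon and
flagged, never an error.

## The bundled aligner and its contract

The aligner contract is: given a read and a substitution budget m, return
*every* placement with ≤ m mismatches on either strand.  The bundled
implementation guarantees this by pigeonhole seeding — an alignment with ≤ m
substitutions contains at least one of m+1 disjoint exact seed segments — with
seed lookups against a sorted rolling-hash index (base-8 Horner in uint64;
hash wraparound can only add candidates, which full numpy verification then
discards, so exhaustiveness is unaffected).  Queries too short to seed
usefully (below 6 nt per seed) fall back to a full sliding scan, which is
exhaustive by construction.  A separate all-positions Hamming scan
(`mapping.brute_force_scan`) exists purely as an independent oracle for
tests; the two routes are never collapsed.

Mismatches are substitutions only.  Indel support is allowed for plugged
aligners but not required, and the bundled one does not attempt it.

## Iterative mapping

Defaults: initial budget 2 mismatches; escalation by 1 up to ⌊L/25⌋
(floor, so a 99 nt read caps at 3); trimming removes 10 nt per round from the
3' end (quality decays there) down to a 25 nt floor; `min_length` equal to
the read length disables trimming.  Escalation rounds re-run genome,
junction and split mapping; trimming rounds re-run genome and split only —
the junction contigs are sized for full-length reads.

Split mapping tries every breakpoint leaving ≥ `min_segment` (default 10) nt
per fragment.  Implementation detail: the first and last `min_segment` nt of
the read are anchors; every anchor pair fixes the intron length regardless of
breakpoint, so all breakpoints for a pair are evaluated from two mismatch
cumulative sums in one vector operation.  Candidates need an intron in
`intron_range` (default 40–500,000 nt) and GT..AG or CT..AC at the edges
(GC..AG behind an off-by-default flag).  Ties break deterministically:
fewest mismatches, then junction already in the library, then smallest
intron, then leftmost donor.

Junction placements must overhang the splice site by `min_span` (default 4)
nt on both sides.  Consequence worth knowing: an error-free read overhanging
a junction by 1–3 nt is *not* junction-mappable and may only be placed by a
later mismatch round against the genome; a read overhanging a hidden
(unannotated) junction by less than `min_segment` cannot be split-mapped at
the true site and occasionally settles on an alternative consensus split with
low support.  Both effects are visible in simulations as a ~1% fringe.

Stage ownership is strict priority: genome/junction round before split,
earlier budgets before later, untrimmed before trimmed; each read's records
come from the single stage that first placed it, so the
unique/multi/unmapped partition is well defined at every phase boundary.

## Uniqueness, rescue

Best stratum = fewest mismatches at the longest surviving effective length;
placements from different references that project to identical genomic
segments are collapsed before counting.  One survivor → unique; otherwise
multi, including the genome-unique-plus-junction-unique case.  Mate rescue
minimizes the inner-end gap on the unique mate's chromosome with FR
orientation required (configurable off) and ties broken toward the smaller
coordinate.  Rescued mates stay flagged multi; quantification counts them
only when explicitly asked (`use_rescued`), because rescue is a heuristic.

## Quantification

Only uniquely mapping reads are counted by default.  A read counts for a
feature iff every aligned base lies within the feature's span; the gene span
is the union of its exon intervals (not the intron-inclusive genomic span).
Reads inside two overlapping exons count for each — exon quantifications are
knowingly overestimates in those regions.  RPKM uses the union-exon length
for genes.  Junction counting demands exact donor/acceptor boundary match, no
wobble.

The exon inclusion index is reported in the bounded form
`inc/(inc+exc)` (absent when both are zero); the raw inclusion and exclusion
counts are emitted alongside so the unbounded ratio `inc/exc` is recoverable.
An exon is *internal* when its gene has at least one annotated exon strictly
on each genomic side of it.

Read-position bias histograms place each compatible read's 5'-most transcript
coordinate (strand-aware) into 20 bins of [0,1], normalized by
`transcript length − read length`; transcripts are grouped into length bins
(default edges 0/500/1000/2000/5000).  A read compatible with several
transcripts counts once per transcript, unweighted.

### Transcript deconvolution

Each locus's transcripts are projected onto minimal exonic segments and
junctions.  Observed evidence: aligned bases per segment (divided by read
length) and spanning reads per junction.  The model is the exact uniform
fragment-start process: with density y_t (reads per valid start position of
transcript t), expected depth at transcript position p is
min(p+1, L, M−L+1, M−p), so segment coefficients taper at transcript ends,
and a junction at transcript coordinate c is spanned by
min(M−L, c−min_span) − max(0, c−L+min_span) + 1 start positions — the same
`min_span` filter the junction mapper applies.  The exact coefficients
matter: with 100 nt reads on few-hundred-nt transcripts, the naive
"coefficient = segment length" model misattributes ~7 percentage points of a
70/30 two-isoform mix.  The system is solved by `scipy.optimize.nnls`
(non-negativity is the constraint that matters; no regularization), counts
are y_t·(M−L+1), and a per-locus cap rescales the estimates if they ever
exceed the reads assigned to the locus, so mass is never created.
Single-isoform loci reduce to overlap counting within rounding.

## Discovery

Cluster overlap is segment-wise between reads: the two blocks of a split read
anchor it to both flanks (one cluster), but the intron gap itself covers
nothing, so reads inside the intron form their own clusters.  Components come
from a sorted sweep; the pairwise union-find is kept as a test oracle.
Staggered count = distinct strand-aware 5' positions.

Chimera detection maps both mates to the spliced transcriptome.  Hits that
project to identical genomic blocks are collapsed before judging uniqueness —
without this, any exon shared between isoforms would annihilate sensitivity.
A pair whose unique loci share no transcript is classified by gene: same gene
→ unannotated splice variant, different genes → putative chimera.  Breakpoint
base-pair resolution is out of scope; the evidence is pair-level.
Transcript-structure assembly (e.g. by an external assembler) is a hook, not
reimplemented: a template step can invoke the external tool when present.

## Workflow engine

Makefile-style templates: `NAME = value` variables up top, `step: deps`
headers, indented command lines with `$VAR` substitution; graphs are
validated (acyclic, dependencies defined) and executed lazily toward the
requested target in lexicographic topological order.  State is a JSON file of
per-step status and completion timestamps; a step re-runs when it is not done
or when any ancestor finished after it (Make semantics — the comparison rule
the timestamp store implies but does not define).  A failing step blocks its
dependents; independent branches still complete.  Results live in two
file-backed stores of TSV tables — `common` for annotation-derived shared
data (the junction library is cached there once per project and reused across
datasets) and `results/<dataset>` for per-dataset tables — an embedded,
human-inspectable stand-in for a two-database split.  Prealigned SAM/BAM
input keeps the `map` step but turns it into ingestion, recorded with
provenance `external`.

## Synthetic data

The generator emulates the structural features the pipeline analyzes:
uniform-composition genomes (optionally guaranteed free of duplicate k-mers,
so uniqueness is controllable), multi-exon genes with correct GT..AG/CT..AC
motifs written at implanted introns on either strand, cassette exons with
two isoforms, genes hidden from the annotation (implanted novel junctions),
fusion transcripts joining two genes, per-base substitution errors, per-cycle
N injection, linear 3' quality decay, and uniform fragment starts (an
optional 3'-bias mode exercises the position-bias detector).  Defaults follow
the conditions the pipeline targets: 100 nt reads, error-free unless stated,
fixed insert size for pairs.

It does *not* emulate: indels, quality-conditional error matrices,
homopolymer artifacts, PCR duplication, repeat families, expression
heterogeneity beyond the supplied weights, or intergenic transcription.
Passing tests therefore demonstrate the correctness of the algorithms under
the stated generative model, not robustness to real-library pathology.

## Problem sizes in the test suite

Simulation-backed tests use 100 kb genomes with ~6 genes and 4,000–50,000
reads of 100 nt; the aligner-vs-oracle check runs 1,000 reads on 50 kb at
budgets 0–2; inclusion and deconvolution recovery use 20,000 and 10,000 reads
on single-gene genomes.  These sizes make every property exactly checkable
against brute-force oracles while keeping the full suite in minutes.

## Known limitations

- Substitution-only alignment; reads over indels map only after trimming, or
  not at all.
- Split mapping is restricted to two fragments; multi-intron reads are not
  recovered (at 100 nt reads and toy intron densities this is rare).
- Junction/split thresholds (`min_span`, `min_segment`) leave a small fringe
  of boundary-overhanging reads to the mismatch-escalation rounds.
- Exon inclusion attributes junction reads by boundary identity only; paralog
  interference is not modeled.
- The engine runs datasets sequentially in-process; parallel execution is by
  running datasets in separate processes (state files are per-dataset, and
  the shared cache is written once).
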