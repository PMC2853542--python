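# Methods

## The marker model

An EPIC (exon-primed intron-crossing) marker is an intron short enough to
amplify and sequence routinely, flanked by coding exon segments that are (a)
single-copy in the query genome, so primers bind one locus, and (b) conserved
across the reference species, so one primer pair transfers across taxa. The
pipeline operationalizes each property as a threshold screen; all thresholds
are exposed in `PipelineParams` and the defaults are the published operating
point of the original five-fish comparison.

| parameter | default | meaning |
|---|---|---|
| `min_cds_len` | 100 bp | minimum CDS segment length (inclusive ≥) |
| `copy_coverage_thresh` | 0.20 | copy-number screen, coverage (strict >) |
| `copy_identity_thresh` | 0.40 | copy-number screen, identity (strict >) |
| `max_intron_len` | 1000 bp | intron limit, ≤ in at least one species |
| `min_mean_identity` | 0.85 | mean flanking-exon identity tier (0.65/0.80/0.85) |
| `merge_window` | 1000 bp | junctions this close merge into one marker |
| `require_all_references` | on | marker must map in every reference |
| `map_identity_floor` | 0.50 | reference hit below this identity = unmapped |
| `map_coverage_floor` | 0.50 | reference hit covering less of the exon = unmapped |
| `min_hit_score` | 20 | minimum score in the all-vs-all self comparison |

The copy-number thresholds are strict inequalities ("more than"); the size
and identity screens are inclusive, with mean identity rounded to two
decimals before comparison with the tier (so 0.846 passes the 0.85 tier, as
tier membership is a two-decimal convention).

## Alignment

Local alignment uses exact affine-gap Smith–Waterman (Biopython's
`PairwiseAligner`, C implementation) with match +1 and mismatch −1 — the
relaxed scheme that lets exon comparison extend across short diverged
stretches; the stock −3 mismatch is available as `BLASTN_SCORING` for
comparison, and relaxing the penalty can never lower an optimal score. Gap
convention: a gap of length L scores `gap_open + L·gap_extend` with defaults
−5/−2, i.e. the classic nucleotide-search costs (open 5, extend 2). N never
matches anything, including N, and scores the mismatch penalty. Identity is
identical columns over all aligned columns (gap columns in the denominator);
coverage is aligned non-gap query bases over the full query length.

Tie-breaking among co-optimal alignments is delegated to the engine's
deterministic traceback order rather than enumerated explicitly: co-optimal
tracebacks can be combinatorially many, every choice yields the same score,
and determinism — the property downstream code relies on — is preserved.
Consequently the *identity* of a hit is pinned down only up to the engine's
co-optimal choice; tests therefore assert score equality against an
independent full-DP oracle plus internal rescoring consistency, not
column-count equality between implementations.

## Reference mapping and intron inference

Reference genomes need no annotation: each flanking exon is aligned to every
reference chromosome on both strands and the best hit kept. A reference's
intron length at a junction is the distance between its two flanking-exon
hits in chromosome coordinate order (which hit comes first depends on the
relative orientation of query gene and reference copy). Hits on different
chromosomes, different strands, or overlapping make that reference unmapped
for the junction. A best hit below the identity floor *or* the coverage floor
counts as unmapped: short spurious local hits routinely reach 70–80% identity
over 20 bp, so identity alone cannot call an exon absent; requiring half the
exon aligned at ≥ 50% identity is a permissive presence test well below the
reporting tiers.

Mean exon identity per junction is query-anchored: the mean over references
of each reference's two flanking-hit identities. An all-pairs average among
the species panel would require reference-vs-reference alignments the
pipeline never computes.

## Merging and naming

Qualifying junctions of the same gene whose query spans (upstream exon start
to downstream exon end) lie within `merge_window` of each other — chained
transitively — are reported as one marker covering the union span. A merged
record's mean identity is the mean over constituents; per-species intron
lengths are summed over constituents for species mapped in all of them.
`Marker start (bp)` is reported as the start of the (merged) upstream
flanking exon region by default; an intron-start convention is available via
`marker_start_convention`, since published catalogues report a single start
position without defining it. Locus names take the last five digits of the
gene identifier (zero-padded), then `E`, then the 1-based ordinal of the
marker within its gene in ascending coordinate order.

## Coordinates

Annotation input is GFF3/GTF (1-based inclusive); everything in memory is
0-based half-open on the chromosome forward strand; catalogue output is
1-based inclusive and BED output 0-based half-open. Each annotated CDS
feature line is one segment; for multi-transcript genes the transcript with
the largest total CDS length is used (catalogues of per-exon coding pieces
imply per-segment granularity; the transcript choice is a package decision).

## Amplifiability statistics

The presence matrix holds 1/0/NA cells (amplified / tested-but-failed /
untested); every statistic is computed over tested cells only. DA_ij =
shared amplified loci / union of amplified loci, over loci tested in both
taxa; an empty union raises rather than returning 0, since "no shared
markers" (DA = 0) and "nothing tested in common" are different facts. DA is
historically described as a *difference* of amplifiability but is a
similarity by its range (1 = identical panels); it is exposed as
`amplifiability_similarity` with `da_ij` as the conventional alias.
p-distance excludes sites with a gap or ambiguity in either sequence
(pairwise deletion, the usual default); complete deletion is available by
flag. Pearson p-values use the exact t transform via `scipy.stats.pearsonr`.
The correlation between amplifiability and divergence is taken over unordered
taxon pairs, diagonal excluded.

## The simulator

`simulate_genome_set` generates an ancestor gene set (exons 150–300 bp,
introns 200–900 bp, 2–3 exons per gene by default) and mutates each species'
copy independently: per-site substitutions at `exon_substitution_rate`
(default 0.02 per lineage) in exons and `intron_substitution_rate` (default
0.08) in introns, plus geometric indels (rate 0.01/site, mean 5 bp) in
introns only. Exons take substitutions but no indels, so realized truth
identities are exact column-wise fractions and the expected query-reference
exon identity has the closed form `(1−r)² + r²/3`. Genes are placed on
random strands with random intergenic spacers; references are written
without annotation to exercise the annotation-free mapping path. Four gene
roles plant the pipeline's decision boundaries: ordinary single-copy genes,
long-intron genes (introns 1200–1600 bp in every species), low-identity
genes (exons at 0.15/lineage, pairwise identity ≈ 0.73 — mapped but below
the 0.85 tier), and duplicated genes (a 95%-identical paralog inserted into
the query, annotated, so the copy-number screen sees realistic self-hits and
must discard both copies). Default rates emulate roughly family-level fish
divergence in spirit; the model is deliberately minimal — independent sites,
no rate heterogeneity, no codon structure, no rearrangements, no assembly
artifacts — so passing tests demonstrate the pipeline's decision logic, not
robustness to real genome messiness.

The truth set stores realized per-species intron lengths and per-exon
identities and derives each junction's qualifies-as-marker flag from them
with the same thresholds the pipeline uses, taking column-wise (Hamming)
identity as the proxy for alignment identity. The two can disagree for
sequences near the floor or tier boundaries (a local alignment may trim
low-identity ends); the noise-free preset (`noise_free_config`: substitution
and indel noise off, 2-exon genes, planted disqualifiers kept far from every
boundary — identity exactly 1.0 or ≈ 0.65) is the configuration under which
exact precision/recall against the truth is asserted.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sets chosen to exercise every code
path: the noise-free recovery set has 18 genes × 5 species (≈ 26 kb per
genome; 12 qualifying markers, 6 planted disqualifiers), and the identity-
tier runs use 10 genes × 5 species over 10 seeds. The alignment oracle is a
pure-Python full-matrix Gotoh DP checked on random pairs up to 100 bp. All
randomness flows through a single seeded `numpy` generator per simulation;
identical configs produce byte-identical genomes, and the pipeline itself is
fully deterministic.

## Known limitations

Best-hit mapping without a reciprocity requirement can mis-pair paralogs the
copy-number screen did not remove (an optional reciprocal-best check is the
obvious extension). Reference intron lengths come from hit gaps, so an
assembly gap or rearrangement between the flanking hits masquerades as an
intron-length change. The merge step can in principle report fewer markers
at a lower identity tier than a higher one when a middle junction of a
≥ 3-junction chain drops out and splits a merged region — marker *regions*
are monotone, their count is not a theorem; with realistic short-gene
simulations (≤ 2 junctions per gene) counts behave monotonically. Genome-
scale results depend on annotation quality and repeat content that the
simulator does not model.
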