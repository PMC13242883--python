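# Methods

`bathypan` re-implements, as one tested pipeline, the comparative-genomics
analyses used to characterise intraspecific diversity in *Bathycoccus
prasinos*-like genome panels: the two-haplotype architecture of the big
outlier chromosome (BOC), sliding-window polymorphism divergence, pangenome
occupancy of outlier-region genes, shared-sequence architecture of the small
outlier chromosome (SOC), metagenomic haplotype-ratio estimation, and
distance-based phylogenomics. Because the analyses are exercised end-to-end
on synthetic genomes with a complete truth set, every stage can be validated
by recovery statistics rather than by eyeballing plots.

All coordinates are 0-based half-open internally; GFF3 and VCF emission
convert to 1-based conventions at the file boundary.

## Synthetic genomes (`simgenome`)

The generator emulates a Mamiellophyceae-style haploid genome: by default 19
chromosomes totalling 15 Mb (18 lengths drawn log-normally from a seeded
generator, configurable), genome GC 0.48, coding density 0.787, mono-exonic
non-overlapping genes with log-normal lengths (~1.1 kb). The BOC
(chromosome 14 by default) carries a distal outlier region — 400 kb in
haplotype A, ~500 kb in haplotype B — at GC 0.40 and coding density 0.47.
GC is controlled by per-base sampling probability, not post-hoc correction,
so the i.i.d. structure assumed by the complexity filter calibration is
preserved; realised composition is checked against tolerance (±0.02 GC,
±0.05 coding fraction), never forced.

Haplotype B's outlier region is derived from A's by a recorded, replayable
event series: most of the region is replaced by novel sequence at outlier
composition, while a few interior segments (default 3 of 5–9 kb) are
retained at ~3% substitution divergence, some inverted, one duplicated.
These retained segments supply the alignable, divergent "core" genes shared
by both haplotypes — the substrate for the BOC-region tree — while the
replaced majority makes the region non-syntenic. Replaying the event list on
A's outlier reconstructs B's exactly; an empty list is the identity.

Strain panels descend from the haplotype ancestors along a balanced binary
genealogy: substitutions only on internal branches (`snp_rate` per bp per
branch), substitutions plus placed SVs at the leaves. SVs (INS/DEL/INV/DUP/
TRANS) are sampled with log-uniform sizes per type, placed without overlap
(100 retries, then an error naming the variant), and barred from the outlier
region and the SOC so those structures stay interpretable. Truth tables
record every SNP and SV in both parent and child frames, and gene models
are lifted over (deleted/disrupted genes dropped and recorded, inverted
genes strand-flipped, duplicated genes copied). Haplotypes are assigned
alternately along the leaf order, so haplotype is orthogonal to the first
genealogy split; the haplotype-B outlier sequence evolves in parallel along
the same genealogy and replaces the backbone outlier in B leaves. Each
strain's SOC is rebuilt from a shared block pool (heavy-tailed block sizes,
~2–45 kb) behind a conserved distal core block, with per-strain block
choice, order and orientation; a single-block pool is treated as the
degenerate deterministic case. Designed gene families (core /
clade-specific / private) are appended distally so carriers hold
byte-identical copies.

Read simulation draws from a weighted strain mixture proportionally to
weight × genome length, uniform starts, random strand, i.i.d. substitution
errors. It does not model read-length or quality variation, indel errors,
paired ends, or coverage bias — so recruitment results on synthetic reads
validate the counting and filtering logic, not robustness to platform
artifacts.

## Alignment (`anchor_align`)

Pairwise chromosome alignment is anchored on the exact set of maximal exact
matches (MEMs) of length ≥ 20 (both strands), found with a packed 2-bit
k-mer index at word size = the minimum MEM length plus per-diagonal
coverage tracking; exactness is property-tested against a quadratic
maximal-common-substring enumerator. Anchors are chained per strand by a
dynamic program (score = anchored bp − `gap_open` − |ref_gap − qry_gap|,
ties toward the smaller reference position); inter-anchor gaps ≤ 500 bp on
both sequences are closed by global edit-distance alignment (edlib), larger
gaps split the chain, and chains spanning < 200 bp are discarded. Each
block stores its full column runs, so identity is exact bookkeeping:
identity = matches / columns, gap-inclusive. Since the closure is an
optimal-edit path, a run of substitutions can be reported as a slightly
gapped path of equal cost; identity may shift ~1% against tools that
optimise a different objective. Blocks are filtered at identity > 0.90 and
aligned length > 100 bp (strict inequalities).

Classification selects the highest-scoring mutually collinear,
strand-consistent, non-overlapping block subset as the syntenic backbone
(both query orientations are tried). Every remaining block is split at the
boundaries of syntenic reference coverage — a chain that runs through a
tandem-duplication junction separates into its duplicated and novel parts —
and each piece is labelled DUP when it overlaps already-assigned reference
or query intervals by ≥ 50% of its own length (one-sided by design: after
splitting, the duplicated piece is usually far smaller than the backbone
block it duplicates, so a reciprocal rule would miss real duplications),
SYN when it extends the backbone collinearly, INV when opposite-strand at a
backbone-consistent position, else TRANS. Non-syntenic reference intervals
are the maximal intervals with zero filtered-block coverage.

The SOC shared-sequence catalog runs all-vs-all filtered alignment of SOC
sequences, merges block intervals per pair into maximal shared intervals
(bridging ≤ 100 bp), suppresses records < 500 bp (the chord display
threshold), and reports per-strain shared fractions.

## Divergence (`divergence`)

SNPs are mismatch columns inside syntenic blocks; indel runs ≥ 30 bp inside
blocks and inter-syntenic-block gaps (one side ≥ 30 bp, the other ≤ 20% of
it) become INS/DEL; INV/DUP/TRANS records are lifted from block labels.
Window statistics use 20-kb windows, default step 5 kb (overlapping
"sliding" windows; conservation checks use step = window, where counts sum
exactly to totals). SNPs count at their position, SVs once at their
reference midpoint. The genome-wide density denominator is aligned
(block-covered) bp when available — unaligned sequence carries no variant
information — and the window ratio is window density over that genome-wide
density. Reduced-polymorphism regions are maximal runs of ≥ 3 consecutive
windows with ratio < 1.

Outlier-region delimitation combines two per-window evidence tracks: GC
z-score ≤ −2 against the chromosome-wide window distribution, and
non-syntenic coverage ≥ 50%. Runs tolerate up to 3 consecutive non-flagged
windows, because retained segments inside the outlier briefly restore
synteny; candidates must span ≥ 50 kb; when both tracks yield a candidate
their intersection is returned, otherwise the available track alone. Note
that when the outlier occupies a large fraction of the chromosome (as in
the default architecture, ~2/3), the bimodal GC distribution keeps z-scores
above −2 and delimitation rests on the synteny track; the GC track carries
the signal for small outlier fractions and for self-comparisons without a
query. Coding density is the union-covered fraction of an interval.

## Pangenome (`pangenome`)

CDS are clustered by a deterministic greedy scheme with CD-HIT-EST-like
semantics: canonical visiting order (length descending, then ids), each
gene joining the first cluster whose representative it matches at global
identity ≥ 0.80 over aligned columns with alignment coverage ≥ 0.80 of
both sequences. The pair screen is a length ratio check plus a k-bounded
edit-distance computation whose bound is derived from the thresholds
themselves (an alignment passing 80/80 has edit distance ≤
la + lb − 1.8 × 0.8 × max(la, lb)), so skipped pairs provably cannot match
and the partition is identical with the screen on or off; a shared-k-mer
screen was rejected because a pair can satisfy 80/80 with no shared k-mer
of useful length. Occupancy classes use strict thresholds: core > 90%
presence, rare < 10%, shell otherwise. Strain dendrograms are
average-linkage on Jaccard distances of occupancy rows (all-zero rows at
distance 0), with strains canonically sorted so ties break by id. Cluster
counts are reported with and without strain-private singletons.

## Recruitment (`recruit`)

References are indexed jointly (competitive mapping) with 21-mers held in
value-sorted arrays. Reads are seeded at stride 4 on both strands, votes
accumulate per (target, diagonal, strand) in one vectorised pass, and the
top diagonals are extended by infix edit-distance alignment. Identity is
gap-inclusive (matches / columns) and coverage is the aligned fraction of
the read — the read-side interpretation of the coverage filter, since the
filter is applied per read. Score ties across targets are assigned by a
deterministic hash of the read id and flagged non-unique, so equivalent
references split tied recruitment evenly.

Base complexity is a DUST-like tiled triplet score,
Σ c(c−1)/2 / (n_triplets − 1) over 64-bp windows: ≥ 2.0 marks bases
low-complexity, ≤ 1.0 high-complexity (uniform random sequence scores
~0.5; homopolymers ~31). The filter stack discards reads with
low-complexity fraction > 0.75, high-complexity fraction < 0.30, aligned
fraction < 0.80 or identity < 0.95, then removes positional duplicates
(same target, position, strand, read length; first read id kept). This
score is a stated stand-in for the undocumented complexity definition of
the original filtering tool; its calibration on uniform sequence is part
of the test suite, not a claim of equivalence.

The haplotype ratio maps reads competitively against the two outlier-region
references, keeps filtered uniquely-mapped reads (the regions share
residual homology through the retained segments), and reports
nA / (nA + nB) with a Wilson 95% CI plus a region-length-normalised variant
(nA/LA) / (nA/LA + nB/LB); the normalised form is the comparable estimate
of mixture proportion when the two regions differ in length (400 vs
~500 kb). Cross-mapping specificity is the uniquely-mapped fraction of
filtered reads recruited per reference.

## Phylogenomics (`phylo`)

Per-gene distances are p-distances (mismatched / ungapped columns) from
affine-gap global alignments (match 1, mismatch −1, open −2, extend −0.5);
for equal-length pairs below 15% Hamming divergence the ungapped diagonal
is the affine optimum and is used directly. An optional Jukes–Cantor
correction is off by default. The concatenated matrix is the
ungapped-column-weighted mean of per-gene distances over clusters that are
single-copy in every strain. Trees are canonical neighbor joining with
deterministic tie-breaks (lexicographically smallest pair), negative branch
lengths clamped to zero with the deficit moved to the sibling, and a
trifurcating root. Gene concordance factors are computed per internal
branch as 100 × (gene trees containing the branch's bipartition restricted
to shared leaves) / (decisive gene trees); branches with no decisive gene
tree are reported as undefined, not 0. This distance-based stage stands in
for maximum-likelihood inference with bootstrap at desk scale: the panel
conclusions tested are topological groupings, which NJ recovers for
near-additive distances (property-tested on random additive matrices). No
NJ analogue of a bootstrap-support display threshold is defined; all
branches are reported.

## Validation experiments and problem sizes

`bathypan.validation` holds the truth-driven experiments run by both the
acceptance script and `tests/test_acceptance.py`. Problem sizes are the
package's desk-scale choices: MEM agreement on 200 random pairs ≤ 2 kb;
SV recovery on a 2-Mb chromosome with 10 inversions (5–50 kb), 5
duplications and 5 deletions (≥ 1 kb) over 5 seeds; outlier delimitation
on a 650-kb BOC pair; the window statistic on a 1-Mb chromosome with a
200-kb implanted region at 10× reduced SNP rate over 20 seeds; ratio
recovery at mixtures 0.9/0.7/0.5 with 50 000 100-bp reads over 20 seeds on
~6-Mb genomes (outlier-region read depth low enough that positional
duplicate removal does not bias counts); a 12-strain designed-occupancy
panel; and the clade-versus-haplotype tree contrast on 8-strain panels over
10 seeds. Passing these shows the machinery recovers known structure under
the generator's assumptions; it does not establish robustness to assembly
error, repeats, diploidy or sequencing artifacts absent from the simulation.

Known limitations: no protein-space comparison (clustering is nucleotide
CDS); no split-read breakpoint refinement below block resolution; no
recombination model between strains; Wilson-CI coverage statements are
themselves stochastic (a nominally calibrated 95% interval misses ~1 seed
in 20 on average).
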