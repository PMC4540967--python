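# Methods

This note documents the models, rules and numerical choices behind
`mitosoup`, in the order the pipeline runs, together with what the
synthetic-data generator does and does not emulate.

## Alignment semantics

A single identity definition is used for every threshold in the package:
**matched columns / total alignment columns × 100**, with gap columns in the
denominator and `N` never counting as a match (not even against another
`N`). This is stricter than some BLAST variants, which exclude end gaps or
count N–N; one unambiguous definition keeps the many 98%/99% thresholds
comparable across stages.

Two engines implement it:

* an exact affine-gap dynamic program (Gotoh; match +1, mismatch −1, gap
  open −2, gap extend −1 by default, a gap of length *k* scoring
  open + (*k*−1)·extend), vectorised over anti-diagonals, with a fixed
  traceback precedence (diagonal, then gap-in-second-sequence, then
  gap-in-first) so results are bit-reproducible. In global mode the two
  sequences are put into a canonical order before alignment and the result
  mirrored back, making score *and* identity symmetric under argument swap
  even on tie cases.
* a seeded heuristic for problems over ~9 million matrix cells: shared
  21-mer diagonal voting locates the homologous region, an edlib
  edit-distance path is computed over it, and identity is recomputed from
  the path under the package's own definition. The test suite pins the
  heuristic to within ±0.5 identity points of the exact DP on sequences up
  to 5 kb; it is only used on near-identical comparisons (merging,
  containment screening) where edit-distance and affine-gap optima
  coincide in practice.

Internally generated similarity hits (the stand-in for external BLASTn
runs) use a k-mer index (k = 13), seeded window extension with edlib, and a
Karlin–Altschul-style surrogate E-value computed from blastn-like raw
scores (+2/−3, gap −5/−2; λ = 0.625, K = 0.41; E = m·n·2^(−bits)). These
E-values are comparable against the pipeline's cutoffs (10⁻⁵, 10⁻¹⁹) but
are not BLAST's numbers; externally produced 12-column tabular hits are
accepted unchanged everywhere hits are consumed. Minus-strand hits are
encoded as s_start > s_end, exactly as in BLAST tabular output. All
internal coordinates are 0-based half-open; all emitted and parsed tables
are 1-based inclusive.

## Read filtering

Quality trimming is a single maximal strip of 3′ (and optionally 5′) bases
strictly below the threshold — not windowed — which is the simplest reading
of "trim bases below Q". The mean-quality test is applied **after**
trimming; the original protocol is silent on the order, and post-trim means
make the two rules composable (a read with a bad tail can still pass).
The two stringency regimes are packaged as `QC_LOW` (min 150 bp, 3′ < Q20
trimmed, mean ≥ Q25, no Ns) and `QC_HIGH` (5′ and 3′ < Q30, mean ≥ Q30).
Pair retention under `both_pass` requires both mates to pass.

Mitochondrial-like pairs keep a pair if one mate (`either`, the default) or
both mates (`both`) hit the panel at E ≤ 10⁻⁵. The conservative
mitochondrial-fraction estimate requires both mates aligned over ≥ 100 bp;
its denominator is the adapter-removed pair count, which is the reading
consistent with the published table arithmetic.

## Contig reconciliation

Filtering keeps contigs with at least one panel hit of alignment length
≥ 1 kb — a deliberate trade: long non-mitochondrial contigs are removed at
the cost of mitochondrial contigs under 1 kb, which the 2-kb supermatrix
criterion would exclude anyway.

Circularization examines contigs ≥ 15 kb for a prefix/suffix overlap of
≥ 50 columns at ≥ 99% identity (windows up to 1 kb; an exact ungapped scan
first, an alignment fallback for indel-bearing termini). One copy of the
longest qualifying overlap is removed, the contig flagged circular and
rotated to the canonical origin — the first base of cox1 when annotated,
else the lexicographically minimal rotation (Booth's algorithm), so
circularization is rotation-invariant and deterministic.

Merging runs the four-step reconciliation: (1) circular contigs clustered
across assemblies at the 99% tier, rotation-invariantly (query against the
doubled representative); representatives chosen longest-first, then by
source preference, then id; (2) linear contigs aligning to a circular
representative at ≥ 99% over ≥ 80% of their own length are dropped (the
80% figure is this package's choice — identity alone would discard contigs
with short chance matches); (3, 4) remaining linear contigs are
single-linkage merged, highest identity first, at 99% then 98%, requiring
≥ 100 bp overlap and a consistent dovetail/containment layout. Candidate
pairs are screened by seed matches concentrated on one alignment diagonal
followed by a banded edit-distance bound; this matters because related
species share scattered exact k-mers *and* a consistent homologous
diagonal, so only an identity bound separates conspecific from
heterospecific pairs cheaply.

Within an overlap, substitutions take the preferred source's base (the
quality-controlled assembly by default, mirroring the original preference);
indel runs are arbitrated by translating a ±600 bp window around the event
from each variant and keeping the variant whose best frame (of six, table
5) has fewer internal stops — ties fall to the longer contig, then the
preferred source. The window is deliberately wide: the invertebrate code
has only two stop codons, so short frameshifted windows often show a
stop-free frame by chance. Whole-contig length (not overhang length) breaks
the "longer contig" rule; every member and every arbitration is recorded in
the provenance/report.

N50 is the largest length L such that contigs ≥ L sum to at least half the
total; size classes are half-open at 1/5/10/15 kb with circular tallies.

## Gene extraction and supermatrices

Inter-tRNA fragments are the exact interval complement of the (unioned)
tRNA features, including terminal segments, with the origin-spanning
fragment emitted wrapped on circular contigs. Where merged contigs lack
annotations, tRNA/PCG features are projected from the best-matching panel
genome by edlib placement of each feature's sequence — a deterministic
stand-in for covariance-model tRNA annotation, which is out of scope.

Binning translates each fragment in six frames and aligns the translations
locally (BLOSUM62, −11/−1) against the 13 reference proteins. A fragment
region is assigned to the best-scoring gene when the score reaches 0.4 ×
the self-score of the covered reference span and the covered fraction of
the reference gene is ≥ 0.5 (coverage is measured on the reference length;
the alternative fragment-length basis is noted as ambiguous in the source
protocol). Because insect gene order places several PCGs back to back
between two tRNAs (atp8–atp6–cox3, nad4–nad4l, nad6–cob), assignment is
**iterative**: the assigned region is masked and the remainder re-scanned,
so multi-gene fragments yield one record per gene. The 5-aa k-mer prescreen
that accelerates scanning is skipped for reference proteins under 120 aa —
a short diverged protein (atp8) can share no exact 5-mer with its homolog
yet align well.

The built-in multiple aligner is a centre-star alignment (pairwise
free-end-gap alignments to a centre sequence; the longest member by
default, a designated reference otherwise). The pipeline uses the
reference gene as the centre in nucleotide space, which keeps alignments
codon-anchored and leaves single-base indels visible as 1-column gaps for
curation; protein-space alignment plus `back_translate` (triplet gaps
exactly where residue gaps occur) is available and round-trips exactly.
External alignment files are accepted in place of the built-in aligner.

Curation trims terminal columns so the width is a multiple of three,
repairs apparent single-base frameshifts by masking the minimal codon
window around any gap run of non-triplet length (the sequence is never
edited — masking is conservative and every event is logged), then drops
members whose non-gap length is under 50% of the final width. Translation
uses table 5 throughout; incomplete terminal codons are ignored.

Supermatrices concatenate the curated amino-acid alignments in a fixed
canonical order (atp6, atp8, cob, cox1–cox3, nad1–nad6, nad4l — the order
is arbitrary for inference but must be deterministic), gap-filling absent
genes and emitting a presence mask and per-gene spans. Two criteria are
built in: ≥ 10 genes per contig, and nad4l present with contig ≥ 2 kb.

## Coverage

Per gene: contributing bases = Σ alignment lengths of qualifying read hits
(long genes, reference > 400 bp: ≥ 200 bp at ≥ 98%; short genes: ≥ 98%
over ≥ 50% of the reference gene length — the two rules coincide exactly
for a hypothetical 400-bp gene); aligned nucleotides = Σ non-gap characters
over the alignment members, so member count and lengths are both accounted
for; mean coverage = ratio, to 1 decimal. Each read contributes once,
through its best hit (best-hit-only also resolves whether one read may
feed two genes' tallies: it may not). Identity comparisons round half-up
to 2 decimals before testing ≥. A gene with zero aligned nucleotides is an
error, not a 0/0. The source tally scores each alignment member present in
an assembly's fragment set iff its best hit there is ≥ 98%.

## Linkage

Haplotype collapsing is exact string deduplication after uppercasing and
stripping terminal Ns (internal Ns keep sequences distinct); the
representative is the first-seen id. The barcode region is located by best
local alignment to reference barcodes (≥ 200 columns at ≥ 70%), oriented
forward. Linking takes the best bait per contig at ≥ 98% identity,
breaking equal-best ties lexicographically within one morphospecies and
flagging (and not linking) contigs whose equal-best baits disagree on the
morphospecies — the original handling of such ties is unrecorded, so
flag-and-skip is this package's own policy. Overlap summaries count
species-level entities under a supplied grouping (an external species
delimitation, or simulator truth), not raw haplotypes.

## Taxonomic assignment and tree comparison

Top-hit: per query, hits above E = 10⁻¹⁹ are discarded and the top
bitscore hit (ties: lower E, then lexicographic subject) supplies its
family. LCA: the deepest rank at which one taxon is contained in ≥ 50% (by
default) of the top-100 hits' lineages — an explicit emulation of a
minimum-coverage heuristic, with both knobs exposed. Tree route: on a
rooted tree, a query is assigned the lowest-rank taxon X such that the
query descends from the MRCA of X's reference tips and every reference tip
under that MRCA belongs to X. The descent condition means a singleton
family can never admit a query, which reproduces the observed conservative
behaviour with sparsely sampled families; assignments escalate to
superfamily or higher rather than risk a wrong family. Multifurcations are
used as given; no support-value filter is applied by default.

Rooting places the root on the edge separating a stated outgroup (an error
names the offending tips if the outgroup is not one side of any edge);
pruning to shared tips suppresses degree-2 nodes. The symmetric difference
counts non-trivial bipartitions present in exactly one tree, each split
canonicalised by the side not containing the overall smallest tip label so
rooted and unrooted encodings agree; the reported maximum is 2(n−3)
regardless of resolution (unresolved trees simply contribute fewer splits).
Evaluation counts each query at the lowest rank assigned, scores
correctness there, and reports family-level success as correct-family
assignments over evaluable queries, to 1 decimal.

## The simulator: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:

* **Genomes.** Circular, ~N(15 700, 800) bp, 13 PCGs as valid ORFs under
  table 5 (ATN start, no internal stop, TAA stop) and 22 ~70-bp tRNAs in a
  fixed insect-like order on both strands, an AT-rich (85%) control region
  at the end of the gene array, so full-length linear contigs terminate in
  it, as real assemblies do.
* **Community.** Species descend from one ancestral genome at 10%
  per-site divergence in the gene-bearing region (frames preserved; the
  control region is redrawn per species). This keeps proteins recognisably
  homologous across the community — the property that makes single-
  reference gene binning and panel-based read filtering work on real
  beetles — while holding pairwise interspecific identity near 80%,
  comfortably under the 95% ceiling the merge thresholds assume.
  Intraspecific haplotypes are point-mutated copies at 0.5% (identity
  ≥ 99%), never introducing in-frame stops. Abundances are
  log-normal(0, σ = 1), normalised.
* **Reads.** 250-bp paired ends, insert ~N(480, 60) truncated to
  [2·250−50, mean+4σ], positions uniform on the circle with wraparound,
  random fragment orientation. 99% of pairs come from a nuclear background
  (matching the ~1% mitochondrial yield of real libraries): half
  GC-matched random sequence, half mitogenome copies mutated to ~75%
  identity, which exercises the false-positive side of hit filtering.
  Substitution errors follow per-base qualities: Q = −10·log₁₀(p) with a
  10-point linear 3′ decay over the final 50 bases, so both trimming rules
  fire.
* **Assemblies.** Two labeled variants per community: per species, one
  variant carries either a circular-completable contig (full genome plus
  an 80-bp duplicated terminus; probability 0.5) or a full-length linear
  contig, the other two fragments overlapping 1.2–2 kb. SNPs are injected
  genome-wide at 5×10⁻⁴ and 1-bp indels inside PCGs at 10⁻⁴, so consensus
  arbitration is exercised. Truth tables (pair → origin/species/haplotype/
  coordinates; contig → species/kind/edits) accompany every output and
  suffice to score all downstream stages without re-simulation.

Randomness is one RNG stream per operation, seeded from (global seed,
CRC32 of the operation name), so identical seeds give byte-identical
outputs and changing one stage's parameters does not perturb another's
draws.

Not emulated: read indel errors and realistic error profiles; codon-usage
bias; lineage-specific gene rearrangements; any mechanism by which longer
inserts raise mitochondrial yield (the fraction is a parameter, not
emergent); chimera formation during assembly. Passing tests therefore show
the pipeline's logic is correct under its stated assumptions, not that the
thresholds are optimal for any particular real library.

## Problem sizes and determinism

The test suite runs the full stack at deliberately desk-scale sizes: the
end-to-end recovery scenario uses 30 species × 2 haplotypes, 100 000 read
pairs and two fractured assemblies (minutes on one CPU); oracle-equivalence
suites use exhaustive enumeration at 5–8 tips and ≤ 30 bp, and 1 000-fold
randomised cross-checks against independent implementations (dendropy's
bipartition counts, a plain-python affine DP, brute-force N50). The
published full-scale quantities that depend on the original ~16 Gb read
set (504 contigs, Table 2/3 metrics, Fig. 1 coverage values) are outside
what simulation can or should reproduce; the published-arithmetic checks
instead verify that the package's estimators return the printed
percentages and maxima exactly when given the printed counts.

Known limitations: the internal aligner applies no low-complexity masking,
so behaviour on AT-rich regions can differ from DUST-disabled BLAST runs
only in E-value scale, not identity; the LCA route is an approximation of
MEGAN's heuristic, not a reimplementation; linkage monotonicity under
threshold lowering can be broken by the ambiguity flag (a tie appearing at
a lower threshold unlinks a contig) — the flag is kept because silent
mis-linking is worse.
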