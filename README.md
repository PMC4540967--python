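# mitosoup

**Mitochondrial metagenomics of bulk arthropod samples** — from shotgun reads
of a pooled, unsorted specimen soup to a set of near-complete mitochondrial
genomes, a community phylogeny, and taxonomic identities for the species in
the pool.

## The problem

Tropical arthropod communities contain hundreds of species per sample, most
of them undescribed. Sorting, barcoding and identifying each specimen does
not scale. An alternative is to extract DNA from the whole pool, shotgun
sequence it, and reconstruct each species' mitochondrial genome (~16 kb,
13 protein-coding genes, 22 tRNAs, an AT-rich control region) directly from
the read mixture. Mitogenomes are abundant enough to assemble from low
coverage (roughly 1% of reads in a typical library are mitochondrial), and
informative enough to place each species in a phylogeny down to family
level.

`mitosoup` implements the bespoke computational stages of that workflow:

1. **readfilter** — quality-trim read pairs (e.g. minimum length 150 bp,
   3′ bases below Q20 trimmed, mean quality ≥ Q25, no Ns) and keep
   "mitochondrial-like" pairs with a hit to a reference mitogenome panel at
   *E* ≤ 10⁻⁵ from either or both mates; estimate the conservative
   mitochondrial fraction (both mates aligned ≥ 100 bp).
2. **contigs** — keep assembled contigs with a panel alignment ≥ 1 kb;
   circularize contigs over 15 kb with near-identical overlapping termini;
   reconcile the contig sets of two assemblers into one non-redundant set
   by tiered merging (99% then 98% identity), resolving substitution
   conflicts by source preference and 1-bp indel conflicts by
   open-reading-frame plausibility; report N50/size-class statistics.
3. **genes** — excise inter-tRNA regions, sort them into the 13
   protein-coding genes by six-frame protein alignment against a reference
   gene set (fragments covering ≥ 50% of the reference gene retained),
   curate codon alignments (complete-triplet trimming, < 50% aligned-length
   drop, frameshift masking), translate with the invertebrate mitochondrial
   code (table 5: AGA/AGG→Ser, ATA→Met, TGA→Trp), and concatenate
   supermatrices (the "10+" criterion: ≥ 10 genes per contig; the
   nad4l-centred criterion: nad4l present and contig ≥ 2 kb).
4. **coverage** — the hit-based per-gene coverage estimator: contributing
   bases (qualifying read hits: ≥ 200 bp at ≥ 98% identity for genes over
   400 bp; ≥ 50% of gene length at 98% for atp8/nad3/nad4l) divided by the
   total non-gap nucleotides in the gene alignment; plus per-gene tallies of
   which assembler contributed each unique sequence.
5. **linkage** — collapse PCR barcode haplotypes, locate the cox1-5′
   barcode region (~648 bp) on each contig, link contigs to morphospecies
   at a 98% identity threshold, and summarise the overlap between
   PCR-derived and contig-derived species entities.
6. **taxassign** — three assignment routes (similarity top hit at
   *E* ≤ 10⁻¹⁹; minimum-support LCA over the top 100 hits; tree placement
   requiring descent from the MRCA of a taxon's reference tips plus
   monophyly of those references), evaluation per rank, rooting, pruning to
   shared tips, and Robinson–Foulds comparison (symmetric difference over
   non-trivial splits; maximum 2(*n*−3) for *n* shared tips).
7. **simulate** — a first-class synthetic community generator: related
   circular mitogenomes descended from a common ancestor, intraspecific
   haplotypes (≥ 99% identity), log-normally skewed abundances, nuclear
   background reads, paired-end reads with an insert-size model, and two
   artificially fractured "assemblies" with injected SNP/indel
   discrepancies — with truth tables so every stage can be scored.

## Worked example

Run the whole pipeline on a simulated 5-species pool:

```python
from mitosoup.pipeline import run_pipeline

out = run_pipeline({
    "seed": 5,
    "stages": ["simulate", "readfilter", "contigs", "genes",
               "coverage", "linkage", "taxassign"],
    "simulate": {"n_species": 5, "n_pairs": 600, "nuclear_fraction": 0.5},
}, outdir="demo_out")
print((out / "run.log").read_text())
```

prints

```
mitosoup 0.1.0
seed 5
stages simulate readfilter contigs genes coverage linkage taxassign
simulate n_species=5 n_pairs=600
readfilter kept=466/600
contigs nonredundant=5
genes alignments=13 taxa10plus=5
coverage genes=13
linkage links=5 contig_only=0 pcr_only=0
taxassign records=10
```

Reading: of 600 simulated read pairs, 466 passed quality control and hit
the mitogenome panel (the excess over the ~50% truly mitochondrial pairs is
deliberate — diverged nuclear copies of mitochondrial sequence also hit, as
in real libraries). The two fractured assemblies were reconciled into
exactly one non-redundant contig per species, all 13 protein-coding genes
were recovered into curated alignments, all five contigs met the 10-gene
supermatrix criterion, every contig was linked to its true morphospecies
through its cox1-5′ barcode, and both the tree route and the top-hit route
assigned every linked contig its correct family
(`assignment_summary.tsv`: 100.0 for both methods).

The same stages are available as shell commands:

```bash
mitosoup simulate --n-species 10 --n-pairs 2000 --seed 1 --out sim/
mitosoup contigs sim/assembly_asmA.fasta sim/assembly_asmB.fasta \
    --panel sim/panel.fasta --out contigs_out/
mitosoup treedist a.nwk b.nwk --prune
```

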