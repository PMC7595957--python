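# grassreg

Comparative analysis of the putative regulatory regions of orthologous genes
in C3 and C4 grasses, built around the four Calvin–Benson–Bassham (CBB) cycle
gene sets *SBPase*, *FBPase*, *PRK* and *GAPDHB*.

Most CBB-cycle enzymes are expressed in both C3 and C4 plants, but in C4
leaves they are enriched in bundle-sheath (BS) over mesophyll (M) cells.
`grassreg` implements the computational side of asking *why*: which candidate
cis-regulatory elements are shared by C3 and C4 orthologs, and which are
specific to one photosynthetic type?

## What the pipeline computes

Given genomes (FASTA), annotations (GFF3), a clade/photosynthesis table, a
motif library (MEME minimal format) and cell-type expression evidence:

1. **Gene windows** — for each ortholog, the window from 2 kb upstream of the
   TSS (start codon if no 5'UTR is annotated) to 1 kb downstream of the 3'UTR
   (or stop codon), strand-normalized, partitioned into putative regulatory
   features: upstream/downstream intergenic, UTRs and introns (CDS excluded).
2. **CNS calling** — exact affine-gap global alignment (Gotoh DP) of each
   ortholog window against a C3 and a C4 reference; conserved non-coding
   sequences are non-coding stretches with **> 70% identity per 50 bp**
   of alignment, assigned a conservation scope (all species / one clade /
   partial) by motif rediscovery across species.
3. **Motif discovery** — one ungapped motif per CNS locus with a ZOOPS
   (zero-or-one occurrence per sequence) EM mixture over both strands,
   BIC-selected over a width grid.
4. **Motif scanning** — log₂-odds PWM scores at every regulatory position on
   both strands; *exact* null p-values by dynamic-programming convolution of
   the discretized column scores under a 0-order background;
   Benjamini–Hochberg control per (library × gene set × species) batch at
   **q < 0.05** (strict).
5. **Set analysis** — per (motif, gene set, species) presence; motifs shared
   by *every* scanned ortholog of a gene set; disjoint UpSet-style
   intersection categories (`common_CBB`, `common_SFG`, `common_PRK`, …);
   clade-specific calls by *absence* (C4-specific = absent from every C3
   ortholog, present in ≥ 1 C4 species); positional TFBS clusters.
6. **Trans-factor classification** — per reference factor, the orthologs'
   log₂FC(BS/M) evidence is reduced to *putative activator* (all BS-enriched),
   *putative repressor* (all M-enriched) or *broad regulator* (mixed), after
   inclusion rules (|log₂FC| ≥ 1 somewhere, evidence from ≥ 2 species).

A seeded synthetic-study generator (`grassreg.simulate`) emits a complete
miniature study — 8 species in two clades (including a C3 PACMAD control),
4 gene sets, planted CNS blocks, planted shared / clade-specific motif
instances, a PWM library and negative-binomial M/BS count tables — with
machine-readable ground truth, so the entire pipeline is testable offline.

## Worked example

```bash
grassreg run-all --outdir demo --seed 1
```

runs simulation → extraction → CNS → discovery → scan → set analysis →
classification and writes a manifest. Typical outputs (seed 1):

```text
$ cut -f1,2,3 demo/categories.tsv
label          gene_subset                  n_motifs
common_CBB     SBPase,FBPase,PRK,GAPDHB     1
common_GAPDHB  GAPDHB                       1

$ cut -f1,2,3 demo/clade_calls.tsv | grep m_
m_c4_SBP   SBPase   C4_specific
m_c4_FBP   FBPase   C4_specific
m_c3_PRK   PRK      C3_specific
```

The planted all-species motif lands in the category shared by all four gene
sets (`common_CBB`, the analogue of the single VRN1-bound site found in every
real gene set), the GAPDHB-only motif in `common_GAPDHB`, and the planted
C4-only/C3-only motifs are recovered as clade-specific calls.
`demo/tf_classification.tsv` labels the planted activator/repressor/broad
factors from the simulated count tables:

```text
tf_id     label               n_species  min_log2fc  max_log2fc
TF_act1   putative_activator  4          1.45        2.80
TF_rep1   putative_repressor  4         -2.76       -1.22
TF_broad1 broad_regulator     3         -2.26        2.11
TF_null1  not_classified      2         -0.71        0.01
```

Positive log₂FC means BS-enriched; the classifier reproduces each planted
class.

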