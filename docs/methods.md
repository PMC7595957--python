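# Methods

This note documents the models behind `grassreg`, the defaults that matter,
what the synthetic-study generator does and does not emulate, and the design
decisions taken where several readings were defensible.

## Gene windows and regulatory features

Each ortholog is analysed in a fixed gene-relative window: 2,000 bp upstream
of the transcription start site, through the gene body, to 1,000 bp
downstream of the 3' end. The anchor is the TSS when a 5'UTR is annotated and
the start codon otherwise; the downstream anchor is the end of the annotated
3'UTR, falling back to the stop codon, then to the last CDS base. Windows are
truncated (never padded) at contig edges, with the realized flank lengths
recorded. One representative transcript per gene is used — the longest mRNA —
a package convention for multi-isoform annotations.

Internally all coordinates are 0-based half-open and strand-normalized (the
window always reads 5'→3' of the gene); GFF3 I/O converts from/to 1-based
closed, BED output stays 0-based half-open. "Intergenic" is defined purely by
the fixed window; neighboring genes are not trimmed away.

Putative regulatory sequence is the non-coding part of the window: the two
intergenic flanks, UTRs, and introns (complement of exons inside the gene
body). CDS bases, and exonic bases that are neither CDS nor UTR, are excluded
from every downstream scan.

## CNS calling

Ortholog windows are aligned pairwise against a reference species (by
default one C3 and one C4 reference, reported separately) with an exact
affine-gap global aligner (Gotoh three-state DP, numba kernel). Defaults:
match +1, mismatch −1, gap open −4, gap extend −0.5; a gap of length L costs
`open + (L−1)·extend`. Ties are broken deterministically (diagonal, then gap
in query, then gap in reference). A guard refuses DP matrices above 25×10⁶
cells so a mistaken genome-scale call fails fast rather than thrashing.

Identity is computed per alignment column over a sliding 50-column window
(step 1); gap and ambiguous columns count as mismatches; the conserved
criterion is strictly greater than 0.70. Two projections of qualifying
windows onto the reference are implemented:

- `center` (default): the central column of each qualifying window is marked
  conserved — the conservation-curve semantics of VISTA-style plots, where a
  position's value is the identity of the window centred on it;
- `span`: all 50 columns of each qualifying window are marked.

The default is `center` because the span rule systematically extends calls
~25–30 bp into background on each side (a window needs only ~22 of 50
conserved columns to qualify) and turns any single qualifying background
window into a 50-bp false call; with the centred rule, boundary positions
qualify only while the majority of their surrounding window is conserved.
Marked columns are merged when touching (no gap bridging), intersected with
the non-coding features, and segments of ≥ 50 bp whose recomputed mean
identity still exceeds the threshold become CNS intervals.

Conservation scope: for each merged CNS locus, a motif is discovered from
the reference segment plus the aligned ortholog segments, every species'
regulatory regions are rescanned with it, and presence requires a q < 0.05
hit. A CNS present in every species is `all_species`; present in all members
of one clade and no member of the other is `clade_restricted:<clade>`;
anything else is `partial`.

## ZOOPS motif discovery

One ungapped motif per CNS set, under a zero-or-one-occurrence-per-sequence
mixture: with probability 1−γ a sequence is pure 0-order background; with
probability γ it carries exactly one motif occurrence, uniformly placed over
offsets and strands. EM alternates the exact posterior over {no site} ∪
{offset × strand} with re-estimation of the PWM (pseudocount 0.01 per cell)
and γ. The tracked objective is the penalized log-likelihood (data
log-likelihood plus the Dirichlet term implied by the pseudocount), which
MAP-EM can never decrease; the raw data log-likelihood is reported alongside.
The background is the 0-order frequency of the input with complementary
bases averaged, which makes the two-strand likelihood exactly
strand-invariant.

Seeding uses the most frequent w-mers (reverse complements collapsed to a
canonical form; ties broken by count then lexicographically), converted to
soft PWMs (0.5 on the matched base, 1/6 elsewhere). Model selection runs EM
over a width grid and several seeds per width and keeps the model maximizing
`loglik − ½(3w+1)·log(total sequence length)` — a BIC penalty in place of
MEME's E-value machinery, chosen for determinism and self-containment.
Multi-start matters: single-start EM falls into a badly wrong local optimum
in roughly 2% of planted-motif instances; keeping the best of the top-5
seeds removes these failures. Fits whose total information content falls
below 4 bits are flagged low-confidence; note that a PWM fitted to pure
background typically measures far more than 4 bits (overfitting sharpens
columns), so the flag is a floor, not a null detector.

## Scanning and FDR

PWMs are converted to log₂-odds matrices against the scan background with a
uniformly applied pseudocount regularization (`p' = p·(1−4c)+c`,
`c = pc/(1+4pc)`), then discretized on a uniform grid (granularity = score
range / 1000). The null distribution of the discretized score under the
0-order background is computed exactly by convolving the per-column score
distributions, so every scanned position receives an exact tail p-value on
the same grid it was scored on. N bases contribute zero log-odds but their
positions are still scanned; hits never cross a regulatory-region boundary.

Multiple testing: Benjamini–Hochberg step-up q-values,
`q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j` (clipped at 1), computed over all scored
positions of one batch — one motif library × one orthologous gene set × one
species — and filtered strictly at q < 0.05. No p-value pre-threshold is
applied by default. Overlapping hits of the same motif are all retained;
downstream presence logic only needs existence.

## Set analysis

Presence is boolean per (motif, gene set, species): at least one retained
hit. Orthologs that were never scanned are *missing*, excluded from every
universal quantifier (absence evidence requires a scanned sequence). A motif
is *shared* in a gene set when present in every non-missing species (quorum
1.0, relaxable). Shared sets are partitioned into disjoint UpSet-style
categories: each motif belongs to the category of the exact gene-set subset
sharing it; the full subset is labelled `common_CBB`, singletons
`common_<gene set>`, other subsets by gene-set initials in canonical order
(e.g. `common_SFG` for {SBPase, FBPase, GAPDHB}).

Clade-specific calls use absence-based logic: C4-specific = absent from
every (non-missing) C3 ortholog and present in at least one C4 species
(quorum configurable), and symmetrically. Requiring presence in *all* C4
species would be too strong given the independent origins of C4. Positional
clustering chains hits whose gaps are ≤ 50 bp (single linkage); the gap is a
package convention and the output is exploratory.

## Expression classification

Evidence is the log₂ fold-change of BS over M expression per ortholog
transcript (positive = BS-enriched), either read from precomputed
differential-expression tables (significance = adjusted p < 0.05, strict) or
derived from raw counts by median-of-ratios normalization (geometric-mean
reference over samples, transcripts with zeros excluded from size-factor
estimation) with `log2fc = log₂((mean BS + 0.5)/(mean M + 0.5))`. The full
negative-binomial GLM machinery of DESeq2/edgeR is deliberately not
reproduced: classification consumes only fold-changes and flags, and the
built-in normalizer exists so the synthetic path needs no external tool.

A reference factor is included when its evidence reaches |log₂FC| ≥ 1 in at
least one ortholog and spans ≥ 2 species. Included factors are classified by
the signs of all fold-changes: all positive → putative activator, all
negative → putative repressor, mixed → broad regulator. Zero fold-changes
are sign-neutral; a factor with only zero evidence stays unclassified.

The package ships a curated enrichment table for grass orthologs of
A. thaliana trans-acting factors (four C4 species: *P. virgatum*,
*S. viridis*, *P. hallii*, *S. italica*) together with its ortholog map;
`adj_p` encodes the curation convention 0.01 = reported significant /
0.5 = reported not significant in the source analyses.

## Synthetic study generator

The generator emulates the study design: 8 species — three C3 BOP species,
one C3 PACMAD control, four C4 PACMAD species (two species carry their genes
on the minus strand to exercise strand handling) — and four gene sets. Each
gene is a two-exon model (60 bp UTRs, 240+240 bp CDS, 300 bp intron)
embedded in a contig that spans exactly the 2 kb + body + 1 kb window.
Sequences descend from a per-gene ancestral sequence through clade then
species branches with per-class substitution rates (background 0.15/0.25,
UTR 0.08/0.12, CDS 0.02/0.03), giving within-clade background identity near
0.58 and cross-clade near 0.45 — far enough below the 0.70 CNS threshold to
keep false conservation rare while coding sequence stays visibly conserved.
Short indels (rate 0.01/site, geometric lengths) scramble background blocks;
block lengths are re-stabilized (trim/pad at block ends) so window
coordinates are identical across species and the truth table needs no
per-species lift-over. Planted CNS blocks (150/120/113/100 bp at pairwise
identity 0.90–0.92, all-species or PACMAD-only, no indels inside) mutate
each carrier independently at the rate solving
`(1−r)² + r²/3 = identity`.

Planted motif instances are sampled from their PWMs (not consensus), placed
at orthologous offsets, three instances per carrier window — TFBS do occur
at multiple coordinates in one gene — with sharing patterns all-species,
C4-only or C3-only. Planted PWMs are 14 wide at ~1.95 bits/column; with BH
computed over the ~2.5×10⁵ scored positions of a batch, only near-consensus
instances reach q < 0.05, so detection power comes from instance multiplicity
rather than from a generous threshold. The filler library (40 motifs total,
widths 8–15, 1.0–1.6 bits/column) supplies realistic negatives.

Expression: negative-binomial counts (dispersion 0.1, lognormal base means
around 300) for the four C4 species, 3 M + 3 BS replicates. Activators put
every ortholog's BS mean at 4× the M mean, repressors the inverse, broad
factors alternate direction between orthologs within a species, null factors
and 50 filler transcripts are flat.

What the simulation does **not** emulate: realistic grass phylogeny branch
lengths, rate heterogeneity along sequences, codon structure, repeats,
annotation errors, multi-isoform genes, read-level noise, or
between-experiment batch effects in expression. Passing tests therefore
demonstrate correctness of the algorithms and calibrated behaviour under a
clean generative model, not performance on real Phytozome genomes.

## Numerical and degenerate-input choices

- Alignment ties: diagonal > up > left, applied in fill and traceback; the
  final state prefers substitution over gap states.
- Identity windows compare alignment columns (not reference bases); the
  threshold comparison is strict (> 0.70), and a CNS must contain at least
  one full 50-bp qualifying window.
- p-values are exact on the discretization grid; scores are reported on the
  same grid, so scanner and null never disagree about a bin.
- BH is computed with the literal step-up formula to be bit-reproducible
  against an independent implementation.
- Empty inputs fail fast with explicit messages (empty sequences, empty
  presence-flag sets, single-sequence discovery, all-zero count samples,
  missing contigs or gene ids, malformed GFF3 lines with line numbers).
- Problem sizes in the test and acceptance runs (6-kb alignment pairs,
  20-seed recovery batches, 5–10 end-to-end seeds) are the package's chosen
  defaults for a desk-scale study.

## Known limitations

- The aligner is exact but quadratic; genome-scale scanning and alignment
  are out of scope (the cell guard enforces this).
- One motif per CNS set; no OOPS/ANR site models, no gapped motifs, no
  MEME E-values.
- Plain BH, not π₀-estimated q-values; higher-order backgrounds are not
  modelled.
- Ortholog maps are inputs; the package does not infer orthology.
- The intersection-category labels assume the four-gene-set study layout;
  other designs get initial-based labels automatically but no curated
  aliases.
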