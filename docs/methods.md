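# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nucmorph`. It is the place where genuinely open design
decisions are recorded as the package's own choices.

## The gene model and the spliced-ORF dynamic programme

A nucleomorph protein-coding gene is modelled as a chain of exons on one
strand, starting with ATG, ending at the first in-parse stop codon, with
no internal stop in the spliced reading, and with every exon–exon gap an
**ultrasmall intron**: 18–23 nt, 5′-GT…AG-3′. Intron candidates are
enumerated exhaustively (`enumerate_intron_candidates`); gene calling
then finds, for every start codon, the parse of **maximal spliced
length** over all chains of candidates, by dynamic programming over
states (genomic position, partial codon). Between splice-donor sites
the parse is a deterministic codon read, resolved in O(1) with
precomputed next-stop tables, so the memo table scales with the number
of donor sites rather than with sequence length (whole chromosomes run
in well under a second).

Ties are broken lexicographically: longest spliced length, then fewest
introns, then reading through rather than splicing, then the shortest
intron. The traceback is therefore fully deterministic.

**Donor consensus.** With the bare GT…AG signal, an AT-rich genome
(~28% GC) contains roughly one candidate donor per ~70 bp, and the
maximal-length criterion then routinely splices *past* the genuine stop
codon of a gene — an alternative parse that gains a dozen random codons
beats the true one for a large fraction of genes. No curator would
accept such calls, and real ultrasmall introns carry an extended,
U6-pairing 5′ consensus beyond the minimal GT. `call_genes` therefore
applies a 5′ donor consensus, default `GTAAG`, when selecting splice
candidates (`CallerParams.donor_consensus`; set to `"GT"` for the
unconstrained search). This is the single most consequential design
choice in the caller.

Other caller parameters: `min_protein_aa` (default 50; kept models must
be *strictly longer*), `intron_min`/`intron_max` (18/23 nt),
`max_introns_per_gene` (12 — nucleomorph genes average ~3 introns, so
this cap is generous), `require_atg` (default true; a stop-to-stop mode
keeps the longest model per terminal stop instead). Overlapping models
are resolved greedily by descending spliced length (ties: leftmost,
then '+' strand), with coordinate overlap counted across strands —
appropriate for a genome this compact, where real genes essentially
never overlap.

## Repeat discovery

*Telomeres.* The smallest period p ≤ 10 whose tandem occupies a
chromosome terminus with ≥ 3 copies; periods < 4 nt are dismissed as
homopolymer/dinucleotide runs. Motifs are reported on the G-rich strand
in the lexicographically smallest rotation, because the biological
`[TCTAGGG]` spelling is rotation-ambiguous.

*Subtelomeric unit.* The longest string occurring exactly (allowing
reverse complement) within `search_depth` (50 kb) of **every**
chromosome end, found by binary search over the length with rolling-hash
substring sets and direct string verification. A unit shorter than
100 bp reports length 0. The all-ends requirement is deliberate: the
defining property of the nucleomorph subtelomeric repeat is its presence
at all six ends.

*Exact duplications.* "Exactly identical" is taken literally — there is
no near-identity mode. Maximal exact repeated pairs ≥ `min_len`
(default 1,000 bp; the observed internal duplications average ~2.9 kb,
but no published threshold exists, so it is exposed in config) are found
by rolling-hash seeding at word size `min_len`, per-diagonal
deduplication, greedy extension to maximality, and re-verification by
direct substring comparison. Tests check the output against an
independent quadratic per-diagonal oracle.

## Homology, families, synteny

Protein similarity is Smith–Waterman local alignment under BLOSUM62
with BLAST-convention affine gaps (open 11, extend 1: a gap of length L
costs 11 + L), via Biopython's PairwiseAligner; E-values use the
Karlin–Altschul form E = K·m·n·e^(−λS) with the standard gapped-BLOSUM62
constants K = 0.041, λ = 0.267. Families are single-linkage connected
components over directional hits with e < 0.001; genes without hits are
singleton families. The internal aligner is intended for desk-scale
sets; a BLAST-tabular import path (`io.load_hit_table`) is the fidelity
route for full genome comparisons.

Synteny blocks are maximal collinear chains of family-matched gene
pairs: strictly increasing in genome A, monotonic (ascending = `same`,
descending = `inverted`) in genome B, with at most `max_gap` (3)
unmatched intervening genes on either side, at least `min_genes` (4)
pairs, each gene in at most one block per genome pair. Tandem
same-family neighbours are collapsed to one anchor first, so duplicated
gene tracts cannot inflate block sizes, and subtelomeric spans can be
masked out. Whole-block inversion is accepted as "same order" because
these genomes contain documented inversions (e.g. of the rDNA operon).

Disjoint-block selection is **exact** (branch-and-bound over all
enumerated chains) when a chromosome pair has ≤ 12 anchors, and greedy
longest-first at scale. Greedy alone is not optimal on small
permutations — a single long chain can steal genes from two disjoint
shorter chains — which is why the exact path exists; tests verify
equality with an exhaustive oracle on gene-order permutations up to
n = 6 (all of them) and on seeded samples for n = 7, 8.

One behaviour worth knowing: when a segment of k genes is inverted, the
flanking collinear block can capture one interior anchor of the segment
under gap tolerance, so the inversion typically surfaces as an inverted
block of k−1…k genes (the same happens with MCScanX-style chaining).

## Intron position conservation

Family members are aligned with a deterministic center-star progressive
MSA (center = highest summed pairwise score, ties by id; merge under
"once a gap, always a gap"). An intron is located by the alignment
column of the codon *containing* the splice (phase 1/2) or *preceding*
it (phase 0), plus the phase; two introns occupy the same site iff both
coordinates agree. Conservation percentages are computed **per site**
(distinct (family, column, phase) triples): `pct_identical_all` counts
sites carried by every compared genome, `pct_shared_ge2` sites carried
by at least two; the per-occurrence count is reported alongside as
`n_introns_compared`. Oversized introns (> 23 nt) are scanned for
internal AG dinucleotides that would terminate an ultrasmall-length 5′
part — the signature of two fused ancestral introns.

## Genome statistics

GC% excludes N from the denominator. Gene density counts all annotated
features over genome size in kb. Intergenic lengths are gaps between
consecutive (merged) feature spans per chromosome, terminal flanks
excluded, overlaps contributing nothing; repeat copies (subtelomeric
genes) can be collapsed to one representative via `collapse_ids`.
Report roundings follow genome-table conventions: GC 1 decimal, density
2 decimals, introns/gene 1 decimal, with introns-per-gene using the
protein-coding count *including* duplicated copies as denominator.
ANOVA is the classical between/within mean-square F with (k−1, N−k)
degrees of freedom, and the two-sample t is pooled-variance by default
(Welch optional); both return (0, 1) on degenerate zero-variance input
instead of NaN, and ANOVA on two groups equals the squared pooled t to
machine precision.

## The synthetic-data generator

`generate_ancestor` emulates the architecture these analyses target:
3 chromosomes × 120 kb at 28% GC; `[TCTAGGG]` telomeres with 15–30
copies per end (copy number varies per end, as in real chromosomes); a
single subtelomeric unit (default 4 kb: SSU–5.8S–LSU rRNA features plus
a spliced dnaK gene) placed forward at left ends and reverse-complement
at right ends, byte-identical at all six ends; AT-rich intergenic
spacers of mean 110 bp (shifted-exponential, minimum 30 bp); and
protein-coding genes of mean 347 aa (normal, sd 120, minimum 60) with
Poisson(3) ultrasmall introns, 40% labelled ORFans. Chromosomes are
filled gene by gene until the target length is reached, so realized
lengths land within one gene of 120 kb.

**Identifiability.** Recovery scoring is only meaningful if the planted
annotation is the unique maximal spliced parse of the sequence, so the
generator guarantees it:

- upstream spacers are resampled until no in-frame, stop-free ATG
  precedes a planted start (otherwise the caller would, correctly,
  extend the gene 5′);
- intron sites keep a 90 nt margin from both CDS termini — an intron
  immediately beside the stop codon cannot be distinguished from
  read-through on sequence alone;
- planted introns carry the `GTAAG` donor consensus, and their
  interiors are rejection-sampled so that (a) reading through the
  unspliced intron hits an in-frame stop *inside* the intron (an 18 or
  21 nt intron read in frame would otherwise make the unspliced parse
  strictly longer than the spliced one) and (b) no secondary in-frame
  AG acceptor sits 3 nt upstream of the true acceptor.

These are properties of what the ground truth *is*; the caller is never
consulted during generation. Residual ambiguities (a spurious
`GTAAG…AG` candidate near a gene's 3′ end that genuinely lengthens the
parse) affect ~1–3% of genes, which is why observed recall sits at
97–99% rather than exactly 100%.

What the generator does **not** emulate: codon-usage structure beyond
base composition, expression-correlated intergenic structure, realistic
rRNA sequence, population-genetic substitution processes, or
near-identical (as opposed to exactly identical) repeats. Passing the
recovery tests therefore demonstrates algorithmic correctness on
genomes with the right architecture and composition, not performance on
real curated annotation.

`evolve_species` applies an ordered event list — substitution
(intergenic/intron-interior point changes plus synonymous and optional
amino-acid-changing codon swaps; telomeres, subtelomeric units and
splice signals protected; codon swaps that would mint a GT avoided),
gene loss (sequence overwritten in place), exact segmental duplication
(a run of genes with spacer flanks copied to a random intergenic site,
either orientation), inversion, and intron gain/loss — with every event
logged. Later events are kept off previously planted duplications so
recorded copies stay exactly identical, and duplication truth intervals
are extended to match-maximality at the end so they equal what an
exact-repeat finder reports.

## Problem sizes used in tests

The test suite and the acceptance script run the full default generator
(3 × 120 kb) for recovery metrics; oracle-equivalence checks use
deliberately small instances where the oracle is exact and cheap:
quadratic repeat oracles on ~4–6 kb toys, exhaustive synteny oracles on
all permutations of up to 6 genes plus seeded samples at 7–8, and a
cubic 3-way alignment oracle on short peptides. These sizes are chosen
so the independent oracles stay brute-force simple.

## Known limitations

- The caller's maximal-length criterion with a bare `GT` donor is
  intentionally available but over-splices in AT-rich sequence; the
  `GTAAG` default is the supported mode.
- The internal all-vs-all aligner is quadratic in the number of
  proteins and meant for desk-scale sets; use BLAST tabular import for
  hundreds of proteins per genome.
- Conservation percentages on real data depend on the alignment method
  and on which homolog families are selected; the center-star MSA is a
  deterministic, desk-scale choice, not a claim of alignment
  optimality (tests bound it at ≥ 0.9× an exhaustive 3-way optimum).
- Exact-repeat discovery deliberately has no near-identity mode; a
  diverged duplication will not be found.
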