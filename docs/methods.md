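# Methods

## Scope and model

`posdist` quantifies where motif occurrences fall in promoters relative
to the TSS.  The promoter is the window [−2000, +200) bp around the TSS
in transcription orientation; minus-strand genes are reverse-complemented
on extraction so downstream code never sees genomic strand.  All internal
coordinates are 0-based half-open (BED native; GFF3 converted on read,
TSS = start−1 on `+`, end−1 on `−`).  Windows clipped at a chromosome
edge are kept and flagged truncated.

## Motif scanning and exact p-values

A motif is a width-w position probability matrix over ACGT.  Scoring uses
integer-scaled log-odds against a 0-order background (uniform by default,
configurable): `round(1000 · log₂((p+λb)/((1+λ)b)))` with fractional
pseudocount λ = 0.1.  The integer scale (1000 units per log₂) bounds the
rounding error of any window score by w/2000 log₂ — negligible against
the score differences that matter — and makes the null score distribution
live on a small integer lattice, so the survival function of a random
background word's total score is computed *exactly* by convolving the w
per-position score distributions (dynamic programming, no sampling, no
asymptotics).  A window is a hit when P(S_bg ≥ S) is strictly below
α = 10⁻⁴.  Both strands are scanned; the opposite strand is scored by
scanning the forward string with the reverse-complemented matrix so both
strands share the start-coordinate convention.  Ambiguous bases (N) score
0, i.e. behave as background; an all-N window can therefore never beat α
for an informative motif.  The p-value table is validated in the tests
against exhaustive enumeration of all 4^w words for w ≤ 6.

Overlapping hits of the same motif are all kept at this stage;
de-duplication is a statistics-level concern (below).

## Conservation test

One-to-one orthologs per reference species: candidates at percent
identity ≤ 50 are discarded, the highest-identity survivor is chosen
(ties: lexicographically smaller id, for determinism), and a gene is
retained only when all three reference species have a chosen ortholog.
Percent identity is taken from the input table as given.

Each retained gene's promoter is aligned pairwise (query vs each
reference promoter) with a global affine-gap aligner: match +5,
mismatch −4, gap open −10, gap extend −0.5.  Alignment is delegated to
Biopython's `PairwiseAligner`; its traceback is deterministic and the
first optimal alignment is used.  Tests verify optimality against an
independent Gotoh dynamic program on 50-bp instances.

A query hit is conserved in a species when that species' promoter has a
hit of the same motif, on the same strand, whose start maps within 100
alignment columns of the query hit's start column (start-to-start, in
alignment space).  A hit passes overall when conserved in all three
species.  The signed column offset of the nearest qualifying occurrence
is recorded per species; the shift histogram is reported in bins
{0, 1–10, >10} as fractions.  A motif passes the conservation test when
at least one of its occurrences passes.

Note a structural fact the synthetic experiments make visible: a site
preserved *verbatim* at its homologous position always has shift 0, even
when the ortholog promoter carries indels, because an optimal aligner
gap-corrects the displacement.  Nonzero shifts require the ortholog
occurrence to be an independent occurrence displaced from the homologous
position (see the generator's `conserved_site_shift_sd` below).

For multi-isoform annotations the 5′-most TSS of the representative
transcript should be used when building the gene models; the synthetic
data has one TSS per gene and this convention is therefore untested here.

## Expression filter

A gene is expressed when its raw RPKM exceeds 1 in at least two samples
(strict inequalities throughout).  Upper-quartile normalization divides
each sample by the 75th percentile (linear interpolation) of its
expressed genes' values and multiplies by the across-sample mean of
those percentiles, preserving overall magnitude.  Co-expression calls
use the Pearson correlation of normalized profiles over *all* samples
(not only jointly-expressed ones — a declared choice), pass at PCC > 0.8,
and require both genes expressed; zero-variance profiles yield NaN and
never pass.  PCC is invariant to the normalization's global constant,
which the tests assert.

## Positional statistics

Positions are site midpoints by default (start + ⌊w/2⌋; anchor
configurable to "start").  Histograms use 50-bp bins over [−2000, +200]
— fine enough to resolve a peak at −50 bp without overfitting; the
density is count/(n·bin width) so it integrates to exactly 1.  The peak
is the midpoint of the maximal bin, ties broken toward the upstream end
for determinism.  Kurtosis is the population-moment excess kurtosis
g₂ = m₄/m₂² − 3 with no small-sample bias correction.  Cumulative
probabilities accumulate from the upstream end and interpolate linearly
within bins.

Family classification: kurtosis < 0 → flat; otherwise by peak position
(< −100 bp upstream-sharp; [−100, 0] TSS-proximal-sharp; > 0
downstream-sharp; kurtosis exactly 0 counts as sharp).  Families need a
minimum number of sites to be classified (default 20 for motif sites;
ChIP-peak families require strictly more than 1000 peaks).

De-duplication implements the "one sequence, one site" rule: hits of
same-family motifs on the same strand whose intervals strictly overlap
(transitively chained) collapse to one site, keeping the smallest
p-value (ties: leftmost, then motif id); different families never
collapse.  The operation is idempotent and never increases counts.
Per-gene averages (sites/gene, families/gene) are over genes with at
least one site; the genes-per-motif average is over motifs with at least
one target.

## Peaks

Strictly overlapping peaks are merged per chromosome (touching intervals
stay separate — a literal reading of "overlap"); merging is idempotent.
Peak position is the midpoint (even lengths round down) and the signed
distance to the nearest TSS (any strand, genome-wide on the peak's
chromosome; ties to the smaller gene id) is negative when the midpoint
lies upstream in the gene's transcription direction.  Distances outside
the reporting window are excluded from the density and counted
separately.  Both are validated against brute-force oracles on random
instances.

## Synthetic data generator

The generator emulates the study design on a toy scale with full ground
truth.  Defaults (the demo conditions): 200 genes, 10 motifs of width 8,
sites planted from a Gaussian positional law centred at −50 bp with
sd 200 bp (the qualitative shape real promoter studies report), plant
rate 0.3 per (gene, motif), three reference species with conservation
rate 0.9, ortholog identity uniform on (60, 95) with a 10% orphan rate
and occasional low-identity decoy candidates, background substitution
rate 0.1 in ortholog promoters, 21 expression samples with co-expression
rate 0.8, peaks of mean length 300 bp (sd 30) jittered around conserved
sites with sd 50 bp plus 20 random decoy peaks.

Construction details that matter for interpretation:

- Background sequence is i.i.d. uniform ACGT, which makes the scanner's
  exact p-value calibration exact for this data.  Genes sit in disjoint
  3,000-bp slots with alternating strands, so promoters never overlap
  and per-gene ground truth is unambiguous.
- Planted instances are sampled from the motif's probability rows — so
  scanner score variability is exercised — but rejection-sampled until
  their scan p-value is below α.  A planted site is by contract an
  occurrence the scanner can see; this is what makes "conservation rate
  1 ⇒ 100% recall" a meaningful pipeline property rather than a
  statement about scanner sensitivity (which the background-rate and
  oracle tests measure separately).
- Ortholog promoters are substitution-mutated copies of the query
  promoter; each planted site is independently preserved verbatim
  (probability = conservation rate) or overwritten with random bases.
  Because the *background* is homologous too, chance occurrences in the
  query promoter are often conserved as well — as in real phylogenetic
  footprinting — so conservation-rate-0 runs still pass some background
  hits while passing zero planted sites.
- `indel_rate` optionally adds small (≤ 3 bp) indels outside preserved
  sites (the TSS base is protected so the anchor survives); this
  exercises alignment robustness.  `conserved_site_shift_sd` optionally
  re-plants a conserved site a few bp from its homologous position as a
  freshly sampled instance, which is the mechanism that produces nonzero
  alignment-column shifts (see the conservation section).
- Expression: independent log-normal profiles (every non-decoy gene has
  RPKM > 1 in ≥ 2 samples); each co-expressed target is its TF's profile
  rescaled plus noise shrunk until the realized PCC exceeds 0.9; at most
  one co-expression driver per target gene (a profile cannot correlate
  > 0.8 with several independent TFs at once).  Unexpressed decoy rows
  fail the expressed filter by construction.

What the generator does *not* emulate: realistic nucleotide composition
(no GC skew, no CpG-like structure), gene structure (no UTR/intron
annotation), read-level noise, genuine evolutionary divergence (indels
and substitutions are i.i.d.), or motif co-occurrence structure.
Passing tests on this data therefore demonstrate correctness of the
pipeline's logic and calibration under its stated model, not performance
on real genomes.

## Numerical and statistical choices

- Exact p-values on an integer lattice; survival function clipped to
  [0, 1] against floating-point drift; densities asserted to integrate
  to 1 within 1e-9.
- Strict inequalities wherever a threshold is quoted (> 1, > 0.8,
  p < 10⁻⁴, identity > 50, > 1000 ChIP sites).
- Deterministic tie-breaks everywhere (lexicographic ids, leftmost
  positions, upstream peaks), so every run with a given seed is
  byte-identical — asserted end to end.
- The histogram-argmax peak estimator is noisy when the underlying
  density is flat near its mode: at n = 2000 and 50-bp bins a truncated
  normal with sd 400 bp yields a modal-bin tie spanning several bins.
  Recovery experiments therefore assert that the recovered peak bin's
  expected mass is within 3 Monte-Carlo standard errors of the maximal
  bin's expected mass (statistical tie with the true mode), and compare
  window fractions to truncated-normal closed forms within 3 MC standard
  errors.  Experiment sizes (2,000 genes for recovery, 10,000 promoters
  for the background-rate check, 10,000 null pairs for co-expression)
  were chosen so these standard errors are small relative to the effects
  being checked.
- The mean planted position under the default law is the *truncated*
  normal mean (≈ −93 bp for sd 200), not −50: the window truncates the
  law at +192 for width-8 motifs.  Tests compare against the truncated
  closed form.

## Known limitations

- Pairwise (not joint four-species) promoter alignment; the conservation
  decision is per species pair, as is standard for footprinting at this
  scale.
- No q-value/FDR layer on scan hits; the α threshold is the only gate.
- Upper-quartile normalization assumes every sample has a nonzero
  expressed 75th percentile; degenerate samples are an error, not a
  fallback.
- The CLI's stagewise commands re-derive promoters and scores from the
  data directory rather than caching them; convenient for small data,
  wasteful for genome-scale inputs.
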