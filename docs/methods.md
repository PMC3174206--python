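# Methods

This note records the models, conventions, numerical choices and known
limitations of `atskew`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Replichore geometry and site classification

A circular chromosome of length L with origin `ori` and terminus `ter` is
split into replichore 1, the arc [ori, ter) in increasing published-strand
coordinates, and replichore 2, the remainder. The published strand is the
leading strand in replichore 1 and the lagging strand in replichore 2. A
gene is *leading-encoded* when its sense strand is the leading strand of
its replichore; genes spanning a boundary are assigned by the majority of
their bases, with a logged warning. When `ter` is not supplied it defaults
to the antipode of `ori`; a cumulative-skew extremum detector is provided
as a diagnostic but never applied silently, because the antipode assumption
is explicit and reproducible while skew extrema can be noisy.

Coordinates are 0-based half-open internally; GFF3 is converted from
1-based inclusive on load. Classification assigns every position exactly
one of {codon1, codon2, codon3, intergenic} or an exclusion reason:

- `overlap` — positions inside two or more CDS; excluded rather than
  double-counted because the reading frame is ambiguous there.
- `non_core`, `pseudogene`, `ambiguous_base` (N), `rna_gene` (RNA-gene
  interiors, which are genic but not codon-classifiable), `bad_frame`
  (CDS length not divisible by three: excluded with a warning, not fatal).
- `length_cap` — intergenic regions whose raw length exceeds 500 bp,
  excluded entirely to limit contamination by unannotated genes.
- `boundary_trim` — the 60 bp nearest each gene boundary in surviving
  regions, where translation-initiation/termination signals distort skew.

Fourfold-degenerate flags are computed from the two-base codon prefix under
the standard genetic code (identical to translation table 11 on sense
codons). All internal codons of a CDS are classified; the skew table drops
each gene's initiator and stop codon by default (configurable) so "coding
positions" means amino-acid-encoding codons 2..L−1. We tally all internal
codons including those overlapping annotated starts of nested genes, since
overlap exclusion already removes genuinely ambiguous positions.

Reading conventions for skew: coding sites are read in the gene's sense
direction; intra-operonic spacers in the operon's transcription sense;
ex-operonic spacers on the leading strand of their replichore, so the
ex-operonic lagging row of the class table is the exact complement mirror
of the leading row.

## Orientation randomization test

The leading-vs-lagging difference in class skew is tested by reassigning
each unit's (gene's or region's) orientation label independently with
probability ½ and recomputing the statistic; P = (r+1)/(n+1) where r
counts null draws at least as extreme in magnitude. For the ex-operonic
class, whose two rows are mirrors, the null instead flips each region's
reading strand with probability ½ and uses the mirrored difference
2·skew(pool). Both modes are seedable and bit-reproducible.

## Mutational equilibrium from singleton SNPs

Singletons (variants in exactly one isolate) stand proxy for very recent
mutations largely unfiltered by selection; the reference base is taken as
ancestral (the majority-allele rule, unambiguous for singletons). Counts
c_ij over the 12 ordered categories are expressed on the leading strand
(SNPs at lagging-published sites are complemented) and divided by the site
composition N_i of the analyzed class to give per-site rates r_ij. The
stationary composition solves, for every base i,

    f_i · Σ_j r_ij = Σ_j f_j · r_ji,    Σ f = 1,  f ≥ 0,

computed as the null space of the 4×4 generator Q (off-diagonal r_ij,
diagonal −Σ_j r_ij) via singular decomposition — robust to zero entries
such as an observed C→G count of 0. Conventions for degenerate inputs:

- A base never touched by any observed mutation (zero inflow and outflow)
  is treated as absent and assigned stationary frequency 0, rather than
  letting it form a trivial closed class.
- A base with inflow but zero outflow is absorbing; the solver returns
  mass 1 on it with an explicit warning rather than failing.
- Genuinely reducible matrices (two or more closed communicating classes
  among active bases) raise an error describing the classes.
- A batched solver (vectorized SVD over stacks of matrices) powers the
  resampling procedures; rows it flags as degenerate fall back to the
  scalar path or are redrawn, with the redraw count logged.

Stationarity of the returned f is verified in tests to a 1e-10 residual,
and the solver is cross-checked against an independent power-iteration
oracle (the long-run limit of I + εQ) on random matrices.

Inference:

- **Bootstrap** — the resampling unit is the SNP event: each of B=1000
  replicates redraws the observed total from the multinomial over the 12
  categories with N_i held fixed (sites outnumber SNPs by ~three orders of
  magnitude, so composition uncertainty is negligible), then recomputes
  rates → stationary solve → skew. The interval is the percentile interval
  (the source analyses report plain 95% bootstrap intervals; BCa would
  pretend to more precision than 140 events support).
- **Leave-k-out** — k SNP events are removed uniformly without replacement
  (multivariate hypergeometric over categories) per simulation; the default
  k=3 matches the expected number of false-positive calls, computed as
  (target fraction of genome) × (error rate per genome) × (genomes).
- **Age-class randomization** — young (singleton) and older (multiplicity
  2–4) spectra are compared by |Δ equilibrium skew|; the null pools both
  groups and redraws groups of the original sizes with replacement
  (equivalently, two independent multinomials from the pooled spectrum),
  P = (r+1)/(n+1).
- **Composition inversion** — published count and rate tables are
  reconciled by N_i = median_j(c_ij / r_ij) with a 1% cross-category
  agreement check, which lets the whole analysis run from printed tables
  alone.

## Codon randomization null

The null codon distribution is P(xyz) ∝ p_x p_y p_z over all codons except
TAA, TAG, TGA, with p the strand-specific ex-operonic intergenic base
frequencies — a model of coding content shaped only by baseline
composition and the hard constraint that stops cannot occur in frame.
Start codons are handled on the observed side (initiator codons are
excluded from observed tallies) rather than by removing ATG from the draw
space: the draw space keeps ATG because simulated sequences stand for
amino-acid-encoding codons, of which internal Met is a legitimate member;
an `exclude` parameter exposes the alternative. Simulated sequences match
the observed amino-acid-encoding codon count; first- and second-position
sense skews and full codon usage are recorded per simulation, with the
analytic positional marginals available as an exact oracle for the
simulation means.

Amino-acid usage is compared to the null per block — the 23 blocks
partition the 61 sense codons, with six-codon amino acids (Leu, Ser, Arg)
split into their 4-block and 2-block because base frequencies act
differently on the two — via Z = (observed − null mean)/null SD, which
normalizes for codon-space size. Z is correlated with per-amino-acid cost
(blocks share their amino acid's cost) by Spearman rank correlation;
one-sided P uses exact permutation enumeration below 10 points and the
t approximation otherwise. Correlation is computed at block level by
default (`cost_correlation` consumes the block table directly); collapsing
six-codon splits is a caller-side aggregation. Bundled cost tables are the
Akashi–Gojobori biosynthetic costs (~P bonds) and molecular weight; other
published schemas load from user TSVs with the same two-column format.

The positional-GC cost ratio compares the observed mean amino-acid cost
per codon with the expectation under a skew-free null (p_G = p_C = GC_k/2
per codon position k, stops excluded). The expectation is computed
analytically — it is the exact mean of the simulated null — so the ratio
is deterministic.

The intergenic outlier screen holds each region's A+T count fixed and draws
its A count from the hypergeometric over the pooled ex-operonic A/T
content; this is the shuffle-and-repartition-at-fixed-AT-content null
reduced to the AT-skew statistic, since skew depends only on the A/T split
at fixed A+T. Regions outside the central 95% band are flagged and the
pooled skew is reported with and without them.

## Strand-bias contrasts

Species summaries pair a strand-bias index with whole-genome leading-strand
AT skew. The default index is `leading_fraction`, 100 × leading coding
bases / total coding bases; the gespi index is named but not implemented
because its defining reference is not available to transcribe, and
guessing a formula would be worse than an explicit NotImplementedError.
Contrasts are differences between disjoint terminal-node pairs supplied as
an input table (multi-species nodes are averaged); the sign convention
follows table row order, which the regression-through-origin logic makes
immaterial. Reuse of a species across pairs is an error (it breaks
independence); a newick validator checks pair species are terminal taxa.
The regression is OLS of Δskew on Δbias with an intercept retained so its
consistency with zero is testable, plus a one-sided binomial sign test on
sign agreement (zero deltas dropped).

## Synthetic data generator

`SynthConfig` defaults mirror the TW20 study system: a 2.8 Mb circle,
ori at 0 with ter at the antipode, 2,500 genes of Normal(300, 80) amino
acid codons (floored at 50), operons of 1 + Poisson(2) genes, leading
orientation probability 0.78, intra-operonic spacers Exponential(80 bp)
(so a realistic minority survives the 60 bp trims), ex-operonic spacers
Uniform(150, 460) bp (inside the 500 bp cap), intergenic base frequencies
equal to the TW20-derived leading values (lagging = complement), per-strand
codon models equal to the stop-free draw distribution of those frequencies,
and 140 singleton plus 54 older SNPs from the TW20 leading rate matrix.
Tests use the same structure scaled to ~40–200 kb and 25–130 genes so the
suite runs in seconds; the statistical conventions are unchanged by the
scaling.

Genes are packed sequentially: each operon draws an orientation relative
to the replichore it starts in, genes are start codon + iid stop-free
codons + a random stop, and operons never cross ter or the origin (the
gap is padded with intergenic sequence, which may exceed the length cap
and is then excluded in truth exactly as the classifier would exclude it).
Intergenic bases are drawn on the leading strand and complemented onto the
published strand in replichore 2. The truth bundle records per-position
class arrays built from the placement records (independently of the
classifier), per-gene orientations, and the rate matrix's stationary
distribution.

SNPs are sprinkled onto eligible ex-operonic sites (trimmed class, hence
≥ 60 bp from genes and inside the cap): category counts follow a
multinomial with weights N_i·r_ij, sites are drawn without replacement
within category, and the emitted table keeps ancestral bases in the
reference sequence so ancestral truth is trivially the reference. Identical
config and seed give byte-identical output.

What the generator does **not** emulate: real gene-length and spacer-length
distributions beyond their first moments, codon-usage selection (unless a
tilted codon model is supplied, as in `examples/05`), transcription-coupled
mutation, recombination or lateral transfer (non-core exists only as a
maskable interval), and sequencing error. Passing tests therefore
demonstrate correctness of the machinery and calibration of the inference
under the stated model, not robustness to every property of real data.

## Numerical conventions

- Base order is A, C, G, T everywhere; complementation is index
  permutation (3, 2, 1, 0).
- A skew with empty denominator propagates as NaN, never 0.
- Windows wrap the circular origin; window counts are doubled-cumulative-sum
  differences, so a full non-overlapping tiling reproduces whole-genome
  counts exactly.
- All randomized procedures take explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds give bit-identical results.
- Percentiles use numpy's default (linear interpolation) definition.

## Problem sizes

Defaults used by the test suite and acceptance script: B = 1000 bootstrap
replicates; 1000 leave-3-out simulations against the exhaustive 274-multiset
enumeration; 10,000 codon-null simulations at 600,000 codons (the scale of
a leading-strand coding complement; the null mean does not depend on this
choice, only its Monte-Carlo spread does); 200 replicate parameter-recovery
experiments on a ~120 kb synthetic genome with 140 singletons each. These
sizes were chosen to keep Monte-Carlo error well inside the tolerances of
the quantities being estimated.
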