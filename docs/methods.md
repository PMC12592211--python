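# Methods

This note records the models implemented in `uvsdr`, the assumptions and
defaults behind them, what the synthetic study system does and does not
emulate, and the numerical choices a maintainer would want to know.

## Coordinate and format conventions

All intervals are 0-based half-open internally. GFF3 and VCF are 1-based
on disk and converted at the boundary; BED stays 0-based half-open.
Window tilings keep a trailing window shorter than the nominal width and
flag it `partial` so statistics can exclude it explicitly (there is no
universally agreed treatment; flagging avoids a silent choice). N
residues participate in no k-mer and no density numerator. FASTA goes
through Biopython, VCF reading through pysam, trees through dendropy;
GFF3/BED/TSV use small validated line parsers because the package needs
strict round-trips and a `compartment` attribute that the heavier
database layers do not model.

## YGS-style k-mer subtraction

Read k-mers are counted canonically (the lexicographic minimum of a
k-mer and its reverse complement, implemented as the numeric minimum of
their 2-bit packed codes), with defaults mirroring the established
protocol: k = 15, bases under phred 20 skipped, counts below 5 dropped.
The count filter is what absorbs sequencing error in real data — an
error k-mer rarely recurs five times.

"Single-copy" is defined genome-wide on the scored assembly: a canonical
k-mer occurring exactly once across all sequences, counting a forward
and a reverse-complement occurrence as the same k-mer. Each single-copy
k-mer belongs to the window containing its start position. A window's
score is 100 × (single-copy k-mers absent from the opposite-sex k-mer
set) / (single-copy k-mers in the window); windows with no single-copy
k-mers score NA and are never called (this avoids 0/0 and spurious calls
in repeat deserts). Candidate calling retains windows at the inclusive
≥ 50% threshold and merges adjacent retained windows. k is capped at 31
so codes fit two bits per base in a 64-bit word; k ≤ 15 uses 32-bit
codes for throughput.

## Coverage classification

Window depths are normalized per sample by the length-weighted
genome-wide mean (weighting by window length makes the normalized mean
exactly 1 regardless of partial windows). A window is a V-SDR candidate
iff male_low ≤ m ≤ male_high and f < female_max with defaults
0.75/1.25/0.50 — male bounds inclusive, female bound strict, read
literally from the rule's phrasing ("within the range", "below") — and
a U-SDR candidate under the sex-swapped rule. `log2_fold_change`
returns ±inf sentinels at zero denominators and NaN when both means are
zero; an optional pseudocount regularizes it.

The desk-scale depth engine places each error-free read at its unique
exact match in the assembly (either strand), discarding multi-mapping
reads; this emulates a mapper plus a MAPQ filter without shipping one.
Placement uses 31-mer anchor codes at every genome position: candidate
positions come from a sorted-anchor lookup of the read's first anchor,
and are verified exactly by comparing a covering set of anchor codes
(offsets chosen so consecutive anchors abut or overlap), so verification
is O(anchors) per candidate with no sequence re-materialization. Depth
from real mappings can instead be ingested as a per-window BED
(`read_depth_bed`), which validates that every requested window is
present.

## Population statistics

Heterozygosity is the fraction of non-missing sites called
heterozygous, per individual and scaffold; missing genotypes leave the
denominator. Sex-biased heterozygosity is log10(H_m/H_f), expected ≈ 0
on autosomes; H_f = 0 yields NaN and H_m = 0 yields −inf rather than a
clamped value. F_ST between sexes is the Weir & Cockerham (1984)
two-allele, two-population estimator: per-site variance components
(a, b, c), per-site θ = a/(a+b+c) reported as computed (negative values
are informative), windowed and overall θ as ratios of sums. Sites where
either group has fewer than two called individuals, or that are
monomorphic among called individuals, are skipped and counted, not
imputed.

## Gametologue pairing and Ka/Ks

Reciprocal best hits use local protein alignment (BLOSUM62, gap open
−11 / extend −1) at toy scale; ties break by longer alignment, then
lexicographic id. Codon back-alignment threads each CDS onto the global
protein alignment (a residue gap becomes `---`), validating that the
CDS translates exactly to its protein and naming the first mismatching
codon otherwise; one trailing stop codon is trimmed.

Divergence uses Nei–Gojobori (1986): per-codon synonymous site counts
as the fraction of the three possible changes per position that are
synonymous (changes to stops are not synonymous), sites averaged
between the two sequences; multi-hit codons average synonymous and
nonsynonymous differences over all minimal substitution paths,
excluding paths through stop codons unless every path is blocked;
codons containing gaps or ambiguous bases are skipped pairwise.
Proportions are Jukes–Cantor corrected; p_s ≥ 3/4 sets the `saturated`
flag with Ks = NA, which is how anciently diverged gametologue pairs
present. NG86 was chosen over likelihood codon models because it is
deterministic and fully checkable against a path-enumeration oracle
(the test suite verifies all 61 × 61 sense-codon pairs), and the
pipeline uses Ks comparatively (relative divergence ordering), where
the estimator family matters little. The interface
(`kaks_for_cds_pair`, `ng86_kaks`) leaves room for alternative
estimators.

An SDR gene is a gametologue iff its reciprocal best hit lies in the
opposite sex's SDR; otherwise it is sex-specific.

## Ancestral gain/loss reconstruction

SDR gene content is coded per orthogroup and species as 1 iff
SDR-linked; orthologues in the PARs, autosomes, or missing code 0.
Presence evolves as a two-state Markov chain with global gain rate g
and loss rate l per unit branch length — P01 = π₁(1 − e^{−(g+l)t}) with
π₁ = g/(g+l) — rather than per-branch free rates, which would not be
identifiable from one binary character per family at this matrix size.
Among-family rate variation is a mean-one discretized gamma
(equal-probability bins represented by conditional means, 10 categories
by default), with one shared multiplier per family applied to both
rates; the simulator exposes independent gain/loss multipliers as a
switch (default joint) since either reading of "independent gain and
loss rates" is defensible. The root prior defaults to the stationary
distribution, with a fixed-root option.

Likelihoods use Felsenstein pruning vectorized across families;
(g, l, α) are fitted on log scale by multi-start L-BFGS-B (default 10
restarts, deterministic seeded starting points, a restart round stopping
the search when it improves the best log-likelihood by less than 0.1).
Marginal posteriors use the up–down (inside–outside) pass per gamma
category, mixed by each category's per-family posterior weight; tip
posteriors equal the observations. Node states are called at posterior
≥ 0.5 (ties present); a branch with parent 0 → child 1 is a gain,
1 → 0 a loss, 1 → 1 retention, and the per-node expected gene count is
the sum of family posteriors.

No ascertainment correction is applied for families that are observable
only because they are SDR-linked in at least one species: all-absent
families are unobservable by construction and contribute no data, so
the uncorrected likelihood slightly overestimates π₁ at very low gain
rates. This is a known caveat, acceptable at the simulated regimes
where most families are segregating.

Gain-mechanism classification votes over orthologue locations in
species outside the gained clade: most-frequent PAR → boundary
expansion (the non-recombining region engulfed adjacent pseudoautosomal
genes), most-frequent autosome → translocation, everything absent →
birth within the SDR, PAR/autosome tie → ambiguous. Outside species
coded SDR are themselves sex-linked and carry no information about the
source compartment, so they do not vote; UNPLACED counts with ABSENT.

Absolute rate estimates trade off against the gamma shape along a flat
likelihood ridge (scaling (g, l) up and α down changes individual
branches little); the gain:loss ratio and posterior gene counts are the
stable quantities, and the parameter-recovery tests should be read with
that in mind.

## Phylostratigraphy

The taxonomy ladder is an ordered list of disjoint strata, rank 1 (most
inclusive) to rank R (the focal species); it is consumed as input, never
fetched. A gene's age is the rank of the oldest stratum holding a hit
with e-value ≤ 10⁻⁵ (inclusive); self-hits in the focal stratum are
ignored (every gene trivially self-matches), and genes with no
qualifying external hit get rank R. TRG flags are `age_rank ≥ cutoff`;
the cutoff is a parameter because clade boundaries are a per-study
choice. Two monotonicity properties are enforced by tests: removing
hits can only make a gene younger or equal, and a stricter e-value
threshold can never make a gene older.

## Enrichment statistics

Wilcoxon rank-sum is two-sided, exact when min(n) ≤ 8 without ties and
a tie/continuity-corrected normal approximation otherwise (scipy
backend). BH adjustment is the standard step-up (statsmodels backend),
returned in the original order. Permutation tests shuffle labels with a
seeded generator and use p = (#{|stat*| ≥ |stat_obs|} + 1)/(n_perm + 1),
which can never be exactly zero; the default is 10,000 permutations.
The orthologue-depletion test compares observed one-to-one orthologue
counts per chromosome against expectations proportional to gene
content, chi-square per chromosome with BH across chromosomes. Pearson
standardized residuals use the adjusted form
r = (O − E)/√(E(1 − row/total)(1 − col/total)) with the |r| > 2.4 flag
threshold. Chi-square tests use no continuity correction by default
(switchable). Windows with NA features are dropped per test, never
imputed. Per-chromosome Wilcoxon contrasts compare each autosome
against the sex chromosome, BH-corrected within a feature.

## The synthetic study system

`SimulationConfig` defaults define the package's study conditions,
chosen once to mirror a desk-scale version of a brown-algal U/V system:

- **Genomes**: four 2-Mb autosomes plus a 2-Mb U/V chromosome (10 Mb
  total per sex); the 500-kb SDR occupies [0.5 Mb, 1.0 Mb) of the U/V
  chromosome, aligned to the 500-kb k-mer-window and 10-kb
  coverage-window grids so window-resolution truth comparisons are
  clean. Autosomes and PARs are identical between sexes; the U and V
  SDR haplotypes are independent random sequences — real old SDR
  haplotypes are saturated in Ks and share essentially no k-mers, so
  simulating the divergence process would add nothing the detectors can
  see. Gametologue CDSs are the controlled exception.
- **TEs**: copies from a shared 20-motif × 500-bp library pasted at
  density 0.08 in autosomes/PARs and 0.20 in SDRs (sex chromosomes are
  repeat-rich), shared between sexes outside the SDR.
- **Genes**: 1.5-kb random in-frame CDSs (sense codons only): 120
  autosomal, 30 pseudoautosomal, and per SDR 12 gametologues plus 8
  sex-specific genes.
- **Gametologue divergence**: each site of the male CDS is substituted
  with probability q = (3/4)(1 − e^{−(4/3)Ks_target}) to a uniform
  alternative base, accepted only when synonymous. Because NG86 counts
  the same per-site synonymous fractions, E[Sd] = q·S, so the
  JC-corrected Ks recovers the target in expectation (within ~15% at
  long CDSs; verified at 30 kb). Default target Ks 0.75 — measurably
  diverged but unsaturated.
- **Reads**: 100-bp reads, both strands, uniform starts, 15× per sex,
  substitution-only errors at rate 0 by default (the exact-match depth
  engine consumes error-free reads; the k-mer counter's min-count
  filter is exercised with explicit error rates in tests).
- **Population**: 12 diploid individuals per sex (a 24-individual
  population), 3,000 sites over 6 scaffolds, Hardy–Weinberg genotypes
  at the allele frequency giving expected heterozygosity 0.3, and 30
  young-XY sites on the last scaffold where every male is heterozygous
  and every female homozygous reference.
- **Families**: 500 families on a 6-tip dated tree under gain 0.5 /
  loss 1.0 with gamma(1) rate multipliers, root drawn from the
  stationary distribution.
- **Phylostratigraphy**: 300 genes over 8 strata, uniform true ages;
  qualifying hits placed in the true stratum and younger strata, decoy
  hits above the e-value threshold to exercise the filter.

What the simulator does **not** emulate: indels and structural
variation, sequencing-error profiles beyond uniform substitutions,
realistic TE sequence evolution, GC/coverage biases, linkage
disequilibrium within scaffolds, gene structure (introns, UTRs), or
gene movement between compartments within a lineage. Passing tests
therefore demonstrate correctness of the statistics and the detection
logic under the stated generative model, not robustness to every
artifact of real sequencing data — for real data the depth engine is
bypassed in favor of external mapper output via `read_depth_bed`.

## Problem sizes and determinism

The default end-to-end demonstration (10-Mb genomes, 15× reads per sex,
500 families, 300 genes) was sized to run in a few minutes on one CPU;
the unit suites use hundred-kb genomes. Every stochastic component
takes a seed, all randomness descends from the single configuration
seed via fixed offsets, and identical configuration + seed reproduces
byte-identical outputs (asserted by tests for genomes, reads, FASTQ
files, fits and reports).
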