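# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `rohscan`, in the order data flows through the package.

## Genotype model and coordinates

Genotypes are biallelic SNP calls in {HOM_A, HET, HOM_B, MISSING}, stored
as a dense int8 matrix aligned to an ordered marker map.  All internal
coordinates are 1-based inclusive (the PLINK MAP convention); BED input and
output convert to/from 0-based half-open at the boundary, so a segment
spanning positions [s, e] is written as `(s-1, e)`.  The PED family-ID
column carries the population (breed) label.  When only one allele is
observed at a marker it is assigned `allele_a` and HOM_B cannot occur; such
markers are monomorphic and are removed by the MAF filter downstream.
Chromosome labels are strings; the autosome set is configurable and
defaults to "1".."26" (sheep).

## Quality control

The cascade order is fixed: sample call rate → non-autosomal marker removal
→ per-SNP missingness → MAF → Hardy–Weinberg, with every step recording
(removed, remaining) so the report reconciles exactly.  All thresholds are
strict as worded in their definitions: a sample is kept iff call rate
*exceeds* 0.95; a SNP is removed iff missingness *exceeds* 0.20 or MAF is
*below* 0.05, and iff the HWE p-value is *below* 1e-5.

The HWE test is the standard exact conditional test: conditioning on the
observed allele counts, the probability of every attainable heterozygote
count is computed by the two-sided recurrence from the distribution's mode,
and the p-value sums all outcomes no more probable than the observed one
(no mid-p correction).  A monomorphic marker admits a single configuration
and has p = 1.  MAF is computed on all populations pooled; the HWE test is
applied per population and a marker deviating in *any* population is
removed globally — the conservative reading of per-population QC in
multi-breed panels (the alternative, removal only when deviating in every
population, is reachable via `per_population=False` plus pre-splitting).
Populations with fewer than two individuals are skipped with a warning.

## Consecutive run detection

The scanner implements the consecutive (non-sliding-window) method.  For a
target state T (homozygous for ROH — either homozygote; heterozygous for
ROHet), every marker is classed target / opposite / missing.  Scanning left
to right:

1. a run seeds at the next target-state marker;
2. it extends while (a) each added marker is target, opposite or missing,
   (b) opposite count ≤ `max_opposite` and missing count ≤ `max_missing`
   (budgets per run, not per window), and (c) the gap to the previous
   marker is ≤ `max_gap_bp` — a larger gap unconditionally terminates the
   run on both sides;
3. the block is trimmed back to its last target-state call, so tolerated
   markers are never terminal and allowances cannot extend a run's span;
4. the block is emitted if it spans ≥ `min_snps` markers and
   `end − start ≥ min_length_bp`; the scan resumes after the block
   (a budget-violating marker is never target-state, so nothing is lost).

Run length is defined as `end_bp − start_bp` (difference of the flanking
SNP positions, not +1), keeping F_ROH self-consistent with the
covered-length denominator below.  Greedy left-to-right extension makes
emitted runs pairwise disjoint and the output deterministic; where the
opposite-state budget is saturated on both flanks of a tolerated marker,
two maximal candidate intervals can overlap, and the leftmost is taken —
the behaviour of the published consecutive algorithm.  Correctness is
defined by set-equality with a brute-force oracle that re-derives every
candidate interval from the criteria (tests and acceptance script).

ROHet detection uses target = heterozygous with allowances 3 homozygous + 2
missing, minimum 15 SNPs and 1 Mb.  Because the ROHet summary ladder starts
at >0.5 Mb, the pipeline's ROHet preset lowers the detection floor to
0.5 Mb so the shortest class is populated; the library default stays 1 Mb.
Both settings are plain config fields.

## Summaries and genomic coefficients

Length classes are cumulative ">t" sets (a 20 Mb ROH belongs to all five
ROH classes; a run of exactly 2.0 Mb is not >2 Mb).  This is the reading
under which per-class counts, length sums, F_ROH and D_ROHet are provably
non-increasing along the threshold ladder — a property the tests assert
for every simulated animal.

F_ROH(>t) per animal = (Σ lengths of that animal's ROH with length > t) /
(Σ over autosomes of (max SNP position − min SNP position)).  The
denominator uses the SNP-covered span, not assembly chromosome lengths,
because array data carry no information outside the mapped span.  D_ROHet
is identical with ROHet runs.  Animals with no runs contribute zeros and
are included in breed means; breed SDs use the n−1 (sample) convention.
An alternative mean over only animals carrying ≥1 run in the class can be
obtained by filtering the per-animal table.

## ROH islands

Per breed, a SNP's incidence is the fraction of individuals with ≥1 ROH
covering its position (overlapping runs of one individual count once).  The
hotspot threshold is the incidence of the ⌈n·pct/100⌉-th highest SNP
(default pct = 1); selection is `incidence ≥ threshold`, so ties at the
threshold are all included — deterministic and permutation-invariant.
Selected SNPs are aggregated into maximal map-consecutive blocks on one
chromosome (no bridging across unselected SNPs or chromosome boundaries);
blocks below `min_island_snps` (default 2 — one SNP is not a region) are
dropped.  Thresholds are computed within breed by default; a dataset-wide
variant is available by flag.  Annotation overlap is positional
intersection (1-based inclusive; overlap = min(ends) − max(starts) + 1)
against local BED files via an interval tree, verified against an all-pairs
oracle in tests.  No network resources are consulted.

## Breed comparisons

Per-animal counts and sums are small, heavily tied integers, so the breed
contrasts are two-sided Wilcoxon rank-sum tests with midranks.  For small
untied samples (both n ≤ 10 in auto mode) the exact null distribution of
the Mann–Whitney U is built by the classical counting recursion and the
two-sided p is 2·min(P(U≤u), P(U≥u)) capped at 1; otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity correction
is used (cross-checked against an independent implementation in the test
suite).  Raw p-values are the primary output; a Bonferroni column
(adjusted across breed pairs within each statistic × class family) is
provided but not applied by default, since the analysis is descriptive.
Shapiro–Wilk (scipy) screens normality and errors on constant samples.

## Synthetic cohorts

The generator provides the known-truth data every pipeline stage is tested
against.  A marker scaffold is built per study: evenly spaced positions
with ±30% jitter (keeping order and bounding gaps below twice the mean
spacing, so the scaffold itself never triggers the 1 Mb gap rule), allele
frequencies uniform on [0.05, 0.5] so the background passes the MAF filter.

**Planted mode** draws background genotypes from Hardy–Weinberg proportions
at each SNP's frequency; autozygous tracts are overwritten with homozygotes
drawn by allele frequency, heterozygous tracts with forced HET.  Tract
flanks are *sealed*: 2 heterozygous calls (for autozygous tracts) or 4
homozygous calls (for heterozygous tracts) are planted immediately outside
each tract — one more than the default allowances — so a detected run can
never extend across a planted boundary and noise-free recovery is SNP-exact
by construction.  Genotyping error flips each call to one of the other two
called states with probability ε (so hom→het with ε/2, the event that
stresses the allowance budget); missingness is applied last.

**Pedigree mode** is a gene drop: founder haplotypes are drawn per SNP by
allele frequency and transmitted through meioses with Haldane (no
interference) recombination — crossover count Poisson with mean equal to
the chromosome length in Morgans at 1 cM/Mb by default.  True autozygous
intervals are the maximal regions where an individual's two haplotypes
descend from the same founder haplotype copy, so the classical expectations
E[F] = 1/4 (full sibs), 1/8 (half sibs), 1/16 (first cousins), 0 (outbred)
apply and are verified by Monte-Carlo.

**Nine-cohort study.**  The end-to-end fixture emulates a nine-breed
conservation-program survey with cohort sizes 104, 100, 97, 99, 69, 50, 59,
104, 90 on a 5 × 50 Mb × 1,000-SNP scaffold (≈50 kb spacing, the density
regime of a 50k array; full 26 × ~48k scale runs but is not required by the
tests).  Per-breed tract loads are scaled to the desk genome so breed-mean
F_ROH(>1 Mb) spans ≈0.02–0.16 — the range reported for conserved sheep
breeds — with the most inbred cohorts carrying the >16 Mb tracts, and small
heterozygous tract loads differentiating D_ROHet.  Each breed also carries
one shared 2.5 Mb autozygous hotspot in 35% of its individuals: strong
enough to be the breed's top-1% incidence signal, mild enough that the
per-population HWE filter (p < 1e-5) does not strip its SNPs.

**Problem sizes.**  The scales used by the tests and the acceptance script
are the package's study conditions: 1,000+ random ≤200-SNP vectors for
scanner/oracle equivalence; a 2 × 50 Mb × 2,500-SNP (≈20 kb spacing)
fixture for planted recovery, so a 1.2 Mb tract holds ≈60 SNPs; 20 × 100 Mb
× 500 SNPs (= 20 Morgans) with 50 full-sib offspring for inbreeding
recovery (50 replicates in the test suite, 10 in the acceptance script);
the nine-cohort study for monotonicity and determinism.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical datasets and byte-identical CSV outputs (fixed
  float format, fixed sort orders, LF line endings).
- HWE probabilities use the mode-anchored recurrence (numerically stable;
  no factorials) with a 1+1e-12 tolerance when comparing outcome
  probabilities to the observed one.
- The exact Wilcoxon U distribution is built by dynamic programming in
  O(n_x · n_y · (n_x·n_y)); exact mode refuses tied data rather than
  silently approximating.
- Degenerate inputs are errors, not silent answers: empty samples,
  constant samples for Shapiro–Wilk, all-zero genotype counts, inverted
  intervals, non-increasing positions, overlapping planted tracts.

## What passing tests do and do not show

The generator emulates marker density, missingness, MAF spectra, genotyping
error and controlled autozygosity/heterozygosity structure, and the
pedigree mode yields correct identity-by-descent segment-length physics
under Haldane recombination.  It does *not* model linkage-disequilibrium
haplotype structure, allele-frequency differentiation between breeds,
demography-driven ROH length mixtures, array-specific clustering artefacts,
or crossover interference.  Passing recovery tests therefore demonstrates
that the detector, coefficients, islands and tests compute what they claim
on data whose truth is known — not that any particular real population has
a given inbreeding level.  On real data, detection sensitivity near the
minimum-length boundary depends on local SNP density, and the consecutive
method's greedy restart can split runs at clustered genotyping errors;
both behaviours are shared with the standard implementations of the method.
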