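# Methods

## In silico T-RFLP

**Degenerate matching.**  Primers and recognition sites are IUPAC strings;
a pattern matches at a position when, at every offset, the base sets of the
two symbols intersect.  This is deliberately symmetric (ambiguity codes are
allowed in the subject as well), so references containing Ns still match.
`U` is normalized to `T` and sequences are validated on ingest.

**Amplicon extraction.**  The forward primer is matched on the given
strand, the reverse primer as its reverse complement downstream.  With
multiple sites the 5′-most forward and 3′-most compatible reverse site are
taken — the maximal outer product, which is what PCR predominantly yields.
Both primer footprints are part of the amplicon.  If the labeled
(fluoresceinated) primer is the reverse one, the amplicon is
reverse-complemented so position 0 is always the labeled 5′ terminus.

**T-RF prediction.**  Coordinates are 0-based half-open internally.  The
T-RF is `first_site_start + cut_offset`, i.e. the number of bases from the
labeled terminus through the last base before the cut.  TaiI is shipped as
(`ACGT`, offset 4): cleavage immediately 3′ of the site on the labeled
strand.  The offset convention is not universal across prediction tools, so
the enzyme catalogue (YAML) makes it configurable; the shipped value is the
one under which a first site starting at position 302 yields the 306 bp
fragment expected for the *H. borneensis*-type reference.  Amplicons the
enzyme never cuts are reported as `uncut` with the full amplicon length and
excluded from category building by default (a flag admits them as
pseudo-T-RFs).

**Enzyme screening and category merging.**  Per clade, the set of predicted
T-RFs is computed over all its references.  Clades whose sets come within
2×tolerance (single linkage on the minimum pairwise length difference) are
merged into one category labeled with the joined clade names; an enzyme's
score is its category count, ties broken by name.  The factor 2 reflects
that two peaks each called within ±tolerance can only be told apart if the
underlying lengths differ by more than twice that.

**Clone cleanup.**  p-distance compares only columns where both symbols are
unambiguous bases, and is undefined (an error, not 0) when no column
qualifies.  Deduplication single-links clones at p < 0.001 — strictly
below, so a pair at exactly the threshold stays separate — and represents
each group by its most frequent member sequence (ties: lexicographically
smallest id); cross-group representatives are automatically ≥ threshold
apart, which makes the operation idempotent.  The chimera screen splits the
alignment at its midpoint and assigns each half to the nearest reference
clade; a clone is chimeric only when the halves disagree *and* the two
clades are ≥ 0.005 apart over each half — below that the halves are not
distinguishable and flagging would be noise.  This deterministic screen
replaces database-search-plus-partial-tree procedures; it needs no external
database and captures the same signal (discordant 5′/3′ ancestry).  Queries
shorter than two half-lengths (default 100 columns each) are
"unscreenable" rather than silently passed.

## Peak profiling

A chromatogram is rejected unless QV is strictly greater than 75; surviving
peaks must lie in [100, 1200] bp (inclusive).  Each peak goes to the
category with the nearest predicted length within the size tolerance
(default 1.5 bp, chosen to match typical capillary size-calling precision
and consistent with the 2×tolerance merge rule); exact ties between two
categories are flagged ambiguous and left unassigned rather than broken
arbitrarily.  A category with several predicted lengths (a clade with two
subtypes) accumulates all its peaks into one RA value.  H_total includes
unassigned peaks by default — they are real amplified material — and they
are reported as an `unassigned` percentage so every profile sums to 100; a
flag drops them from the denominator instead.  Monthly summaries are
five-number (min, Q1, median, Q3, max) with linear-interpolation quartiles,
stated in the output metadata; months with fewer than 3 samples are flagged
low-n.

## Permuted Brunner–Munzel test

The statistic is the studentized difference of mean pooled midranks with
the Brunner–Munzel rank-based variance estimate; p_hat estimates
P(X<Y) + ½P(X=Y) and equals brute-force pair counting.  Degenerate inputs:
when the rank-variance estimate is zero the statistic is ±inf if the mean
ranks differ (complete separation — the most extreme outcome a permutation
can produce) and 0 if they are equal (e.g. all values tied).  Without the
±inf convention an exhaustive test on completely separated samples could
not distinguish the observed split from any other, and the small-sample
enumeration example (n = 3 vs 3, p = 2/20) would be unattainable.

The null reassigns pooled values to the two group labels.  With
C(N, n_x) ≤ 20 000 all distinct assignments are enumerated and the
two-sided p is the exact proportion with |W*| ≥ |W_obs| (a 1e-12 slack
absorbs float noise in ties); otherwise `n_perm` (default 10 000) seeded
Monte Carlo draws are taken and p = (1 + hits)/(1 + n_perm), never zero.
Both paths share a vectorized batch evaluator (midranks per row via
`rankdata(axis=1)`), which keeps the calibration experiments cheap.  The
test is two-sided; no multiple-testing correction is applied by default
(a Benjamini–Hochberg helper is provided).  Sample-size floor: N ≥ 4,
because below that the permutation null is vacuous.

## Trophic position

TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β)/TEF + 1 with β = 3.4‰ and TEF = 7.6‰,
both configurable for other calibrations.  Group estimates average
per-specimen TPs and report a 1σ spread; the sample (n−1) convention is the
default, with the population value always carried alongside, since
published tables rarely state which was used.  Because the formula is
linear, the mean of per-specimen TPs equals the TP of the group-mean δ
values on the same raw data; published tables can still disagree with
recomputation from their own printed group means when those means were
rounded first (e.g. rounded means of 16.1 and 5.5 give 1.95 → 1.9 while
unrounded per-specimen data print 2.0).  The package reports both numbers
rather than trying to reproduce rounding artefacts.  Values display at one
decimal next to the full-precision estimate.

## Synthetic data

The generators emulate the study's inputs so every stage is testable
offline, with defaults set to the study conditions:

* **References**: 8 clades (labels A–H), 700 bp templates (the scale of the
  *rbcL* T-RFLP amplicon), 3 references per clade, between-clade divergence
  0.05 and within-clade divergence 0.002 per site.  Each clade root is the
  common ancestor mutated at the between-clade rate, with a concrete
  expansion of the degenerate primer pair at the ends and one designed
  recognition site placed so the clade's T-RF falls on a 25 bp grid
  starting at 130 bp (inside the 100–1200 bp analysis window, like the
  study's 138–366 bp range, and ≥ 5 bp apart).  Any accidental earlier
  recognition site is scrubbed by point mutation outside protected
  (primer/site) positions.  Requested collision pairs share a T-RF to
  emulate indistinguishable source algae.  Within-clade variants mutate
  only downstream of the first cut site, so the designed T-RF is invariant
  within a clade.
* **Clone libraries**: multinomial clade counts, PCR point error
  0.001/base, chimera rate 0.01 (the study found 2 chimeras among 209
  clones).  Chimeras splice two distinct clades at the alignment midpoint
  ±5%, so the midpoint-split screen can see them.
* **Electropherograms**: one peak per (possibly shared) clade T-RF; height
  proportional to mixture weight — which presumes equal chloroplast genome
  copy number per kleptoplast, the same assumption the RA interpretation
  itself makes — with multiplicative lognormal noise (CV 0.10; lognormal
  keeps heights positive) and Gaussian size jitter (σ 0.3 bp).  Optional
  spurious peaks outside 100–1200 bp exercise the QC.
* **Isotopes**: the TP formula inverted, δ_Phe ~ base + ε and
  δ_Glu = δ_Phe + β + TEF·(TP−1) + ε′ with independent Gaussian ε of σ
  0.3‰.

Every generator is deterministic given its seed.  What the simulations do
*not* model: indels and alignment error (all sequences stay co-aligned by
construction), phylogenetically structured substitution, amplification bias
between clades, peak overlap/deconvolution, and size-standard
miscalibration.  Passing recovery tests therefore demonstrate that the
analysis logic is correct under the stated noise model, not that real
electropherograms are this well behaved.

## Problem sizes in the test suite

The suite's stochastic experiments use: 1 000 random sequences (200–2 000
bp) for the digestion oracle; 5 000 null replicates at n = 10 vs 10 with
999 permutations each for test calibration; 1 000 replicates for p-value
uniformity; 200 replicates for the seasonal-shift power check; 100
electropherogram replicates for RA recovery; 500 replicates for TP
unbiasedness.  These sizes give binomial/standard-error bands comfortably
tighter than the asserted tolerances while keeping the whole suite under a
minute of compute.

## Known limitations

* The chimera screen only sees breakpoints near the alignment midpoint;
  staggered or multi-breakpoint chimeras require the tree-based methods it
  stands in for.
* Nearest-reference clade assignment has no "novel clade" outcome; a query
  from an unsampled lineage is forced into the closest known clade.
* The T-RF cut-offset convention must match the instrument/standard
  combination; validate with single-species controls (a reference producing
  one predicted-length peak) before interpreting field samples.
* Exhaustive permutation p-values at very small n are coarse (minimum 2/20
  at 3 vs 3); the low-power flag should be taken seriously.
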