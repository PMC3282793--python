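# Methods

## Scope and data model

`barcodegap` evaluates candidate DNA barcode loci from *pre-aligned*,
species-labelled sequences. Alignment is deliberately upstream: every
computation in the package is defined on alignment columns, and no aligner
is bundled. The universal container is the `LocusAlignment` (one locus,
members ordered as in the input FASTA, all sequences equal length over
`{A,C,G,T, IUPAC codes, -}`); a `MultiLocusDataset` groups loci over one
sample collection and enforces that a sample's species label is consistent
across loci. Sequences are uppercased and `U` mapped to `T` on read;
ambiguity codes are preserved and interpreted per operation.

Multi-locus analyses are dual, mirroring the two ways combinations are used
in barcoding studies:

- distance-based summaries (divergence metrics, gap histograms, rank-sum
  tests) run on the **concatenated supermatrix** restricted to samples
  present in all member loci (intersection semantics);
- identification combines **per-locus calls** with the traffic-light rule
  (any member locus identifying a sample identifies the combination).

## Site classification

Per column, only unambiguous bases {A,C,G,T} are considered; gaps and
ambiguity codes are ignored within the column. A column with fewer than two
unambiguous bases is *excluded* (it supports no comparison); a column whose
unambiguous bases are all identical is *conserved*; otherwise it is
*variable*, and *parsimony-informative* iff at least two distinct bases each
occur in at least two sequences (else a *singleton* site). The explicit
excluded bucket makes the partition exact and testable:
`conserved + variable + excluded = alignment_length` and
`informative + singleton = variable`. Columns containing gaps are *not*
excluded wholesale — only columns with <2 usable bases — for consistency
with the pairwise-deletion distance convention. Tools differ in how they
treat gapped/ambiguous columns when printing such tables, so counts from
other software may differ on gappy alignments even when the definitions of
the site classes agree.

## Distances

K2P and p-distance are computed per pair under pairwise deletion: a site is
comparable only if both sequences carry an unambiguous base there. With
transition proportion P and transversion proportion Q over comparable
sites, `d_K2P = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)` and `d_p = P + Q`. K2P is
the default model (the de-facto barcoding standard); p-distance is available
everywhere via a flag, and all downstream modules are model-agnostic.

Degenerate pairs are flagged, never fabricated: zero comparable sites or a
non-positive K2P log argument (saturation) yield a missing entry (NaN) that
is excluded from every downstream summary, with the count logged and
recorded. Distances are not clamped to a ceiling. Per-distance variance
estimation is not implemented — only means/SDs over distance *sets* are
reported.

## Divergence metrics

Defined on the partition of all defined unordered pairs into conspecific
(intra) and heterospecific (inter) sets:

| metric | definition |
|---|---|
| all_intra | mean ± SD of all intraspecific pair distances |
| mean_theta | per-species mean intraspecific distance, averaged over species with ≥2 samples |
| coalescent_depth | per-species **maximum** intraspecific distance, averaged over species |
| all_inter | mean ± SD of all interspecific pair distances |
| theta_prime | per-species mean distance to heterospecific samples, averaged over species |
| min_inter | per-species minimum heterospecific distance, averaged over species |

Coalescent depth uses the maximum pairwise distance rather than a tree: for
an ultrametric (e.g. UPGMA) clustering of one species, the deepest split
equals the maximum pairwise distance, so no tree machinery is needed.
θ′ is realized as the per-species mean heterospecific distance since, within
a single genus, all heterospecific samples are congeners. SDs are sample
SDs (n−1; n=1 → 0). A metric with empty support is reported as missing,
never as 0. These order constraints hold by construction and are asserted
in tests: mean(min_inter) ≤ mean(all_inter) and
mean(coalescent_depth) ≥ mean(mean_theta).

## Rank tests

Both Wilcoxon tests use midranks for ties. The signed-rank test pairs the
*same sample-pair's* interspecific distance at two loci (pairing key: the
unordered sample-id pair, present and defined at both loci — this is why the
paired n differs between locus comparisons); zero differences are dropped.
The rank-sum test compares the intra vs inter distance distributions of one
locus. Two-sided p-values are reported with the direction given separately.

p-value policy: for small samples the exact conditional permutation
distribution is computed (signed-rank: dynamic programming over doubled
midranks, n ≤ 25; rank-sum: full enumeration of group assignments, pooled
n ≤ 20); above those sizes the normal approximation with tie correction and
a 0.5 continuity correction is used. Real barcode datasets have thousands of
pairs and always take the approximation path; the exact path exists so that
small-sample results are exact rather than approximate. The two-sided exact
p is `2·min(P(W ≤ w), P(W ≥ w))` capped at 1.

## Barcoding gap

Distances are histogrammed in half-open bins `[k·w, (k+1)·w)` with default
width 0.001, separately for intra and inter pairs; counts are conserved by
construction. Because "fraction of samples with zero interspecific
distance" is ambiguous, both readings are computed: the fraction of
interspecific *pairs* at distance exactly 0, and the fraction of *samples*
participating in at least one zero-distance heterospecific pair. A coarse
0.01-unit section summary is also emitted for the conventional
"distances mainly fall in section 0.00–0.01" reading of gap plots.

## Identification

Leave-one-out throughout: each sample is queried against the library of all
remaining samples. (Querying one sequence per species instead would yield
only a species-level rate; per-sample LOO yields both levels.)

- **Nearest distance**: the query takes the species of the library sample at
  minimal defined distance, provided that distance is *below* the threshold
  (default 0.01 substitutions/site — the conventional plant-barcoding
  value; configurable, with a data-driven alternative of the 95th
  percentile of intraspecific distances). Minimum attained by ≥2 species →
  ambiguous; minimum ≥ threshold, or no defined distance → no call.
- **Best hit**: the query's ungapped sequence is scored against every
  library sequence by local alignment (match +1, mismatch −2, gap open −5,
  gap extend −2, via Biopython's PairwiseAligner); the best hit must clear
  an E-value cutoff (default 1e−6) with `E = K·m·n·e^(−λS)` using the
  published ungapped Karlin–Altschul constants for the +1/−2 nucleotide
  scheme (λ = 1.33, K = 0.621). Score ties across species → ambiguous.
  Scores under this scheme are symmetric, so batch LOO computes the
  all-pairs score matrix once.

Efficiencies are computed over an explicit eligible population: sample
efficiency = correctly called samples / all eligible samples (a sample
without a call — e.g. amplification dropout — counts as a failure);
species efficiency = species whose samples are *all* correct / all species.
The all-samples rule is chosen because it is the strictest reading
consistent with species efficiency never exceeding sample efficiency.
Ambiguous and no-call both count as failures; singleton species stay in
both denominators and their count is reported. The traffic-light
combination takes precedence correct > incorrect > ambiguous > no-call over
member-locus calls, which makes combined sample efficiency ≥ the best
member's (monotonicity, asserted in tests).

## Synthetic data generator

The generator emulates the statistical structure of a genus-level barcode
survey, with all randomness from a single seed (byte-identical re-runs):

1. a random root sequence per locus;
2. a **star phylogeny** of species: each species ancestor evolves from the
   root along a branch of `(expected_inter − expected_intra)/2` expected
   substitutions/site, so heterospecific *samples* diverge by
   `expected_inter` in expectation. The star topology makes expected inter
   divergence uniform across species pairs and therefore directly testable;
   a nested species tree would only add untestable covariance structure for
   distance-based analyses;
3. each sample evolves from its species ancestor by `expected_intra/2`, so
   conspecific pairs diverge by `expected_intra`;
4. substitution events per site are Poisson with the branch length as mean
   (multiple hits arise naturally and are undone by the K2P correction);
   each event is a transition with probability `kappa/(kappa+2)`;
5. optionally, an insert of configurable length flanked by an AT-rich
   repeat motif is placed into a fraction of species at a fixed position,
   with all non-carriers gap-padded (non-coding-spacer indels);
6. each sample×locus is independently dropped with `dropout_prob`
   (amplification failure).

Calibration is in expected substitutions per site because the emulation
targets are distance summaries, not times or rates. Setting
`expected_intra == expected_inter` collapses the species structure
(zero-length internal branches) — the limiting case in which identification
must fail, used as the negative control in tests.

The default profile (`dioscorea_like_profile`) is a 38-species genus with
1–8 samples per species (148 total) and three loci whose lengths
(752/553/~546 bp), divergence levels (intra 0.0095/0.0019/0.0195, inter
0.0295/0.0125/0.0879), dropout rates (0.30/0.17/0.26) and the 234-bp insert
at position 183 in the non-coding spacer match the magnitudes reported in
genus-level plant-barcode surveys of yams. What the generator does **not**
emulate: coalescent demography and incomplete lineage sorting, rate
variation across sites and lineages, sequencing error and ambiguity codes,
alignment error, and shared haplotypes beyond what low divergence produces
by chance. Passing tests on synthetic data therefore validate the
*computations*, not the biological difficulty of any real genus — real data
with introgression or para/polyphyletic species will be harder than the
star-phylogeny emulation.

## Numerical and degenerate-input choices

- Distances on flagged-missing pairs propagate as NaN and are excluded,
  with counts, from partitions, summaries, histograms and identification
  (a query whose library distances are all undefined gets no call).
- Ties: midranks in both rank tests (with tie-corrected approximation
  variance); species ties in identification yield `ambiguous` rather than an
  arbitrary winner.
- All report files are TSV/JSON with fixed float formatting; the run
  manifest records config and SHA-256 hashes, making determinism checkable
  at the byte level.
- Tests that need scale use reduced problem sizes (e.g. 20 species × 4
  samples at 700 bp for recovery checks; 6–10 species for pipeline checks),
  chosen as the smallest sizes at which the targeted effects are
  unambiguous.

## Known limitations

- No substitution models beyond K2P/p-distance, no rate heterogeneity, no
  tree building — by design, the package evaluates barcodes, it does not do
  phylogenetics.
- The best-hit scorer is an in-package local-alignment search, not a wrapper
  around an external BLAST executable; E-values use fixed ungapped
  Karlin–Altschul constants and are meant for thresholding, not for exact
  agreement with any particular BLAST build.
- Identification thresholds (0.01 distance; E ≤ 1e−6) are conventions, not
  estimates; both are configurable and a percentile-based data-driven
  threshold is provided.
- Species-level efficiency uses the all-samples-correct rule; studies using
  a majority or any-sample rule will report higher species efficiencies on
  the same calls.
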