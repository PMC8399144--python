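# Methods

## Genotype representation

Calls are categorical diploid genotype states: two-letter strings with
alleles in alphabetical order (`AA`, `AG`, `GG`, …), missing = `NN`. A
biallelic marker therefore has at most three states (two homozygotes, one
heterozygote). All statistics operate on states, not alleles, except the
minor-allele-frequency summary and the singleton rule, which split states
into allele copies.

## Cleaning cascade

Order is fixed: replicate concordance → monomorphic → singleton →
excess-state → missingness tiers. Each rule is idempotent and the
`FilterReport` balances exactly (input = retained at the loosest tier + sum
of removals, evaluated sequentially). Conventions, chosen where raw-data
pipelines genuinely differ and recorded here rather than asserted as the only
reading:

* **Replicate concordance.** A marker passes if all *non-missing* calls
  across the control replicates are one identical state; missing calls are
  non-informative. Under GBS missingness, requiring six observed identical
  calls would discard most markers on missingness alone, which the
  missingness tiers already handle. All control replicates but one keeper are
  then dropped from the sample set, and later missingness denominators use
  this post-concordance sample set.
* **Singleton.** The marker's rarest allele is carried by exactly one sample,
  whether heterozygous or homozygous — the standard population-genetic usage.
* **Excess states.** More than `max_states` (default 3) distinct observed
  genotype states per marker, the tri-state biallelic expectation; markers
  beyond it are treated as unreliable multi-allelic or paralog-collapsed
  calls.
* **Missingness tiers.** Inclusive thresholds (`≤ 0.50` etc.), so tier sets
  are nested (M15 ⊆ M30 ⊆ M50).

## Dissimilarity and APD

`d(i,j)` is the mismatch fraction over pairwise-complete loci. This makes the
denominator pair-specific; a dissimilarity converted to "equivalent different
loci" via `round(d · L)` (half away from zero, `L` = marker total) is
therefore an *inflated* estimate of the raw mismatch count when calls are
missing, by the factor `L / shared_loci`. Duplicate thresholds should allow
for that inflation (the acceptance script uses twice the planted mismatch
count; real collections sit orders of magnitude away on either side of any
sensible cutoff). Pairs with zero shared loci are reported as undefined with
a warning; APD refuses such matrices rather than imputing, because a silent
fill would bias the ranking the method exists to produce.

APD per sample is the row mean of off-diagonal `d`; the collection mean of
APD equals the mean off-diagonal dissimilarity by construction (tested to
1e−12). Selection of extremes is exposed as top-*n* / bottom-*n* with ties
broken by lexicographic sample id: published APD cutoffs are data-realized
quantiles of a particular collection, not transferable parameters. Counts of
samples beyond 1/2/3 SD of the mean are reported alongside.

Duplicate pairs form an undirected graph; each connected component of size
*s* contributes *s* − 1 GD samples (one representative is kept), so the total
GD count is nodes − components. The minimum percent identity among reported
pairs is `100·(1 − max d)`.

## PCoA

Classical scaling: Gower double-centering of `−d²/2`, symmetric
eigendecomposition, coordinates = eigenvectors × √eigenvalue. Simple-matching
dissimilarities are generally non-Euclidean, so negative eigenvalues occur;
they are excluded from both the coordinates and the percent-explained
denominator (hence axis percentages sum to ≤ 100 over the retained axes).
Eigenvalues within `1e−10` of zero (relative to the spectral radius) are
treated as null.

## Neighbor-joining

Saitou–Nei agglomeration with the standard Q criterion. Determinism: ties in
Q break toward the smallest (i, j) index pair under the current taxon
ordering. Negative branch lengths (possible for non-additive inputs) are
clamped to zero with the deficit transferred to the sister branch, preserving
the joined pair's summed length. On additive matrices the tree reproduces the
input path lengths exactly (tested to 1e−9 at full precision). Newick output
uses 6 significant digits by default (a `precision` argument raises it) and
quotes labels only when they contain reserved characters.

## AMOVA

Distance-based analysis of molecular variance on *squared* pairwise
dissimilarities, samples treated as single multilocus genotypes, two-level
design (among groups / within groups):

* `SSD_total = Σ_{i<j} δ²_ij / N`, `SSD_within = Σ_g Σ_{i<j∈g} δ²_ij / n_g`,
  `SSD_among` by difference — on Euclidean distances these equal the classic
  coordinate sums of squares, which is the oracle used in the tests.
* `df_among = G − 1`, `df_within = N − G`. This is the sample-level
  convention, stated explicitly because programs that weight by allele copies
  report roughly doubled within-group df on the same data; Φ and the percent
  of variation are unaffected by that choice of scale only when comparing
  like with like.
* Variance components via the weighted average group size
  `n₀ = (N − Σn_g²/N)/(G−1)`; `Φ_ST = σ²_a/(σ²_a+σ²_w)`. A negative among
  component is reported as computed and truncated to zero only for the
  percent-of-variation display.
* Permutation p: sample-to-group labels shuffled `B` times (default 999,
  seeded), `p = (#{Φ_perm ≥ Φ_obs} + 1)/(B + 1)`.

Pairwise group distances run a two-group AMOVA per pair. Raw significance at
α = 0.05 is the default, with any statsmodels multiple-testing method
available as an option, because published surveys of this kind report raw
counts of significant pairs. A singleton-vs-singleton pair has no within
degrees of freedom: Φ is reported as 1 (0 for identical samples) and p as
NaN, flagged rather than fabricated.

## Evanno ΔK

For a table of clustering log-likelihoods over consecutive K with ≥ 2 runs
each: `ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / SD(L at K)` (sample
SD, ddof = 1). ΔK is undefined at boundary K and wherever SD = 0 (flagged
NaN, not an error — identical runs are a real STRUCTURE outcome at K = 1).
The supported K is the argmax over defined values. The clustering MCMC
itself is out of scope; only its likelihood output is post-processed.

## Synthetic collections

The generator draws, from one seeded NumPy generator: per-marker ancestral
alternate-allele frequencies from `Beta(0.5, 6)` (mass concentrated at MAF
< 0.1, matching the GBS spectra this package targets); group frequencies
Balding–Nichols style, `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
`F = fst_like_divergence`; Hardy–Weinberg genotypes within groups (groups
assigned round-robin, so sizes are balanced); per-*marker* missingness rates
uniform on `missing_rate_range` applied independently per sample (the GBS
pattern — marker dropout, not sample dropout). Duplicates copy a source row
*including its missing pattern* and flip exactly `duplicate_mismatch_loci`
non-missing loci, so planted mismatch counts are exact and
`d = k / shared_loci` holds exactly at any missingness. Control replicates
are the designated control sample plus `n_control_replicates − 1` copies
perturbed at `replicate_error_rate` per non-missing locus.

What the generator does **not** emulate: linkage disequilibrium, coalescent
history, within-accession heterogeneity (each accession is one genotype,
appropriate for a heavily selfing crop), read-level error processes, or
correlation between missingness and allele frequency. Passing tests on these
collections therefore demonstrate correctness of the *computations* under
the stated statistical structure, not robustness to every artifact of real
GBS data.

## Problem sizes and defaults

The default `SimConfig` mirrors a realistic collection (571 accessions,
20,000 markers, 3 groups, 20 chromosomes, missingness up to 50%, 6 control
replicates). Tests and the acceptance script run scaled-down collections
(tens of samples × hundreds–thousands of markers; the acceptance pipeline
uses 200 accessions × 5,000 markers) — sizes chosen so the whole suite runs
in seconds while leaving every rate and structural parameter at its
realistic value. Permutation counts default to B = 999.

## Known limitations

* Pairwise dissimilarities are O(n²·m); at 571 × 19,898 the matrix takes a
  few tens of seconds in pure NumPy. No bit-packing is attempted.
* AMOVA implements the two-level design only (no within-individual level,
  no regional hierarchy).
* The duplicate threshold is a parameter with a conventional default
  (≤ 37 equivalent loci of 19,898, ≈ 99.8% identity); there is no principled
  universal cutoff, and the report should be read as candidate duplicates
  for field verification.
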