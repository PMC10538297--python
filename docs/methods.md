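# Methods

`ystrpop` implements the statistical core of a forensic Y-chromosome
population study: direct-count diversity statistics over a multi-marker
haplotype table, pairwise Rst between populations by haploid AMOVA, and the
two standard structure summaries of an Rst matrix (classical MDS, NJ tree).
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data does and does not emulate.

## Data model

A *haplotype* is one male's calls at a set of Y markers. Y-STR alleles are
named by repeat count; a microvariant allele carries one fractional digit
(`14.1` = 14 repeats + 1 bp) and is kept as printed text alongside its
numeric value, so tables round-trip byte-identically. A *multi-copy* locus
(DYS385, DYF387S1, DYS527, DYF404S1) yields an unordered allele multiset per
male that is treated as one allelic state; copy-number anomalies (a
bi-allelic call at a single-copy locus, a tri-allelic call at a double-copy
locus) are ordinary values, not errors. Y-InDels are two-state categorical
loci. Panels are ordered locus lists with multi-copy/InDel annotation; a
multi-copy locus counts as two markers, giving the familiar kit sizes
(9, 12, 17, 23, 27, 44). DYS389II is used as typed, with no DYS389I
subtraction, because conventions differ between laboratories; users who need
the subtracted convention can pre-transform their table.

Missing data follow direct-counting semantics: an individual missing any
panel locus is excluded from that panel's haplotype-level statistics but
still contributes to allele frequencies at the loci it does carry.

## Diversity statistics

For a frequency spectrum with state frequencies `Pi` over `n` observations:

* gene / haplotype diversity `GD = n (1 - sum Pi^2) / (n - 1)` (Nei's
  unbiased estimator; the `n/(n-1)` factor corrects the small-sample bias of
  `1 - sum Pi^2`),
* match probability `HMP = sum Pi^2`,
* discrimination capacity `DC = Ndistinct / n`.

`sum Pi^2` is computed as `sum c_i^2 / n^2` in integer arithmetic before a
single division, so spectra derived from counts are exact. `GD` requires
`n >= 2`. Report layers round HD/HMP to 5 decimals and DC to 4, matching
forensic reporting practice; full precision is kept internally.

## Rst by haploid AMOVA

The distance kernel is the sum over loci of squared repeat differences, the
metric under which Rst is the natural differentiation statistic for
microsatellites evolving by stepwise mutation. Microvariant fractions enter
numerically (14.1 vs 14 differ by 0.1); this preserves allele identity
without inventing an exclusion list for intermediate alleles. Multi-copy and
InDel loci are excluded by default (a repeat difference is undefined for an
unordered multiset; InDels are not repeat counts); the locus set is a
parameter. Individuals with a missing or anomalous call at any included
locus are dropped listwise for that comparison.

Sums of squared deviations use the centered-sum identity
`sum_{i<j} d_ij / N = sum_i |x_i - xbar|^2` per locus rather than explicit
pair enumeration; the test suite checks the two routes agree to 1e-9 over
randomized inputs. Components follow the standard haploid layout:
`df_among = P - 1`, `df_within = N - P`, `sigma2_within = MSD_within`,
`sigma2_among = (MSD_among - MSD_within)/n0` with
`n0 = (N - sum n_p^2/N)/(P - 1)`, and
`Rst = sigma2_among / (sigma2_among + sigma2_within)`. Negative Rst —
expected sampling noise when true differentiation is near zero — is reported
as computed and clamped to zero only where a non-negative dissimilarity is
required (the pairwise matrix fed to MDS/NJ). When both variance components
are zero the denominator is zero and Rst is defined as 0 (identical
monomorphic populations). A permutation test (individuals shuffled across
the two labels, sizes preserved, `p = (1 + #{Rst* >= Rst})/(n_perm + 1)`)
accompanies the estimate; it is seeded and reproducible.

## Ordination and tree

Classical (Torgerson) metric MDS: double-center the squared-distance matrix,
eigendecompose, scale the top-k eigenvectors by the square roots of their
eigenvalues. It is chosen over iterative stress-majorization variants for
determinism and testability; on a Euclidean-realizable matrix it reproduces
the input distances exactly (tested to 1e-8). Negative eigenvalues (the
non-Euclidean part of an Rst matrix) are truncated; the eigenvector sign is
fixed by making each axis's first nonzero loading positive; the reported
stress is `sqrt(sum (d - dhat)^2 / sum d^2)` so users can judge the fit.

Neighbor-Joining uses the canonical Q-matrix agglomeration. Ties in Q are
broken by the lowest (row, column) index pair in current label order, making
builds reproducible. A negative branch length at a join is clamped to zero
with the deficit moved to the sibling edge, preserving the pair's summed
length; at the final three-taxon join negative lengths are simply clamped.
On an additive matrix no clamping triggers and NJ provably recovers the
generating topology and branch lengths; the suite verifies this exactly
(1e-9) on randomized trees up to 8 leaves and cross-checks topologies
against scikit-bio's independent NJ. Trees are scikit-bio `TreeNode`
objects; Newick serialization and re-parsing preserve topology (labels with
spaces survive the round trip under the usual space/underscore convention).

## Synthetic data

Two generators with different purposes:

* **Spectrum-constrained sampling** builds a sample whose haplotype spectrum
  is exactly prescribed — e.g. 296 singleton + 8 doubleton haplotypes in 312
  males, the spectrum that forces HD 0.99984 / HMP 0.00337 / DC 0.9744 under
  the formulas above. States are drawn uniformly over the panel's allele
  space with rejection on collision, after a feasibility check that the
  state space can host the requested number of distinct haplotypes.
* **Forward stepwise-mutation simulation**: every lineage descends
  independently from a common founder; each STR copy mutates with
  probability `mu` per generation by ±1 repeat with equal probability (the
  single-step symmetric model — the model under which Rst is the canonical
  estimator; multi-step mutations are out of scope). Defaults are the study
  conditions: 312 males, the 44-marker panel, `mu = 3.35e-3` per locus per
  generation (the accepted average Y-STR mutation rate). 200 generations and
  founder repeats drawn once per locus from 10–25 are chosen as realistic
  for within-population Y-STR variability and repeat ranges. InDel states
  are i.i.d. draws with a major-allele frequency of 0.9, reproducing the low
  (< 0.2) gene diversities such loci show. Microvariants are modelled as
  lineage markers: configured loci carry an inherited fractional offset at a
  configured frequency, mutating in whole steps thereafter. Divergent pairs
  shift population B's founder by `delta` repeats at every STR locus before
  within-population evolution; `delta = 0` reduces to two draws from one
  population.

What the simulation does **not** emulate: a shared coalescent genealogy
(lineages are independent, so haplotype sharing between individuals is rarer
than in real pedigreed populations and DC saturates quickly as markers are
added), mutation-rate heterogeneity across loci, directional or
length-dependent mutation bias, and linkage of the Y haplogroup background.
Passing tests therefore demonstrate correctness of the estimators and their
documented invariances, not calibration of the simulator to any real
population.

## Problem sizes and determinism

Every generator and test is a pure function of an explicit integer seed.
The test suite runs at deliberately small scale — populations of 15–60,
panels of 17–44 markers, 100–200 replicate batches for the Monte-Carlo
checks (the null-Rst mean is required to sit within ±0.02 of zero over 200
split-sample replicates) — sizes at which the brute-force oracles
(all-pairs AMOVA, pairwise-equality grouping) remain exact and cheap.

## Known limitations

* Rst here is the two-population (pairwise) haploid AMOVA; no hierarchical
  (region/population) designs.
* No Fst from allele identity, no confidence intervals on diversity
  statistics, no haplotype-frequency surveying estimators.
* MDS coordinates are defined up to rotation/reflection; only inter-point
  distances are contractual.
* The 44-marker roster ships as a realistic default; laboratories should
  supply their kit's exact locus list via a panel config file.
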