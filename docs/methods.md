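# Methods

This note records the statistical conventions, defaults and design
choices behind `dartpool`, and what the synthetic-data tests do and do
not demonstrate.

## Pooled-call model

Each accession is genotyped as a DNA pool of `pool_size` seedlings
(default 8).  A locus call is one of: 0 (only the reference allele seen),
2 (only the alternative), 1 (both alleles present in the pool), or
missing.  Code 1 is *presence of both alleles*, not individual
heterozygosity; in a selfing crop it indicates that the pooled population
segregates at the locus.  All statistics treat one pool as one
diploid-equivalent sample: the alternative-allele frequency is
`p = (n_het + 2 n_hom_alt) / (2 n_called)`.  This is the only frequency
the pooled matrix supports — the true within-pool allele dose is not
observable from a presence call — and it slightly compresses frequency
extremes for strongly heterogeneous pools.

## Quality filtering

Criteria are applied in a fixed order so per-criterion removal counts are
reproducible: reproducibility (RepAvg ≥ 0.95) → call rate (≥ 0.95) →
MAF (strictly > 0.01) → known chromosome placement.  Filtering is
idempotent and the report counts partition the input.  The MAF comparison
is strict because a threshold of exactly 0.01 must still exclude
monomorphic loci when set to zero.

## Diversity coefficients

* `PIC = 1 − (p² + q²) − 2p²q²` (Botstein's biallelic form; its maximum
  is 0.375 at p = 0.5).  Reports of biallelic SNP panels with PIC above
  0.4 are not reproducible under any standard biallelic PIC — this bound
  is a mathematical property, and we document it rather than adopt a
  non-standard formula.
* `Ho` per locus is the fraction of code-1 calls among non-missing calls;
  per accession, the fraction of code-1 loci (its heterogeneity proxy).
* `uHe = (2n/(2n−1)) (1 − p² − q²)` with `n` = accessions with a
  non-missing call; undefined (NaN) for groups of size 1.
* `F = 1 − Ho/uHe`.  With collection-level coefficients Ho = 0.242 and
  uHe = 0.443 this form gives 0.454, consistent (to rounding) with a
  published value of 0.455 for the same pair, whereas the
  plain-He variant is not; that consistency fixed the convention.

## Substitution spectrum

Loci are classified by the ordered ref>alt pair; transitions are
{A>G, G>A, C>T, T>C}.  Loci with non-ACGT alleles or unplaced
chromosomes are excluded from the table.  `spectrum_to_loci` inverts the
counting step so published count tables can be re-analyzed through the
same code path.

## Sliding windows

Per chromosome of length L, 250 window centers sit at `k·L/251`
(k = 1..250), each window the closed interval ±250 kb clipped to [1, L].
Windows may overlap (they do whenever the spacing is below 500 kb) and a
locus on a shared closed boundary is counted in both — the track is a
smoothed density, not a partition.  With full-length cereal chromosomes
and the default 250 positions the windows do *not* tile the chromosome;
callers wanting exhaustive coverage should raise `n_positions` above
`L / (2·half_width)`.

## Distances, ordination, AMOVA, Mantel

* Jaccard dissimilarity on the codominant binary expansion (two
  presence/absence columns per locus), pairwise-complete over columns
  where both accessions are non-missing.
* Gower dissimilarity: mean over variables of |Δ|/range, zero-range
  variables dropped with a warning.
* PCoA: Gower double centering of −D²/2, `eigh`, coordinates scaled by
  √λ for positive eigenvalues.  Percent explained uses the
  positive-eigenvalue denominator; no Cailliez/Lingoes correction is
  applied by default (Jaccard matrices at this scale are near-Euclidean;
  negative eigenvalues are still reported).
* PCA standardizes with the unbiased (n−1) standard deviation; component
  signs are fixed so the largest-|loading| element is positive.
* AMOVA is the one-level Excoffier partition of squared distances;
  `n0 = (N − Σn_g²/N)/(G−1)`; a negative among-group component is
  truncated to zero and flagged; the p-value permutes whole accessions
  among groups.  The identity SS_among + SS_within = SS_total is exact.
* Mantel is one-sided for positive association, with the
  `(hits + 1)/(n_perm + 1)` convention; 10⁵ permutations are feasible but
  the pipeline default is 10⁴.
* Geographic distance is haversine on a spherical Earth (R = 6371 km);
  geodesic corrections are below 0.5 % at within-country scales.

## Eco-geography

Monthly series use the 11-parameter TerraClimate vocabulary.  States
(tmax, tmin, ws, PDSI) are averaged within a scope; fluxes and totals
(aet, def, pet, ppt, srad, q, soil) are summed.  PDSI is averaged even
though it sits among "total"-style parameters in some published tables,
because it is a dimensionless end-of-month state, not a flux.  The
growing season defaults to November–May (Mediterranean winter-cereal
season) and is configurable; wrapped seasons are credited to the calendar
year in which they end, and only complete scopes enter the aggregation.

Screening runs a one-way ANOVA per parameter across sites with calendar
years as replicates; parameters with p ≥ 0.05 are dropped.  Altitude has
no yearly replication, so it bypasses the screen and is carried into
downstream analyses directly.  Extreme-site groups come from the Tukey
homogeneous letter display: the low group is the letter group containing
the minimum-mean site, provided it excludes the maximum's letters (and
symmetrically for the high group); when letters cannot separate the
tails the selector falls back to the k lowest/highest site means and
logs the decision.

## Unique alleles

An allele is unique to an extreme group when at least one group member
carries it (code 1 counts as carrying both alleles) and no background
accession outside the group shows it in a non-missing call.  The default
background is all landraces with eco-geographical data, and the default
missing policy is `strict` (any missing call outside the group
disqualifies the locus, since the allele could be hidden there);
`lenient` treats missing as absent.  Both are logged per run.  Counts are
reported with multiplicity (per parameter) and deduplicated on
(locus, allele).  Gene lookup clusters records with inter-record gaps
≤ 2 Mb and reports genes within 500 kb of a cluster; both knobs are
configurable and recorded because biologically meaningful cluster extents
vary by two orders of magnitude.

## Generalized Procrustes Analysis

Configurations are zero-padded to a common width, centered, then
iteratively rotated (full orthogonal group, reflections allowed) and
isotropically scaled under the constraint that the total sum of squares
is preserved.  Two numerical choices matter:

* each configuration is rotated to the mean of the *others*; rotating to
  the full mean admits fixed points whose cross-products are indefinite
  (suboptimal alignments), while the leave-one-out target makes the fixed
  point pairwise-Procrustes optimal — for two configurations the result
  equals the closed-form solution `rc = (1 + ρ)/2` with ρ the
  trace-correlation, which the tests verify to 1e-8;
* the scale step solves its subproblem exactly via the leading
  eigenvector of the normalized inner-product matrix rather than a
  one-at-a-time update.

PANOVA attributes discrepancy reduction in the fixed order translation →
rotation → scaling (the order is a reporting convention; it affects
attribution, not the fit) and the four components telescope to the total
exactly.  The consensus test permutes object rows independently within
every configuration but the first.  For the genotype–phenotype analysis
the inputs are the PCoA coordinates of the Jaccard matrix (first 7 axes
by default) and the standardized 7-variable morphometric table.

## Bayesian-clustering post-processing

ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)) over replicate
log-probabilities; endpoints and zero-sd interior points are undefined.
Membership assignment is pure-i iff q_i ≥ 0.8 (inclusive).  The MCMC
itself is out of scope; the readers take plain CSV summaries.

## Synthetic collection generator

The generator emulates the study system whose conventions this package
implements: 63 accessions (48 landrace pools, 15 breeding materials),
9737 placed loci on 7 chromosomes with telomere-enriched density, a
target Ts/Tv of 1.48 (realized binomially), 47 collection sites with
1958–2020 monthly climate, and 129 drought-contrast alleles planted in
windows on 5H and 6H.  Design choices:

* Ancestral allele frequencies are Beta(4, 4) (marker panels are
  ascertained toward intermediate frequencies); gene pools diverge by a
  Balding–Nichols model with `fst_like = 0.13`; pools segregate at a
  locus with probability `h` (0.34 for landraces, 0.04 for breeding
  materials).  These values were chosen so the default collection
  reproduces the magnitudes reported for the real one — mean Ho ≈ 0.24,
  uHe ≈ 0.44, among-status AMOVA ≈ 20 %, mean Jaccard ≈ 0.48.
* Pools are unions of independently drawn gametes; there is no pedigree,
  linkage or selection, so LD-dependent statistics are out of scope.
* Climate correlations arise from one latent site "wetness" factor
  loading on ppt, q, aet and soil (> 0.9 between-site correlations) and
  a negative altitude–tmin tie; tmax, def, srad and pet are
  site-invariant by default so the screening step has a known answer.
  Designated extreme sites are shifted ±6 monthly-noise SD.
* Planted alleles overwrite chosen loci: background accessions become
  homozygous reference and only extreme-group carriers receive the
  alternative allele.  A lone carrier is planted homozygous-alt so the
  allele dose (2 of 2N) survives the MAF > 0.01 filter — with a single
  heterozygous pool the dose (1/126 ≈ 0.008) would be removed by the
  pipeline's own filter and the planted truth would be undetectable by
  construction.  Planted loci carry no missing calls and perfect quality
  metadata.  After planting, the generator scans all other loci and
  breaks any *accidental* group-exclusive allele (by giving one outside
  accession a both-alleles call), so the manifest exactly predicts
  detector output under the strict policy.
* Grain morphometry shifts area, perimeter and length (not width or
  color) between breeding and landrace accessions, matching the pattern
  of significant status differences the morphometric ANOVA is meant to
  detect.

What passing synthetic tests show: the implementations are internally
consistent, calibrated (permutation p-values are super-uniform under
their nulls), and exact where exactness is claimed (detector vs manifest,
GPA vs closed form, AMOVA identities).  What they do not show: behavior
under real DArTseq artifacts (allele dropout correlated with divergence,
batch effects, reference bias), real LD structure, or real climate
autocorrelation — none of which the generator models.

## Problem sizes

The test suite runs scaled-down collections (hundreds of loci, ~30
accessions, ~10 years of climate) chosen to keep the full suite under a
minute while leaving every statistical check well-powered; the
acceptance script runs the full default conditions (9737 loci, 63
accessions, 63 years) in a few minutes on one core.  All stochastic
steps take explicit seeds and reruns are bit-identical.

## Known limitations

* Pooled MAF is diploid-equivalent, not pool-dose; rare-allele
  frequencies are coarse.
* PIC is capped at 0.375 for biallelic markers by construction (see
  above).
* The AMOVA is one-level (among/within); nested designs are not
  implemented.
* GPA requires complete object overlap across configurations; objects
  missing from one table must be dropped before fitting.
* The unique-allele detector is a presence/absence screen, not a
  genotype–environment association model; it makes no claim of
  statistical association, only of exclusivity within the sampled
  collection.
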