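# Methods

This note documents the models, parameter choices and numerical
conventions behind `invscan`, and what the simulation-based tests do and
do not establish.

## Data model and conventions

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with a
MISSING sentinel, indexed by chromosome and 1-based position (VCF
convention). Every sliding window in the package is half-open
`[start, start + W)` on those positions. Phase is ignored throughout:
the method operates on genotypes, not haplotypes, which is what makes it
applicable to imputed low-coverage data. Half-missing genotype calls
(e.g. `./1`) are treated as missing rather than as fractional dosages.

## Filtering and LD pruning

Variants are removed at minor-allele frequency < 0.1 or missingness
≥ 0.5, then samples at missingness ≥ 0.5 (variant-first maximises sample
retention; the two orders differ only for pathological inputs). Pruning
follows the windowed `indep-pairwise` scheme: within 14 kb windows
advancing by 9 kb, pairs with genotypic r² > 0.05 are greedily broken by
removing the lower-MAF member (tie: the downstream SNP), keeping the more
informative marker deterministically. Windows are anchored at each
chromosome's first SNP. The pruning contract is window-scoped: pairs
that never share a 14 kb window can remain correlated — that residual
long-range LD inside inversions is precisely the signal the scan uses.
The 14 kb / 9 kb / 0.05 defaults suit data whose background r² at
~12.5 kb is near 0.1, i.e. the pruned panel is close to linkage
equilibrium at short range.

All pairwise r² computations use pairwise-complete samples (drop samples
missing in either SNP); post-imputation data has little missingness, so
this differs negligibly from casewise deletion while keeping every
statistic well defined.

## PCA and the loading-variance scan

Each chromosome's dosage matrix is standardised per SNP to
`(d − 2p)/sqrt(2p(1−p))` — unit variance under Hardy–Weinberg — with
missing entries set to the column mean (zero after centring) and
zero-variance columns dropped. The decomposition is computed from the
samples × samples Gram matrix (equivalent to the SVD of the standardised
matrix at O(n²m) cost); loadings are unit-norm right singular vectors,
eigenvalues are squared singular values over n − 1, and each component's
sign is fixed by making its largest-|loading| SNP positive. Five
components are scanned by default; inversion signals on real data have
been observed up to the fifth component, and deeper components on these
matrices are noise.

The scan statistic is the unbiased sample variance of a component's
loadings within 10 kb windows stepping 7.5 kb, anchored at the first SNP.
Windows with fewer than 3 loadings carry no value: a variance over one
or two points is too unstable to threshold. A window is flagged when its
variance reaches `max(quantile(values, 0.75), 5 × median(values))`;
flagged windows are chained with up to 2 tolerated gaps, and chains of at
least 10 flagged windows become candidate regions.

The flagging policy quantifies "contiguous high-shifted region", which
has no canonical definition, and all four knobs are exposed in config.
The binding bar under the null is the fold-over-median term: null window
variances are approximately scaled chi-square, so 5× the median sits far
in their tail and structureless chromosomes produce no chains (the null
simulations in the acceptance suite yield zero regions in 20/20 seeds).
The quantile term is a guard for heavy-tailed profiles; it must stay
below the plausible inverted fraction of a chromosome, since an
inversion spanning ~40% of a chromosome lifts ~40% of the windows — a
0.95 quantile would then sit inside the shifted block itself and
fragment the run. 0.75 keeps the guard while tolerating inversions up to
roughly half a chromosome. Comparisons use ≥, so constructed profiles
with exact ties at the quantile are flagged rather than dropped.

## Karyotyping

For each chromosome-component with at least one candidate region, the
top `ceil(0.01 × n_snps)` SNPs by |loading| (chromosome-wide, since the
component is chromosome-scoped; ties broken toward lower position) define
the IBS similarity `IBS(i,j) = mean((2 − |d_i − d_j|)/2)` over
pairwise-complete SNPs. Classical (Torgerson) MDS embeds `D = 1 − IBS`
via double-centring; negative eigenvalues (possible since D is not
guaranteed Euclidean) are clamped to zero, and the k = 1 axis is used for
clustering (k = 2 coordinates are exported for biplot-style diagnostics
only). Axis sign is fixed by the largest-|coordinate| sample.

Fuzzy c-means with c = 3, fuzzifier m = 2, tolerance 1e-6 runs from two
deterministic starts — centers at the 1/6, 3/6, 5/6 quantiles of the
coordinate, and at (min, median, max) — keeping the lower-objective
solution. The second start matters when one homozygote cluster holds
more than half the samples: all interior quantiles then fall inside it,
and the single-start iteration can converge with two centers splitting
that cluster (observed on Hardy–Weinberg draws at q ≈ 0.26 with a
heterozygote-rich realisation). A point exactly at a center receives
crisp membership there.

Genotypes are assigned by maximal membership. Orientation is
frequency-based: the larger flanking (homozygote) cluster is AA, making
the minor-arrangement frequency ≤ 0.5 by construction. A component is
retained only if all three clusters have ≥ 3 samples, the mean maximal
membership is ≥ 0.8, and the middle center's relative position between
the flanking centers lies in [0.3, 0.7] (a Hardy–Weinberg inversion
yields ≈ 0.5). These thresholds quantify "three well-defined groups";
failing components are reported with the failed criterion, and all three
knobs are configurable. Summaries are `q = (2 n_BB + n_AB)/2n` and
`F = 1 − H_obs/H_exp` (0 when `H_exp = 0`).

## Coordinate estimation

Karyotypes coded 0/1/2 serve as a quantitative phenotype in per-SNP
simple linear regression on dosage over pairwise-complete samples, with
a two-sided t-test on the slope. (For simple OLS the t statistic is
symmetric in predictor and response, so the regression direction is
presentational.) Monomorphic SNPs get β = 0, p = 1 and are excluded from
the Bonferroni denominator, which is the number of polymorphic SNPs on
the scanned chromosome — the scan is per chromosome-component.
Significant SNPs (adjusted p < 0.05) are single-linkage clustered with a
1 Mb gap threshold; the largest cluster (tie: larger span) spans the
estimate. Clustering tolerates stray significant SNPs elsewhere on the
chromosome; on contiguous signals the estimate is insensitive to the gap
parameter over a wide range. Breakpoint-nucleotide precision is out of
scope: the estimate tracks the recombination-suppression footprint.

## LD profile

All SNP pairs within 12 kb (configurable to a [min, max] band, e.g.
12–13 kb) get genotypic r² — squared Pearson correlation of dosages —
computed lag-by-lag over the sorted position vector, which enumerates
exactly the brute-force pair set. Pairs are assigned to windows of 0.5%
of the chromosome length (step half a window) by midpoint; windows with
< 5 pairs carry no value; the window value is the median r². The
corroboration statistic is the Spearman ρ (average ranks for ties)
between windowed median r² and the mean |loading| of the candidate
component over the same grid, significant at p < 0.05.

## Inversion-pair tests

All pairs of retained inversions are tested for karyotype dependence on
shared samples: Spearman correlation of the 0/1/2 codes (each under its
own orientation) with Benjamini–Hochberg adjustment across all pairs in
the run (one family), significant at FDR ≤ 0.05; plus an asymptotic
chi-square test, no continuity correction, on the genotype contingency
table with zero-margin rows/columns dropped. Pairs sharing fewer than 10
called samples are flagged and excluded from the FDR family.

## Simulator

The simulator generates a single chromosome at the genotype level:

* SNP positions uniform at `snp_density_per_kb` (default 2.2/kb; after
  pruning a recovery dataset retains ≈ 1.7–2/kb);
* karyotypes `k ~ Binomial(2, q)` per sample (Hardy–Weinberg);
* outside inversions, an ancestral frequency `p ~ U(0.1, 0.5)` per site
  and dosage `Binomial(2, p)`;
* inside an inversion, a fraction `divergence` of sites are near-fixed
  between arrangements (standard-arrangement frequency ε = 0.02,
  inverted 1 − ε); the remaining sites draw each arrangement's frequency
  from a Balding–Nichols Beta around the ancestral value with
  differentiation `fst_drift` (default 0.2), giving the intermediate-LD
  within-arrangement background that makes loadings — not only fixed
  differences — informative. Dosage is
  `Binomial(k, p_inv) + Binomial(2 − k, p_std)`, so heterokaryotypes are
  maximally heterozygous at divergent sites;
* a genotype-error rate `e` replaces calls with uniform draws from
  {0, 1, 2}; e ≈ 0.08–0.15 reproduces the ~85–92% genotype-concordance
  regime of imputed ~2× sequencing, and e = 0.1 is the default; a
  missing rate (default 0, as imputation returns complete matrices) can
  be layered on top. Everything is deterministic given the seed.

What the simulator does **not** model: read-level error structure and
its MAF dependence, linked ancestry/recombination maps within
arrangements (sites are conditionally independent given karyotype),
selection, nested or overlapping inversions, and cross-chromosome
structure. Passing recovery tests therefore demonstrate that the
pipeline extracts the statistical footprint the method targets —
arrangement-stratified allele frequencies under Hardy–Weinberg with
realistic genotype noise — not performance on any particular organism's
LD landscape.

## Test problem sizes

The acceptance suite simulates 20 recovery and 20 null datasets of 200
samples × ~44,000 SNPs (20 Mb at 2.2/kb) — large enough that the
quantile-based detection thresholds and the FCM cluster geometry operate
in their intended regime, small enough that the full 40-run sweep
completes in a few minutes on one CPU. Unit tests use a 3 Mb / 120
sample dataset with stronger divergence (0.6) for single-seed stability.
`scripts/acceptance.py` defaults to 10 runs per condition (`--runs`).

## Known limitations

* Overlapping or nested inversions are not modelled and, on real data,
  would appear as overlapping candidate regions on different components;
  disentangling them is left to the analyst.
* The association-based coordinate estimate inherits the marker density:
  expected edge offsets are on the order of the inter-marker spacing of
  karyotype-correlated SNPs, and real-data offsets of hundreds of kb are
  plausible near breakpoints where divergence decays.
* One Spearman ρ is reported per retained chromosome-component; when
  several components on one chromosome are retained the per-component
  values are strictly more informative than a single per-chromosome
  number, and downstream consumers may collapse them as needed.
* Genome-wide (cross-chromosome) PCA, relatedness correction and
  haplotype-aware statistics are out of scope.
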