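# Methods

## Autozygosity likelihood model

A site with reference-allele frequency `f_A` (alternate `f_B = 1 − f_A`)
and error/mutation rate `ε` contributes a log10 likelihood ratio of
autozygosity (X = 1) versus non-autozygosity (X = 0):

* homozygote AA: `log10(((1−ε) f_A + ε f_A²) / f_A²)` — positive, largest
  for rare alleles;
* heterozygote: `log10(ε)` — a constant penalty;
* missing: 0.

The quadratic homozygote term makes the three genotype probabilities sum
to one under both hypotheses for every `f_A` and `ε` (a property the test
suite asserts on a grid and under hypothesis-generated inputs). Genotype
codes only are used — phase is never required by the likelihood.

Frequencies are estimated by resampling 100 alleles with replacement per
site (implemented as a binomial draw at the observed frequency, which is
distributionally identical), giving every population the same frequency
resolution regardless of sample size. When a carried allele receives a
resampled frequency of zero, that site is treated as missing for its
carriers. Sites with all genotypes missing contribute zero everywhere.
With per-genotype error estimates (sequence data; `ε = 1 −` likelihood of
the called genotype, GQ convention `10^(−GQ/10)`), the per-genotype value
replaces the global `ε` site-by-site.

## Window scores and weights

The unweighted LOD score of a K-SNP window is the plain sum of per-site
ratios. The wLOD score multiplies each site's ratio (positive or
negative — the heterozygote penalty is weighted identically, following
the estimator's definition) by three factors:

1. **LD redundancy**: `1 / Σ_l r²(k,l)` over the window's sites,
   self-term included, hence bounded in `[1/K, 1]` (clipped after
   floating-point evaluation). r² comes from phased haplotype indicators
   when phase is available, else from genotype dosages (composite LD),
   from a without-replacement subsample of 55 individuals per pair
   (everyone, when the population is no larger). Pairwise r² is stored
   banded — only pairs co-occurring in a window — never as a full S×S
   matrix. A single frequency table and a single LD store serve all
   window sizes.
2. **Recombination gap weight** `exp(−2M Δg)` and
3. **mutation gap weight** `exp(−2M μ Δp)`, both over the gap to the
   preceding genotyped SNP on the chromosome (window-independent, so
   overlapping windows score consistently); the first SNP of a chromosome
   has weight 1. `M` is the assumed minimum number of meioses to the
   shared ancestor: it defaults to 7 for real-data calls (a conservative
   human-population value) and to the pedigree-derived values 3/4 in the
   scenario-1/2 benchmarks.

Windows slide by one SNP (each interior SNP sits in exactly K windows)
and never span chromosome boundaries. The scan kernel (numba) maintains
the window LD denominators incrementally, so a full scan is
O(S·K·N_individuals); an independent brute-force implementation verifies
it to 1e−10 on small panels.

## Threshold selection

Pooled window scores of all analysed individuals (at least 10
recommended; a panel with more than 5×10⁶ windows per individual is
subsampled to 20 random individuals to bound KDE memory) are summarised
with a Gaussian KDE (statsmodels FFT implementation, Silverman
bandwidth, 4096-point grid). Local maxima with prominence below 1% of
the density maximum are ignored, and adjacent maxima whose separating
valley exceeds 50% of the lower peak are merged into one mode — our
formalisation of the "clear" multimodality that is otherwise judged by
eye; without the merge rule, KDE ripple on coarse panels occasionally
split the non-autozygous mass in two and the threshold landed inside it.
The calling threshold is the density minimum between the non-autozygous
mode and the (left-most) autozygous mode. In trimodal distributions the
minimum between the two autozygous modes additionally separates
endogamy-like from consanguinity-like windows, and each ROA is labelled
by the proportion of its windows above that minimum (> 0.8
consanguinity-like, < 0.1 endogamy-like, otherwise mixed).

Window size can be chosen automatically: the largest K in a grid whose
pooled distribution stays multimodal (ROA-calling mode), or the K
maximising the distance between the non-autozygous and autozygous modal
scores (group-contrast mode). For routine use the fitted density rules
`K = 16.400 ln(D) + 218.020` and `fraction = 0.0736 ln(D) + 0.8063`
(D in SNVs/bp; K clamped to ≥ 20, fraction to [0, 0.5] because the lines
go negative at extreme densities) give platform guidance without a scan.

## ROA assembly, classification, evaluation

A SNP is in-ROA when the fraction of its *existing* covering windows
(fewer near chromosome ends — using the true count keeps edge SNPs
reachable) scoring above threshold exceeds the overlap fraction; maximal
runs form ROA, with boundaries at the first/last in-ROA SNP. At fraction
0 this reduces to the union-join of above-threshold windows. Genetic
lengths come from interpolated boundary positions on the genetic map.

Classification fits Gaussian mixtures (free weights, means, variances;
scikit-learn EM, 10 initialisations, fixed seed) to ROA genetic lengths
in cM (physical length is an option, but genetic length is preferred:
map-length classes stay discrete where physical-length classes blur),
selects the component count in 1..10 by BIC, orders components by mean
and assigns maximum-posterior labels, so the largest label is the
longest (most recent) class. At least 25 individuals are recommended for
stable classification; fewer triggers a warning, as does threshold
estimation from fewer than 10.

Against simulated truth we report: power = overlapped true length /
total true length (optionally restricted to true segments above a length
floor); false-discovery = inferred length not overlapping truth / total
inferred length; per-detected-segment length ratios (union of
overlapping inferred calls over true length); and counts of
false-positive ROA (no true overlap) and false-negative true segments
(below the 1 bp minimum-overlap default, which is configurable). The
optimal-parameter search scans K (50–130 by default) × overlap fraction
(0–0.5 by 0.05) and returns the lexicographically smallest pair with
zero false-positive ROA and a **length-weighted** ratio within 0.05 of
one. The unweighted per-segment mean ratio is reported but not used for
selection: under our truth model (below) it is dominated by very short
true segments swept up by window-scale calls (individual ratios of
10–100) and approaches 1 nowhere on the grid, which would degenerate the
selection to the largest fraction; the length-weighted form preserves
the intent — no spurious calls, accurate boundaries — while remaining
attainable. When no cell qualifies, the best-effort cell (fewest false
positives, then ratio closest to one) is returned and flagged.

The naive genotype-counting baseline flags 50-SNP windows with at most
2% heterozygous and 5% missing genotypes (boundary inclusive) and
assembles them identically at fraction 0.

## Differential autozygosity

Per window, a one-sided Wilcoxon rank-sum statistic (mid-ranks for ties)
compares the two groups' per-individual scores, in both directions.
Significance uses a genome-wide max-statistic null: 1000 label
permutations (group sizes preserved; ranks computed once, since label
permutation leaves them unchanged), each recording the maximum statistic
across all windows per direction. `P_perm = (1 + #{max ≥ observed}) /
(n_perm + 1)` — the add-one convention keeps P off zero and counts ties
against significance; permutation maxima are recorded separately per
direction. Overlapping windows with `P_perm ≤ α` (default 0.05) merge
into enriched regions reported with window count and minimum P. On
exchangeable inputs the family-wise rate of any window reaching 0.05 is
controlled at ~5% (verified over 200 simulated null datasets).

## The simulator

One chromosome of physical length `(g_max[cM]/θ) Mb` is built from an
Mb-spaced backbone of sorted Uniform(0, g_max) genetic positions (ends
pinned at 0 and g_max so the map spans its nominal length), predetermined
SNVs placed uniformly at distinct base pairs with genetic positions drawn
inside their backbone interval (kept monotone), and every other base pair
interpolated — a non-uniform cM/Mb profile like a real chromosome.
Defaults: g_max = 3.25 Morgans, θ = 1.3 cM/Mb (250 Mb), μ = 1.18e−8,
both rates scaled ×10 during the run to boost end-point diversity;
725,000 (scenario 1) or 650,000 (scenario 2) predetermined SNVs.

Scenario 1: N_e = 75, 150 non-overlapping generations, exactly one
migrant individual per generation replacing a random offspring (the
simplest reading of "approximately one migrant per generation"); migrant
haplotypes are fresh founder-style draws. Scenario 2: N_e = 500, 100
generations, closed. Each offspring draws two distinct parents uniformly
(selfing excluded). Per gamete: Poisson(scaled g_max) crossovers without
interference, positions uniform on the genetic map and mapped to bp;
Poisson(scaled μ × L) de novo mutations at uniformly drawn unused base
pairs (an infinite-sites approximation — collisions are redrawn).
Founder haplotype alleles are independent Bernoulli draws at per-site
frequencies Uniform(0.05, 0.95) — the reference construction is not
specified anywhere, so this is a documented modelling knob. Haplotypes
are tracked as founder-copy mosaics, so true autozygous segments (equal
founder copy on both homologs) are exact, with ends at crossover
breakpoints; all segments are reported, with length filtering left to
the evaluator. The pedigree record yields each sampled individual's
parental-MRCA depth (mean ≈ 3 generations under scenario 1, matching
the intended demography). Genotyping errors flip each genotype to a
uniformly chosen different state at rate 0.001; density thinning is a
uniform site subsample. Identical seeds reproduce panels bit-for-bit.

### Benchmark problem sizes

Benchmarks and the acceptance script run the simulator at 1/10
chromosome scale — 25 Mb, 72,500 predetermined SNVs, thinning targets
scaled identically (12,500 / 8,000 / 5,000 / 1,800 sites) — which
preserves SNV density (the quantity the method's operating
characteristics depend on), per-meiosis event rates per Morgan, the
demography and the error model, while keeping a three-replicate,
three-caller benchmark grid in the minutes range. The acceptance script
uses 3 replicates; the test suite 1.

### What the synthetic benchmark does and does not show

The simulated panels reproduce several published composition statistics
(≈ 4% of polymorphic SNVs de novo; parental MRCA ≈ 3 generations;
per-meiosis crossover counts at the scaled map length), and full-density
power, long-ROA power and caller ordering behave as expected. Two
divergences are documented and deliberate:

* **Truth composition.** With this founder model and migration scheme,
  the exact founder-mosaic truth is dominated by short background-IBD
  segments (median ≈ 57 kb; only ≈ 37% of true length in segments
  > 1 Mb). Overall length-weighted power at sparse densities is
  therefore bounded far below what a long-segment-dominated truth set
  would give — at 14 kb marker spacing no window method can see a 50 kb
  segment. Reported overall power at the lowest density (~35–55%) is a
  property of this truth definition, not of the estimator; power
  restricted to segments > 1 Mb (> 99% at full density, ~90% averaged
  over thinned densities) is the robust quantity.
* **Rare-variant fraction.** 150 generations of drift at N_e = 75
  flattens the predetermined-SNV frequency spectrum, leaving ≈ 13–15% of
  polymorphic sites below 5% MAF in the sampled panels. No variant of
  the described founder/migration model concentrates the spectrum enough
  to reduce this several-fold, so the statistic is reported as measured.

Simulated LD also lacks the structure of real populations (admixture,
bottlenecks, selection), so the wLOD–LOD gap on synthetic panels is
small and can invert within parameter-selection noise; the LD correction
is expected to matter most on real data.

## Numerical and policy choices

* Internal coordinates are 1-based inclusive; BED output is 0-based
  half-open. True segments are half-open [start, end) bp intervals.
* Windows above threshold means strictly greater; coverage above the
  overlap fraction is strictly greater (so fraction 0 requires ≥ 1
  window).
* KDE: Silverman bandwidth, 4096-point grid, 1% prominence floor, 50%
  valley merge rule (all configurable).
* GMM: `reg_covar = 1e−6`, components skipped when fewer than 2G ROA.
* Optimal search ratio tolerance 0.05 (length-weighted), "smallest"
  means lexicographic in (K, fraction).
* Every stochastic step takes an explicit seed; CLI runs log their
  parameters and seeds to the JSON report.

## Limitations

Biallelic SNVs only (multi-allelic and indel records are skipped, not
decomposed); no X-chromosome model; no HMM-based calling; no haplotype
phasing (phase is consumed, never inferred); the simulator models a
single chromosome without crossover interference or selection. Group
discovery (clustering) is out of scope for the contrast test — groups
are supplied by the user.
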