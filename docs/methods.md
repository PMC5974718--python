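# Methods

## The scan statistic

For a biallelic SNP with allele frequencies `p1`, `p2` in two populations,
the package uses Wright's frequency-only two-population fixation index

    Fst = var(p) / (p̄ (1 − p̄)),   p̄ = (p1 + p2) / 2,

with `var` the population (divide-by-two) variance, which reduces to the
closed form `(p1 − p2)² / (4 p̄ q̄)`. The sample-variance alternative
(divide-by-one) would double every value and exceed 1 at fixed differences,
so the population form is used; it is bounded in [0, 1] by construction. The
"pooled minor allele" orientation (flip both frequencies when their mean
exceeds 0.5) is applied for interpretability, but the expression is
algebraically invariant to which allele is counted, so the orientation never
changes the value — `wright_fst` is symmetric in the pair and in the allele
labels, and the test suite asserts both. A marker monomorphic across the pair
(denominator zero) scores 0 rather than undefined so that windows stay dense.

ΔFst is the per-SNP difference `Fst(pair B) − Fst(pair A)`, averaged over
sliding windows of `window_size = 5` consecutive SNPs. Windows advance one
marker at a time (step 1) and never span a chromosome boundary; a chromosome
with fewer than five retained markers contributes no windows. Each window
also records its strongest single SNP. Since each per-SNP value lies in
[0, 1], every windowed ΔFst lies in [−1, +1], with the extremes attainable
only when one pair is fully differentiated at all five SNPs while the other
is identical.

Candidate windows are chosen greedily by descending window mean; a candidate
is discarded when it overlaps, or lies within `prune_distance_bp` (default
1 Mb, configurable) of, an already-chosen window on the same chromosome.
This collapses runs of overlapping windows over one linked signal into a
single representative — without pruning, a strong locus would occupy all top
ranks by itself. Ties are broken by (chromosome, start) for determinism.

## Quality control and relatedness

Marker QC applies four filters in a fixed order — call rate < 0.99 over the
analysed breed pair, pooled minor allele frequency < 1e-5, zero non-missing
calls in either breed of the pair ("not common between the breeds"), and
X-chromosome membership — attributing each marker to the first filter that
removes it, so the report's counts plus the remainder always equal the input
count and a second pass removes nothing. At the default threshold the MAF
filter only strips markers monomorphic in the pair. Samples are never
filtered here; the relatedness check is a separate step.

Pairwise relatedness is the method-of-moments PI_HAT
(`P(IBD=2) + P(IBD=1)/2`) solved from identity-by-state counts, as in
PLINK's `--genome`. Allele frequencies come from the panel itself, so the
expected IBS proportions use falling-factorial (finite-sample) corrections;
with plug-in frequency powers the estimator is noticeably biased upward at
panel sizes in the tens. PI_HAT is assembled from the raw moment estimates
and clamped to [0, 1] only at the end — clamping each IBD-state proportion
first would make truly unrelated pairs average positive. Markers on the X,
markers fixed in the panel and markers with fewer than four observed alleles
are excluded. Pairs above 0.25 are flagged for removal, the conventional
ceiling excluding first-degree relationships.

## Trait transforms and the association model

Earnings-type traits are transformed `ln(x + 1000)` after converting
Norwegian amounts to SEK at the long-run mean rate 0.95; best race times
(seconds per km) are transformed `ln(x − 68.2)`, with 68.2 s/km acting as a
physiological lower bound (a recorded time at or below it is a domain error
naming the horse); counts and frequencies are transformed `log10(x + 1)` —
the +1 shift is needed because many raced horses have zero wins, where a
plain log10 is undefined. Horses without a time record for a start method
drop out of that trait's model only.

Each transformed trait is fitted by a single OLS model with the candidate
genotype as an unordered 3-level factor plus fixed effects of sex, age,
country and DMRT3 genotype (also unordered 3-level: the gait locus's classes
act distinctly, not additively). The number-of-starts covariate enters for
career totals (wins, placings, earnings) and is omitted for per-start rates,
time records, and the starts trait itself. The three pairwise genotype
contrasts are linear-contrast t-tests within that one fit — equivalent to
subset refits under homoscedasticity, and antisymmetric in the pair by
construction. P-values are nominal; no multiple-testing correction is
applied, and reports should say so.

Two-locus D′ and r² are computed from EM-estimated haplotype frequencies
(the k-locus machinery at k = 2): `D = p_AB − p_A p_B`, `D′ = |D| / D_max`,
`r² = D² / (p_A p_a p_B p_b)`. A marker monomorphic in the panel makes both
undefined (flagged, not raised).

## EM haplotype estimation and regression

Unphased genotypes over an ordered window of up to 12 SNPs (the full
2^k-enumeration bound) are resolved by classical EM: each individual's
compatible haplotype pairs are enumerated (2^(h−1) resolutions for h
heterozygous sites), the E-step weights pairs by `2 f_i f_j` (or `f_i²`),
and the M-step re-estimates pool frequencies from expected pair counts.
Initialisation is uniform over the observed-compatible haplotypes, making
results deterministic and independent of individual ordering; the seed
argument is reserved for optional random restarts, none of which are taken
by default. Convergence is declared when the largest frequency change drops
below `tol` (default 1e-6); hitting `max_iter` logs a warning with the last
delta instead of raising. The log-likelihood is recorded per iteration and
is non-decreasing, which the tests assert; with phase-unambiguous data EM
reproduces direct counting exactly. Individuals with any missing call inside
the window are excluded from both EM and the regression — the simplest
defensible rule, at the cost of a smaller analysis set than methods that
marginalise over missing genotypes.

Expected haplotype dosages (posterior-weighted copy counts, summing to 2 per
individual) enter an OLS regression of the transformed trait on all
haplotypes above the rare threshold (default 2%, applied to the converged
frequencies) except the most frequent one, which serves as the base;
frequency ties for the base are broken lexicographically and logged. Rare
haplotypes are excluded from the design entirely rather than pooled.

## The synthetic-data generator

The generator exists so that every stage has data with the structure the
analysis assumes, at study-like sizes.

* **Breed divergence.** Ancestral frequencies are uniform on (0.05, 0.95);
  each breed's frequencies are Beta-distributed around them under the
  Balding–Nichols model, whose drift parameter is that breed's Fst against
  the ancestor. Genotypes are Hardy–Weinberg within breed. The default
  drift triplet (0.071, 0.099, 0.280 for trotter/draught/Standardbred) is
  calibrated so the genome-wide mean pairwise Wright Fst matches the
  published levels 0.082 / 0.041 / 0.088; the calibration inverts
  `t ≈ s (1 − 0.42 s) / (4 − s)` with `s` the pair's drift sum (the first
  factor is the ratio-of-expectations term, the 0.42 an empirical
  second-order correction fitted once against large simulations, accurate to
  ~1% relative for s ≤ 0.6). Calibration is verified against the
  generator's *true* breed frequencies: observed-frequency Fst at 11/19/12
  samples per breed additionally carries ~1/(2n) finite-sample inflation,
  just as the published values themselves do.
* **Scan-scale defaults** are the study conditions: 11/19/12 horses,
  5,000 markers over 5 chromosomes at ~72.5 kb mean spacing.
* **Implanted selection signature.** A 5-marker span (a full scan window) on
  one chromosome is set to the frequency triplet (0.80, 0.15, 0.75) —
  racing breeds alike, draught breed divergent — patterned on the focal
  region's reported frequencies. A single-SNP implant would be diluted 5:1
  by the window mean; the span-wide implant makes the signature's window
  rank first in ≥ 90% of replicates, which the acceptance suite checks.
* **LD block.** Seven chromosome-22 SNPs are generated by sampling whole
  haplotypes from the published four-haplotype pool
  (TGTAAAG/GGTAAAA/TTCGGGA/GTCGGGG at 0.34/0.33/0.19/0.12, renormalised from
  their printed two-decimal sum of 0.98), inducing the strong within-block
  LD the haplotype stage expects. The third SNP is the focal marker
  (C/T with T ≈ 0.67 in trotters).
* **Phenotypes.** A standardised latent performance score per trait carries
  fixed covariate effects (sex, age, country, DMRT3) plus a recessive
  penalty of `genotype_effect` (default −0.5 latent SD) for focal-SNP
  `allele_a` homozygotes — the CC class. Each recorded trait is the inverse
  of its normalising transform applied to an intercept + scale × latent
  value, with intercepts/scales chosen once for realistic Swedish trotting
  careers (median ≈ 25 starts, median earnings near 80 kSEK, best times
  around 90 s/km); earnings are floored at 0, starts at 1, and wins ≤
  placings ≤ starts holds by construction (wins and extra placings are
  binomial in the starts). Time records get 10%/15% injected missingness
  (volt/auto); Norwegian horses (20%) are recorded in NOK. No effect size
  for the penalty is published on any transformed scale; the default is
  chosen for detectability at n = 400, not to match reported trait means.

What the generator does **not** emulate: pedigree structure and cryptic
relatedness within breeds, realistic recombination maps or background LD
outside the implanted block, genotyping error, ascertainment bias of array
SNPs, and selection acting over generations. Passing tests therefore show
the statistics behave correctly under their own assumptions, not that those
assumptions hold in any particular real dataset.

## Numerical and interface choices

* Missing genotypes are a distinct code (−1), never conflated with dosage 0;
  PED "0 0" maps to it on read and back on write.
* PED/MAP files carry no allele-coding metadata, so reading adopts the
  first-observed convention (first allele seen is `allele_a`); panels have a
  `canonicalized()` form on which write→read is the exact identity, and
  re-coding preserves all frequencies. Merging matches markers by id
  (intersection), detects swapped allele coding and flips dosages `2 − x`;
  pairs that neither match nor swap — including apparent strand flips — are
  conflicts, never guesses.
* Coordinates are 1-based inclusive, as in MAP files. Horse chromosome 23
  is autosomal (the DMRT3 chromosome); only literal "X"/"x" labels are
  treated as the X.
* All simulations derive their streams from `numpy`'s `SeedSequence` on the
  config seed, so every output is bit-reproducible.
* Problem sizes used by the test and acceptance runs — 5,000-marker panels
  for scan replicates, 2,000 markers for the windowed-range check, n = 400
  horses and 100–200 replicates for the association properties — were
  chosen as the smallest sizes at which the binomial/Monte-Carlo noise is
  comfortably inside the asserted margins.

## Known limitations

* The frequency-only Wright Fst has no sample-size correction
  (Weir–Cockerham/Hudson estimators are out of scope by design), so scan
  values at 11–19 animals per breed are upward-biased relative to
  population parameters; the ΔFst contrast partially cancels this.
* Window significance is not assessed (no permutation machinery); ranking
  and the 0.25 descriptive bound are the only selection criteria.
* The haplotype regression treats EM dosages as fixed covariates, ignoring
  phase-uncertainty variance, as haplo.stats-style GLMs do.
* The EM enumeration bound (k ≤ 12) is deliberate; larger windows need
  phasing methods this package does not provide.
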