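# Methods

## Scope and data model

The package analyses diploid genotypes of two closely related populations
(the reference use case is 9 northern + 4 southern white rhinoceros genomes
at 10–15×).  All statistics operate on a `VariantTable`: a sites × samples
genotype matrix (allele indices, −1 for missing) with per-site metadata
(alleles, site quality, a rank-sum bias p-value, an alternate-support count,
indel flag) and declared scaffold lengths.  Sites absent from the table are
assumed homozygous-reference, so per-bp proportions are always taken over a
callable genome length (defaulting to the total scaffold length), never over
the number of records.  Missing annotations are stored as NaN and are never
conflated with 0.

## Hard filtering

Five rules are applied in a fixed order: (1) non-indel variants within 3 bp
(inclusive, POS distance — the `bcftools --SnpGap` convention) of an indel;
(2) in each transitive cluster of indels ≤ 10 bp apart, all but one indel
(survivor = highest QUAL, ties toward the smaller position; the calls
themselves only require that one passes); (3) QUAL < 10; (4) rank-sum
p < 0.1 and QUAL < 15; (5) alternate support < 2 and QUAL < 15.  A record
matching several rules is removed once and attributed to the first matching
rule, making the report deterministic and conservative
(input = passed + Σ removals).  A rule whose annotation is absent on a
record never removes that record.  Which INFO keys carry the rank-sum
p-value and the support count varies between callers, so both are
configuration options (`ranksum_key`, default `RPB`; `alt_support_key`,
default `ANC`); "support" is read as the count of high-quality
alternate-supporting observations in the `samtools varFilter -a` sense.
Filtering is idempotent: cluster survivors cannot form new clusters
(clusters are separated by more than the gap), and variants near removed
indels were already removed alongside them.

## Diversity statistics

* **Heterozygosity** — per individual, the count of genotypes with two
  distinct non-missing alleles divided by the callable length.
* **Divergence** — d<sub>xy</sub>: each diploid genotype is an allele
  frequency p ∈ {0, ½, 1}; a site contributes p₁(1−p₂) + p₂(1−p₁) to a
  cross-population pair, and d<sub>xy</sub> is the mean over all pairs of the
  per-pair sums divided by the callable length.  "Average total genetic
  divergence" is ambiguous between d<sub>xy</sub>, net divergence and
  consensus differences; d<sub>xy</sub> is implemented and labelled as such.
  Note that two individuals with identical genotypes have d > 0 wherever
  both are heterozygous (each draw of one allele per individual differs half
  the time); d = 0 identity holds only for homozygous genotypes.
* **SNP partition** — per biallelic site, each population's alternate-allele
  frequency over non-missing alleles classifies the site as polymorphic in
  both (0 < f < 1 in both), fixed in both (f = 1 in both), unique to one
  population (f > 0 in it, f = 0 in the other), or invariant.  These four
  classes are not exhaustive: a site can be fixed in one population while
  still polymorphic in the other; such sites get an explicit fifth class
  (`fixed_one_polymorphic_other`) so that the categories are mutually
  exclusive and collectively exhaustive.  Sites with one population entirely
  missing, and multiallelic sites, are skipped and counted.
* **Joint SFS** — counts of sites by (alt alleles in population 1, alt
  alleles in population 2) over a fixed sample subset; sites with any
  missing genotype in the subset are excluded and counted.  The spectrum is
  polarized on the reference/alternate axis (no outgroup is modelled);
  minor-allele folding is available since published spectra do not always
  state their polarization.  Output uses the ∂a∂i plain-text layout with the
  absorbing corners masked.
* **LD thinning** — PLINK-style greedy pruning on unphased dosages
  (composite LD): within a 50-SNP window advanced 10 SNPs at a time, the
  later SNP of any surviving pair with squared Pearson correlation > 0.1 is
  removed ("later" is a deterministic tie-break; monomorphic SNPs have
  undefined r², treated as 0).

## Runs of homozygosity

Heterozygous genotypes of one sample are counted in overlapping windows
(1 Mbp, 200-kbp step; windows start at every multiple of the step and are
truncated at scaffold ends).  A window is ROH when its heterozygosity *rate*
is below 0.0004/bp — the rate form (rather than the raw 400-count) keeps
truncated end windows comparable.  The published procedure selects this
threshold from heterozygosity density plots; here it is an explicit
configurable constant.  Consecutive ROH windows merge into runs (run start =
first window start, run end = last window start + window, clipped), so k
full windows span 1 Mbp + (k−1)·0.2 Mbp; runs that still overlap genomically
(an isolated above-threshold interior window) are union-merged so a sample's
runs never overlap.  F<sub>ROH</sub> is the union length of runs divided by
the genome length.

**Boundary refinement.**  With background heterozygosity h and threshold t,
a window overlapping a zero-heterozygosity tract by fraction x is called ROH
when (1−x)·h < t; at h = 0.001 and t = 0.0004 this means x > 0.6, so raw
window-union boundaries systematically overshoot the true tract edge by up
to 0.4 Mbp.  `refine_roh_boundaries` therefore trims each run to its longest
heterozygote-free interior interval: the autozygous core contains no
heterozygotes while the overshot flanks do, so the refined boundary error is
set by the background heterozygote spacing (≈ 1/h ≈ 1 kbp), well inside one
window step.  The pipeline applies refinement by default (`roh_refine`);
the window-convention runs remain available for comparison with
window-counting conventions.

## Selection scan

Per non-overlapping 50-kbp window over the scan population (the first panel
population by default, i.e. the 9-individual NWR-like sample): S counts
biallelic sites segregating within the subset; θ<sub>W</sub> accumulates
1/a₁(n) and θ<sub>π</sub> accumulates 2j(n−j)/(n(n−1)) per segregating site
with j the alternate count and n the haplotypes actually observed at that
site (per-site n avoids biasing S and θ<sub>π</sub> downward under
missingness; constants a₁, a₂ … e₁, e₂ are cached per n).  Tajima's
D = (θ<sub>π</sub> − θ<sub>W</sub>)/√(e₁S + e₂S(S−1)) uses the lower median
of the per-site n over the window's segregating sites (a fixed n can be
configured); D is reported absent when S = 0 or the variance term is ≤ 0.
Both θ estimators need allele counts only, so phasing is never assumed.

Outliers are taken two-tailed at 1% per tail (the published account uses the
plural "1% quantiles" and discusses both balancing and positive selection);
cutoffs are linear-interpolation quantiles (numpy default, identical to R's
type 7, matching the original analysis in R), ties at a cutoff are included,
and adjacent same-tail windows merge into regions.  Coding SNPs are SNPs
inside both an outlier region and a gene interval (transcript spans from BED
or GFF3; CDS-only analyses can pass `feature_types=("CDS",)`), classified by
population frequencies as fixed-in-one (f = 1 vs f < 1), fixed-in-both, or
polymorphic.  Gene intervals extending beyond declared scaffold lengths
raise an error, which catches 0- vs 1-based coordinate mix-ups.

## Synthetic data

The generator emulates the study design, not sequencing: two diploid
populations (9 + 4 by default) with independent sites.

* Ancestral alternate frequency p ~ U(0.05, 0.95); population frequencies
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation F
  (default 0.1, a typical mammal-subspecies value consistent with two
  well-separated but recently diverged clusters; F = 0 keeps both at p).
  Genotypes are binomial(2, f) per individual, unphased.
* Expected heterozygosity per segregating site is 2p(1−p)(1−F), which
  integrates in closed form over the uniform ancestral range; the site
  density is derived from this so that a target per-bp heterozygosity
  (default 0.001, the white-rhinoceros magnitude) is hit in expectation.
  The binomial standard error √(h(1−h)/L) is exact enough for recovery
  tests because the compound (Poisson site count × beta frequency) variance
  is strictly smaller.
* ~1% of records are indels (insertions and deletions in equal proportion);
  indels and all deliberately invalid records are placed at positions
  isolated by ≥ 26 bp so that the five filter rules never interact except
  where engineered.  Per rule, a configurable fraction (default 0.002) of
  records is constructed to violate exactly that rule and is recorded in the
  truth set, making the filter report exactly checkable.  Clean records draw
  QUAL ~ U(20, 60), rank-sum p ~ U(0, 1) and a support count tied to the
  simulated alternate-allele count, so no clean record can trip a rule.
* Autozygous tracts are stamped in by duplicating one allele (chosen
  deterministically from the seed) of every heterozygous genotype of the
  named sample inside the tract, giving tracts with heterozygosity exactly 0
  against the 0.001 background.
* All draws flow through one `numpy.random.Generator` seeded from the
  config, so outputs (including written VCFs) are byte-identical under a
  fixed seed.

What the generator does **not** emulate: linkage (sites are independent, so
LD-thinning behaviour on realistic haplotype structure is exercised only via
hand-built correlated fixtures), mutation-model detail, genotyping error,
coverage-dependent missingness, and selection.  Tests passing on this
generator therefore validate the estimators and their bookkeeping, not
robustness to artefacts of real sequencing data.

A separate single-population neutral coalescent simulator (exponential
coalescence times with rate k(k−1)/2, uniform pair merges, Poisson(θ/2 ×
branch length) infinite-sites mutations) provides haplotype windows with
known expectations (E[S] = θ·a₁, E[π] = θ, E[η<sub>i</sub>] = θ/i) used to
calibrate the Tajima's D machinery.  It is kept per-window and
single-population deliberately: the Balding–Nichols genotype generator has
sharp analytic expectations for recovery tests, while the coalescent covers
the genealogical variance that D calibration needs.  Note that SFS class
counts within one window share a genealogy and are overdispersed relative to
multinomial sampling, so spectrum checks use per-class Monte-Carlo standard
errors rather than a plain chi-square.

## Numerical and design notes

* Quantiles and medians use numpy defaults (R type 7).  Tajima constants are
  computed in double precision from direct harmonic sums.
* Problem sizes in the test and acceptance suites are desk-scale by design:
  1–10-Mbp genomes for estimator recovery, a 50-Mbp genome with four
  inserted tracts (1.5/2.6/5/10 Mbp) for ROH recovery, 2,000 coalescent
  windows (n = 18, θ = 5) for scan calibration and 5,000 replicates for
  E[S].  Headline field values from full genomes (heterozygosity ≈ 0.0011
  vs 0.0009, d<sub>xy</sub> ≈ 0.001, F<sub>ROH</sub> 2–3%) are magnitude
  anchors for the generator defaults, not desk-reproducible quantities.
* VCF I/O goes through pysam; INFO floats round-trip through 32-bit storage,
  so table equality uses a 1e−5 relative tolerance on float annotations.
* Degenerate inputs: empty tables round-trip as header-only VCFs; windows
  with S = 0 report no D; an empty run list gives F<sub>ROH</sub> = 0 with
  absent median/max; all-missing populations at a site are skipped and
  counted rather than silently dropped.

## Known limitations

* The ROH caller is the windowed-heterozygosity recipe, not an HMM; very
  short ROH (< 1 window) are invisible by construction, and tracts below
  ~1.5 Mbp are detected but with less reliable boundaries.
* d<sub>xy</sub> treats each genotype as a frequency rather than sampling
  haplotypes, which is the estimator's definition here but differs from
  sequence-pair d<sub>xy</sub> at heterozygous sites (see above).
* Multiallelic sites are excluded from frequency-based statistics rather
  than split into biallelic records.
* The scan's per-window n (lower median over segregating sites) is one of
  several defensible conventions under missingness; fully-called data is
  unaffected.
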