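# Methods

This note documents the models, defaults, and numerical choices behind
`bsaqtl`, and what the synthetic experiments do and do not establish.

## Experimental design being modelled

A biparental cross between two inbred lines with strongly contrasting fruit
length (long parent "KG1", short parent "MBF"), an F1, and an F2 of ~231
selfed offspring. Two phenotypic extreme bulks of ~20 F2 plants each
(fruit length > 45 cm and < 20 cm) are sequenced together with the parents;
allele-frequency skew between the bulks localizes the trait locus, KASP
marker genotyping of recombinants narrows the interval, and a
four-generation segregation analysis characterizes the trait's inheritance.

## Synthetic data generator (`simdata`)

The generator emulates the statistical structure the scan assumes; it is a
first-class, tested component, not a fixture.

* **Genome.** Default desk-scale map: 20 chromosomes of 2-10 Mb with
  markers every 12 kb (~10,000 biallelic sites), not the real ~269 Mb
  assembly. Genetic distance is uniform within a chromosome at 10 cM/Mb —
  published Cucurbita consensus maps put the genome-wide average near
  11 cM/Mb, and with no published recombination map for this cross a uniform
  rate is the minimal assumption (it is a stand-in, not an inference).
* **Meiosis.** Each gamete is a Markov walk along ordered marker positions;
  the first allele is Bernoulli(½) and each inter-marker interval switches
  parental phase with the Haldane fraction r = (1 − e^(−2d/100))/2 for d cM.
  The QTL is simulated as a pseudo-marker inserted into the walk, so its
  linkage to flanking markers follows the map exactly. No crossover
  interference (Haldane), consistent with the one-locus questions asked.
* **Phenotype.** y = m + {+a, +d, −a} by QTL dose + N(0, σ²pg) + N(0, σ²e).
  Defaults: m = 32.5 cm, a = 12.5 cm, d = 0, σpg = 5, σe = 3. With the
  study's bulk thresholds (< 20 cm / > 45 cm) these defaults put the two
  cutoffs symmetrically ~2.15 residual SDs outside the homozygote means, so
  each tail yields a plausible extreme-bulk pool (~20-40 plants of 231).
  The real cross is far more extreme (parent means 107 vs 12 cm) and its F2
  is right-skewed; the generator reproduces the *design geometry* (tail
  bulks, additive major gene over polygenic noise), not the raw scale.
* **Sequencing.** Per site and bulk, true long-parent allele frequency
  p = Σdoses/(2·bulk size); depth ~ Poisson(λ = depth_mean, default 30)
  truncated ≥ 1; long-parent reads ~ Binomial(depth, p(1−e) + (1−p)e) with
  symmetric error e = 0.001. Parents are emitted as clean fixed homozygotes
  (inbred lines; the scan uses parental genotypes, not parental depths).
  Read positions, mates, and mapping artefacts are not modelled.
* **Determinism.** All randomness flows from one root seed through named
  substreams (genotypes, phenotypes, depths, reads), so any stage replays
  independently of the others.

Because real BSA-seq data adds alignment error, depth heterogeneity,
segregation distortion, and structural variation, passing tests on this
generator demonstrate correctness of the statistics and calling logic under
the model's assumptions — not robustness to those artefacts.

## Scan statistics (`bsa_scan`)

* **SNP-index orientation.** Index = fraction of long-parent (KG1) alleles
  in a bulk, so Δ = index_L − index_S is positive at a long-allele QTL.
  Sites are only scan-eligible when the parents are opposite homozygotes;
  the default depth filter is ≥ 10 reads per bulk (configurable; ~the
  design's minimum average depth). InDels are treated exactly like SNPs
  (one alt allele, length-agnostic) and averaged jointly in windows.
* **Windows.** Per chromosome, windows of 1 Mb anchored at position 1
  advance by a fixed step; a site at p belongs to [start, start + size).
  Window means use prefix sums (O(1) per window). Empty windows are kept on
  the grid but excluded from threshold crossing. Anchoring at 1 makes the
  grid deterministic; midpoints are reported.
* **Null thresholds.** For a given bulk size and depth, each of 10,000
  replicates draws two bulks of F2 genotypes at ¼:½:¼, forms binomial read
  counts, and computes Δ; the 95%/99% quantiles of |Δ| give symmetric
  (−q, +q) bounds. Site depths are binned to multiples of 5 and each bin's
  simulation is cached; a window's bound is the mean of its member sites'
  bounds, mirroring how the window Δ is the mean of site Δs. Averaging
  site-level bounds is conservative for window means (correlated but
  averaged sites), which the null-calibration experiment confirms
  empirically (observed exceedance ≤ nominal 5%).
* **G and G′.** G = 2 Σ n ln(n/ê) over the 2×2 allele-by-bulk table with
  independence expectations; zero cells contribute 0 (x ln x limit). G′ is
  Nadaraya-Watson smoothing of G with tricube weights
  k = (1 − (d/h)³)³, h = window/2, over physical distance. G′ p-values via
  log-normal null fitting are not implemented; G′ regions are called
  against the empirical genome-wide 95% quantile of G′, matching the single
  "95% significance level" used for both detectors.

## Region calling and fine mapping (`regions`)

* Regions are maximal runs of consecutive above-threshold populated
  windows; bounds are the run's min window start / max window end (window
  extents, not site positions — deterministic and consistent with windowed
  detection). Runs separated by more than one step are distinct.
* Intersection is pairwise same-chromosome max(start)/min(end);
  commutative and idempotent.
* Interval length in kb is (end − start)/1000, rounded half-up to 2
  decimals. The end − start convention (no +1) reproduces published
  marker-interval lengths computed from marker coordinates (791,681 to
  842,449 bp → 50.77 kb).
* Gene lookup uses any-overlap (not containment), since boundary-straddling
  genes belong in a candidate list.
* **Recombinant narrowing.** Inputs are ordered marker genotypes
  (P1hom/het/P2hom) per individual plus each individual's phenotype class
  at the causal locus. A marker is *excluded* when some individual's
  genotype there mismatches its phenotype class (that individual is a
  recombinant between the marker and the locus). The locus lies in the
  maximal run of non-excluded markers, flanked by the nearest excluded
  marker on each side; when every marker is excluded the locus falls
  between adjacent markers, and the unique adjacent pair whose
  non-recombinant individuals (identical genotype at both flanks) all match
  their phenotype class is returned. Individuals sharing enclosed genotypes
  but differing in phenotype class are reported as conflicts, never
  dropped. With no recombinants the full initial interval is returned.

## Segregation analysis (`inheritance`)

* **Model.** Joint likelihood over four generations: P1, P2, F1 normal with
  free means and shared σ²e; F2 a structured normal mixture (0MG single
  normal; 1MG-A means m±a, m at ¼:½:¼; 1MG-AD means m+a, m+d, m−a; 2MG-A
  nine components (1:2:1)⊗(1:2:1) with additive means m ± a1 ± a2). The F2
  residual variance is reparameterized σ²f = σ²e + σ²pg with σ²pg ≥ 0,
  since polygenic variance segregates only in F2. The four-model set covers
  the decision actually at stake (is there a major gene; is it additive);
  the full segregation-analysis catalogue is out of scope but the mixture
  machinery is extensible.
* **Fitting.** EM on the F2 mixture: E-step responsibilities with fixed
  weights; M-step solves the structured means in closed form (weighted
  least squares; for 1MG-AD the three free means map bijectively to
  (m, a, d)), then updates (σ²e, σ²f) jointly — unconstrained MLEs, pooled
  when the constraint σ²f ≥ σ²e binds. Convergence at relative logL change
  < 1e-8 or 2,000 iterations; logL is asserted non-decreasing every
  iteration. Starts are deterministic: an F2-quantile start (0.1/0.5/0.9),
  a parent/F1-moment start, and a near-null start anchored at the nested
  submodel (for 1MG-A, exactly a = 0 — an EM fixed point reproducing the
  0MG optimum, which guarantees the nested-model logL ordering can never
  invert through a local optimum). Best start is retained; k counts 5 base
  parameters (3 generation means, σ²e, σ²pg) plus the mixture mean
  parameters.
* **Model choice.** Ascending AIC among models whose goodness-of-fit tests
  are all non-significant at 0.05; if none pass, minimal AIC with a
  warning. GoF: KS against the fitted mixture CDF plus three uniformity
  moment tests on the probability integral transform — normalized shifted
  Legendre polynomial means U1-U3, each asymptotically N(0,1) under the
  fitted model. (The classical segregation-analysis software's exact
  internals are unpublished; these are standard PIT moment tests of the
  same three orders.)
* Validation is parameter-recovery-based: at the design point (m = 30,
  a = 20, σf = 5, n = 500) the fit recovers a within ±2 and m within ±1.5
  in ≥ 18/20 seeds, strong-effect AIC ranking prefers 1MG-A in ≥ 90% of 50
  replicates, and a pure-normal F2 selects 0MG.

## Association and expression (`assoc_expr`)

One-way ANOVA across genotype classes with Welch pairwise t-tests
(unequal-variance; no multiple-testing correction by default, Bonferroni by
flag, matching simple pairwise reporting practice). Pearson correlation
with t-based p. Printed-percentage reproductions round half-up to 2
decimals. Motif scanning is exact string matching (overlaps allowed, N
never matches), 1-based on the searched strand; reverse-strand search is
off by default since the element of interest (GGAAAA) is discussed on the
forward strand. The variant-effect analysis rescans after an in-silico
substitution and reports lost/gained hit positions.

## Problem sizes and replication defaults

The self-validation experiments (`experiments`, also driven by
`scripts/acceptance.py`) use: 50 seeded replicates of 200 F2 with top-20
bulks per tail, depth 30, one additive QTL of 1.5 residual SDs on the
default ~10,000-site genome; scan windows of 1 Mb advancing 10 kb (at a
1 Mb window the detection geometry is insensitive to step; 10 kb keeps a
50-replicate sweep around half a minute, while the CLI default step remains
1 kb for production-style scans); 10,000 null replicates per depth bin;
20 seeds for parameter recovery and 50 for AIC ranking. These sizes are the
package's chosen desk-scale defaults and are stated alongside each reported
value by the acceptance script.

## Known limitations

* Uniform cM/Mb and Haldane (no-interference) meiosis; no segregation
  distortion.
* Two bulks only; F2 designs only (no RIL/backcross index expectations).
* G′ significance is empirical-quantile based, not p-value based.
* The inheritance module fits four models, not the full mixed-major-gene
  catalogue, and uses moment-based PIT uniformity tests rather than any
  particular legacy implementation's internals.
* The automated chromosome-exclusion heuristic used to discard minor
  regions (variant counting inside candidate intervals) is provided as
  primitives (`genes_in_interval`, region calls), not as an automated rule.
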