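# Methods

## Quantification model

Targeted MRM quantification against a spiked internal standard (IS),
glucotropaeolin, which does not occur in cabbage tissue. Calibration
curves (peak area vs nmol injected) give per-compound slopes; only the
**ratio of slopes** enters the analysis:

    RF_analyte = slope_IS / slope_analyte
    nmol_analyte = (area_analyte / area_IS) · RF_analyte · nmol_IS
    concentration [µmol g⁻¹ dw] = nmol_analyte / dry_mass [g] / 1000

Defaults: 50 mg dry tissue, 25 nmol IS. These constants give the unit
anchor used throughout testing: an analyte with RF = 1 whose area equals
the IS area is at exactly 0.5 µmol g⁻¹ dw. Calibration intercepts are
stored for diagnostics but never used — whether the standards regression
is forced through the origin is therefore immaterial to outputs.
Consequences of the slope-ratio form, verified as properties: doubling all
analyte areas doubles concentrations; doubling the IS area halves them;
rescaling both calibration slopes by any constant changes nothing. A
sample with missing or non-positive IS area cannot be quantified and is
flagged, never silently dropped. Non-detection is an exact 0.0 (a
biological zero, e.g. gluconasturtiin-null genotypes), not a "<LOD" code.

## Compositional analysis

GSL profiles carry relative information, so multivariate structure is
analysed in Aitchison geometry. The centred log-ratio transform
clr(x)ᵢ = ln xᵢ − (1/D)Σⱼ ln xⱼ maps strictly positive profiles to a
zero-sum Euclidean space; the Aitchison distance is the Euclidean
distance between clr images and is invariant to per-genotype rescaling.

**Zero replacement.** The clr needs strictly positive parts. Zeros are
replaced multiplicatively: δⱼ = 0.65 × (smallest positive value of
compound j across genotypes); zeros in a row become δⱼ and the positive
parts shrink proportionally so the row total is preserved. The 0.65
fraction is the standard conservative choice for below-detection parts
and is configurable; a compound that is zero everywhere admits no δ and
is an error.

**Clustering.** Agglomerative clustering with Ward linkage on the
Aitchison distance matrix, flat labels by cutting at k = 2 for the
headline line-group dichotomy (both configurable). Linkage choice is a
genuinely open design point; Ward gives compact, balanced groups and
recovers the generator's planted 3C/4C dichotomy exactly at strong
separation.

**Standardisation.** Heatmap matrices use column z-scores with
population SD (ddof = 0), fixed for test stability; zero-variance columns
are returned as zeros with a warning rather than NaN.

**Spearman correlations.** Pairwise rank correlations (average ranks for
ties) among the 13 compounds plus the total; coefficients only, no
p-values. The matrix is invariant to strictly monotone transforms of any
single compound column — except columns' relationships with the derived
total, which depends on raw values.

**PCA.** Default: PCA of the column-z-scored genotype means (correlation
PCA), reported as variance fractions, genotype scores and compound
loadings; `scale_mode="clr"` (after zero replacement) and `"raw"` are
provided because the appropriate pre-treatment for compositional PCA is
debatable. Four components are reported by default.

## Heterosis

MPV = (mother + father)/2 on genotype means (mean over 3–4 replicate
heads); MPH = 100·(H − MPV)/MPV per hybrid × trait. Genotype means are
the units: replicate-level MPH is not defined. MPH is bounded below by
−100% for non-negative traits and is undefined at MPV = 0 (both parents
compound-null); undefined cells are flagged, counted, and excluded from
medians and z-scores rather than coerced to ±∞.

Per-compound central tendency across the 11 hybrids is the median with a
**percentile bootstrap** 95% CI (B = 1,000 resamples of hybrids with
replacement, seeded). Percentile rather than BCa because the target is a
median of 11 skewed values where BCa's acceleration estimate is itself
unstable. Resampling is at hybrid level (n = 11), not replicate level —
an assumption, since the alternative is defensible; hybrid-level
resampling matches treating the hybrid as the experimental unit. Seeded
coverage at n = 11 under symmetric noise is ≈92–95% (slight undercoverage
is a known property of the percentile method for medians at small n);
the acceptance suite checks 95% ± 4 points over 500 Monte-Carlo panels.
Consistent heterosis is declared when the CI excludes zero.

## Parent–hybrid regression

Per trait, OLS of hybrid genotype mean on MPV across the 11 hybrids
(commercial checks have no MPV and are excluded). Reported: slope,
intercept, r², two-sided slope p-value, significance at p < 0.05, and a
95% **confidence band for the mean response** over the observed MPV range
(a prediction-interval mode exists, default off). No multiple-testing
correction across the 14 per-trait models, mirroring per-model reporting
practice; a Bonferroni option can be applied by the caller. A constant
response is reported as slope 0, r² = 0, p = 1 rather than NaN.

**Sensitivity refit.** Hybrids with H = 0 *and* MPV = 0 (double-null
pairs) anchor the line at the origin and can manufacture significance for
presence/absence compounds such as gluconasturtiin. The refit excludes
them (a generic rule rather than named genotypes) and reports both fits
and whether the significance call flips. Fewer than 3 remaining points
marks the refit non-fittable.

## Group comparisons

Welch (unequal-variance) two-sample t-tests of line vs hybrid genotype
means — Welch because equal variances between the groups is not a safe
assumption. Bonferroni adjustment: total GSL tested alone (m = 1), the 13
compounds as a family (m = 13), the 5 agronomic traits as a family
(m = 5, kept at 5 even when a trait is missing). Commercial checks are in
the hybrid group by default (`include_checks=False` restricts to program
hybrids); both group sizes are reported.

## Synthetic generator: what it emulates, and what not

The generator's defaults are the stated world of the emulated design:
14 DH lines, 11 hybrids on distinct ordered parent pairs with one
reciprocal pair, 2 pedigree-less checks, 4 replicates per genotype with
probability 0.75 else 3 (pest/disease loss), replicate CV 0.15
(multiplicative mean-one lognormal — concentrations are positive and
right-skewed; the CV is loosely calibrated to published panel means ± SE).

* **Line means** ~ Uniform over compound-specific ranges spanning
  published cabbage concentrations (sinigrin up to ~27 µmol g⁻¹ dw,
  gluconasturtiin a trace compound).
* **Planted dichotomy**: 40% of lines are "4C-high" — their 4C-aliphatic
  means are drawn from the upper sub-range and 3C from the lower, and
  vice versa (separation 0.6 by default; 0 removes the structure, →1
  makes sub-ranges disjoint).
* **Hybrids**: H = (1 + δ)·MPV per compound, so planted δ is exactly
  MPH/100. Defaults plant consistent positive heterosis for gluconapin
  (δ = +1.0), gluconasturtiin (+0.5), glucoiberverin (+0.4) and
  consistent negative heterosis for glucobrassicin (−0.3) and
  neoglucobrassicin (−0.35), the qualitative pattern of the emulated
  study.
* **GNS complementation**: two pathway loci; each line independently
  carries a nonfunctional allele per locus with p = 0.25 (or explicit
  assignments). A homozygous line lacking function at either locus makes
  no GNS. A hybrid lacks GNS iff both parents are null at the **same**
  locus; parents null at different loci complement (the hybrid inherits
  one functional copy of each gene) and the hybrid's GNS is redrawn from
  the line range. The minimal two-locus Bernoulli model consistent with a
  complementation interpretation.
* **Agronomic traits**: five head traits with uniformly positive planted
  effects, head weight largest (δ = 4.738, i.e. +473.8% MPH) and head
  compactness smallest (δ = 0.406).
* **Peak areas**: exact inverse of the quantification model
  (area = slope × nmol, IS area from its slope and 25 nmol), optional
  area-level Gaussian noise, default off so the round trip is exact.

What the generator does **not** emulate — and hence what a green test
does not establish: genotype-by-environment interaction, within-head
sampling heterogeneity, correlated replicate errors across compounds,
non-uniform (e.g. skewed) distributions of line means, per-hybrid
variation around the planted δ beyond replicate noise, and any linkage
between the GSL loci and agronomic traits. Recovery tests therefore
validate the *analysis machinery*, not field predictivity.

All randomness flows from one seed via namespaced child streams
(`SeedSequence((seed, stream_id))`), so each operation is reproducible
independently of call order and identical seeds give byte-identical CSV
outputs (hashed in the pipeline manifest).

## Numerical choices and degenerate inputs

* Population SD (ddof = 0) for all z-scores; sample SD (ddof = 1) for
  genotype-mean standard errors; single-replicate SE is NaN.
* Scipy's two-variable Spearman scalar is expanded to a 2×2 matrix;
  constant columns give NaN entries with a warning.
* Cluster labels come from `scipy.cluster.hierarchy.fcluster(…,
  criterion="maxclust")`; label identities are arbitrary, tests compare
  partitions via the adjusted Rand index.
* `MPH = NaN` (undefined) propagates as missing through z-scores and is
  excluded from bootstrap samples; CIs require ≥ 2 defined values.
* Regression band width is minimised at the MPV mean (OLS property used
  as a test oracle); predictions pass through the centroid.
* The bootstrap uses `numpy.random.Generator.integers` index resampling;
  B and α are configurable, B ≥ 100 enforced in the pipeline config.

## Known limitations

* Peak integration, chromatography and instrument control are out of
  scope: areas arrive pre-integrated.
* No heritability estimation, heterobeltiosis, or standard heterosis
  against commercial checks.
* The bootstrap's hybrid-level resampling assumption (vs replicate-level)
  changes CI widths at the margins; both are defensible, one is
  implemented.
* Plots are convenience output only; no figure content is tested.
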