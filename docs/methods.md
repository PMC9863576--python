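# Methods

This note records the statistical models implemented in `medscan`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know.

## 1. Synthetic panel (`syndata`)

**Population model.** Subpopulation allele frequencies follow the
Balding–Nichols construction: per marker, an ancestral frequency
p ~ Uniform(0.1, 0.9) and subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), so the expected divergence among
subpopulations equals the `fst` parameter. Defaults mirror the panel the
package models: 153 accessions, 10 458 markers on 21 chromosomes
(1A…7D), three subpopulations with west/north/east Mediterranean country
pools (23 countries), FST 0.10. A realized-FST check against an
independent Weir–Cockerham estimator holds to ±0.02 at m ≥ 5000.

**Admixture.** A configurable fraction of accessions (default 0.20, a
calibration choice — the real panel's admixture proportion is not
published) draws each marker from a 50/50 mixture of two subpopulation
frequency vectors and carries the first component's label. With this
default the top-5 PCoA axes explain roughly 19–24% of the genetic
variance, bracketing the ~22% reported for the real panel.

**Linkage.** Markers are independent by default. An optional
Gaussian-copula haplotype mode (`ld_scale_cm`) draws each haplotype from
a latent AR(1) process along the chromosome with correlation
exp(−d/ld_scale_cm), producing realistic LD decay for tests that need
it. No recombination histories are simulated.

**Physical map.** Genetic positions are uniform per chromosome (default
length 150 cM). Physical positions follow a piecewise wheat-like
recombination landscape: the distal 30% of the map on each arm maps at
0.3× the genome-average Mb/cM (recombination-rich telomeric regions),
the central 40% is physically expanded so the chromosome averages
`bp_per_cm` (default 5 Mb/cM, the bread-wheat genome average). Without
this, every hotspot would exceed the 20 Mb candidate-gene cut, which
contradicts the published interval widths (0.23–16.37 Mb).

**Phenology traits.** Plot values are genetic score + year + row +
column + residual. Planted QTLs with a `heritability_share` are rescaled
against the empirical marker variance so each explains exactly its
stated fraction of phenotypic variance; when the shares sum to less than
the trait h², the difference is filled by a polygenic background over
100 randomly chosen markers (never the planted ones), so structured
panels give structure-correlated traits. The default recovery scenario
plants one QTL at 15% of phenotypic variance with h² = 0.6 — chosen
prospectively because a 10%-variance QTL at n = 153 sits at ~77% power
for −log₁₀ p > 3, i.e. exactly on the acceptance boundary. The field
layout is an augmented design: one plot per accession per year plus two
check cultivars interleaved at a 1:5 ratio.

**Climate.** Countries inherit their subpopulation's mean per variable ×
window plus country-level noise scaled by the across-subpopulation
spread; default means follow a smooth west-to-east warming/drying
gradient matching the spread of the packaged country normals.

**What a green test does not establish.** The generator has no
genotype-by-environment interaction, no chip-specific missingness, no
allele-frequency ascertainment bias, and LD is either absent or
stationary; conclusions about those aspects of real panels are out of
reach.

## 2. Field-trial BLUPs (`pheno`)

Per environment, y = Xβ + Z_row u_row + Z_col u_col + Z_acc u_acc + e
with checks fixed. Variance components by EM-REML on Henderson's
mixed-model equations; the EM property that the restricted
log-likelihood never decreases is asserted on every fit (computed
densely — designs are a few hundred plots). Convergence: successive
variance-component changes < 1e-8, max 2000 iterations (EM is slow near
a zero boundary; estimates stabilise long before the formal criterion).
Components are floored at 1e-12; a rank-deficient fixed design or
unreplicated checks raise a `DegenerateModelError` naming the problem.
Year fits are averaged into the GWAS phenotype — the source study fits
per environment without stating how years combine; the mean is the
package's choice, with `per_year=True` available.

Climate windows: SA = 20 Nov–31 Mar (132 days), AM = 1 Apr–30 Jun.
Rain is summed over the window (published values, e.g. 663.4 mm, are
seasonal totals); all other variables are daily means.

## 3. Structure (`popstruct`)

Kinship is the centred-dosage cross-product; `centered_ibs`
(trace-normalised, mean diagonal 1) is the default, `vanraden`
(2Σp(1−p) scaling) the alternative — the source study names no formula,
and both are standard. Missing calls are mean-imputed per marker for
kinship/PCA/association only, never written back. PCoA is classical
scaling of the squared allele-sharing distance (1 − IBS); axes are
oriented so the first accession loads non-negatively, making outputs
reproducible up to that convention. Eigen phenotypes are the top-k axis
scores (default k = 5).

## 4. Association scans (`assoc`)

REML profiles the restricted likelihood over the genetic:residual
variance ratio γ on the spectrum of K: a 49-point grid on
log₁₀ γ ∈ [−6, 6] brackets a bounded scalar minimisation (xatol 1e-8).
With kinship estimated from ~10³ markers the profile can be nearly flat
in γ (the Wishart bulk of K mimics the identity), so ratio estimates at
the bound are possible and harmless — the implied whitening changes
negligibly. P3D (null components reused for every marker) is the
default; per-marker refitting is available via `p3d=False`.

Marker tests are exact F-tests in the whitened model; r² is the squared
partial correlation between whitened marker and whitened phenotype given
the whitened covariates, a bounded quantity matching the magnitude of
published per-MTA r² (0.001–0.102). Markers whose whitened dosage is
numerically constant (monomorphic after imputation, or collinear with a
fixed PC) are skipped with a named reason. Because tested markers also
enter K, mixed-model p-values are conservative relative to OLS (proximal
contamination); at the panel's marker density the effect is modest, at
ten times fewer markers it roughly halves −log₁₀ p.

Eigenvector scans drop the fixed PC whose rank matches the axis under
test (eigen3 → PC3), avoiding a self-regression; the flag is
configurable because the original pipeline is silent on this. Optional
kinship compression (average-linkage groups with averaged kinship) is
off by default — the "optimum compression level" of the original
analysis is not operationally defined.

## 5. Hotspots (`hotspots`)

σ = CI/3.92 per chromosome (the 95% Gaussian width convention,
2 × 1.96), U(x) summed at integer cM positions and divided by nbE, the
number of trait–scan experiments (phenology traits + climate
variable×window combinations + eigenvectors). The mean threshold is
nbQTL/(nbE·map length); the high threshold is `high_multiplier` × mean
with default 5 (5 × 0.19 ≈ 0.95 against the published 0.93 — consistent
but not exactly derivable, hence a knob). Mass conservation
(ΣU·1 cM = nbQTL/nbE within 1%) holds away from chromosome ends for
CI ≥ 3 cM; below that the 1-cM grid undersamples the Gaussian (Riemann
error ≈ 2·exp(−2π²σ²)), and density mass beyond chromosome ends is not
reflected — both documented edge biases.

Peaks are the argmax (leftmost on ties) of maximal above-threshold runs.
Peaks whose ±CI/2 intervals overlap on a chromosome merge into one
hotspot — a declared reconstruction of the unpublished peak→hotspot
consolidation rule. Flanking markers are the bp-mapped markers nearest
each interval end; the physical width is |right − left|/10⁶ rounded to
two decimals, order-insensitive. Selection keeps widths ≤ 20 Mb;
same-chromosome hotspots with intersecting bp intervals (1-based,
inclusive) fuse, names concatenating ordinals (1B.1-2).

## 6. Differentiation (`diffpattern`)

A subpopulation pair is *robust* at a marker when majority alleles
differ and both majority frequencies ≥ 0.80; *moderate* when both
≥ 0.60 but not robust; *none* otherwise — the reading consistent with
every narrated case in the source tables. Classification is symmetric
and invariant to allele relabelling; majority ties break by allele
letter. Published frequency rows that do not sum to 100% (rare third
alleles) are used as printed. Admixed accessions are excluded upstream
when frequencies are computed from genotypes.

## 7. Candidate genes (`candgenes`)

Gene–hotspot overlap is "any intersection" of 1-based inclusive
intervals (strict containment is ill-defined at flanking-marker edges);
genes in several hotspots are deduplicated by first occurrence. The
expression filter requires tpm(stress) − tpm(control) > 2 strictly, in
at least one tissue and one study; a delta of exactly 2 is excluded and
down-regulation never selects. GFF3 I/O goes through gffutils (gene
features only; GO terms in `Ontology_term`).

## 8. Known limitations

* The published headline counts (651 MTAs, 46 hotspots, 1097 candidate
  genes) depend on undeposited genotypes and external expression
  databases and are not reproduction targets; the package reproduces
  the printed worked examples exactly and the statistical properties of
  the method on synthetic panels.
* EM-REML and the dense restricted likelihood scale to a few hundred
  plots per environment, not to large multi-site trials.
* The accession-missingness QC threshold (25%) mirrors the marker rule;
  the original accession rule is ambiguous in the source.
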