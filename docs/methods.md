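# Methods

## The association model

Expression of probe *g* in sample *i* is modelled as

    y_gi = alpha_g + beta_gv * d_vi + Sum_k gamma_gk * PC_ki + eps_gi

with `d_vi` the alternate-allele dosage in [0, 2] and `PC_1..PC_K` the
top principal components of the probe-centred expression matrix,
included to absorb hidden technical and biological confounders. The
default K = 15 follows the study design this pipeline reproduces; on
synthetic data the calibration tests show that including PCs restores
nominal type-I error when latent factors are present.

The scan computes every pair's t statistic by the matrix method:
residualize dosages and expression on the covariates (Frisch–Waugh),
then t = r·sqrt(df)/sqrt(1−r²) from the residual correlation r, with
df = n − (#covariates including intercept) − 1. This equals the dosage
coefficient's t in a per-pair OLS exactly (the test suite asserts
max |Δt| < 1e−8 against statsmodels on a 100×500×50 simulation); beta
and its SE are recovered on the original scale, and the reported R² is
the squared partial correlation — the fraction of covariate-adjusted
expression variance the variant explains. The df is stated here
explicitly so that t ↔ p is reproducible from the output alone.

Pair eligibility: *cis* = variant position within 1 Mb of the probe
interval [start, end] (distance to the interval, not to the TSS — TSS
distance is a separate annotation); *trans* = variant on a different
chromosome. Same-chromosome pairs beyond 1 Mb fall in neither family;
this gap mirrors the non-contiguous-chromosome definition of trans and
is deliberate. Each family receives its own Benjamini–Hochberg FDR
(defaults 5% cis, 1% trans), computed by the step-up formula
q_(i) = min_{j≥i} p_(j)·m/j and cross-checked against statsmodels.
Monomorphic-after-residualization variants are skipped and logged.
Underflowing p-values are floored at the smallest positive normal
double and flagged in the log. Peak selection per probe (or per gene)
breaks p ties by larger |beta|, then smaller position, then
lexicographic variant id — a total order, so peaks are deterministic.

Conditional scanning appends the conditioning variant's (mean-imputed)
dosage to the covariates and re-tests the probe's cis window, excluding
the conditioning variant itself. Note that the conditional family is
typically small and block-correlated; with two-sided tests the
probability of *some* marginal BH rejection under the null exceeds the
nominal level even though FDR is controlled in expectation, so "no
secondary peak" should be judged by the collapse of the top statistic,
not by the absence of any q < 0.05 row.

## Quality control

Variants are filtered in a fixed order — imputation info score (< 0.9),
call rate (> 5% missing; the source study does not quantify "poor call
rates", so this default is an explicit choice), MAF (< 5%), HWE exact
test — and the exclusion report names the first filter each variant
failed. Two HWE thresholds coexist: 1e−6 for directly genotyped and
1e−3 for imputed variants, selected by the `imputed` provenance flag
and defaulting to the imputed rule when provenance is absent. The HWE
test is the exact conditional test on hard genotype counts; dosages are
rounded with tolerance 0.1 (a dosage further from an integer is treated
as an uncertain call and excluded from the HWE table only), since HWE is
defined on genotype counts and near-integer dosages are confidently
called. Missing dosages are stored as missing and mean-imputed per
variant only at scan time.

Expression QC: probes flagged as multi-mapping or overlapping common
polymorphisms are dropped; detection filtering keeps a probe only when
it is confidently detected (detection p < 0.01) in strictly more than 5%
of samples. Normalization is per-sample quantile normalization to the
mean empirical distribution followed by an optional log2(x+1)
(auto-detected for raw-scale intensities). This deliberately replaces
the array-vendor random-spline + variance-stabilizing transform, which
is tied to bead-level internals unavailable outside the vendor software;
the association model downstream needs only equalized per-sample
distributions and approximately stabilized variance, which quantile
normalization provides. Sample outliers are removed iteratively on
Euclidean distance to the probe-wise centroid with a mean + 3 SD cut
(the source algorithm names no numeric threshold; 3 SD is configurable
and not claimed to reproduce any particular cohort's exclusions),
re-normalizing between iterations, at most 10 iterations, with a guard
against the degenerate n < 3 case.

## Paired-cell comparison

Both result tables must already be FDR-filtered. A *shared pair* is the
same variant–gene pair significant in both cells; gene-level sharing is
tracked separately since both granularities are informative. Opposing
pairs are shared pairs with strictly opposite beta signs (beta = 0 is
never opposing); no cross-cell joint test is invented — each side must
pass its own cell's FDR. Genes significant in both cells with different
peak variants are *independent-peak* genes when the two peaks' LD
r² < 0.2. Pleiotropic variants are those significant for different
genes in the two cells, implemented literally (a flag switches to the
stricter definition that excludes variants sharing any gene across
cells, since the looser/stricter choice is ambiguous in practice).
Effect-size concordance is the Spearman correlation of per-gene peak
betas over genes significant in both cells; note that when the two
cells' peaks are different (even perfectly linked) variants, allele
coding can invert the sign, which attenuates this correlation — a real
feature of peak-based comparisons, visible in the analysis chain.

## Enrichment

Consensus tracks: positions covered by at least ceil(min_frac·n_donors)
donors (default half), each donor counting once per position, merged
into maximal intervals via a sweep line. Overlap is containment with
inclusive ends (distance-to-nearest-feature = 0), verified against a
brute-force oracle. All internal coordinates are 1-based inclusive;
BED's 0-based half-open convention is converted at the I/O boundary.

Enrichment of a foreground variant set (peak cis-eQTL for feature
tracks, all significant eQTL variants for the trait-catalog analysis —
both modes exposed) against a background (all tested variants) is the
2×2 fold = (fg_in/fg_n)/(bg_in/bg_n), with a two-sided Fisher exact p.
The reported 95% CI is the Katz log interval for the fold itself, since
the fold is the plotted estimate and planted-fold recovery is only
coherent on that scale; the Woolf log-OR interval is also computed and
reported separately (with 0.5 continuity correction when a cell is
zero). A zero background-in count leaves the fold undefined (NaN, with
a warning) rather than infinite. Fisher's test assumes independent
loci; variants in LD violate this and no correction is applied — the
caveat is inherited from the analysis being reproduced and documented
rather than patched.

Trait-catalog tagging: an eQTL variant is tagged for a trait when it is
the catalog variant or has a catalog variant among its LD proxies
(r² > 0.8 within 1 Mb, cohort dosage correlation — whether the original
analysis used dosages or hard calls is unstated; dosages are used).
Traits carry up to three disease categories; per-category enrichment
compares tagged fractions of the eQTL set against the tested-variant
background. No default background is hard-coded for locus-level
enrichment claims, which require a context-specific denominator.

## ddPCR and allele-specific binding

Droplets partition template molecules at random, so per-droplet counts
are Poisson and λ = −ln(n_neg/n_total) estimates mean occupancy (the
droplet volume is not modelled; every quantity used is a ratio, from
which the volume cancels). The delta-method SE is sqrt((e^λ−1)/n).
Saturated wells (n_neg = 0) are errors, never clamped — clamping would
bias λ without bound. Technical replicates are pooled by summing
droplet counts before the λ transform.

The allele-specific binding test: the expected C:T ratio comes from
input-material wells (for a heterozygote its deviation from 1 is purely
probe-efficiency), the ChIP wells give the observed ratio, and under
the null the two ChIP λs share their observed total split per the
expected ratio. Expected positive/negative droplet counts follow from
1 − e^−λ, and the statistic is the 4-cell Pearson chi-square. The
default reference distribution is chi-square with 2 df, following the
published procedure; since only one free quantity is actually
constrained (the split of a fitted total), the statistic is
asymptotically chi-square with 1 df, making the 2-df default
conservative (simulated null rejection ≈ 1.4% at alpha = 5%). Both dfs
are supported; the calibration test uses df = 1 (rejection in the
3–8% band) and the power test the default df = 2, which still detects
a 2-fold imbalance at 15,000 droplets essentially always.

## The synthetic-data generators

Genotypes use a founder-mosaic model: each LD block holds `n_founders`
haplotypes whose alleles are Bernoulli draws at a per-site frequency
from `maf_range`; every sample draws two founder labels per block, so
within-block variants correlate through shared founders and cross-block
variants are independent. With 2 founders, segregating sites within a
block are in near-perfect LD (the r² > 0.8 proxy regime); cross-block
pairs supply the r² < 0.2 independence regime. The variant table
records the target frequency and the realized founder-pool frequency;
sample allele draws are binomial around the latter, which is therefore
the generating frequency that MAF-recovery tests check. At small
founder counts the pool frequency deviates from the target (and sites
can fix), which is a property of the mosaic model, not an estimator
bias; QC then removes the low-MAF tail, as seen in the analysis chain.
This is deliberately not a coalescent simulation: no recombination map,
no allele-frequency spectrum realism — just the LD regimes the pipeline
needs, cheaply and reproducibly.

Expression is the generative mirror of the scan model: baseline +
additive dosage effects + latent factors (standard normal scores,
N(0, sd²) loadings) + Gaussian noise. Defaults (beta magnitude 1.0,
noise SD 1.0, cohort sizes 100–200, 15,000 droplets at λ ≈ 0.2–0.4)
are the regimes the recovery and calibration tests exercise. Paired
cells share genotypes; opposing pairs have beta_A = −beta_B, and
cell-specific pairs have beta = 0 in the other cell. Feature tracks
cover causal variants with one probability and the rest with another
(planted fold = their ratio); trait catalogs are analogous. Droplet
wells draw positives as Binomial(n, 1−e^−λ) independently per channel.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: array probe-intensity noise models, batch
effects beyond latent factors, realistic recombination and
allele-frequency spectra, population structure, dosage uncertainty
correlated with allele frequency, or LD between the causal variant and
background annotation structure. Results on real cohorts additionally
depend on those factors.

## Numerical choices

- Degrees of freedom, tie-breaks and p-value flooring: above.
- BH q-values: vectorised step-up with a stable sort; input order
  preserved.
- HWE exact test: log-gamma weights normalized by logsumexp; tail
  membership uses a (1 + 1e−12) relative tolerance so exact ties are
  not split by float noise. Verified against an exact integer
  enumeration for every table with n ≤ 50.
- Residualization via `numpy.linalg.lstsq` (SVD), robust to collinear
  covariates; an explicit intercept column is required.
- Zero-variance guards: LD r² is NaN for monomorphic vectors;
  residual-monomorphic variants are skipped in scans; all-zero
  genotype tables and saturated ddPCR wells are errors.
- Simulation sizes in the tests (e.g. 10,000-test null scans, 20-seed
  FDR averages, 50-replicate recovery loops) were chosen so each check
  has enough resolution for its stated band while the whole suite runs
  in a few minutes on one core.

## Known limitations

- Normalization is a stand-in (see above); vendor detection p-values
  are consumed, never reproduced.
- No permutation-based gene-level p-values, interaction/ANOVA models,
  CNV association, or haplotype-based LD (D′); imputation itself is out
  of scope (dosages are inputs).
- Fisher enrichment ignores LD between foreground variants.
- The trans scan tests all cross-chromosome pairs by default, which at
  biobank scale would need the provided variant-subset restriction.
- The conditional-scan caveat on small-family BH behaviour, above.
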