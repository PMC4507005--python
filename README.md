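# cellqtl

Cell-type-resolved eQTL analysis: cis/trans association scanning under a
linear-additive genetic model with principal-component covariates, paired
two-cell-type comparison, LD-aware enrichment of eQTL in genomic
annotations and trait catalogs, and Poisson quantification of droplet
digital PCR (ddPCR) for allele-specific transcription-factor binding.

## Who this is for

Groups mapping expression quantitative trait loci (eQTL) in purified
primary immune cells — e.g. neutrophils and monocytes isolated from the
same donors — who need the full downstream chain: QC, scanning, FDR
control, cross-cell-type classification of regulatory effects, epigenomic
and disease-catalog enrichment, and wet-lab follow-up quantification.
Because real cohorts of this kind are rarely redistributable, the package
ships a first-class synthetic-data module that generates genotypes with
block LD, expression with planted effects and latent confounders,
annotation tracks with planted enrichment, and Poisson-partitioned
droplet counts — all with recorded ground truth, so every estimator has a
parameter-recovery test.

## The model

For each variant–probe pair the scan fits the additive model

    y_g = alpha + beta * d_v + sum_k gamma_k * PC_k + epsilon

where `d_v` is the alternate-allele dosage (0–2, from genotypes or
imputation) and `PC_1..PC_K` are expression principal components standing
in for hidden confounders (K = 15 by default). The implementation uses
the matrix method: dosages and expression are residualized against the
covariates (Frisch–Waugh), and the per-pair statistic is recovered from
the residual correlation r as

    t = r * sqrt(df) / sqrt(1 - r^2),   df = n - (#covariates incl. intercept) - 1

which is algebraically identical to the per-pair OLS t (verified against
that oracle to < 1e-8 in the tests) at a fraction of the cost. Pairs are
*cis* when the variant lies within 1 Mb of the probe interval and *trans*
when the variant sits on a different chromosome; each family gets its own
Benjamini–Hochberg FDR (5% cis, 1% trans by default). The variance a peak
variant explains is its squared partial correlation after covariate
adjustment.

Downstream: paired-cell classification (shared / cell-specific /
directionally opposing pairs; genes with LD-independent peaks at
r² < 0.2; cross-gene pleiotropic variants), 2×2 Fisher enrichment of eQTL
in feature tracks and trait categories with LD-proxy tagging (r² > 0.8),
consensus tracks (features present in at least half of donors), and a
ddPCR allele-specific binding test: per-channel occupancy
λ = −ln(n_neg / n_total), an input-derived expected allele ratio that
absorbs probe-efficiency differences, and a chi-square comparison of the
ChIP ratio against it.

## Worked example

```python
from cellqtl import simulate, eqtl, preprocess, enrichment

G = simulate.simulate_genotypes(150, 400, seed=7)          # 150 donors
probes = simulate.make_probes(G, 100, seed=8)              # 100 genes
mafs = G.maf()
probe = probes.index[0]
row = probes.loc[probe]
cis = mafs[(G.variants["chrom"] == row["chrom"])
           & (G.variants["pos"] - row["tss"]).abs().le(500_000)
           & (mafs > 0.2)].index
var = cis[0]                                               # causal variant
E, truth = simulate.simulate_expression(                   # beta = +0.8
    G, probes, [(var, probe, 0.8)], n_confounders=3, noise_sd=1.0, seed=9)

pcs = preprocess.compute_pcs(E, 5)
C = eqtl.make_covariates(150, pcs)
res = eqtl.cis_scan(G, E, covariates=C)
sig = eqtl.significant(res, cis_fdr=0.05)
peak = eqtl.peak_per_probe(sig).iloc[0]
```

This prints (via the obvious f-strings):

```
tests: 1518, significant at FDR 5%: 1
planted: v00269 -> p0000 (beta = 0.8)
peak:    v00269 -> p0000 beta = 0.828 +/- 0.117, p = 6.16e-11, q = 9.36e-08, R^2 = 0.259
worked-example fold enrichment: 5.72
```

The scan tested 1,518 cis pairs, kept exactly the planted pair at FDR 5%,
and recovered the planted effect (0.83 ± 0.12 vs the true 0.8); the
variant explains 26% of the covariate-adjusted expression variance. The
last line is `enrichment.ratio_of_proportions(261, 646, 646, 9147)` — the
fold by which a 261/646 observed rate exceeds a 646/9147 background rate.

## Analysis chain

The `analysis/` scripts run the pipeline end to end on a simulated
two-cell cohort and write their tables under `results/`:

1. `01_simulate_cohort.py` — cohort with planted effects and truth
2. `02_quality_control.py` — variant filters and expression QC
3. `03_eqtl_scan.py` — cis/trans scans, FDR, peaks, variance explained
4. `04_cell_type_comparison.py` — shared/specific/opposing sets,
   peak-independence, conditional re-scan
5. `05_annotation_enrichment.py` — consensus tracks, feature and
   trait-category enrichment
6. `06_ddpcr_asb.py` — per-donor allele-specific binding tests

There is also a `cellqtl` CLI (`simulate`, `qc`, `scan`, `compare`,
`enrich`, `ddpcr`) exposing the same operations on files.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generators and what they do and do not emulate, numerical choices, and
known limitations.
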