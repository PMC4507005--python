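"""Genotype QC statistics and linkage-disequilibrium utilities."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

#: dosage-to-hard-genotype rounding tolerance (HWE only): a dosage further
#: than this from an integer is treated as an uncertain call and excluded.
HARD_CALL_TOL = 0.1


def maf(dosages) -> float:
    """Minor allele frequency from a dosage vector, missing excluded."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def hard_calls(dosages, tol: float = HARD_CALL_TOL) -> np.ndarray:
    """Round dosages to genotype counts; uncertain calls (>tol from an
    integer) and missing become NaN."""
    d = np.asarray(dosages, dtype=float)
    g = np.rint(d)
    with np.errstate(invalid="ignore"):
        g[np.abs(d - g) > tol] = np.nan
    return g


def _hwe_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with
    ``n`` diploid samples carrying ``n_minor`` minor alleles, under the
    exact conditional (all orderings equally likely) null."""
    het_min = n_minor % 2
    hets = np.arange(het_min, min(n_minor, 2 * n - n_minor) + 1, 2)
    lg = math.lgamma
    logs = np.array([
        lg(n + 1) - lg((n_minor - h) // 2 + 1) - lg(h + 1)
        - lg(n - (n_minor + h) // 2 + 1) + h * math.log(2)
        for h in hets
    ])
    logs -= logs.max()
    logs -= math.log(np.exp(logs).sum())
    return hets, logs


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (given the allele
    counts) whose conditional probability does not exceed the observed
    table's — the standard two-sided exact HWE test on genotype counts.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets, logs = _hwe_log_probs(n, n_minor)
    probs = np.exp(logs)
    p_obs = probs[hets == n_ab][0]
    # tolerance guards against float noise splitting exact ties
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_p_dosages(dosages) -> float:
    """HWE exact test from dosages via hard-call rounding."""
    g = hard_calls(dosages)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("no confidently called genotypes")
    return hwe_exact_p(int((g == 0).sum()), int((g == 1).sum()),
                       int((g == 2).sum()))


def qc_variants(G: GenotypeMatrix, maf_min: float = 0.05,
                hwe_p_min: float = 1e-6, hwe_p_min_imputed: float = 1e-3,
                info_min: float = 0.9, max_missing: float = 0.05,
                ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Variant QC: info score, call rate, MAF, HWE — applied in that order.

    A variant is tested against the imputed-provenance HWE threshold when
    its ``imputed`` flag is true or provenance is absent; the (stricter)
    genotyped threshold applies only to variants flagged imputed=False.
    Returns the retained matrix and an exclusion report (variant, reason,
    value) with one row per excluded variant, naming the first failed
    filter.
    """
    reasons, values = {}, {}
    meta = G.variants
    info = meta["info_score"] if "info_score" in meta.columns else None
    imputed = (meta["imputed"].astype(bool) if "imputed" in meta.columns
               else pd.Series(True, index=meta.index))
    miss = G.missing_rate()
    mafs = G.maf()
    for vid in meta.index:
        if info is not None and not np.isnan(info[vid]) and info[vid] < info_min:
            reasons[vid], values[vid] = "info", float(info[vid])
            continue
        if miss[vid] > max_missing:
            reasons[vid], values[vid] = "call_rate", float(miss[vid])
            continue
        if mafs[vid] < maf_min:
            reasons[vid], values[vid] = "maf", float(mafs[vid])
            continue
        thr = hwe_p_min_imputed if imputed[vid] else hwe_p_min
        try:
            p = hwe_exact_p_dosages(G.dosages[vid].to_numpy(dtype=float))
        except ValueError:
            reasons[vid], values[vid] = "call_rate", float(miss[vid])
            continue
        if p < thr:
            reasons[vid], values[vid] = "hwe", float(p)
    keep = [v for v in meta.index if v not in reasons]
    report = pd.DataFrame({
        "variant": list(reasons), "reason": list(reasons.values()),
        "value": [values[v] for v in reasons],
    })
    return G.subset(variants=keep), report


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Returns NaN when either vector is constant over the complete pairs
    (LD undefined for a monomorphic variant).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    va, vb = a.var(), b.var()
    if va <= 0 or vb <= 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def ld_r2_matrix(G: GenotypeMatrix, target: str,
                 candidates: pd.Index) -> pd.Series:
    """r^2 of one target variant against many candidates (vectorised,
    complete-case against the target)."""
    x = G.dosages[target].to_numpy(dtype=float)
    M = G.dosages.loc[:, candidates].to_numpy(dtype=float)
    out = np.full(len(candidates), np.nan)
    for j in range(M.shape[1]):
        out[j] = ld_r2(x, M[:, j])
    return pd.Series(out, index=candidates)


def ld_proxies(G: GenotypeMatrix, target: str, r2_threshold: float = 0.8,
               window_bp: int = 1_000_000) -> set[str]:
    """Variants within ``window_bp`` of the target with r^2 strictly above
    the threshold; the target itself is always included."""
    if target not in G.variants.index:
        raise KeyError(f"unknown variant {target!r}")
    v = G.variants.loc[target]
    near = G.variants[
        (G.variants["chrom"] == v["chrom"])
        & (G.variants["pos"] - v["pos"]).abs().le(window_bp)
    ].index.drop(target, errors="ignore")
    r2 = ld_r2_matrix(G, target, near)
    out = set(r2.index[r2 > r2_threshold])
    out.add(target)
    return out
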