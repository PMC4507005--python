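"""Paired two-cell-type eQTL comparison.

Classifies FDR-significant variant-gene associations from two cell types
into shared, cell-specific, independent-peak (same gene, different peak
variants at LD r^2 below a threshold), cross-gene pleiotropic, and
directionally opposing sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import eqtl, ld as ld_tools
from .types import GenotypeMatrix


@dataclass
class PairedComparison:
    shared_pairs: set = field(default_factory=set)          # (variant, gene)
    a_only: set = field(default_factory=set)
    b_only: set = field(default_factory=set)
    genes_both: set = field(default_factory=set)
    independent_peak_genes: set = field(default_factory=set)
    pleiotropic_variants: set = field(default_factory=set)
    opposing: set = field(default_factory=set)              # (variant, gene)

    def summary(self) -> dict:
        return {
            "n_shared_pairs": len(self.shared_pairs),
            "n_a_only": len(self.a_only),
            "n_b_only": len(self.b_only),
            "n_genes_both": len(self.genes_both),
            "n_independent_peak_genes": len(self.independent_peak_genes),
            "n_pleiotropic_variants": len(self.pleiotropic_variants),
            "n_opposing": len(self.opposing),
            "n_opposing_genes": len({g for _, g in self.opposing}),
        }


def harmonize(res_a: pd.DataFrame, res_b: pd.DataFrame,
              probes_a: pd.DataFrame, probes_b: pd.DataFrame
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both result sets to genes present in both probe panels."""
    common_genes = set(probes_a["gene"]) & set(probes_b["gene"])
    return (res_a[res_a["gene"].isin(common_genes)].reset_index(drop=True),
            res_b[res_b["gene"].isin(common_genes)].reset_index(drop=True))


def _pairs(res: pd.DataFrame) -> set:
    return set(zip(res["variant"], res["gene"]))


def opposing_effects(res_a: pd.DataFrame, res_b: pd.DataFrame) -> set:
    """(variant, gene) pairs significant in both cells with strictly
    opposite effect signs; a beta of exactly zero is never opposing."""
    merged = res_a.merge(res_b, on=["variant", "gene"],
                         suffixes=("_a", "_b"))
    mask = np.sign(merged["beta_a"]) * np.sign(merged["beta_b"]) == -1
    return set(zip(merged.loc[mask, "variant"], merged.loc[mask, "gene"]))


def classify(res_a: pd.DataFrame, res_b: pd.DataFrame, G: GenotypeMatrix,
             r2_independent: float = 0.2,
             exclusive_pleiotropy: bool = False) -> PairedComparison:
    """Full paired classification of two FDR-significant result tables.

    ``exclusive_pleiotropy`` additionally requires a pleiotropic variant
    to have no gene in common between the two cells.
    """
    pa, pb = _pairs(res_a), _pairs(res_b)
    shared = pa & pb
    genes_a, genes_b = set(res_a["gene"]), set(res_b["gene"])
    genes_both = genes_a & genes_b

    # genes with different, LD-independent peak variants in the two cells
    peaks_a = eqtl.peak_per_gene(res_a).set_index("gene")
    peaks_b = eqtl.peak_per_gene(res_b).set_index("gene")
    independent = set()
    for gene in genes_both:
        va = peaks_a.at[gene, "variant"]
        vb = peaks_b.at[gene, "variant"]
        if va == vb:
            continue
        if va in G.variants.index and vb in G.variants.index:
            r2 = ld_tools.ld_r2(G.dosages[va].to_numpy(dtype=float),
                                G.dosages[vb].to_numpy(dtype=float))
            if np.isnan(r2) or r2 < r2_independent:
                independent.add(gene)
        else:
            independent.add(gene)

    genes_of_a: dict[str, set] = {}
    genes_of_b: dict[str, set] = {}
    for v, g in pa:
        genes_of_a.setdefault(v, set()).add(g)
    for v, g in pb:
        genes_of_b.setdefault(v, set()).add(g)
    pleiotropic = set()
    for v in set(genes_of_a) & set(genes_of_b):
        ga, gb = genes_of_a[v], genes_of_b[v]
        cross = any(x != y for x in ga for y in gb)
        if exclusive_pleiotropy:
            cross = cross and not (ga & gb)
        if cross:
            pleiotropic.add(v)

    return PairedComparison(
        shared_pairs=shared,
        a_only=pa - pb,
        b_only=pb - pa,
        genes_both=genes_both,
        independent_peak_genes=independent,
        pleiotropic_variants=pleiotropic,
        opposing=opposing_effects(res_a, res_b),
    )


def effect_size_correlation(res_a: pd.DataFrame, res_b: pd.DataFrame
                            ) -> tuple[float, float, int]:
    """Spearman rank correlation of per-gene peak effect sizes over genes
    significant in both cells.  Returns (rho, two-sided p, n genes)."""
    peaks_a = eqtl.peak_per_gene(res_a).set_index("gene")["beta"]
    peaks_b = eqtl.peak_per_gene(res_b).set_index("gene")["beta"]
    genes = sorted(set(peaks_a.index) & set(peaks_b.index))
    if len(genes) < 3:
        return float("nan"), float("nan"), len(genes)
    rho, p = stats.spearmanr(peaks_a.loc[genes], peaks_b.loc[genes])
    return float(rho), float(p), len(genes)
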