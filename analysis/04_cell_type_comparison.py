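#!/usr/bin/env python
"""Paired comparison of neutrophil and monocyte eQTL.

Classifies significant associations into shared / cell-specific /
opposing sets, checks peak independence (LD r^2 < 0.2) for genes hit in
both cells, correlates peak effect sizes across cell types, and runs a
conditional re-scan on the strongest shared gene to confirm a single
causal signal.
"""

import json
from pathlib import Path

import pandas as pd

from cellqtl import compare, eqtl, io_formats, preprocess

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    G = io_formats.read_genotypes(DATA / "genotypes_qc.tsv", "tsv")
    res_a = io_formats.read_results(DATA / "scan_neutrophil_significant.tsv")
    res_b = io_formats.read_results(DATA / "scan_monocyte_significant.tsv")
    res_a = res_a[res_a["mode"] == "cis"]
    res_b = res_b[res_b["mode"] == "cis"]

    pc = compare.classify(res_a, res_b, G)
    rho, p, n = compare.effect_size_correlation(res_a, res_b)
    truth = pd.read_csv(RESULTS / "01_causal_truth.tsv", sep="\t")
    opp_truth_probes = set(truth.loc[truth["sign_discordant"], "probe"])

    summary = pc.summary() | {
        "spearman_rho_shared_peak_betas": round(rho, 3),
        "spearman_p": p,
        "n_genes_correlated": n,
        "planted_opposing_probes": len(opp_truth_probes),
    }

    # conditional re-scan of the strongest shared gene: conditioning on
    # the peak variant should leave no secondary signal
    if pc.shared_pairs:
        top = (res_a[res_a["gene"].isin({g for _, g in pc.shared_pairs})]
               .sort_values("p").iloc[0])
        E, _ = io_formats.read_expression(
            DATA / "expression_neutrophil_qc.tsv", DATA / "probes.tsv")
        common = [s for s in G.samples if s in set(E.samples)]
        Gc, Ec = G.subset(samples=common), E.subset(samples=common)
        pcs = preprocess.compute_pcs(Ec, 15)
        C = eqtl.make_covariates(Ec.n_samples, pcs)
        cond = eqtl.conditional_scan(Gc, Ec, top["probe"], top["variant"],
                                     covariates=C)
        summary["conditional_scan"] = {
            "gene": top["gene"], "conditioned_on": top["variant"],
            "n_conditional_tests": len(cond),
            "min_conditional_q": float(cond["q"].min()) if len(cond)
            else None,
            "secondary_peak": bool((cond["q"] <= 0.05).any()) if len(cond)
            else False,
        }

    for name, pairs in (("shared", pc.shared_pairs),
                        ("opposing", pc.opposing),
                        ("neutrophil_only", pc.a_only),
                        ("monocyte_only", pc.b_only)):
        pd.DataFrame(sorted(pairs), columns=["variant", "gene"]).to_csv(
            RESULTS / f"04_pairs_{name}.tsv", sep="\t", index=False)
    (RESULTS / "04_comparison_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
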