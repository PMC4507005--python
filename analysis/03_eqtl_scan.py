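#!/usr/bin/env python
"""Cis and trans eQTL scans for both cell types.

Runs the linear-additive scan with PC covariates over the QC'd cohort,
applies FDR 5% (cis) / 1% (trans), selects peak associations per probe,
and summarizes detection: how many planted effects were found, the
median variance explained by peak eQTL, and the TSS-distance profile of
peaks.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cellqtl import enrichment, eqtl, io_formats, preprocess

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
N_PCS = 15


def main() -> None:
    G_all = io_formats.read_genotypes(DATA / "genotypes_qc.tsv", "tsv")
    truth = pd.read_csv(RESULTS / "01_causal_truth.tsv", sep="\t")
    summary: dict = {"n_pcs": N_PCS}

    for cell in ("neutrophil", "monocyte"):
        E, _ = io_formats.read_expression(
            DATA / f"expression_{cell}_qc.tsv", DATA / "probes.tsv")
        common = [s for s in G_all.samples if s in set(E.samples)]
        G = G_all.subset(samples=common)
        E = E.subset(samples=common)
        pcs = preprocess.compute_pcs(E, N_PCS)
        C = eqtl.make_covariates(E.n_samples, pcs)

        cis = eqtl.cis_scan(G, E, covariates=C, cell_type=cell)
        trans = eqtl.trans_scan(G, E, covariates=C, cell_type=cell)
        full = pd.concat([cis, trans], ignore_index=True)
        sig = eqtl.significant(full)
        peaks = eqtl.peak_per_probe(sig[sig["mode"] == "cis"])
        if len(peaks):
            peaks = peaks.assign(
                tss_distance=enrichment.tss_distance(peaks, E.probes))

        io_formats.write_results(full, DATA / f"scan_{cell}_full.tsv")
        io_formats.write_results(sig, DATA / f"scan_{cell}_significant.tsv")
        peaks.to_csv(RESULTS / f"03_peaks_{cell}.tsv", sep="\t",
                     index=False)

        cell_label = {"neutrophil": ("both", "A"),
                      "monocyte": ("both", "B")}[cell]
        planted = truth[truth["cell_type"].isin(cell_label)]
        planted_probes = set(planted["probe"])
        found_probes = set(sig.loc[sig["mode"] == "cis", "probe"])
        summary[cell] = {
            "n_cis_tests": int((full["mode"] == "cis").sum()),
            "n_trans_tests": int((full["mode"] == "trans").sum()),
            "n_cis_significant_pairs": int((sig["mode"] == "cis").sum()),
            "n_cis_genes": int(sig.loc[sig["mode"] == "cis",
                                       "gene"].nunique()),
            "n_trans_significant_pairs": int((sig["mode"] == "trans").sum()),
            "planted_probes_detected":
                f"{len(planted_probes & found_probes)}/{len(planted_probes)}",
            "median_peak_variance_explained_pct":
                round(100 * float(peaks["r2"].median()), 1) if len(peaks)
                else None,
            "median_abs_peak_tss_distance_bp":
                int(peaks["tss_distance"].abs().median()) if len(peaks)
                else None,
        }

    (RESULTS / "03_scan_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
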