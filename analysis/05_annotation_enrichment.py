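#!/usr/bin/env python
"""Enrichment of eQTL in feature tracks and trait catalogs.

Builds a consensus track from per-donor replicates of the planted
feature map, tests peak cis-eQTL for enrichment in the planted
(fold-10) and neutral (fold-1) tracks against the all-tested-variants
background, and runs LD-aware (r^2 > 0.8) per-category trait-catalog
enrichment of all significant eQTL variants.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cellqtl import enrichment, io_formats, simulate

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    G = io_formats.read_genotypes(DATA / "genotypes_qc.tsv", "tsv")
    sig = io_formats.read_results(DATA / "scan_neutrophil_significant.tsv")
    sig = sig[sig["mode"] == "cis"]
    peaks = pd.read_csv(RESULTS / "03_peaks_neutrophil.tsv", sep="\t")
    fg_peaks = G.variants.loc[[v for v in peaks["variant"].unique()
                               if v in G.variants.index]]
    background = G.variants

    # consensus across 6 simulated donor replicates of the active mark:
    # donor tracks share the causal-biased coverage, so features seen in
    # at least half of donors concentrate on the planted regions
    truth = pd.read_csv(RESULTS / "01_causal_truth.tsv", sep="\t")
    causal = set(truth["variant"])
    rng = np.random.default_rng(55)
    donor_tracks = [
        simulate.simulate_feature_track(
            G.variants, causal, width_bp=500, p_cover_causal=0.8,
            p_cover_background=0.05, seed=int(rng.integers(2 ** 31)),
            label=f"donor{i}")
        for i in range(6)]
    consensus = enrichment.consensus_track(donor_tracks, min_frac=0.5,
                                           label="active_mark_consensus")

    results = []
    for track in (io_formats.read_bed(DATA / "track_active_mark.bed"),
                  io_formats.read_bed(DATA / "track_neutral_mark.bed"),
                  consensus):
        results.append(enrichment.track_enrichment(fg_peaks, background,
                                                   track))

    catalog = io_formats.read_catalog(DATA / "catalog.tsv")
    all_sig_variants = list(sig["variant"].unique())
    results += enrichment.category_enrichment(
        all_sig_variants, list(G.variant_ids), catalog, G, r2=0.8)

    table = enrichment.enrichment_table(results)
    table.to_csv(RESULTS / "05_enrichment.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    summary = {
        r.label: {"fold": round(r.fold, 2),
                  "ci95": [round(r.ci95[0], 2), round(r.ci95[1], 2)],
                  "p": r.p}
        for r in results}
    (RESULTS / "05_enrichment_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
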