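"""Consensus tracks, overlap, TSS distance, Fisher enrichment, GWAS tagging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellqtl import enrichment, ld, simulate
from cellqtl.types import FeatureTrack


def _track(rows, label="t"):
    return FeatureTrack(label, pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))


def _variants(positions, chrom="chrS1"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "G",
    }, index=pd.Index([f"v{i}" for i in range(len(positions))], name="id"))


# ---------------------------------------------------------------------------
# consensus tracks

def test_consensus_single_donor_identity():
    t = _track([("chrS1", 10, 20), ("chrS1", 40, 50)])
    out = enrichment.consensus_track([t], min_frac=0.5)
    pd.testing.assert_frame_equal(out.intervals, t.intervals)


def test_consensus_two_disjoint_donors_is_union():
    a = _track([("chrS1", 10, 20)])
    b = _track([("chrS1", 40, 50)])
    out = enrichment.consensus_track([a, b], min_frac=0.5)  # need 1 of 2
    assert [tuple(r) for r in out.intervals.to_numpy()] == [
        ("chrS1", 10, 20), ("chrS1", 40, 50)]


def test_consensus_coverage_threshold_arithmetic():
    """4 donors, min_frac=0.5 -> need 2: an interval shared by two donors
    survives, one private to a single donor does not."""
    shared = ("chrS1", 100, 200)
    private = ("chrS1", 500, 600)
    tracks = [_track([shared]), _track([shared]), _track([private]),
              _track([("chrS2", 1, 10)])]
    out = enrichment.consensus_track(tracks, min_frac=0.5)
    got = [tuple(r) for r in out.intervals.to_numpy()]
    assert got == [("chrS1", 100, 200)]


def test_consensus_partial_overlap_depth():
    # [10,30] and [20,40]: only [20,30] reaches depth 2
    a = _track([("chrS1", 10, 30)])
    b = _track([("chrS1", 20, 40)])
    out = enrichment.consensus_track([a, b], min_frac=1.0)
    assert [tuple(r) for r in out.intervals.to_numpy()] == [
        ("chrS1", 20, 30)]


# ---------------------------------------------------------------------------
# overlap

def test_overlap_inclusive_end_convention():
    track = _track([("chrS1", 10, 20)])
    v = _variants([20, 21, 10, 9])
    got = enrichment.overlap(v, track)
    assert got.tolist() == [True, False, True, False]


def test_overlap_matches_brute_force_oracle(rng):
    variants = _variants(sorted(rng.choice(100_000, 2000, replace=False)))
    rows = []
    for _ in range(300):
        s = int(rng.integers(1, 99_000))
        rows.append(("chrS1", s, s + int(rng.integers(1, 500))))
    track = _track(rows)
    got = enrichment.overlap(variants, track)
    brute = variants["pos"].map(
        lambda p: any(s <= p <= e for _, s, e in rows))
    assert (got.to_numpy() == brute.to_numpy()).all()
    assert got.sum() > 0


# ---------------------------------------------------------------------------
# TSS distance

@pytest.mark.parametrize("strand,pos,expected", [
    ("+", 1000, 0), ("+", 1100, 100), ("-", 1100, -100), ("-", 900, 100),
])
def test_tss_distance_sign_convention(strand, pos, expected):
    probes = pd.DataFrame({"tss": [1000], "strand": [strand]},
                          index=["p1"])
    peaks = pd.DataFrame({"probe": ["p1"], "pos": [pos]})
    assert enrichment.tss_distance(peaks, probes).iloc[0] == expected


# ---------------------------------------------------------------------------
# Fisher enrichment and worked ratios

def test_equal_proportions_fold_one():
    res = enrichment.fisher_enrichment(10, 100, 100, 1000)
    assert res.fold == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0, abs=0.3)


def test_mouse_homolog_worked_example():
    """261 of 646 mouse-homolog genes with a human eQTL, against a 646 of
    9147 background rate, is a 5.72-fold enrichment."""
    res = enrichment.fisher_enrichment(261, 646, 646, 9147)
    assert round(res.fold, 2) == 5.72
    assert enrichment.ratio_of_proportions(261, 646, 646, 9147) == \
        pytest.approx(5.72, abs=0.005)
    assert res.p < 1e-50


def test_ratio_of_proportions_guards():
    assert enrichment.ratio_of_proportions(1, 2, 1, 2) == 1.0
    with pytest.raises(ValueError, match="denominators"):
        enrichment.ratio_of_proportions(1, 0, 1, 2)
    assert math.isnan(enrichment.ratio_of_proportions(1, 2, 0, 5))


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Full hypergeometric enumeration of the two-sided exact test."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    probs = {k: (math.comb(col1, k) * math.comb(n - col1, row1 - k))
             / math.comb(n, row1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_p_matches_enumeration_oracle(rng):
    """Exact p agrees with full hypergeometric enumeration for random
    tables with total <= 200."""
    for _ in range(200):
        n = int(rng.integers(4, 201))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        d = n - a - b - c
        fg_n, bg_n = a + b, c + d
        if fg_n == 0 or bg_n == 0:
            continue
        res = enrichment.fisher_enrichment(a, fg_n, c, bg_n)
        want = fisher_two_sided_oracle(a, b, c, d)
        assert res.p == pytest.approx(want, rel=1e-6, abs=1e-12)


def test_fisher_p_invariant_under_transposition():
    res = enrichment.fisher_enrichment(30, 100, 50, 400)
    # transpose the 2x2: rows become (in, out) groups
    trans = enrichment.fisher_enrichment(30, 80, 70, 420)
    assert res.p == pytest.approx(trans.p, rel=1e-9)
    assert res.fold != pytest.approx(trans.fold)  # fold is directional


def test_fisher_zero_background_in_is_nan_fold():
    res = enrichment.fisher_enrichment(5, 10, 0, 100)
    assert math.isnan(res.fold)
    assert res.p < 1.0


def test_fold_ci_covers_planted_fold():
    """Estimated fold's 95% CI covers the planted fold-10 in >= 90% of 50
    seeded replicates (fg_n=500, bg_n=10,000); at fold 1 the type-I rate
    stays inside the binomial 99% band."""
    rng = np.random.default_rng(42)
    cover = 0
    for _ in range(50):
        fg_in = rng.binomial(500, 0.5)
        bg_in = rng.binomial(10_000, 0.05)
        res = enrichment.fisher_enrichment(int(fg_in), 500, int(bg_in), 10_000)
        if res.ci95[0] <= 10.0 <= res.ci95[1]:
            cover += 1
    assert cover >= 45

    rejections = 0
    n_rep = 50
    for _ in range(n_rep):
        fg_in = rng.binomial(500, 0.05)
        bg_in = rng.binomial(10_000, 0.05)
        res = enrichment.fisher_enrichment(int(fg_in), 500, int(bg_in), 10_000)
        rejections += res.p < 0.05
    hi = stats.binom.ppf(0.995, n_rep, 0.05) / n_rep
    assert rejections / n_rep <= hi


def test_planted_track_fold_recovered_through_pipeline():
    """simulate_feature_track -> overlap -> fisher_enrichment recovers the
    planted fold-10 inside the reported 95% CI."""
    G = simulate.simulate_genotypes(5, 4000, seed=110)
    causal = list(G.variant_ids[:500])
    background = list(G.variant_ids[500:])
    track = simulate.simulate_feature_track(
        G.variants, set(causal), width_bp=1, p_cover_causal=0.5,
        p_cover_background=0.05, seed=111)
    fg = G.variants.loc[causal]
    bg = G.variants.loc[background]
    res = enrichment.track_enrichment(fg, bg, track)
    assert res.ci95[0] <= 10.0 <= res.ci95[1]
    assert 6.0 < res.fold < 16.0


# ---------------------------------------------------------------------------
# GWAS tagging and category enrichment

def test_gwas_tag_direct_and_untagged():
    G = simulate.simulate_genotypes(100, 50, seed=112)
    cat = simulate.simulate_trait_catalog(
        G.variants.iloc[:5], ["autoimmune"], set(G.variant_ids[:5]),
        p_assoc_causal=1.0, p_assoc_background=0.0, seed=113)
    tags = enrichment.gwas_tag([G.variant_ids[0], G.variant_ids[40]],
                               cat, G, window_bp=1)
    assert tags[G.variant_ids[0]] == {"autoimmune_trait"}
    assert tags[G.variant_ids[40]] == set()


def test_gwas_tag_through_ld_proxy():
    """A non-catalog variant in near-perfect LD with a catalog variant is
    tagged through the proxy."""
    rng = np.random.default_rng(13)
    base = rng.binomial(2, 0.4, 500).astype(float)
    other = rng.binomial(2, 0.4, 500).astype(float)
    dosages = pd.DataFrame(
        {"eqtl": base, "gwas": base, "far": other},
        index=pd.Index([f"s{i}" for i in range(500)], name="sample"))
    variants = pd.DataFrame(
        {"chrom": "chrS1", "pos": [100, 200, 5000], "ref": "A", "alt": "G"},
        index=dosages.columns)
    from cellqtl.types import GenotypeMatrix, TraitCatalog
    G = GenotypeMatrix(dosages, variants)
    cat = TraitCatalog(pd.DataFrame({
        "variant": ["gwas"], "trait": ["ra"],
        "categories": [("autoimmune",)]}))
    tags = enrichment.gwas_tag(["eqtl", "far"], cat, G, r2=0.8,
                               window_bp=1000)
    assert tags["eqtl"] == {"ra"} and tags["far"] == set()


def test_category_enrichment_planted_recovery():
    """A planted 10x category enrichment is recovered within the CI; a
    category absent from the catalog yields no result row."""
    G = simulate.simulate_genotypes(50, 3000, seed=114)
    causal = list(G.variant_ids[:300])
    background = list(G.variant_ids[300:])
    cat = simulate.simulate_trait_catalog(
        G.variants, ["autoimmune"], set(causal), p_assoc_causal=0.5,
        p_assoc_background=0.05, seed=115)
    results = enrichment.category_enrichment(
        causal, background, cat, G, window_bp=1)
    assert [r.label for r in results] == ["autoimmune"]
    res = results[0]
    assert res.ci95[0] <= 10.0 <= res.ci95[1]
    assert res.p < 1e-10


def test_category_enrichment_identical_sets_fold_one():
    G = simulate.simulate_genotypes(20, 200, seed=116)
    cat = simulate.simulate_trait_catalog(
        G.variants, ["metabolic"], set(G.variant_ids[:20]),
        p_assoc_causal=0.5, p_assoc_background=0.5, seed=117)
    res = enrichment.category_enrichment(
        list(G.variant_ids), list(G.variant_ids), cat, G, window_bp=1)[0]
    assert res.fold == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)
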