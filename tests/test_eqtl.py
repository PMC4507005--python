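"""The association scan: oracle equivalence, FDR, peaks, conditioning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cellqtl import eqtl, preprocess, simulate
from cellqtl.types import GenotypeMatrix


# ---------------------------------------------------------------------------
# residualize

def test_residualize_intercept_only_centres(rng):
    M = rng.normal(size=(30, 4))
    C = np.ones((30, 1))
    out = eqtl.residualize(M, C)
    np.testing.assert_allclose(out, M - M.mean(0), atol=1e-12)


def test_residualize_column_in_span_is_zeroed(rng):
    C = np.column_stack([np.ones(30), rng.normal(size=30)])
    M = C @ rng.normal(size=(2, 3))
    np.testing.assert_allclose(eqtl.residualize(M, C), 0, atol=1e-10)


def test_residualize_matches_per_column_ols(rng):
    C = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
    M = rng.normal(size=(40, 5))
    got = eqtl.residualize(M, C)
    for j in range(5):
        want = M[:, j] - C @ np.linalg.lstsq(C, M[:, j], rcond=None)[0]
        np.testing.assert_allclose(got[:, j], want, atol=1e-10)


def test_residualize_requires_intercept(rng):
    with pytest.raises(ValueError, match="intercept"):
        eqtl.residualize(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)))


# ---------------------------------------------------------------------------
# matrix scan vs per-pair OLS oracle

def test_scan_matches_per_pair_ols_oracle():
    """The module's core correctness property: matrix-method statistics
    equal per-pair OLS (expression ~ dosage + covariates) on a
    100-sample x 500-variant x 50-probe simulation, max |dt| < 1e-8."""
    G = simulate.simulate_genotypes(100, 500, seed=71)
    probes = simulate.make_probes(G, 50, seed=72)
    effects = [(G.variant_ids[10], probes.index[0], 0.8)]
    E, _ = simulate.simulate_expression(G, probes, effects,
                                        n_confounders=3, seed=73)
    pcs = preprocess.compute_pcs(E, 5)
    C = eqtl.make_covariates(100, pcs)
    res = eqtl.cis_scan(G, E, covariates=C)
    assert len(res) > 500
    rng = np.random.default_rng(0)
    rows = res.iloc[rng.choice(len(res), 300, replace=False)]
    max_dt = 0.0
    for row in rows.itertuples(index=False):
        x = G.dosages[row.variant].to_numpy()
        y = E.values[row.probe].to_numpy()
        fit = sm.OLS(y, np.column_stack([x, C])).fit()
        max_dt = max(max_dt, abs(fit.tvalues[0] - row.t))
        assert fit.params[0] == pytest.approx(row.beta, abs=1e-10)
        assert fit.bse[0] == pytest.approx(row.se, abs=1e-10)
        assert fit.pvalues[0] == pytest.approx(row.p, abs=1e-10)
        assert row.r2 == pytest.approx(
            fit.tvalues[0] ** 2 / (fit.tvalues[0] ** 2 + fit.df_resid),
            abs=1e-10)
    assert max_dt < 1e-8


def test_perfect_effect_saturates(rng):
    """A noiseless planted pair yields r2 = 1 and the floored minimal p."""
    G = simulate.simulate_genotypes(50, 100, seed=74)
    probes = simulate.make_probes(G, 5, seed=75)
    var = G.maf().idxmax()
    probe = probes.index[0]
    probes.loc[probe, ["chrom", "tss", "start", "end"]] = [
        G.variants.at[var, "chrom"], G.variants.at[var, "pos"],
        G.variants.at[var, "pos"], G.variants.at[var, "pos"] + 49]
    E, _ = simulate.simulate_expression(G, probes, [(var, probe, 1.0)],
                                        n_confounders=0, noise_sd=0.0,
                                        seed=76)
    res = eqtl.cis_scan(G, E)
    hit = res[(res["variant"] == var) & (res["probe"] == probe)].iloc[0]
    assert hit["r2"] == pytest.approx(1.0)
    assert hit["p"] == eqtl.P_FLOOR


def test_null_scan_calibrated_with_confounders_only_when_pcs_included():
    """Latent confounders inflate the null unless PCs are covariates;
    with PCs the p<0.05 fraction returns to its binomial band."""
    G = simulate.simulate_genotypes(100, 200, seed=77)
    probes = simulate.make_probes(G, 50, seed=78)
    E, _ = simulate.simulate_expression(G, probes, [], n_confounders=4,
                                        confounder_sd=2.0, seed=79)
    pcs = preprocess.compute_pcs(E, 4)
    with_pcs = eqtl.cis_scan(G, E, covariates=eqtl.make_covariates(100, pcs))
    without = eqtl.cis_scan(G, E)
    frac_with = (with_pcs["p"] < 0.05).mean()
    frac_without = (without["p"] < 0.05).mean()
    m = len(with_pcs)
    band = 2.576 * np.sqrt(0.05 * 0.95 / m)
    assert abs(frac_with - 0.05) < band + 0.01  # tests are LD-correlated
    assert frac_without > frac_with


# ---------------------------------------------------------------------------
# BH FDR

def test_bh_single_p():
    np.testing.assert_allclose(eqtl.bh_fdr([0.05]), [0.05])


def test_bh_hand_example():
    np.testing.assert_allclose(eqtl.bh_fdr([0.01, 0.02, 0.06]),
                               [0.03, 0.03, 0.06])


def test_bh_definitional_properties(rng):
    p = rng.uniform(size=200)
    q = eqtl.bh_fdr(p)
    assert (q >= p - 1e-15).all() and (q <= 1).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.uniform(size=500)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(eqtl.bh_fdr(p), q_sm, atol=1e-12)


# ---------------------------------------------------------------------------
# significance filtering

def test_significant_empty_and_all_null():
    empty = eqtl._empty_results()
    assert len(eqtl.significant(empty)) == 0
    df = pd.DataFrame({"variant": ["a", "b"], "probe": ["p", "p"],
                       "p": [1.0, 1.0], "mode": "cis"})
    assert len(eqtl.significant(df)) == 0


def test_fdr_families_are_separate():
    df = pd.DataFrame({
        "variant": list("abcd"), "probe": list("pqrs"),
        "p": [0.001, 0.04, 0.001, 0.004],
        "mode": ["cis", "cis", "trans", "trans"],
    })
    out = eqtl.significant(df, cis_fdr=0.05, trans_fdr=0.01)
    # trans q = (0.002, 0.004) both pass 1%; cis q = (0.002, 0.04) pass 5%
    assert len(out) == 4
    out2 = eqtl.significant(df, cis_fdr=0.05, trans_fdr=0.001)
    assert set(out2[out2["mode"] == "trans"]["variant"]) == set()


# ---------------------------------------------------------------------------
# trans scan

def test_trans_empty_on_single_chromosome():
    G = simulate.simulate_genotypes(
        40, 50, chrom_lengths={"chrS1": 5_000_000}, seed=81)
    probes = simulate.make_probes(G, 5, seed=82)
    E, _ = simulate.simulate_expression(G, probes, [], seed=83)
    assert len(eqtl.trans_scan(G, E)) == 0


def test_trans_partition_excludes_same_chromosome():
    G = simulate.simulate_genotypes(60, 100, seed=84)
    probes = simulate.make_probes(G, 10, seed=85)
    E, _ = simulate.simulate_expression(G, probes, [], seed=86)
    trans = eqtl.trans_scan(G, E)
    vchrom = trans["variant"].map(G.variants["chrom"])
    pchrom = trans["probe"].map(E.probes["chrom"])
    assert (vchrom.to_numpy() != pchrom.to_numpy()).all()
    cis = eqtl.cis_scan(G, E)
    cis_pairs = set(zip(cis["variant"], cis["probe"]))
    trans_pairs = set(zip(trans["variant"], trans["probe"]))
    assert not cis_pairs & trans_pairs


def test_planted_trans_pair_detected():
    """A strong cross-chromosome effect reaches q < 0.01 in the trans
    family (beta=1.5, n=150)."""
    G = simulate.simulate_genotypes(150, 300, seed=87)
    probes = simulate.make_probes(G, 20, seed=88)
    mafs = G.maf()
    var = mafs[G.variants["chrom"] == "chrS1"].idxmax()
    probe = next(p for p in probes.index
                 if probes.at[p, "chrom"] == "chrS2")
    E, _ = simulate.simulate_expression(G, probes, [(var, probe, 1.5)],
                                        noise_sd=1.0, seed=89)
    trans = eqtl.trans_scan(G, E)
    hit = trans[(trans["variant"] == var) & (trans["probe"] == probe)]
    assert hit.iloc[0]["q"] < 0.01


# ---------------------------------------------------------------------------
# peaks

def test_peak_single_association_is_itself():
    df = pd.DataFrame({"variant": ["a"], "probe": ["p"], "gene": ["g"],
                       "pos": [10], "beta": [1.0], "p": [0.01]})
    peak = eqtl.peak_per_probe(df)
    assert len(peak) == 1 and peak.iloc[0]["n_tested"] == 1


def test_peak_tie_breaks_are_deterministic():
    df = pd.DataFrame({
        "variant": ["b", "a", "c"], "probe": "p", "gene": "g",
        "pos": [5, 10, 1], "beta": [1.0, -2.0, 1.0],
        "p": [0.01, 0.01, 0.01],
    })
    assert eqtl.peak_per_probe(df).iloc[0]["variant"] == "a"  # larger |beta|
    df["beta"] = 1.0
    assert eqtl.peak_per_probe(df).iloc[0]["variant"] == "c"  # smaller pos


def test_peak_invariant_minimal_p(rng):
    df = pd.DataFrame({
        "variant": [f"v{i}" for i in range(100)],
        "probe": rng.choice(["p1", "p2", "p3"], 100),
        "gene": "g", "pos": rng.integers(1, 1000, 100),
        "beta": rng.normal(size=100), "p": rng.uniform(size=100),
    })
    peaks = eqtl.peak_per_probe(df).set_index("probe")
    for probe, sub in df.groupby("probe"):
        assert peaks.at[probe, "p"] == sub["p"].min()


def test_strongest_planted_effect_usually_wins():
    """With two planted variants at a 2:1 effect ratio the stronger one
    is the peak in >= 95% of simulations."""
    G = simulate.simulate_genotypes(150, 60, seed=90)
    probes = simulate.make_probes(G, 3, seed=91)
    probe = probes.index[0]
    chrom = probes.at[probe, "chrom"]
    mafs = G.maf()
    cands = mafs[(G.variants["chrom"] == chrom) & (mafs > 0.2)].index
    strong, weak = cands[0], cands[len(cands) // 2]
    wins = 0
    for rep in range(100):
        E, _ = simulate.simulate_expression(
            G, probes, [(strong, probe, 1.0), (weak, probe, 0.5)],
            noise_sd=1.0, seed=1000 + rep)
        res = eqtl.cis_scan(G, E, window=50_000_000)
        sub = res[res["probe"] == probe]
        peak_var = eqtl.peak_per_probe(sub).iloc[0]["variant"]
        wins += peak_var in set(
            # count LD-equivalents of the strong variant as wins
            [strong]) or G.variants.at[peak_var, "block"] == \
            G.variants.at[strong, "block"]
    assert wins >= 95


# ---------------------------------------------------------------------------
# conditional scan

@pytest.fixture(scope="module")
def conditional_setup():
    G = simulate.simulate_genotypes(150, 200, seed=92)
    probes = simulate.make_probes(G, 5, seed=93)
    probe = probes.index[0]
    row = probes.loc[probe]
    mafs = G.maf()
    in_cis = ((G.variants["chrom"] == row["chrom"])
              & (G.variants["pos"] - row["tss"]).abs().le(900_000))
    causal = mafs[in_cis & (mafs > 0.2)].index[0]
    return G, probes, probe, causal


def test_conditioning_on_causal_removes_signal(conditional_setup):
    """Conditioning on the single causal variant removes the eQTL: the
    strong unconditional peak disappears and only marginal,
    dependence-driven rejections remain in a minority of replicates.

    The per-replicate "no conditional q<0.05" event is not guaranteed at
    95%: the conditional family is a handful of block-correlated
    two-sided tests, for which BH's P(any false rejection) exceeds the
    nominal level, so a clean run in >= 3/4 of replicates together with
    a collapsed top statistic is the calibrated expectation.
    """
    G, probes, probe, causal = conditional_setup
    clean = 0
    for rep in range(20):
        E, _ = simulate.simulate_expression(G, probes, [(causal, probe, 1.0)],
                                            noise_sd=1.0, seed=2000 + rep)
        base = eqtl.cis_scan(G, E)
        base_hit = base[(base["variant"] == causal)
                        & (base["probe"] == probe)].iloc[0]
        assert base_hit["q"] < 1e-4  # the unconditional eQTL is unmissable
        res = eqtl.conditional_scan(G, E, probe, causal)
        # no secondary peak: nothing near the original signal strength
        assert res["t"].abs().max() < 0.6 * abs(base_hit["t"])
        if (res["q"] > 0.05).all():
            clean += 1
    assert clean >= 15


def test_conditioning_on_null_variant_leaves_peak(conditional_setup):
    """Conditioning on an unlinked null variant barely moves the peak t."""
    G, probes, probe, causal = conditional_setup
    other_chrom = next(c for c in pd.unique(G.variants["chrom"])
                       if c != probes.at[probe, "chrom"])
    null_var = G.variants[G.variants["chrom"] == other_chrom].index[0]
    E, _ = simulate.simulate_expression(G, probes, [(causal, probe, 1.0)],
                                        noise_sd=1.0, seed=94)
    base = eqtl.cis_scan(G, E)
    base_t = base.set_index("variant").loc[causal, "t"]
    cond = eqtl.conditional_scan(G, E, probe, null_var)
    cond_t = cond.set_index("variant").loc[causal, "t"]
    assert abs(base_t - cond_t) < 0.5


def test_conditioning_variant_absent_from_output(conditional_setup):
    G, probes, probe, causal = conditional_setup
    E, _ = simulate.simulate_expression(G, probes, [(causal, probe, 1.0)],
                                        seed=95)
    res = eqtl.conditional_scan(G, E, probe, causal)
    assert causal not in set(res["variant"])
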