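"""Synthetic-data generators with recorded ground truth.

The generators mirror the statistical structure the analysis assumes:

* genotypes — a founder-mosaic model: each LD block holds a handful of
  founder haplotypes; every sample draws two founder labels per block, so
  variants within a block are correlated (shared founders) and variants in
  different blocks are independent;
* expression — additive genotype effects plus latent confounders plus
  Gaussian noise, the generative mirror of the linear-additive scan model;
* paired cell types — shared, cell-specific and sign-discordant effects;
* feature tracks / trait catalogs — annotations covering causal variants
  preferentially, with a known planted fold;
* droplets — Poisson-partitioned two-channel ddPCR counts.

Every generator is bit-reproducible given a seed, and the returned
``SimTruth`` determines the expectation of each downstream estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CausalEffect, DdpcrWell, ExpressionMatrix, FeatureTrack, GenotypeMatrix,
    SimTruth, TraitCatalog,
)

DEFAULT_CHROM_LENGTHS = {"chrS1": 20_000_000, "chrS2": 20_000_000}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_genotypes(n_samples: int, n_variants: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       block_len: int = 25, n_founders: int = 6,
                       chrom_lengths: dict[str, int] | None = None,
                       seed=0) -> GenotypeMatrix:
    """Founder-mosaic biallelic dosage matrix with block LD.

    Per block, ``n_founders`` founder haplotypes carry Bernoulli(f) alleles
    with per-site frequency f drawn from ``maf_range``; each sample draws
    two founder labels per block independently and its dosage is the
    haplotype sum.  The variant table records the block id, the target
    frequency f ("target_freq") and the realized founder-pool frequency
    ("gen_freq") — allele draws from the pool are binomial around the
    latter.  Variants are positioned uniformly over the chromosome map.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    chroms = list(chrom_lengths)

    # spread variants over chromosomes proportional to length
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_variants * lens / lens.sum()).astype(int)
    for i in range(n_variants - counts.sum()):
        counts[i % len(counts)] += 1

    meta_rows = []
    dosage_cols = []
    block_id = 0
    v = 0
    for chrom, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        pos = np.sort(rng.choice(
            np.arange(1, chrom_lengths[chrom] + 1), size=cnt, replace=False))
        done = 0
        while done < cnt:
            size = min(block_len, cnt - done)
            f = rng.uniform(lo, hi, size=size)
            founders = (rng.random((n_founders, size)) < f).astype(float)
            labels = rng.integers(0, n_founders, size=(n_samples, 2))
            block = founders[labels[:, 0]] + founders[labels[:, 1]]
            pool = founders.mean(axis=0)
            for k in range(size):
                meta_rows.append((
                    f"v{v:05d}", chrom, int(pos[done + k]), "A", "G",
                    1.0, block_id, float(f[k]), float(pool[k])))
                v += 1
            dosage_cols.append(block)
            done += size
            block_id += 1
    variants = pd.DataFrame(
        meta_rows,
        columns=["id", "chrom", "pos", "ref", "alt", "info_score",
                 "block", "target_freq", "gen_freq"],
    ).set_index("id")
    dosages = pd.DataFrame(
        np.hstack(dosage_cols),
        index=pd.Index([f"s{i:04d}" for i in range(n_samples)], name="sample"),
        columns=variants.index)
    return GenotypeMatrix(dosages, variants)


def make_probes(G: GenotypeMatrix, n_probes: int, seed=0,
                probe_len: int = 50,
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Random probe annotation over the genotype map: one gene per probe,
    random strand, probe interval = [tss, tss + probe_len - 1]."""
    rng = _rng(seed)
    chrom_lengths = chrom_lengths or {
        c: int(G.variants.loc[G.variants["chrom"] == c, "pos"].max())
        for c in pd.unique(G.variants["chrom"])
    }
    chroms = rng.choice(list(chrom_lengths), size=n_probes)
    rows = []
    for i in range(n_probes):
        chrom = chroms[i]
        tss = int(rng.integers(1, max(2, chrom_lengths[chrom] - probe_len)))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"p{i:04d}", f"GENE{i:04d}", chrom, tss, strand,
                     tss, tss + probe_len - 1, False, False))
    return pd.DataFrame(rows, columns=[
        "probe_id", "gene", "chrom", "tss", "strand", "start", "end",
        "multi_mapping", "polymorphic_target"]).set_index("probe_id")


def simulate_expression(G: GenotypeMatrix, probes: pd.DataFrame,
                        effects: list[CausalEffect] | list[tuple],
                        n_confounders: int = 0, confounder_sd: float = 1.0,
                        noise_sd: float = 1.0, baseline: float = 7.5,
                        seed=0) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression = baseline + sum(beta * dosage) + loadings @ factors + noise.

    ``effects`` entries are CausalEffect or (variant, probe, beta) tuples;
    latent factors are standard normal per sample, loadings N(0,
    confounder_sd^2) per probe.
    """
    rng = _rng(seed)
    effects = [e if isinstance(e, CausalEffect) else CausalEffect(*e)
               for e in effects]
    for e in effects:
        if e.variant not in G.variants.index:
            raise KeyError(f"effect references unknown variant {e.variant!r}")
        if e.probe not in probes.index:
            raise KeyError(f"effect references unknown probe {e.probe!r}")
    n, m = G.n_samples, len(probes)
    Y = np.full((n, m), float(baseline))
    col = {p: j for j, p in enumerate(probes.index)}
    for e in effects:
        d = G.dosages[e.variant].to_numpy(dtype=float)
        d = np.where(np.isnan(d), np.nanmean(d), d)
        Y[:, col[e.probe]] += e.beta * d
    loadings = scores = None
    if n_confounders > 0:
        scores = rng.standard_normal((n, n_confounders))
        loadings = rng.normal(0.0, confounder_sd, size=(m, n_confounders))
        Y += scores @ loadings.T
    if noise_sd > 0:
        Y += rng.normal(0.0, noise_sd, size=(n, m))
    E = ExpressionMatrix(
        pd.DataFrame(Y, index=G.samples, columns=probes.index), probes.copy())
    truth = SimTruth(causal_pairs=effects, confounder_loadings=loadings,
                     confounder_scores=scores)
    return E, truth


def _pick_cis_variant(G: GenotypeMatrix, probe_row, rng,
                      window: int = 500_000, min_maf: float = 0.1) -> str:
    near = G.variants[
        (G.variants["chrom"] == probe_row["chrom"])
        & (G.variants["pos"] - probe_row["tss"]).abs().le(window)]
    mafs = G.maf().loc[near.index]
    near = near[mafs >= min_maf]
    if len(near) == 0:
        raise ValueError(
            f"no cis variant with MAF>={min_maf} near probe at "
            f"{probe_row['chrom']}:{probe_row['tss']}")
    return str(rng.choice(near.index))


def simulate_paired_cells(G: GenotypeMatrix, probes: pd.DataFrame,
                          n_shared: int = 10, n_cell_a_only: int = 5,
                          n_cell_b_only: int = 5, n_opposing: int = 3,
                          beta: float = 1.0, n_confounders: int = 0,
                          confounder_sd: float = 1.0, noise_sd: float = 1.0,
                          seed=0
                          ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                     SimTruth]:
    """Two cell types over shared genotypes with planted effect classes.

    Each requested effect gets its own probe (never reused): shared pairs
    have identical beta in both cells, cell-specific pairs beta in one
    cell only, opposing pairs beta_A = -beta_B.
    """
    rng = _rng(seed)
    total = n_shared + n_cell_a_only + n_cell_b_only + n_opposing
    if total > len(probes):
        raise ValueError(f"{total} effects requested but only "
                         f"{len(probes)} probes available")
    chosen = list(rng.choice(probes.index, size=total, replace=False))
    groups = {
        "shared": chosen[:n_shared],
        "a_only": chosen[n_shared:n_shared + n_cell_a_only],
        "b_only": chosen[n_shared + n_cell_a_only:
                         n_shared + n_cell_a_only + n_cell_b_only],
        "opposing": chosen[n_shared + n_cell_a_only + n_cell_b_only:],
    }
    eff_a: list[CausalEffect] = []
    eff_b: list[CausalEffect] = []
    truth_pairs: list[CausalEffect] = []
    for kind, plist in groups.items():
        for p in plist:
            var = _pick_cis_variant(G, probes.loc[p], rng)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            b = sign * beta
            if kind == "shared":
                eff_a.append(CausalEffect(var, p, b, "both"))
                eff_b.append(CausalEffect(var, p, b, "both"))
                truth_pairs.append(CausalEffect(var, p, b, "both"))
            elif kind == "a_only":
                eff_a.append(CausalEffect(var, p, b, "A"))
                truth_pairs.append(CausalEffect(var, p, b, "A"))
            elif kind == "b_only":
                eff_b.append(CausalEffect(var, p, b, "B"))
                truth_pairs.append(CausalEffect(var, p, b, "B"))
            else:
                eff_a.append(CausalEffect(var, p, b, "both", True))
                eff_b.append(CausalEffect(var, p, -b, "both", True))
                truth_pairs.append(CausalEffect(var, p, b, "both", True))
    seed_a, seed_b = rng.integers(0, 2 ** 31, size=2)
    EA, truth_a = simulate_expression(
        G, probes, eff_a, n_confounders, confounder_sd, noise_sd,
        seed=int(seed_a))
    EB, _ = simulate_expression(
        G, probes, eff_b, n_confounders, confounder_sd, noise_sd,
        seed=int(seed_b))
    truth = SimTruth(causal_pairs=truth_pairs,
                     confounder_loadings=truth_a.confounder_loadings,
                     confounder_scores=truth_a.confounder_scores)
    return EA, EB, truth


def simulate_feature_track(variants: pd.DataFrame, causal_set,
                           width_bp: int = 500, p_cover_causal: float = 0.5,
                           p_cover_background: float = 0.05, seed=0,
                           label: str = "sim_track") -> FeatureTrack:
    """Intervals of ``width_bp`` centred on covered variants; causal
    variants are covered with ``p_cover_causal``, the rest with
    ``p_cover_background`` (planted fold = their ratio)."""
    rng = _rng(seed)
    causal = set(causal_set)
    half = (width_bp - 1) // 2
    rows = []
    for vid, row in variants.iterrows():
        p = p_cover_causal if vid in causal else p_cover_background
        if rng.random() < p:
            start = max(1, int(row["pos"]) - half)
            rows.append((row["chrom"], start, start + width_bp - 1))
    return FeatureTrack(label, pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))


def simulate_trait_catalog(variants: pd.DataFrame, categories: list[str],
                           causal_set, p_assoc_causal: float = 0.5,
                           p_assoc_background: float = 0.05,
                           seed=0) -> TraitCatalog:
    """Per category, associate causal variants with probability
    ``p_assoc_causal`` and the rest with ``p_assoc_background``."""
    rng = _rng(seed)
    causal = set(causal_set)
    rows = []
    for cat in categories:
        trait = f"{cat}_trait"
        for vid in variants.index:
            p = p_assoc_causal if vid in causal else p_assoc_background
            if rng.random() < p:
                rows.append((vid, trait, (cat,)))
    return TraitCatalog(pd.DataFrame(
        rows, columns=["variant", "trait", "categories"]))


def simulate_droplets(n_droplets: int, lam_c: float, lam_t: float,
                      seed=0, role: str = "chip",
                      replicate: str = "1") -> tuple[DdpcrWell, DdpcrWell]:
    """Two-channel Poisson-partitioned droplet counts.

    Each droplet is positive for an allele with probability
    1 - exp(-lambda_allele); the channels are independent.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if lam_c < 0 or lam_t < 0:
        raise ValueError("lambda must be non-negative")
    rng = _rng(seed)
    wells = []
    for allele, lam in (("C", lam_c), ("T", lam_t)):
        p = 1.0 - np.exp(-lam)
        n_pos = int(rng.binomial(n_droplets, p))
        wells.append(DdpcrWell(allele, role, n_pos, n_droplets - n_pos,
                               replicate))
    return wells[0], wells[1]
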