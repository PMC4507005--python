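"""Annotation enrichment: consensus tracks, interval overlap, TSS
distance, Fisher 2x2 enrichment, and LD-aware trait-catalog tagging.

Foreground/background convention: the enrichment fold is the ratio of
the foreground "in" proportion to the background "in" proportion, as
plotted in eQTL-annotation figures; the exact p comes from Fisher's test
on the 2x2 table.  Fisher's test assumes independent loci — variants in
LD violate this, and no correction is applied (the published analysis
carries the same caveat).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import ld as ld_tools
from .types import EnrichmentResult, FeatureTrack, GenotypeMatrix, TraitCatalog

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# consensus tracks and overlap

def _merge_intervals(df: pd.DataFrame) -> list[tuple]:
    """Merge overlapping/adjacent 1-based inclusive intervals per chrom."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return out


def consensus_track(per_donor_tracks: list[FeatureTrack],
                    min_frac: float = 0.5,
                    label: str | None = None) -> FeatureTrack:
    """Positions covered by at least ceil(min_frac * n_donors) donors,
    merged into maximal intervals.  Each donor counts once per position
    (a donor's own overlapping intervals are merged first)."""
    if not per_donor_tracks:
        raise ValueError("no donor tracks supplied")
    n = len(per_donor_tracks)
    need = int(np.ceil(min_frac * n))
    label = label or per_donor_tracks[0].label
    events: dict[str, list[tuple[int, int]]] = {}
    for track in per_donor_tracks:
        for chrom, s, e in _merge_intervals(track.intervals):
            events.setdefault(chrom, []).append((s, 1))
            events[chrom].append((e + 1, -1))
    rows = []
    for chrom, ev in events.items():
        ev.sort()
        depth = 0
        open_start = None
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            while i < len(ev) and ev[i][0] == pos:
                depth += ev[i][1]
                i += 1
            if depth >= need and open_start is None:
                open_start = pos
            elif depth < need and open_start is not None:
                rows.append((chrom, open_start, pos - 1))
                open_start = None
    return FeatureTrack(label, pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))


def overlap(variants: pd.DataFrame, track: FeatureTrack) -> pd.Series:
    """Boolean membership: a variant is "in" iff its position falls inside
    an interval (inclusive ends; distance to nearest feature = 0)."""
    merged = _merge_intervals(track.intervals)
    lists: dict[str, tuple[list, list]] = {}
    for chrom, s, e in merged:
        lists.setdefault(chrom, ([], []))
        lists[chrom][0].append(s)
        lists[chrom][1].append(e)
    by_chrom = {c: (np.asarray(v[0]), np.asarray(v[1]))
                for c, v in lists.items()}
    out = np.zeros(len(variants), dtype=bool)
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    for chrom, (starts, ends) in by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        j = np.searchsorted(starts, pos[mask], side="right") - 1
        inside = (j >= 0) & (pos[mask] <= ends[np.maximum(j, 0)])
        out[mask] = inside
    return pd.Series(out, index=variants.index, name="in_track")


def tss_distance(peaks: pd.DataFrame, probes: pd.DataFrame) -> pd.Series:
    """Signed bp from each peak variant to its probe's TSS, oriented so
    positive means downstream of the TSS in gene orientation."""
    tss = peaks["probe"].map(probes["tss"])
    strand = peaks["probe"].map(probes["strand"])
    d = (peaks["pos"] - tss) * np.where(strand == "-", -1, 1)
    return pd.Series(d.to_numpy(), index=peaks.index, name="tss_distance")


# ---------------------------------------------------------------------------
# Fisher enrichment

def ratio_of_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Fold enrichment (k1/n1) / (k2/n2); the standalone worked-example op."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if k2 == 0:
        return float("nan")
    return (k1 / n1) / (k2 / n2)


def fisher_enrichment(fg_in: int, fg_n: int, bg_in: int, bg_n: int,
                      label: str = "") -> EnrichmentResult:
    """2x2 enrichment of a foreground set against a background.

    fold = (fg_in/fg_n)/(bg_in/bg_n) with a Katz log 95% CI; the odds
    ratio carries a Woolf log CI (0.5 continuity correction when any cell
    is zero); the two-sided p is Fisher's exact (hypergeometric tail
    summation).  bg_in = 0 leaves the fold undefined (NaN, warned).
    """
    if fg_n <= 0 or bg_n <= 0:
        raise ValueError("set sizes must be positive")
    if not (0 <= fg_in <= fg_n and 0 <= bg_in <= bg_n):
        raise ValueError("inconsistent 2x2 counts")
    a, b = fg_in, fg_n - fg_in
    c, d = bg_in, bg_n - bg_in
    if c == 0:
        logger.warning("background 'in' count is zero: fold undefined")
        fold = float("nan")
        fold_ci = (float("nan"), float("nan"))
    else:
        fold = ratio_of_proportions(a, fg_n, c, bg_n)
        # Katz log-RR interval; continuity correction keeps zero cells finite
        aa, cc = (a, c) if a > 0 else (a + 0.5, c + 0.5)
        se_log = np.sqrt(1 / aa - 1 / fg_n + 1 / cc - 1 / bg_n)
        log_rr = np.log((aa / fg_n) / (cc / bg_n))
        fold_ci = (float(np.exp(log_rr - 1.96 * se_log)),
                   float(np.exp(log_rr + 1.96 * se_log)))
    if min(a, b, c, d) == 0:
        aw, bw, cw, dw = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aw, bw, cw, dw = a, b, c, d
    or_point = (aw * dw) / (bw * cw)
    se_or = np.sqrt(1 / aw + 1 / bw + 1 / cw + 1 / dw)
    or_ci = (float(or_point * np.exp(-1.96 * se_or)),
             float(or_point * np.exp(1.96 * se_or)))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(label, a, b, c, d, float(fold), fold_ci,
                            float(or_point), or_ci, float(p))


def track_enrichment(fg_variants: pd.DataFrame, bg_variants: pd.DataFrame,
                     track: FeatureTrack) -> EnrichmentResult:
    """Enrichment of a foreground variant set in a feature track, against
    a background variant set (both as variant tables with chrom/pos)."""
    fg_in = int(overlap(fg_variants, track).sum())
    bg_in = int(overlap(bg_variants, track).sum())
    return fisher_enrichment(fg_in, len(fg_variants), bg_in,
                             len(bg_variants), label=track.label)


# ---------------------------------------------------------------------------
# trait-catalog tagging

def gwas_tag(eqtl_variants, catalog: TraitCatalog, G: GenotypeMatrix,
             r2: float = 0.8, window_bp: int = 1_000_000
             ) -> dict[str, set[str]]:
    """Map each eQTL variant to the traits it is, or tags (LD r^2 > ``r2``
    within ``window_bp``), a catalog variant for.  Untagged variants map
    to an empty set."""
    traits_of: dict[str, set[str]] = {}
    for rec in catalog.records.itertuples(index=False):
        traits_of.setdefault(rec.variant, set()).add(rec.trait)
    cat_meta = G.variants.loc[[v for v in traits_of if v in G.variants.index]]
    out: dict[str, set[str]] = {}
    for vid in eqtl_variants:
        tagged: set[str] = set(traits_of.get(vid, set()))
        if vid in G.variants.index and len(cat_meta):
            v = G.variants.loc[vid]
            near = cat_meta[
                (cat_meta["chrom"] == v["chrom"])
                & (cat_meta["pos"] - v["pos"]).abs().le(window_bp)]
            for cvid in near.index:
                if cvid == vid or cvid in tagged:
                    continue
                r2_obs = ld_tools.ld_r2(
                    G.dosages[vid].to_numpy(dtype=float),
                    G.dosages[cvid].to_numpy(dtype=float))
                if not np.isnan(r2_obs) and r2_obs > r2:
                    tagged |= traits_of[cvid]
        out[vid] = tagged
    return out


def category_enrichment(eqtl_variants, all_tested_variants,
                        catalog: TraitCatalog, G: GenotypeMatrix,
                        r2: float = 0.8, window_bp: int = 1_000_000
                        ) -> list[EnrichmentResult]:
    """Per disease category: Fisher enrichment of trait-tagged eQTL
    variants against the all-tested-variants background."""
    eqtl_variants = list(eqtl_variants)
    all_tested_variants = list(all_tested_variants)
    trait_cat: dict[str, set[str]] = {}
    for rec in catalog.records.itertuples(index=False):
        trait_cat.setdefault(rec.trait, set()).update(rec.categories)
    fg_tags = gwas_tag(eqtl_variants, catalog, G, r2, window_bp)
    bg_tags = gwas_tag(all_tested_variants, catalog, G, r2, window_bp)
    results = []
    for cat in catalog.categories():
        def n_in(tags):
            return sum(
                1 for traits in tags.values()
                if any(cat in trait_cat.get(t, set()) for t in traits))
        res = fisher_enrichment(n_in(fg_tags), len(eqtl_variants),
                                n_in(bg_tags), len(all_tested_variants),
                                label=cat)
        results.append(res)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
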