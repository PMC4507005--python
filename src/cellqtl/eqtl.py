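"""Cis/trans eQTL scanning under a linear-additive model with PC covariates.

The scan uses the matrix method: dosages and expression are residualized
against the covariates (Frisch-Waugh), columns are standardized, and the
per-pair t statistic is recovered from the residual correlation,
t = r * sqrt(df) / sqrt(1 - r^2), with df = n - (#covariates incl.
intercept) - 1.  This is algebraically identical to the dosage
coefficient's t in a per-pair OLS of expression on dosage + covariates
(verified against that oracle in the test suite), but costs one matrix
product per probe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GenotypeMatrix, RESULT_COLUMNS

logger = logging.getLogger(__name__)

#: floor for underflowing p-values (smallest positive normal double)
P_FLOOR = float(np.finfo(float).tiny)


def residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Replace each column of M with its OLS residual on C.

    C must contain an intercept (a non-zero constant column); without it
    the residual correlation no longer matches the regression t.
    """
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != M.shape[0]:
        raise ValueError("covariate matrix shape mismatch")
    const = (np.ptp(C, axis=0) == 0) & (C[0] != 0)
    if not const.any():
        raise ValueError("covariate matrix must include an intercept column")
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def make_covariates(n: int, pcs: np.ndarray | None = None) -> np.ndarray:
    """Intercept column plus optional PC scores."""
    cols = [np.ones((n, 1))]
    if pcs is not None and np.asarray(pcs).size:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        cols.append(pcs)
    return np.hstack(cols)


def _impute_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Per-variant mean imputation of missing dosages (flagged in the log)."""
    X = G.dosages.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if miss.any():
        logger.info("mean-imputing %d missing dosages at scan time",
                    int(miss.sum()))
        means = np.nanmean(X, axis=0)
        X[miss] = np.take(means, np.nonzero(miss)[1])
    return X


class _ScanContext:
    """Residualized, precomputed quantities shared by all pair tests."""

    def __init__(self, G: GenotypeMatrix, E: ExpressionMatrix,
                 covariates: np.ndarray | None):
        if list(G.samples) != list(E.samples):
            raise ValueError(
                "genotype and expression samples differ or are out of order")
        n = G.n_samples
        C = (covariates if covariates is not None
             else make_covariates(n))
        self.df = n - C.shape[1] - 1
        if self.df < 1:
            raise ValueError(
                f"not enough samples (n={n}) for {C.shape[1]} covariates")
        X = _impute_dosages(G)
        self.Xr = residualize(X, C)
        self.Yr = residualize(E.values.to_numpy(dtype=float), C)
        self.gg = np.einsum("ij,ij->j", self.Xr, self.Xr)
        self.ee = np.einsum("ij,ij->j", self.Yr, self.Yr)
        self.poly = self.gg > n * 1e-12      # monomorphic-after-residual guard
        if not self.poly.all():
            logger.info("skipping %d monomorphic variants",
                        int((~self.poly).sum()))
        self.G, self.E = G, E

    def test_probe(self, probe_j: int, var_idx: np.ndarray) -> pd.DataFrame:
        """All variant tests for one probe column; returns result rows."""
        var_idx = var_idx[self.poly[var_idx]]
        if var_idx.size == 0 or self.ee[probe_j] <= 0:
            return _empty_results()
        y = self.Yr[:, probe_j]
        ge = self.Xr[:, var_idx].T @ y
        gg = self.gg[var_idx]
        ee = self.ee[probe_j]
        beta = ge / gg
        r2 = np.clip(ge * ge / (gg * ee), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.sign(ge) * np.sqrt(r2 * self.df / (1.0 - r2))
            rss = np.maximum(ee - ge * ge / gg, 0.0)
            se = np.sqrt(rss / self.df / gg)
        p = 2.0 * stats.t.sf(np.abs(t), self.df)
        floored = p < P_FLOOR
        if floored.any():
            logger.info("flooring %d underflowed p-values at %.3g",
                        int(floored.sum()), P_FLOOR)
            p = np.maximum(p, P_FLOOR)
        probe = self.E.probes.index[probe_j]
        vids = self.G.variants.index[var_idx]
        return pd.DataFrame({
            "variant": vids,
            "probe": probe,
            "gene": self.E.probes.at[probe, "gene"],
            "chrom": self.G.variants["chrom"].to_numpy()[var_idx],
            "pos": self.G.variants["pos"].to_numpy()[var_idx],
            "beta": beta, "se": se, "t": t, "p": p,
            "r2": r2,
        })


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object if c in
                                      ("variant", "probe", "gene", "chrom",
                                       "mode", "cell_type") else float)
                         for c in RESULT_COLUMNS})


def _finalize(frames: list[pd.DataFrame], mode: str,
              cell_type: str) -> pd.DataFrame:
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_results()
    out = pd.concat(frames, ignore_index=True)
    out["mode"] = mode
    out["cell_type"] = cell_type
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.loc[:, list(RESULT_COLUMNS)]


def cis_pairs(G: GenotypeMatrix, E: ExpressionMatrix,
              window: int = 1_000_000) -> dict[int, np.ndarray]:
    """Probe column -> candidate variant columns whose position lies within
    ``window`` bp of the probe interval [start, end]."""
    out: dict[int, np.ndarray] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(G.variants["chrom"]):
        mask = (G.variants["chrom"] == chrom).to_numpy()
        idx = np.nonzero(mask)[0]
        pos = G.variants["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], idx[order])
    for j, (probe, row) in enumerate(E.probes.iterrows()):
        got = by_chrom.get(row["chrom"])
        if got is None:
            continue
        pos, idx = got
        lo = np.searchsorted(pos, row["start"] - window, side="left")
        hi = np.searchsorted(pos, row["end"] + window, side="right")
        if hi > lo:
            out[j] = idx[lo:hi]
    return out


def cis_scan(G: GenotypeMatrix, E: ExpressionMatrix,
             window: int = 1_000_000, covariates: np.ndarray | None = None,
             cell_type: str = "") -> pd.DataFrame:
    """Test every variant within ``window`` bp of each probe's interval.

    Returns one row per tested pair with beta, se, t, p, BH q (over the
    whole cis family), and r^2 (squared partial correlation = fraction of
    covariate-adjusted expression variance explained).
    """
    ctx = _ScanContext(G, E, covariates)
    pairs = cis_pairs(G, E, window)
    frames = [ctx.test_probe(j, idx) for j, idx in pairs.items()]
    return _finalize(frames, "cis", cell_type)


def trans_scan(G: GenotypeMatrix, E: ExpressionMatrix,
               covariates: np.ndarray | None = None,
               cell_type: str = "",
               variant_subset=None) -> pd.DataFrame:
    """Test variants on a different (non-contiguous) chromosome from the
    probe.  ``variant_subset`` optionally restricts the variants tested."""
    ctx = _ScanContext(G, E, covariates)
    chroms = G.variants["chrom"].to_numpy()
    allowed = np.ones(G.n_variants, dtype=bool)
    if variant_subset is not None:
        allowed = G.variants.index.isin(set(variant_subset))
    frames = []
    for j, (probe, row) in enumerate(E.probes.iterrows()):
        idx = np.nonzero((chroms != row["chrom"]) & allowed)[0]
        if idx.size:
            frames.append(ctx.test_probe(j, idx))
    return _finalize(frames, "trans", cell_type)


def significant(associations: pd.DataFrame, cis_fdr: float = 0.05,
                trans_fdr: float = 0.01) -> pd.DataFrame:
    """FDR-filter associations, each mode forming its own BH family."""
    if len(associations) == 0:
        return associations.copy()
    parts = []
    for mode, thr in (("cis", cis_fdr), ("trans", trans_fdr)):
        fam = associations[associations["mode"] == mode].copy()
        if len(fam) == 0:
            continue
        fam["q"] = bh_fdr(fam["p"].to_numpy())
        parts.append(fam[fam["q"] <= thr])
    if not parts:
        return associations.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


def peak_per_probe(associations: pd.DataFrame) -> pd.DataFrame:
    """The most significant association per probe.

    Ties on p are broken by larger |beta|, then smaller position, then
    lexicographic variant id — a total, deterministic order.
    """
    if len(associations) == 0:
        out = associations.copy()
        out["n_tested"] = pd.Series(dtype=int)
        return out
    df = associations.copy()
    df["_absbeta"] = -df["beta"].abs()
    df = df.sort_values(["p", "_absbeta", "pos", "variant"],
                        kind="mergesort")
    n = associations.groupby("probe").size()
    peaks = df.drop_duplicates("probe", keep="first").drop(columns="_absbeta")
    peaks["n_tested"] = peaks["probe"].map(n)
    return peaks.reset_index(drop=True)


def peak_per_gene(associations: pd.DataFrame) -> pd.DataFrame:
    """As peak_per_probe but at gene granularity."""
    if len(associations) == 0:
        return associations.copy()
    df = associations.copy()
    df["_absbeta"] = -df["beta"].abs()
    df = df.sort_values(["p", "_absbeta", "pos", "variant"],
                        kind="mergesort")
    return (df.drop_duplicates("gene", keep="first")
            .drop(columns="_absbeta").reset_index(drop=True))


def conditional_scan(G: GenotypeMatrix, E: ExpressionMatrix, probe: str,
                     condition_variant: str,
                     covariates: np.ndarray | None = None,
                     window: int = 1_000_000,
                     cell_type: str = "") -> pd.DataFrame:
    """Re-run the cis scan of one probe with the conditioning variant's
    (mean-imputed) dosage added to the covariates; the conditioning
    variant itself is excluded from the output."""
    if condition_variant not in G.variants.index:
        raise KeyError(f"unknown variant {condition_variant!r}")
    if probe not in E.probes.index:
        raise KeyError(f"unknown probe {probe!r}")
    d = G.dosages[condition_variant].to_numpy(dtype=float)
    d = np.where(np.isnan(d), np.nanmean(d), d)
    C = (covariates if covariates is not None
         else make_covariates(G.n_samples))
    C = np.column_stack([C, d])
    sub_E = E.subset(probes=[probe])
    res = cis_scan(G, sub_E, window=window, covariates=C,
                   cell_type=cell_type)
    return res[res["variant"] != condition_variant].reset_index(drop=True)
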