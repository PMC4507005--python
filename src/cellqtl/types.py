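"""Core in-memory containers for the eQTL pipeline.

Coordinates are 1-based inclusive throughout (the VCF/GFF convention);
BED input is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: columns every variant table must carry (index = variant id)
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")

#: columns every probe table must carry (index = probe id)
PROBE_COLUMNS = ("gene", "chrom", "tss", "strand", "start", "end")

#: fixed column order of association result tables
RESULT_COLUMNS = (
    "variant", "probe", "gene", "chrom", "pos",
    "beta", "se", "t", "p", "q", "r2", "mode", "cell_type",
)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages`` is a samples-by-variants DataFrame of alternate-allele
    dosages in [0, 2]; missing genotypes are NaN and are mean-imputed only
    at scan time.  ``variants`` is indexed by variant id and carries at
    least chrom, pos, ref, alt; optional columns include ``info_score``
    (imputation quality) and ``imputed`` (provenance flag).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.is_unique:
            dup = self.variants.index[self.variants.index.duplicated()][0]
            raise ValueError(f"duplicate variant id: {dup!r}")
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns do not match variant table index")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be >= 1 (1-based)")
        bad = self.variants["ref"] == self.variants["alt"]
        if bad.any():
            raise ValueError(
                f"ref == alt for variant {self.variants.index[bad][0]!r}")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-9 or np.nanmax(vals, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant (missing dosages excluded)."""
        p = self.dosages.mean(axis=0, skipna=True) / 2.0
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1).rename("maf")

    def missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0).rename("missing_rate")

    def subset(self, variants: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "GenotypeMatrix":
        d, v = self.dosages, self.variants
        if variants is not None:
            d = d.loc[:, list(variants)]
            v = v.loc[list(variants)]
        if samples is not None:
            d = d.loc[list(samples)]
        return GenotypeMatrix(d, v)


@dataclass
class ExpressionMatrix:
    """Samples x probes expression with probe -> gene annotation.

    ``probes`` is indexed by probe id with gene, chrom, tss, strand and the
    probe's genomic interval [start, end] (1-based inclusive).  Optional
    boolean flag columns ``multi_mapping`` and ``polymorphic_target`` mark
    probes excluded from association analysis.
    """

    values: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if list(self.values.columns) != list(self.probes.index):
            raise ValueError("expression columns do not match probe table index")
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table lacks columns: {missing}")
        if (self.probes["start"] > self.probes["end"]).any():
            raise ValueError("probe interval start > end")
        bad = ~self.probes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"bad strand for probe {self.probes.index[bad][0]!r}")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, probes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        v, p = self.values, self.probes
        if probes is not None:
            v = v.loc[:, list(probes)]
            p = p.loc[list(probes)]
        if samples is not None:
            v = v.loc[list(samples)]
        return ExpressionMatrix(v, p)


@dataclass
class FeatureTrack:
    """Labelled genomic intervals, 1-based inclusive, sorted per chromosome."""

    label: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"interval table lacks column {c!r}")
        if len(df) and (df["start"] > df["end"]).any():
            raise ValueError("interval with start > end")
        self.intervals = (
            df.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class TraitCatalog:
    """Variant-trait associations with up to three disease categories per trait."""

    records: pd.DataFrame  # columns variant, trait, categories (tuple of str)

    MAX_CATEGORIES = 3

    def __post_init__(self) -> None:
        df = self.records
        for c in ("variant", "trait", "categories"):
            if c not in df.columns:
                raise ValueError(f"catalog lacks column {c!r}")
        for cats, trait in zip(df["categories"], df["trait"]):
            if len(cats) > self.MAX_CATEGORIES:
                raise ValueError(
                    f"trait {trait!r} has {len(cats)} categories (max "
                    f"{self.MAX_CATEGORIES})")
        self.records = df.reset_index(drop=True)

    @property
    def variants(self) -> set:
        return set(self.records["variant"])

    def categories(self) -> list[str]:
        out: set[str] = set()
        for cats in self.records["categories"]:
            out.update(cats)
        return sorted(out)

    def by_category(self, category: str) -> set:
        """Variant ids associated with at least one trait of the category."""
        mask = self.records["categories"].map(lambda cs: category in cs)
        return set(self.records.loc[mask, "variant"])


@dataclass
class DdpcrWell:
    """One ddPCR well: droplet counts for a single allele channel."""

    allele: str           # channel label, e.g. "C" or "T"
    role: str             # input | chip | positive_control | negative_control
    n_pos: int
    n_neg: int
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("droplet counts must be non-negative")
        if self.n_pos + self.n_neg == 0:
            raise ValueError("well has no droplets")

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class AsbResult:
    """Allele-specific binding test outcome for one donor."""

    observed_ratio: float
    expected_ratio: float
    chi2: float
    df: int
    p: float
    lambda_c: float = float("nan")
    lambda_t: float = float("nan")


@dataclass
class EnrichmentResult:
    """2x2 enrichment of a foreground variant set in an annotation."""

    label: str
    fg_in: int
    fg_out: int
    bg_in: int
    bg_out: int
    fold: float
    ci95: tuple          # 95% CI of the fold (ratio of proportions)
    odds_ratio: float
    or_ci95: tuple       # Woolf 95% CI of the odds ratio
    p: float

    def as_dict(self) -> dict:
        return {
            "label": self.label, "fg_in": self.fg_in, "fg_out": self.fg_out,
            "bg_in": self.bg_in, "bg_out": self.bg_out, "fold": self.fold,
            "fold_ci_lo": self.ci95[0], "fold_ci_hi": self.ci95[1],
            "odds_ratio": self.odds_ratio,
            "or_ci_lo": self.or_ci95[0], "or_ci_hi": self.or_ci95[1],
            "p": self.p,
        }


@dataclass
class CausalEffect:
    """One planted variant -> probe effect in a simulation."""

    variant: str
    probe: str
    beta: float
    cell_type: str = "both"      # "both", or a cell label for cell-specific
    sign_discordant: bool = False


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generators."""

    causal_pairs: list = field(default_factory=list)        # CausalEffect
    confounder_loadings: np.ndarray | None = None           # probes x k
    confounder_scores: np.ndarray | None = None             # samples x k
    enriched_tracks: list = field(default_factory=list)     # (label, fold)
    droplet_truth: dict = field(default_factory=dict)       # well -> lambda

    def causal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.variant, c.probe, c.beta, c.cell_type, c.sign_discordant)
             for c in self.causal_pairs],
            columns=["variant", "probe", "beta", "cell_type", "sign_discordant"],
        )
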