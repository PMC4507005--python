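"""Readers and writers for the pipeline's external formats.

Formats handled: VCF (via pysam) and a self-describing dosage TSV for
genotypes; TSV for expression, probe annotation, detection p-values,
trait catalogs, ddPCR well tables and association results; BED for
feature tracks.  Internal coordinates are 1-based inclusive; BED's
0-based half-open convention is converted at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import (
    DdpcrWell, ExpressionMatrix, FeatureTrack, GenotypeMatrix, TraitCatalog,
    RESULT_COLUMNS,
)

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", ".", "NA", "NaN", "nan"}
_META_COLS = ["id", "chrom", "pos", "ref", "alt", "info_score"]


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype dosage matrix from VCF or dosage TSV.

    VCF: per-sample DS is used when present, otherwise GT is converted to
    an alternate-allele count.  TSV: metadata columns (id, chrom, pos, ref,
    alt, info_score) followed by one column per sample.  Missing genotypes
    become NaN; they are mean-imputed only at scan time.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".bcf", ".gz"} else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    has_info = "INFO" in vf.header.info
    rows, meta, ids = [], [], set()
    for rec in vf:
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        if vid in ids:
            raise ValueError(f"duplicate variant id {vid!r} in {path}")
        ids.add(vid)
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"variant {vid!r}: exactly one ALT allele required")
        dos = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            sample = rec.samples[s]
            ds = sample.get("DS") if "DS" in sample else None
            if ds is not None:
                dos[i] = float(ds if np.isscalar(ds) else ds[0])
            else:
                gt = sample.get("GT")
                if gt is not None and None not in gt:
                    dos[i] = float(sum(gt))
        info = rec.info.get("INFO", None) if has_info else None
        meta.append((vid, rec.chrom, rec.pos, rec.ref, rec.alts[0],
                     float(info) if info is not None else np.nan))
        rows.append(dos)
    vf.close()
    variants = pd.DataFrame(
        meta, columns=_META_COLS).set_index("id")
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"), columns=variants.index)
    return GenotypeMatrix(dosages, variants)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLS if c not in raw.columns]
    if missing_meta:
        raise ValueError(f"{path}: dosage TSV lacks columns {missing_meta}")
    if raw["id"].duplicated().any():
        dup = raw.loc[raw["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate variant id {dup!r}")
    sample_cols = [c for c in raw.columns if c not in _META_COLS]
    dos = np.full((len(raw), len(sample_cols)), np.nan)
    for j, c in enumerate(sample_cols):
        col = raw[c].str.strip()
        num = pd.to_numeric(col.where(~col.isin(_NA_STRINGS)), errors="coerce")
        bad = num.isna() & ~col.isin(_NA_STRINGS)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{path}: malformed dosage {col[bad.idxmax()]!r} at line {line}")
        dos[:, j] = num.to_numpy()
    variants = pd.DataFrame({
        "chrom": raw["chrom"].to_numpy(),
        "pos": pd.to_numeric(raw["pos"]).astype(int).to_numpy(),
        "ref": raw["ref"].to_numpy(),
        "alt": raw["alt"].to_numpy(),
        "info_score": pd.to_numeric(
            raw["info_score"].where(~raw["info_score"].isin(_NA_STRINGS)),
            errors="coerce").to_numpy(),
    }, index=pd.Index(raw["id"], name="id"))
    dosages = pd.DataFrame(dos.T, index=pd.Index(sample_cols, name="sample"),
                           columns=variants.index)
    return GenotypeMatrix(dosages, variants)


def write_genotypes(G: GenotypeMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        _write_vcf(G, path)
    elif fmt == "tsv":
        _write_dosage_tsv(G, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _fmt(x: float) -> str:
    return "." if np.isnan(x) else f"{x:.10g}"


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.variants["chrom"]):
            sub = G.variants.loc[G.variants["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(sub.max()) + 10_000}>\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,'
                 'Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.samples)) + "\n")
        order = G.variants.sort_values(["chrom", "pos"], kind="mergesort").index
        dos = G.dosages
        for vid in order:
            v = G.variants.loc[vid]
            info = ("." if "info_score" not in G.variants.columns
                    or np.isnan(v.get("info_score", np.nan))
                    else f"INFO={v['info_score']:.6g}")
            vals = "\t".join(_fmt(x) for x in dos[vid].to_numpy(dtype=float))
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t"
                     f"{v['alt']}\t.\t.\t{info}\tDS\t{vals}\n")


def _write_dosage_tsv(G: GenotypeMatrix, path: Path) -> None:
    meta = G.variants.copy()
    if "info_score" not in meta.columns:
        meta["info_score"] = np.nan
    cols = {
        "id": meta.index, "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(), "ref": meta["ref"].to_numpy(),
        "alt": meta["alt"].to_numpy(),
        "info_score": [_fmt(x) for x in meta["info_score"].to_numpy(dtype=float)],
    }
    dos = G.dosages.to_numpy(dtype=float)
    for i, s in enumerate(G.samples):
        cols[s] = [_fmt(x) for x in dos[i]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def read_expression(path, probes_path, detection_path=None
                    ) -> tuple[ExpressionMatrix, pd.DataFrame | None]:
    """Read a samples x probes expression TSV plus probe annotation.

    Probes lacking annotation are dropped (count logged).  Returns the
    matrix and, if ``detection_path`` is given, the matching detection
    p-value frame.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "sample"
    probes = pd.read_csv(probes_path, sep="\t", index_col=0)
    probes.index.name = "probe_id"
    for flag in ("multi_mapping", "polymorphic_target"):
        if flag in probes.columns:
            probes[flag] = probes[flag].astype(bool)
        else:
            probes[flag] = False
    known = [p for p in values.columns if p in probes.index]
    n_drop = values.shape[1] - len(known)
    if n_drop:
        logger.warning("dropping %d expression probes lacking annotation", n_drop)
    E = ExpressionMatrix(values.loc[:, known], probes.loc[known])
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
        detection = detection.loc[E.values.index, known]
    return E, detection


def write_expression(E: ExpressionMatrix, values_path, probes_path=None,
                     float_format: str = "%.10g") -> None:
    E.values.to_csv(values_path, sep="\t", float_format=float_format)
    if probes_path is not None:
        E.probes.to_csv(probes_path, sep="\t")


def check_sample_alignment(G: GenotypeMatrix, E: ExpressionMatrix) -> None:
    """Raise if genotype and expression sample sets differ."""
    gs, es = set(G.samples), set(E.samples)
    if gs != es:
        diff = sorted(gs.symmetric_difference(es))
        raise ValueError(f"sample mismatch between genotypes and expression: {diff}")


# ---------------------------------------------------------------------------
# BED feature tracks

def read_bed(path, label: str | None = None) -> FeatureTrack:
    """Read BED3+ (0-based half-open) into a 1-based inclusive track."""
    path = Path(path)
    rows = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with <3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: BED start {start} >= end {end}")
            if len(parts) >= 4:
                names.add(parts[3])
            rows.append((chrom, start + 1, end))
    if label is None:
        label = names.pop() if len(names) == 1 else path.stem
    return FeatureTrack(label, pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for row in track.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{track.label}\n")


# ---------------------------------------------------------------------------
# trait catalog

def read_catalog(path) -> TraitCatalog:
    """TSV with columns variant, trait, categories (comma-separated, <=3)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for c in ("variant", "trait"):
        if c not in df.columns:
            raise ValueError(f"{path}: catalog lacks column {c!r}")
    if "categories" not in df.columns:
        df["categories"] = ""
    cats = df["categories"].map(
        lambda s: tuple(x.strip() for x in s.split(",") if x.strip()))
    return TraitCatalog(pd.DataFrame({
        "variant": df["variant"], "trait": df["trait"], "categories": cats}))


def write_catalog(catalog: TraitCatalog, path) -> None:
    out = catalog.records.copy()
    out["categories"] = out["categories"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ddPCR wells

def read_wells(path) -> list[DdpcrWell]:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    needed = {"allele", "role", "n_pos", "n_neg"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: well table lacks columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    return [DdpcrWell(r.allele, r.role, int(r.n_pos), int(r.n_neg),
                      str(r.replicate))
            for r in df.itertuples(index=False)]


def write_wells(wells: list[DdpcrWell], path) -> None:
    pd.DataFrame(
        [(w.allele, w.role, w.replicate, w.n_pos, w.n_neg) for w in wells],
        columns=["allele", "role", "replicate", "n_pos", "n_neg"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association result tables

def write_results(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", index=False,
                           float_format=float_format)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
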