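"""Expression QC: detection filtering, probe exclusion, normalization,
iterative outlier removal, and PCA covariates.

Normalization is quantile normalization to the mean empirical
distribution followed by an optional log2(x+1).  The array-vendor
random-spline + variance-stabilizing pipeline this stands in for is tied
to bead-level internals; the association model downstream only needs the
per-sample distributions equalized and the variance roughly stabilized,
which quantile normalization provides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)


def detection_filter(E: ExpressionMatrix, detection_p: pd.DataFrame,
                     alpha: float = 0.01,
                     min_frac: float = 0.05) -> ExpressionMatrix:
    """Keep a probe iff it is confidently detected (detection p < alpha)
    in strictly more than ``min_frac`` of samples."""
    if detection_p.shape != E.values.shape:
        raise ValueError(
            f"detection matrix shape {detection_p.shape} does not match "
            f"expression {E.values.shape}")
    det = detection_p.loc[E.values.index, E.values.columns]
    frac = (det.to_numpy() < alpha).mean(axis=0)
    keep = E.probes.index[frac > min_frac]
    dropped = E.values.shape[1] - len(keep)
    if dropped:
        logger.info("detection filter dropped %d probes", dropped)
    return E.subset(probes=keep)


def filter_probes(E: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes flagged multi-mapping or overlapping common polymorphisms."""
    flags = (E.probes.get("multi_mapping", False)
             | E.probes.get("polymorphic_target", False))
    if np.isscalar(flags):
        return E
    keep = E.probes.index[~flags.astype(bool)]
    dropped = len(E.probes) - len(keep)
    if dropped:
        logger.info("probe filter dropped %d flagged probes", dropped)
    return E.subset(probes=keep)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample quantile normalization to the mean empirical distribution.

    Each sample's i-th smallest value is replaced by the mean of the i-th
    smallest values across samples; sample-wise sorted vectors are
    identical afterwards and within-sample rank order is preserved.
    """
    X = values.to_numpy(dtype=float)
    order = np.argsort(X, axis=1, kind="mergesort")
    ranks = np.argsort(order, axis=1, kind="mergesort")
    mean_dist = np.sort(X, axis=1).mean(axis=0)
    return pd.DataFrame(mean_dist[ranks], index=values.index,
                        columns=values.columns)


def normalize_expression(E: ExpressionMatrix,
                         log_transform: bool | None = None
                         ) -> ExpressionMatrix:
    """Quantile-normalize, then log2(x+1) unless already log-scale.

    ``log_transform=None`` auto-detects: raw array intensities (max > 30)
    are logged, already-transformed data are left on their scale.
    """
    if log_transform is None:
        log_transform = bool(np.nanmax(E.values.to_numpy()) > 30)
    vals = quantile_normalize(E.values)
    if log_transform:
        if (vals.to_numpy() < -1).any():
            raise ValueError("negative values: refusing log2(x+1)")
        vals = np.log2(vals + 1.0)
    return ExpressionMatrix(vals, E.probes)


def remove_outliers(E: ExpressionMatrix, threshold_sd: float = 3.0,
                    max_iter: int = 10, renormalize: bool = True
                    ) -> tuple[ExpressionMatrix, list]:
    """Iterative sample-outlier removal on Euclidean distance to centroid.

    Each iteration removes samples whose distance to the probe-wise mean
    exceeds mean + threshold_sd * SD of the distances, then re-normalizes
    the survivors; stops when nothing is removed or after ``max_iter``.
    With fewer than three samples the SD rule is degenerate and nothing
    is removed.
    """
    current = E
    removed: list = []
    for _ in range(max_iter):
        if current.n_samples < 3:
            break
        X = current.values.to_numpy(dtype=float)
        dist = np.sqrt(((X - X.mean(axis=0)) ** 2).sum(axis=1))
        cut = dist.mean() + threshold_sd * dist.std(ddof=0)
        out = dist > cut
        if not out.any():
            break
        if out.all():
            raise ValueError("outlier removal would discard every sample")
        removed.extend(current.samples[out])
        keep = current.samples[~out]
        current = current.subset(samples=keep)
        if renormalize:
            current = ExpressionMatrix(quantile_normalize(current.values),
                                       current.probes)
    if removed:
        logger.info("removed %d outlier samples", len(removed))
    return current, removed


def compute_pcs(E: ExpressionMatrix, k: int = 15) -> np.ndarray:
    """Top-k principal-component scores of the probe-centred matrix.

    Columns are mutually orthogonal and ordered by decreasing explained
    variance; used downstream as scan covariates for hidden confounders.
    """
    n = E.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples ({n})")
    X = E.values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    return scores
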