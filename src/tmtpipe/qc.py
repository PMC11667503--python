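"""Three-step QC for TMT cohort matrices.

Step 1 — missingness filter (strict: a protein missing in >= max_frac of the
samples is dropped), sample-loading normalization (each column scaled to its
total), and log2 transform. Step 2 — iterative PCA outlier removal: samples
whose score on any of the leading principal components lies more than
``sd_cut`` sample standard deviations from the component mean are removed,
and PCA is recomputed on the survivors until an iteration removes nobody.
Step 3 — per-protein least-squares regression on batch indicators; residuals
plus the protein grand mean are returned, equalizing batch means while
preserving within-batch structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, AnalysisConfig, Dataset, Scale, TraitTable, TmtPipeError, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = [
    "QCReport",
    "filter_missingness",
    "normalize_loading",
    "log2_transform",
    "detect_outliers_pca",
    "regress_batch",
    "run_qc",
]


@dataclass
class QCReport:
    proteins_in: int = 0
    proteins_out: int = 0
    samples_in: int = 0
    samples_out: int = 0
    outliers_removed: list = field(default_factory=list)  # [(iteration, [sample ids])]
    batch_levels: int = 0
    parameters: dict = field(default_factory=dict)

    @property
    def outlier_ids(self) -> list[str]:
        return [s for _, ids in self.outliers_removed for s in ids]

    def to_dict(self) -> dict:
        return {
            "proteins_in": self.proteins_in,
            "proteins_out": self.proteins_out,
            "samples_in": self.samples_in,
            "samples_out": self.samples_out,
            "outliers_removed": [[it, list(ids)] for it, ids in self.outliers_removed],
            "batch_levels": self.batch_levels,
            "parameters": self.parameters,
        }


def filter_missingness(matrix: AbundanceMatrix, max_frac: float = 0.5) -> AbundanceMatrix:
    """Retain proteins whose missing fraction is strictly below ``max_frac``."""
    if not (0 < max_frac <= 1):
        raise ValidationError("max_frac must be in (0, 1]")
    frac = matrix.data.isna().mean(axis=1)
    keep = frac[frac < max_frac].index
    if len(keep) == 0:
        raise TmtPipeError(
            f"missingness filter at {max_frac} removed every protein; review the threshold"
        )
    dropped = matrix.n_features - len(keep)
    if dropped:
        logger.info("filter_missingness: dropped %d/%d proteins at max_frac=%g",
                    dropped, matrix.n_features, max_frac)
    return matrix.subset_features(keep)


def normalize_loading(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its total abundance (non-missing cells)."""
    if matrix.scale is not Scale.LINEAR:
        raise ValidationError("normalize_loading expects a linear-scale matrix")
    totals = matrix.data.sum(axis=0, skipna=True)
    bad = totals.index[(totals <= 0) | matrix.data.isna().all(axis=0)]
    if len(bad):
        raise TmtPipeError(f"samples with non-positive or all-missing totals: {list(bad)}")
    return matrix.with_data(matrix.data / totals, Scale.LINEAR)


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of a positive linear-scale matrix; missing cells preserved."""
    if matrix.scale is not Scale.LINEAR:
        raise ValidationError("log2_transform expects a linear-scale matrix")
    vals = matrix.data.to_numpy()
    nonpos = (vals <= 0) & ~np.isnan(vals)
    if nonpos.any():
        r, c = np.argwhere(nonpos)[0]
        raise ValidationError(
            f"non-positive value at feature {matrix.feature_ids[r]!r}, sample {matrix.sample_ids[c]!r}"
        )
    return matrix.with_data(np.log2(matrix.data), Scale.LOG2)


def _pca_scores(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Sample scores on the leading PCs of the feature covariance (unscaled).

    Missing cells are mean-imputed per feature for the decomposition only.
    """
    X = values.copy()
    row_mean = np.nanmean(X, axis=1, keepdims=True)
    inds = np.where(np.isnan(X))
    if inds[0].size:
        X[inds] = np.take(row_mean[:, 0], inds[0])
    X -= X.mean(axis=1, keepdims=True)
    # SVD of samples x features gives sample scores directly
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)
    k = min(n_pcs, len(s))
    return U[:, :k] * s[:k]


def detect_outliers_pca(
    matrix: AbundanceMatrix,
    sd_cut: float = 4.0,
    n_pcs: int = 2,
    max_iter: int = 10,
) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Iterative PCA outlier detection on a log2 matrix.

    Returns (kept sample ids, trace of per-iteration removals). The SD in the
    cut is the sample standard deviation of the retained samples' scores on
    each component at that iteration.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("detect_outliers_pca expects a log2-scale matrix")
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples for outlier detection")
    kept = list(matrix.sample_ids)
    trace: list[tuple[int, list[str]]] = []
    for it in range(1, max_iter + 1):
        sub = matrix.data.loc[:, kept]
        complete = sub.dropna(how="all")
        scores = _pca_scores(complete.to_numpy(), n_pcs)
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        flag = (np.abs(scores - mean) > sd_cut * sd).any(axis=1)
        removed = [kept[i] for i in np.where(flag)[0]]
        if not removed:
            break
        trace.append((it, removed))
        kept = [s for s in kept if s not in set(removed)]
        if len(kept) < 3:
            raise TmtPipeError("outlier removal left fewer than 3 samples")
    if trace:
        logger.info("detect_outliers_pca: removed %d samples in %d iteration(s)",
                    sum(len(r) for _, r in trace), len(trace))
    return kept, trace


def regress_batch(matrix: AbundanceMatrix, traits: TraitTable) -> AbundanceMatrix:
    """Remove batch means per protein, keeping the protein grand mean.

    Equivalent to least squares on batch indicator variables over complete
    observations: the returned values are the residuals plus the protein's
    grand mean, so batch-level means are equalized and within-batch deviations
    preserved. Missing cells stay missing.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("regress_batch expects a log2-scale matrix")
    missing_traits = [s for s in matrix.sample_ids if s not in set(traits.sample_ids)]
    if missing_traits:
        raise ValidationError(f"samples without trait rows: {missing_traits[:5]}")
    batch = traits.data.loc[matrix.sample_ids, "batch"]
    df = matrix.data
    grand = df.mean(axis=1, skipna=True)
    batch_means = df.T.groupby(batch).transform("mean").T
    out = df - batch_means.to_numpy() + grand.to_numpy()[:, None]
    return matrix.with_data(out, Scale.LOG2)


def run_qc(dataset: Dataset, config: Optional[AnalysisConfig] = None) -> tuple[Dataset, QCReport]:
    """Full QC chain on a linear-scale dataset.

    Order: missingness filter -> loading normalization -> log2 -> iterative
    PCA outlier removal (GIS channels excluded from the detector and dropped
    from the delivered dataset) -> batch regression.
    """
    cfg = config or AnalysisConfig()
    report = QCReport(
        proteins_in=dataset.matrix.n_features,
        samples_in=dataset.matrix.n_samples,
        parameters={
            "missing_max_frac": cfg.missing_max_frac,
            "outlier_sd": cfg.outlier_sd,
            "outlier_pcs": cfg.outlier_pcs,
            "outlier_max_iter": cfg.outlier_max_iter,
        },
    )
    m = filter_missingness(dataset.matrix, cfg.missing_max_frac)
    m = normalize_loading(m)
    m = log2_transform(m)

    gis = set(dataset.traits.gis_samples())
    donor_ids = [s for s in m.sample_ids if s not in gis]
    kept, trace = detect_outliers_pca(
        m.subset_samples(donor_ids), cfg.outlier_sd, cfg.outlier_pcs, cfg.outlier_max_iter
    )
    report.outliers_removed = trace

    m = m.subset_samples(kept)
    traits = dataset.traits.subset(kept)
    m = regress_batch(m, traits)

    report.proteins_out = m.n_features
    report.samples_out = m.n_samples
    report.batch_levels = traits.data["batch"].nunique()
    # bookkeeping counts are donor-sample based once GIS channels are set aside
    report.samples_in = len(donor_ids)
    logger.info("run_qc: %d->%d proteins, %d->%d samples, %d outliers",
                report.proteins_in, report.proteins_out,
                report.samples_in, report.samples_out, len(report.outlier_ids))
    return Dataset(m, traits), report
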