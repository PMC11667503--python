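"""GIS-anchored two-way median-polish harmonization and covariate adjustment.

`tampor_polish` removes multiplicative batch effects from a linear-scale
matrix by (1) dividing every sample's values by the batch's GIS median
profile (falling back to the batch median profile when a batch carries no GIS
channel), (2) log2-transforming the ratios, and (3) alternately subtracting
row (protein) and column (sample) medians until all medians are within
tolerance. The harmonized values live on a centered log2 ratio scale, which
is strictly invariant to rescaling any batch (including its GIS channel) by
a positive constant; ``restore_central=True`` adds back each protein's
median-across-batches log2 anchor for display on an abundance-like scale
(that offset is estimated from the data, so it is not batch-rescaling
invariant).

`adjust_covariates` residualizes each protein on nuisance covariates (age,
sex by default) with the regression coefficients averaged over bootstrap
refits, then restores the protein grand mean. Race and diagnosis are never
adjusted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, Dataset, Scale, TraitTable, TmtPipeError, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = ["PolishResult", "tampor_polish", "adjust_covariates"]

_NEVER_ADJUST = {"race", "diagnosis"}


@dataclass
class PolishResult:
    matrix: AbundanceMatrix          # log2 abundance scale, batch-harmonized
    iterations: int
    max_final_median: float
    converged: bool


def tampor_polish(
    matrix: AbundanceMatrix,
    traits: TraitTable,
    tol: float = 1e-4,
    max_iter: int = 250,
    gis_fallback: bool = True,
    restore_central: bool = False,
) -> PolishResult:
    """Two-way median polish of log2 ratios to the batch GIS profile."""
    if matrix.scale is not Scale.LINEAR:
        raise ValidationError("tampor_polish expects a linear-scale matrix")
    missing = [s for s in matrix.sample_ids if s not in set(traits.sample_ids)]
    if missing:
        raise ValidationError(f"samples without trait rows: {missing[:5]}")
    tr = traits.data.loc[matrix.sample_ids]
    batches = tr["batch"]
    df = matrix.data

    # per-batch anchor profile: GIS median, else batch median
    ratio = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    anchors: dict = {}
    for b, members in batches.groupby(batches).groups.items():
        cols = list(members)
        gis_cols = [c for c in cols if tr.loc[c, "is_gis"]]
        if gis_cols:
            anchor = df[gis_cols].median(axis=1)
        else:
            if not gis_fallback:
                raise TmtPipeError(f"batch {b!r} has no GIS channel and fallback is disabled")
            anchor = df[cols].median(axis=1)
        absent = anchor.index[anchor.isna() | (anchor <= 0)]
        if len(absent):
            if not gis_fallback:
                raise TmtPipeError(
                    f"batch {b!r}: anchor undefined for proteins {list(absent[:5])}"
                )
            fallback = df[cols].median(axis=1)
            anchor = anchor.where(~(anchor.isna() | (anchor <= 0)), fallback)
        ratio[cols] = df[cols].div(anchor, axis=0)
        anchors[b] = anchor

    log_ratio = np.log2(ratio)

    vals = log_ratio.to_numpy()
    iterations = 0
    max_median = np.inf
    for it in range(1, max_iter + 1):
        iterations = it
        row_med = np.nanmedian(vals, axis=1)
        row_med = np.where(np.isnan(row_med), 0.0, row_med)
        vals = vals - row_med[:, None]
        col_med = np.nanmedian(vals, axis=0)
        col_med = np.where(np.isnan(col_med), 0.0, col_med)
        vals = vals - col_med[None, :]
        check_r = np.nanmedian(vals, axis=1)
        check_c = np.nanmedian(vals, axis=0)
        max_median = max(
            float(np.nanmax(np.abs(check_r))) if check_r.size else 0.0,
            float(np.nanmax(np.abs(check_c))) if check_c.size else 0.0,
        )
        if max_median <= tol:
            break
    converged = max_median <= tol
    if not converged:
        logger.warning("tampor_polish: max |median| %.3g after %d iterations (tol %.3g)",
                       max_median, iterations, tol)

    out = pd.DataFrame(vals, index=df.index, columns=df.columns)
    if restore_central:
        central = np.log2(pd.DataFrame(anchors)).median(axis=1, skipna=True)
        out = out + central.to_numpy()[:, None]
    return PolishResult(AbundanceMatrix(out, Scale.LOG2), iterations, max_median, converged)


def adjust_covariates(
    matrix: AbundanceMatrix,
    traits: TraitTable,
    covariates: Sequence[str] = ("age", "sex"),
    n_boot: int = 200,
    seed: int = 0,
    bootstrap: bool = True,
) -> AbundanceMatrix:
    """Residualize each protein on covariates with bootstrap-averaged coefficients.

    Coefficients are the mean over ``n_boot`` OLS refits on samples resampled
    with replacement (seeded); ``bootstrap=False`` gives the plain single fit.
    Samples with missing covariates are excluded from fitting and returned
    unadjusted. The protein grand mean is preserved.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("adjust_covariates expects a log2-scale matrix")
    banned = _NEVER_ADJUST.intersection(covariates)
    if banned:
        raise ValidationError(f"refusing to adjust for {sorted(banned)}")
    tr = traits.data.loc[matrix.sample_ids]
    cols = []
    names = []
    for c in covariates:
        if c not in tr.columns:
            raise ValidationError(f"covariate {c!r} not in trait table")
        if c == "sex":
            v = tr["sex"].map({"female": 1.0, "male": 0.0})
        else:
            v = pd.to_numeric(tr[c], errors="coerce")
        if v.nunique(dropna=True) < 2:
            logger.warning("adjust_covariates: covariate %r constant; skipped", c)
            continue
        cols.append(v.to_numpy(dtype=float))
        names.append(c)
    if not cols:
        return matrix.copy()

    C = np.column_stack(cols)
    usable = ~np.isnan(C).any(axis=1)
    Cc = C[usable] - C[usable].mean(axis=0)
    X = np.column_stack([np.ones(usable.sum()), Cc])

    Y = matrix.data.to_numpy()[:, usable]          # proteins x usable samples
    Yfit = np.where(np.isnan(Y), 0.0, Y)
    obs = (~np.isnan(Y)).astype(float)

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_draws = n_boot if bootstrap else 1
    coef_sum = np.zeros((Y.shape[0], X.shape[1]))
    done = 0
    for b in range(n_draws):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        Xb = X[idx]
        if np.linalg.matrix_rank(Xb) < X.shape[1]:
            continue
        # per-protein weighted fit is approximated by zero-filling missing
        # cells; proteins with missingness get an exact per-protein refit below
        beta, *_ = np.linalg.lstsq(Xb, Yfit[:, idx].T, rcond=None)
        coef_sum += beta.T
        done += 1
    if done == 0:
        raise TmtPipeError("all bootstrap designs were rank deficient")
    coef = coef_sum / done

    # exact handling for proteins with missing cells: refit on observed samples
    has_missing = (obs < 1).any(axis=1)
    if has_missing.any():
        for i in np.where(has_missing)[0]:
            m = obs[i] > 0
            if m.sum() <= X.shape[1]:
                continue
            coef[i] = _boot_coef(X[m], Y[i, m], n_draws, np.random.default_rng(seed + 1 + i), bootstrap)

    fitted_cov = coef[:, 1:] @ Cc.T                # exclude intercept: keep level
    out = matrix.data.copy()
    vals = out.to_numpy()
    adj = vals[:, usable] - fitted_cov
    vals[:, usable] = adj
    out.iloc[:, :] = vals
    logger.info("adjust_covariates: removed %s over %d samples (%s)",
                names, int(usable.sum()), "bootstrap x%d" % done if bootstrap else "single fit")
    return matrix.with_data(out, Scale.LOG2)


def _boot_coef(X: np.ndarray, y: np.ndarray, n_draws: int, rng: np.random.Generator,
               bootstrap: bool) -> np.ndarray:
    n = X.shape[0]
    total = np.zeros(X.shape[1])
    done = 0
    for _ in range(n_draws):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        Xb = X[idx]
        if np.linalg.matrix_rank(Xb) < X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(Xb, y[idx], rcond=None)
        total += beta
        done += 1
    return total / max(done, 1)
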