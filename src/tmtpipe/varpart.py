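"""Per-protein variance partitioning across donor traits and batch.

For each protein the log2 abundance y is decomposed as

    y = mu + (sex) + (race) + (diagnosis) [+ batch] + residual

with every categorical factor treated as a random effect. Variance components
are estimated by REML (profiled over the residual variance, with the
Woodbury identity keeping every likelihood evaluation at the cost of a small
q x q Cholesky, q = total number of factor levels) and reported as fractions
of the total variance. Race is dichotomized African American vs all others
and diagnosis AD vs all others by default, matching the two-level contrasts
of the reference analysis; full multi-level coding is available by flag.

A fixed-effects sums-of-squares mode (`method="anova"`) is provided as an
independent cross-check: sequential type-I sums of squares (batch first,
reference-coded dummies) normalized by the total sum of squares, so
fractions add to one exactly. Note its batch share cannot fall below the
chance level (k-1)/(n-1), since k-1 batch degrees of freedom absorb that
much noise; REML instead reports a zero component at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .core import Dataset, Scale, TmtPipeError, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = ["VarianceModelSpec", "VariancePartitionResult", "fit_variance_partition", "rank_by_factor"]


@dataclass
class VarianceModelSpec:
    """Which factors enter the per-protein model and how."""

    factors: tuple = ("sex", "race", "diagnosis")
    include_batch: bool = False
    dichotomize: bool = True
    method: str = "reml"          # "reml" | "anova"
    min_obs: int = 10

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValidationError("factors must be nonempty")
        if len(set(self.factors)) != len(self.factors):
            raise ValidationError("duplicate factors")
        if self.method not in ("reml", "anova"):
            raise ValidationError(f"unknown method {self.method!r}")


@dataclass
class VariancePartitionResult:
    """fractions: protein x (factors..., residual); method per protein; skipped ids."""

    fractions: pd.DataFrame
    method: pd.Series
    skipped: list = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.fractions.columns if c != "residual"]

    def medians(self) -> dict:
        return {c: float(self.fractions[c].median()) for c in self.fractions.columns}


def _factor_codes(dataset: Dataset, spec: VarianceModelSpec) -> pd.DataFrame:
    """Per-sample integer level codes for each modeled factor (donor samples)."""
    traits = dataset.traits.data
    codes = {}
    names = list(spec.factors) + (["batch"] if spec.include_batch else [])
    for f in names:
        if f not in traits.columns:
            raise ValidationError(f"factor {f!r} not in trait table")
        col = traits[f].astype(str)
        if spec.dichotomize and f == "race":
            col = np.where(col == "AfricanAmerican", "AfricanAmerican", "other")
        elif spec.dichotomize and f == "diagnosis":
            col = np.where(col == "AD", "AD", "other")
        cat = pd.Categorical(col)
        if len(cat.categories) < 2:
            raise ValidationError(f"factor {f!r} has a single level")
        codes[f] = pd.Series(cat.codes, index=traits.index)
    return pd.DataFrame(codes)


def _dummies(codes: np.ndarray) -> np.ndarray:
    n_levels = codes.max() + 1
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class _RemlWorkspace:
    """Precomputed cross-products for one design (shared across proteins)."""

    def __init__(self, codes: pd.DataFrame):
        self.factor_names = list(codes.columns)
        self.blocks = [_dummies(codes[f].to_numpy()) for f in self.factor_names]
        self.block_sizes = [Z.shape[1] for Z in self.blocks]
        self.Z = np.hstack(self.blocks)
        self.n = self.Z.shape[0]
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.sum(axis=0)  # X = intercept
        self.expand = np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)

    def neg2_reml(self, t: np.ndarray, Zty: np.ndarray, Sy: float, yty: float) -> float:
        gamma = np.exp(t)[self.expand]           # per-column variance ratios
        d = np.sqrt(gamma)
        M = np.eye(self.ZtZ.shape[0]) + (d[:, None] * self.ZtZ * d[None, :])
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(L)).sum()
        a = np.linalg.solve(L, d * Zty)
        b = np.linalg.solve(L, d * self.ZtX)
        yWy = yty - a @ a
        xWy = Sy - b @ a
        xWx = self.n - b @ b
        ypy = yWy - xWy * xWy / xWx
        if ypy <= 0 or xWx <= 0:
            return np.inf
        sigma2 = ypy / (self.n - 1)
        return (self.n - 1) * np.log(sigma2) + logdet + np.log(xWx)

    def fit(self, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
        """Returns (one variance component per factor, residual variance, converged)."""
        Zty = self.Z.T @ y
        Sy = y.sum()
        yty = y @ y
        F = len(self.block_sizes)
        res = optimize.minimize(
            self.neg2_reml, x0=np.zeros(F), args=(Zty, Sy, yty),
            method="L-BFGS-B", bounds=[(-18.0, 12.0)] * F,
        )
        t = res.x
        gamma = np.exp(t)
        d = np.sqrt(gamma[self.expand])
        M = np.eye(self.ZtZ.shape[0]) + (d[:, None] * self.ZtZ * d[None, :])
        L = np.linalg.cholesky(M)
        a = np.linalg.solve(L, d * Zty)
        b = np.linalg.solve(L, d * self.ZtX)
        ypy = (yty - a @ a) - (Sy - b @ a) ** 2 / (self.n - b @ b)
        sigma2 = max(ypy / (self.n - 1), 1e-300)
        comps = gamma * sigma2
        comps[gamma <= np.exp(-17.0)] = 0.0      # boundary -> exact zero
        return comps, sigma2, bool(res.success)


def _anova_fractions(Y: np.ndarray, codes: pd.DataFrame, order: list[str]) -> np.ndarray:
    """Sequential type-I SS fractions for proteins x samples Y (complete data).

    Returns array proteins x (factors + residual) in `order` + residual.
    """
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    total = (Yc ** 2).sum(axis=1)
    total = np.where(total <= 0, np.nan, total)
    design = [np.ones((n, 1))]
    prev_df = 0.0
    fracs = []
    for f in order:
        # reference coding keeps the cumulative design full rank, so the QR
        # basis spans exactly the factor subspace and SS increments are exact
        design.append(_dummies(codes[f].to_numpy())[:, 1:])
        Q, _ = np.linalg.qr(np.hstack(design))
        proj = Yc @ Q @ Q.T
        ss_cum = (proj ** 2).sum(axis=1)
        fracs.append(np.maximum(ss_cum - prev_df, 0.0) / total)
        prev_df = ss_cum
    resid = np.maximum(total - prev_df, 0.0) / total
    return np.column_stack(fracs + [resid])


def fit_variance_partition(dataset: Dataset, spec: Optional[VarianceModelSpec] = None) -> VariancePartitionResult:
    """Decompose each protein's variance into per-factor and residual fractions.

    GIS channels are excluded. Proteins with fewer than ``spec.min_obs``
    complete observations are skipped with a warning. REML fits that fail to
    converge fall back to the sums-of-squares decomposition and are flagged
    ``anova-fallback``.
    """
    spec = spec or VarianceModelSpec()
    if dataset.matrix.scale is not Scale.LOG2:
        raise ValidationError("variance partition expects a log2-scale matrix")
    ds = dataset.donor_view()
    codes_all = _factor_codes(ds, spec)
    order = list(["batch"] if spec.include_batch else []) + [f for f in spec.factors]
    col_names = order + ["residual"]

    Y = ds.matrix.data
    skipped = [p for p in Y.index if Y.loc[p].notna().sum() < spec.min_obs]
    if skipped:
        logger.warning("variance partition: skipping %d proteins with < %d observations",
                       len(skipped), spec.min_obs)
    keep = [p for p in Y.index if p not in set(skipped)]
    Y = Y.loc[keep]

    fractions = pd.DataFrame(np.nan, index=keep, columns=col_names)
    method = pd.Series("", index=keep, dtype=object)

    # check per-factor level counts on the full sample set once
    for f in order:
        if codes_all[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single observed level")

    if spec.method == "anova":
        _fit_anova_all(Y, codes_all, order, fractions, method)
        return VariancePartitionResult(fractions, method, skipped)

    # REML: group proteins by identical missingness pattern so the workspace
    # (cross-products of the design) is built once per pattern.
    patterns: dict[bytes, list] = {}
    mask = Y.isna().to_numpy()
    for i, p in enumerate(keep):
        patterns.setdefault(mask[i].tobytes(), []).append((i, p))
    for key, members in patterns.items():
        obs = ~np.frombuffer(key, dtype=bool)
        codes = codes_all.loc[codes_all.index[obs]]
        # re-code factor levels present in this subset
        sub = codes.apply(lambda c: pd.Series(pd.Categorical(c).codes, index=c.index))
        if any(sub[f].nunique() < 2 for f in order):
            for i, p in members:
                fractions.loc[p] = np.nan
                method.loc[p] = "skipped-single-level"
            continue
        ws = _RemlWorkspace(sub[order])
        for i, p in members:
            y = Y.iloc[i].to_numpy()[obs]
            comps, sigma2, ok = ws.fit(y)
            per_factor = comps
            tot = per_factor.sum() + sigma2
            fractions.loc[p, order] = per_factor / tot
            fractions.loc[p, "residual"] = sigma2 / tot
            method.loc[p] = "reml" if ok else "reml-nonconverged"
            if not ok:
                row = _anova_fractions(y[None, :], sub, order)[0]
                fractions.loc[p] = row
                method.loc[p] = "anova-fallback"
    return VariancePartitionResult(fractions, method, skipped)


def _fit_anova_all(Y: pd.DataFrame, codes_all: pd.DataFrame, order: list[str],
                   fractions: pd.DataFrame, method: pd.Series) -> None:
    mask = Y.isna().to_numpy()
    patterns: dict[bytes, list] = {}
    for i, p in enumerate(Y.index):
        patterns.setdefault(mask[i].tobytes(), []).append((i, p))
    for key, members in patterns.items():
        obs = ~np.frombuffer(key, dtype=bool)
        codes = codes_all.loc[codes_all.index[obs]]
        sub = codes.apply(lambda c: pd.Series(pd.Categorical(c).codes, index=c.index))
        if any(sub[f].nunique() < 2 for f in order):
            for i, p in members:
                method.loc[p] = "skipped-single-level"
            continue
        idx = [i for i, _ in members]
        block = Y.to_numpy()[idx][:, obs]
        rows = _anova_fractions(block, sub, order)
        for row, (i, p) in zip(rows, members):
            fractions.loc[p] = row
            method.loc[p] = "anova"


def rank_by_factor(result: VariancePartitionResult, factor: str, k: Optional[int] = None) -> pd.DataFrame:
    """Top-k proteins by a factor's variance fraction (ties broken by id)."""
    if factor not in result.fractions.columns:
        raise ValidationError(f"unknown factor {factor!r}; have {list(result.fractions.columns)}")
    df = result.fractions[[factor]].dropna()
    order = np.lexsort((df.index.to_numpy(), -df[factor].to_numpy()))
    df = df.iloc[order]
    if k is not None:
        df = df.head(k)
    return df
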