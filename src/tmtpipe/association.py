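"""Robust correlation screens and race-stratified differential abundance.

Implements the biweight midcorrelation (bicor) — a median/MAD-weighted
correlation that downweights outlying observations — and the downstream
analyses built on it: proteome-wide correlate screens against an anchor
protein (APP- or MAPT-style), one-way ANOVA with Tukey's HSD across the four
race x diagnosis groups, classification of differentially abundant proteins
(DAPs) into shared/race-specific response groups, and the cross-race
fold-change concordance statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, Dataset, Scale, TmtPipeError, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = [
    "bicor",
    "bicor_pvalue",
    "CorrelationResult",
    "correlate_proteome",
    "race_dx_groups",
    "DiffAbundanceResult",
    "anova_tukey",
    "classify_dap",
    "fc_concordance",
    "volcano_table",
    "trend_by_stage",
]

P_CEILING = 300.0  # cap for -log10(p) when p underflows to 0

WITHIN_RACE_CONTRASTS = (("White.AD", "White.CT"), ("AA.AD", "AA.CT"))


def _biweight(x: np.ndarray, c: float) -> Optional[np.ndarray]:
    """Biweight-weighted deviations; None when MAD == 0 (degenerate)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (c * mad)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return (x - med) * w


def bicor(x: Sequence[float], y: Sequence[float], c: float = 9.0) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete).

    Falls back to the Pearson correlation, with a logged flag, when either
    vector has zero median absolute deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("need at least 3 complete pairs")
    a = _biweight(x, c)
    b = _biweight(y, c)
    if a is None or b is None:
        logger.warning("bicor: zero MAD, falling back to Pearson")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValidationError("constant vector: correlation undefined")
        return float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValidationError("degenerate weights: correlation undefined")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def bicor_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation on n-2 df."""
    if n < 4:
        raise ValidationError("need n >= 4 for a p-value")
    if abs(r) >= 1.0:
        logger.warning("bicor_pvalue: |r| = 1, returning p = 0")
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


@dataclass
class CorrelationResult:
    anchor: str
    table: pd.DataFrame  # index protein: bicor, p, n, significant, low_confidence, pearson_fallback
    alpha: float


def correlate_proteome(dataset: Dataset, anchor: str, config: Optional[AnalysisConfig] = None) -> CorrelationResult:
    """bicor of every protein against the anchor, over pairwise-complete donor samples."""
    cfg = config or AnalysisConfig()
    if dataset.matrix.scale is not Scale.LOG2:
        raise ValidationError("correlate_proteome expects a log2-scale matrix")
    ds = dataset.donor_view()
    if anchor not in ds.matrix.data.index:
        raise ValidationError(f"anchor protein {anchor!r} not in matrix")
    Y = ds.matrix.data
    xa = Y.loc[anchor].to_numpy()
    rows = []
    for pid in Y.index:
        if pid == anchor:
            continue
        y = Y.loc[pid].to_numpy()
        ok = ~(np.isnan(xa) | np.isnan(y))
        n = int(ok.sum())
        if n < max(3, 4):
            continue
        xs, ys = xa[ok], y[ok]
        fallback = (_biweight(xs, cfg.bicor_c) is None) or (_biweight(ys, cfg.bicor_c) is None)
        try:
            r = bicor(xs, ys, cfg.bicor_c)
        except ValidationError:
            continue
        p = bicor_pvalue(r, n)
        rows.append((pid, r, p, n, p < cfg.alpha, n < 30, fallback))
    table = pd.DataFrame(
        rows, columns=["protein", "bicor", "p", "n", "significant", "low_confidence", "pearson_fallback"]
    ).set_index("protein").sort_values("bicor", ascending=False)
    logger.info("correlate_proteome: anchor %s, %d proteins, %d significant at alpha=%g",
                anchor, len(table), int(table["significant"].sum()), cfg.alpha)
    return CorrelationResult(anchor, table, cfg.alpha)


def race_dx_groups(dataset: Dataset) -> pd.Series:
    """Four-level race x diagnosis labels (White/AA x AD/CT); others NaN."""
    tr = dataset.traits.data
    race = tr["race"].map({"White": "White", "AfricanAmerican": "AA"})
    dx = tr["diagnosis"].map({"AD": "AD", "Control": "CT"})
    lab = race + "." + dx
    lab[tr["is_gis"]] = np.nan
    return lab


@dataclass
class DiffAbundanceResult:
    """Long table: one row per protein per contrast.

    Columns: log2fc (first minus second group mean), anova_p (family F test),
    raw_p (pooled-variance pairwise t), tukey_p, n_1, n_2, significant.
    """

    table: pd.DataFrame
    alpha: float
    k_groups: int
    skipped: list = field(default_factory=list)

    def contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        if sub.empty:
            raise ValidationError(f"unknown contrast {name!r}; have {sorted(self.table['contrast'].unique())}")
        return sub.set_index("protein")


def _tukey_sf(q: np.ndarray, k: int, df: np.ndarray) -> np.ndarray:
    """P(Q > q) for the studentized range with k groups.

    k == 2 reduces exactly to the two-sided t probability via q = |t| * sqrt(2).
    """
    q = np.asarray(q, dtype=float)
    if k == 2:
        return 2.0 * stats.t.sf(q / np.sqrt(2.0), df)
    with np.errstate(all="ignore"):
        p = stats.studentized_range.sf(q, k, df)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def anova_tukey(
    dataset: Dataset,
    grouping: Union[str, pd.Series] = "race_dx",
    config: Optional[AnalysisConfig] = None,
    contrasts: Optional[Sequence[tuple]] = None,
    separate: bool = False,
) -> DiffAbundanceResult:
    """One-way ANOVA + Tukey HSD per protein across group levels.

    ``grouping`` is a trait column name, the special "race_dx" label set, or
    a per-sample label Series. By default a single 4-level model is fitted
    and the two within-race AD-vs-control contrasts are reported;
    ``separate=True`` instead fits each reported contrast as its own 2-group
    model (Tukey with k = 2 equals the pooled t-test). Proteins lacking
    ``min_per_group`` observations in any level are skipped.
    """
    cfg = config or AnalysisConfig()
    if dataset.matrix.scale is not Scale.LOG2:
        raise ValidationError("anova_tukey expects a log2-scale matrix")
    ds = dataset.donor_view()
    if isinstance(grouping, str):
        labels = race_dx_groups(dataset) if grouping == "race_dx" else ds.traits.data[grouping].astype(object)
    else:
        labels = grouping
    labels = labels.reindex(ds.matrix.sample_ids)
    levels = sorted(pd.unique(labels.dropna()))
    if len(levels) < 2:
        raise ValidationError("grouping must have at least 2 observed levels")
    if contrasts is None:
        if set(np.ravel(WITHIN_RACE_CONTRASTS)) <= set(levels):
            contrasts = list(WITHIN_RACE_CONTRASTS)
        else:
            contrasts = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]

    if separate:
        parts = []
        skipped: set = set()
        for pair in contrasts:
            sub_labels = labels.where(labels.isin(pair))
            res = anova_tukey(dataset, sub_labels, cfg, contrasts=[pair], separate=False)
            parts.append(res.table)
            skipped.update(res.skipped)
        return DiffAbundanceResult(pd.concat(parts, ignore_index=True), cfg.alpha, 2, sorted(skipped))

    Y = ds.matrix.data
    k = len(levels)
    masks = {g: (labels == g).to_numpy() for g in levels}
    V = Y.to_numpy()
    obs = ~np.isnan(V)
    counts = {g: obs[:, masks[g]].sum(axis=1) for g in levels}
    sums = {g: np.nansum(np.where(obs, V, 0.0)[:, masks[g]], axis=1) for g in levels}
    means = {g: np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), np.nan) for g in levels}
    sq = {g: np.nansum((np.where(obs, V, 0.0)[:, masks[g]]) ** 2, axis=1) for g in levels}

    n_tot = sum(counts.values())
    usable = np.ones(Y.shape[0], dtype=bool)
    for g in levels:
        usable &= counts[g] >= cfg.min_per_group
    skipped_ids = list(Y.index[~usable])
    if skipped_ids:
        logger.info("anova_tukey: skipped %d proteins below min_per_group=%d",
                    len(skipped_ids), cfg.min_per_group)

    grand = sum(sums.values()) / n_tot
    ssb = sum(counts[g] * (means[g] - grand) ** 2 for g in levels)
    ssw = sum(sq[g] - counts[g] * means[g] ** 2 for g in levels)
    dfb, dfw = k - 1, n_tot - k
    with np.errstate(all="ignore"):
        msw = ssw / dfw
        F = (ssb / dfb) / msw
        anova_p = stats.f.sf(F, dfb, dfw)

    rows = []
    for a, b in contrasts:
        diff = means[a] - means[b]
        with np.errstate(all="ignore"):
            se_t = np.sqrt(msw * (1.0 / counts[a] + 1.0 / counts[b]))
            tstat = np.abs(diff) / se_t
            raw_p = 2.0 * stats.t.sf(tstat, dfw)
            # Tukey-Kramer: q on the HSD scale for unequal n
            q = np.abs(diff) / np.sqrt(msw / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
        tukey_p = np.full_like(q, np.nan)
        m = usable
        tukey_p[m] = _tukey_sf(q[m], k, dfw[m].astype(float))
        for i in np.where(usable)[0]:
            rows.append((
                Y.index[i], f"{a}_vs_{b}", diff[i], anova_p[i], raw_p[i], tukey_p[i],
                int(counts[a][i]), int(counts[b][i]), bool(tukey_p[i] < cfg.alpha),
            ))
    table = pd.DataFrame(rows, columns=[
        "protein", "contrast", "log2fc", "anova_p", "raw_p", "tukey_p", "n_1", "n_2", "significant",
    ])
    return DiffAbundanceResult(table, cfg.alpha, k, skipped_ids)


DAP_LABELS = ("G1_down_both", "G2_white_only", "G3_aa_only", "G4_up_both", "mixed", "nonsig")


def classify_dap(result: DiffAbundanceResult, alpha: Optional[float] = None) -> pd.Series:
    """Four-group DAP labels from the two within-race AD-vs-control contrasts.

    G1/G4: significant down/up in both races; G2/G3: significant in exactly
    one race; mixed: significant in both with opposite signs.
    """
    alpha = result.alpha if alpha is None else alpha
    names = {f"{a}_vs_{b}" for a, b in WITHIN_RACE_CONTRASTS}
    have = set(result.table["contrast"].unique())
    if not names <= have:
        raise ValidationError(f"need contrasts {sorted(names)}, have {sorted(have)}")
    w = result.contrast("White.AD_vs_White.CT")
    a = result.contrast("AA.AD_vs_AA.CT")
    common = w.index.intersection(a.index)
    w, a = w.loc[common], a.loc[common]
    sig_w = w["tukey_p"] < alpha
    sig_a = a["tukey_p"] < alpha
    up_w = w["log2fc"] > 0
    up_a = a["log2fc"] > 0
    out = pd.Series("nonsig", index=common, dtype=object, name="dap_group")
    out[sig_w & ~sig_a] = "G2_white_only"
    out[~sig_w & sig_a] = "G3_aa_only"
    out[sig_w & sig_a & up_w & up_a] = "G4_up_both"
    out[sig_w & sig_a & ~up_w & ~up_a] = "G1_down_both"
    out[sig_w & sig_a & (up_w ^ up_a)] = "mixed"
    return out


def fc_concordance(result: DiffAbundanceResult, alpha: Optional[float] = None,
                   c: float = 9.0) -> tuple[float, int, pd.DataFrame]:
    """bicor of the two within-race log2 fold changes over race-significant proteins."""
    alpha = result.alpha if alpha is None else alpha
    w = result.contrast("White.AD_vs_White.CT")
    a = result.contrast("AA.AD_vs_AA.CT")
    common = w.index.intersection(a.index)
    w, a = w.loc[common], a.loc[common]
    sel = (w["tukey_p"] < alpha) | (a["tukey_p"] < alpha)
    if sel.sum() < 3:
        raise TmtPipeError(f"only {int(sel.sum())} significant proteins; need >= 3")
    fc_w = w.loc[sel, "log2fc"]
    fc_a = a.loc[sel, "log2fc"]
    r = bicor(fc_w.to_numpy(), fc_a.to_numpy(), c)
    scatter = pd.DataFrame({
        "log2fc_white": fc_w, "log2fc_aa": fc_a,
        "sig_white": w.loc[sel, "tukey_p"] < alpha, "sig_aa": a.loc[sel, "tukey_p"] < alpha,
    })
    return r, int(sel.sum()), scatter


def volcano_table(result: DiffAbundanceResult, contrast: str, use: str = "tukey_p") -> pd.DataFrame:
    """Plot-ready volcano columns for one contrast (both p columns reported)."""
    sub = result.contrast(contrast)
    out = pd.DataFrame(index=sub.index)
    out["log2fc"] = sub["log2fc"]
    for col in ("tukey_p", "anova_p"):
        p = sub[col].to_numpy(dtype=float)
        capped = p <= 10.0 ** (-P_CEILING)
        with np.errstate(divide="ignore"):
            nl = -np.log10(p)
        nl[capped] = P_CEILING
        out[f"neg_log10_{col}"] = nl
        out[f"{col}_underflow"] = capped
    sig = sub[use] < result.alpha
    out["class"] = np.where(~sig, "ns", np.where(sub["log2fc"] > 0, "up", "down"))
    return out


def trend_by_stage(dataset: Dataset, protein: str, stage: str = "cerad") -> tuple[pd.DataFrame, float]:
    """Per-stage summary (n, median, quartiles) plus Spearman trend for one protein."""
    ds = dataset.donor_view()
    if protein not in ds.matrix.data.index:
        raise ValidationError(f"unknown protein {protein!r}")
    y = ds.matrix.data.loc[protein]
    s = pd.to_numeric(ds.traits.data[stage], errors="coerce")
    ok = y.notna() & s.notna()
    if s[ok].nunique() < 2:
        raise ValidationError(f"stage {stage!r} has fewer than 2 observed levels")
    df = pd.DataFrame({"stage": s[ok], "value": y[ok]})
    summary = df.groupby("stage")["value"].agg(
        n="count", median="median",
        q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75),
    ).reset_index()
    rho = float(stats.spearmanr(df["stage"], df["value"]).statistic)
    return summary, rho
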