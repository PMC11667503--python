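"""bicor, ANOVA+Tukey, DAP classes, concordance, volcano, stage trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tmtpipe as tp
from tmtpipe.association import (
    anova_tukey,
    bicor,
    bicor_pvalue,
    classify_dap,
    correlate_proteome,
    fc_concordance,
    trend_by_stage,
    volcano_table,
)
from tmtpipe.core import TmtPipeError, ValidationError
from .conftest import make_dataset


def bicor_reference(x, y, c=9.0):
    """Independent brute-force evaluation of the biweight midcorrelation."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        return (v - med) * w

    a, b = weighted(x), weighted(y)
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=25)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=25)
        assert bicor(x, 2.0 + 3.0 * x) == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, 2.0 - 3.0 * x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 30.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, -10.0])
        assert bicor(x, y) == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert bicor(x, y) == pytest.approx(bicor(y, x), abs=1e-14)
        assert -1.0 <= bicor(x, y) <= 1.0

    def test_mad_zero_pearson_fallback(self, rng):
        x = np.array([1.0] * 9 + [2.0])  # MAD = 0
        y = rng.normal(size=10)
        expected = float(np.corrcoef(x, y)[0, 1])
        assert bicor(x, y) == pytest.approx(expected, abs=1e-12)

    def test_short_vectors_error(self):
        with pytest.raises(ValidationError):
            bicor([1.0, 2.0], [3.0, 4.0])


class TestBicorPvalue:
    def test_zero_correlation_p_one(self):
        assert bicor_pvalue(0.0, 30) == pytest.approx(1.0)

    def test_matches_t_distribution(self):
        r, n = 0.5, 30
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert bicor_pvalue(r, n) == pytest.approx(2 * stats.t.sf(t, n - 2), abs=1e-15)

    def test_monotone_in_abs_r(self):
        ps = [bicor_pvalue(r, 50) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_perfect_correlation_p_zero(self):
        assert bicor_pvalue(1.0, 10) == 0.0


class TestCorrelateProteome:
    def test_planted_correlate_ranked_first(self, rng):
        n = 400
        anchor = rng.normal(0, 1, n)
        rho = 0.9
        mate = rho * anchor + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        others = rng.normal(0, 1, (30, n))
        vals = np.vstack([anchor, mate, others])
        ds = make_dataset(vals, feature_ids=["ANCHOR", "MATE"] + [f"P{i}" for i in range(30)])
        res = correlate_proteome(ds, "ANCHOR")
        assert res.table.index[0] == "MATE"
        assert res.table.loc["MATE", "bicor"] == pytest.approx(0.9, abs=0.05)
        assert "ANCHOR" not in res.table.index

    def test_missing_anchor_errors(self, rng):
        ds = make_dataset(rng.normal(0, 1, (3, 20)))
        with pytest.raises(ValidationError):
            correlate_proteome(ds, "nope")


def tukey_reference(groups, pair):
    """Independent studentized-range oracle via statsmodels."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    from itertools import combinations

    vals = np.concatenate(groups)
    labs = np.concatenate([[f"g{i}"] * len(g) for i, g in enumerate(groups)])
    res = pairwise_tukeyhsd(vals, labs)
    pairs = list(combinations(sorted(np.unique(labs)), 2))
    lookup = {frozenset(p): float(pv) for p, pv in zip(pairs, res.pvalues)}
    return lookup[frozenset((f"g{pair[0]}", f"g{pair[1]}"))]


class TestAnovaTukey:
    def _dataset(self, groups, labels=None):
        vals = np.concatenate(groups)[None, :]
        labs = labels or sum([[f"g{i}"] * len(g) for i, g in enumerate(groups)], [])
        cols = [f"s{i}" for i in range(vals.shape[1])]
        ds = make_dataset(vals, sample_ids=cols)
        return ds, pd.Series(labs, index=cols)

    def test_hand_instance_matches_oracle(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [5.0, 6, 7]]
        ds, labels = self._dataset(groups)
        res = anova_tukey(ds, labels, contrasts=[("g0", "g1"), ("g0", "g2"), ("g1", "g2")])
        F_ref, p_ref = stats.f_oneway(*groups)
        tab = res.table.set_index("contrast")
        assert tab.loc["g0_vs_g1", "anova_p"] == pytest.approx(p_ref, abs=1e-9)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            got = tab.loc[f"g{a}_vs_g{b}", "tukey_p"]
            assert got == pytest.approx(tukey_reference(groups, (a, b)), abs=1e-6)

    def test_two_group_tukey_equals_pooled_t(self, rng):
        ga = list(rng.normal(0, 1, 8))
        gb = list(rng.normal(0.5, 1, 11))
        ds, labels = self._dataset([ga, gb])
        res = anova_tukey(ds, labels, contrasts=[("g0", "g1")])
        t_p = stats.ttest_ind(ga, gb, equal_var=True).pvalue
        assert float(res.table["tukey_p"].iloc[0]) == pytest.approx(t_p, abs=1e-9)

    def test_tukey_p_at_least_raw_p(self, rng):
        groups = [list(rng.normal(m, 1, 10)) for m in (0, 0.3, 0.8, 1.2)]
        ds, labels = self._dataset(groups)
        res = anova_tukey(ds, labels)
        assert (res.table["tukey_p"] >= res.table["raw_p"] - 1e-12).all()

    def test_min_per_group_skips(self, rng):
        vals = rng.normal(0, 1, (2, 8))
        vals[1, :2] = np.nan  # g0 has 1 observation for P1
        cols = [f"s{i}" for i in range(8)]
        ds = make_dataset(vals, sample_ids=cols)
        labels = pd.Series(["g0"] * 3 + ["g1"] * 5, index=cols)
        res = anova_tukey(ds, labels, contrasts=[("g0", "g1")])
        assert res.skipped == ["P1"]

    def test_single_level_errors(self, rng):
        ds, labels = self._dataset([[1.0, 2, 3]])
        with pytest.raises(ValidationError):
            anova_tukey(ds, labels)


class TestClassifyDap:
    def _result(self, rows):
        table = pd.DataFrame(rows, columns=["protein", "contrast", "log2fc", "anova_p",
                                            "raw_p", "tukey_p", "n_1", "n_2", "significant"])
        return tp.DiffAbundanceResult(table, alpha=0.05, k_groups=4)

    def _row(self, p, race, fc, tp_):
        name = "White.AD_vs_White.CT" if race == "w" else "AA.AD_vs_AA.CT"
        return (p, name, fc, 0.01, tp_, tp_, 10, 10, tp_ < 0.05)

    def test_group_labels(self):
        rows = [
            self._row("SMOC1like", "w", 1.2, 1e-10), self._row("SMOC1like", "a", 0.8, 1e-8),
            self._row("VGFlike", "w", -1.0, 1e-6), self._row("VGFlike", "a", -0.7, 1e-4),
            self._row("Wonly", "w", 0.9, 1e-4), self._row("Wonly", "a", 0.1, 0.6),
            self._row("AAonly", "w", 0.1, 0.4), self._row("AAonly", "a", -0.9, 1e-3),
            self._row("Mixed", "w", 0.5, 1e-3), self._row("Mixed", "a", -0.5, 1e-3),
            self._row("Null", "w", 0.01, 0.9), self._row("Null", "a", 0.02, 0.8),
        ]
        out = classify_dap(self._result(rows))
        assert out["SMOC1like"] == "G4_up_both"
        assert out["VGFlike"] == "G1_down_both"
        assert out["Wonly"] == "G2_white_only"
        assert out["AAonly"] == "G3_aa_only"
        assert out["Mixed"] == "mixed"
        assert out["Null"] == "nonsig"

    def test_labels_partition(self):
        rows = [self._row(f"P{i}", r, fc, p) for i, (fc, p) in enumerate([(0.5, 0.01), (-0.5, 0.2), (1.0, 1e-5)])
                for r in ("w", "a")]
        out = classify_dap(self._result(rows))
        assert len(out) == 3 and out.notna().all()


class TestVolcano:
    def _result(self, rng):
        groups = [list(rng.normal(m, 0.3, 12)) for m in (0, 0, 1.0, -1.0)]
        vals = np.concatenate(groups)[None, :].repeat(3, axis=0) + rng.normal(0, 0.3, (3, 48))
        cols = [f"s{i}" for i in range(48)]
        ds = make_dataset(vals, sample_ids=cols)
        labels = pd.Series(sum([[g] * 12 for g in ("White.CT", "AA.CT", "White.AD", "AA.AD")], []), index=cols)
        return anova_tukey(ds, labels)

    def test_p_of_one_maps_to_zero(self):
        table = pd.DataFrame([("P1", "c", 0.5, 1.0, 1.0, 1.0, 5, 5, False)],
                             columns=["protein", "contrast", "log2fc", "anova_p", "raw_p",
                                      "tukey_p", "n_1", "n_2", "significant"])
        res = tp.DiffAbundanceResult(table, 0.05, 2)
        v = volcano_table(res, "c")
        assert v["neg_log10_tukey_p"].iloc[0] == 0.0

    def test_underflow_capped_with_flag(self):
        table = pd.DataFrame([("P1", "c", 3.0, 0.0, 0.0, 0.0, 5, 5, True)],
                             columns=["protein", "contrast", "log2fc", "anova_p", "raw_p",
                                      "tukey_p", "n_1", "n_2", "significant"])
        res = tp.DiffAbundanceResult(table, 0.05, 2)
        v = volcano_table(res, "c")
        assert v["neg_log10_tukey_p"].iloc[0] == 300.0
        assert bool(v["tukey_p_underflow"].iloc[0])

    def test_class_consistent_with_alpha_and_sign(self, rng):
        res = self._result(rng)
        v = volcano_table(res, "White.AD_vs_White.CT")
        sig = res.contrast("White.AD_vs_White.CT")["tukey_p"] < 0.05
        assert ((v["class"] == "ns") == ~sig).all()
        up = v[v["class"] == "up"]
        assert (up["log2fc"] > 0).all()


class TestFcConcordance:
    def test_identical_effects_approach_one(self, rng):
        effects = np.concatenate([rng.normal(0, 1, 40), np.zeros(10)])
        se = 0.02
        rows = []
        for i, e in enumerate(effects):
            fw = e + rng.normal(0, se)
            fa = e + rng.normal(0, se)
            pw = 1e-8 if abs(e) > 0.1 else 0.9
            rows.append((f"P{i}", "White.AD_vs_White.CT", fw, 0.01, pw, pw, 10, 10, pw < 0.05))
            rows.append((f"P{i}", "AA.AD_vs_AA.CT", fa, 0.01, pw, pw, 10, 10, pw < 0.05))
        table = pd.DataFrame(rows, columns=["protein", "contrast", "log2fc", "anova_p",
                                            "raw_p", "tukey_p", "n_1", "n_2", "significant"])
        r, n, scatter = fc_concordance(tp.DiffAbundanceResult(table, 0.05, 4))
        assert r > 0.99
        assert n == int((np.abs(effects) > 0.1).sum())

    def test_too_few_significant_errors(self):
        table = pd.DataFrame([
            ("P1", "White.AD_vs_White.CT", 0.5, 0.9, 0.9, 0.9, 5, 5, False),
            ("P1", "AA.AD_vs_AA.CT", 0.4, 0.9, 0.9, 0.9, 5, 5, False),
        ], columns=["protein", "contrast", "log2fc", "anova_p", "raw_p", "tukey_p", "n_1", "n_2", "significant"])
        with pytest.raises(TmtPipeError):
            fc_concordance(tp.DiffAbundanceResult(table, 0.05, 4))


class TestTrendByStage:
    def test_planted_monotone_trend(self):
        cfg = tp.SimConfig(n_proteins=80, n_samples=400, n_batches=27, seed=31,
                           trait_effects={"sex": (0, 0.0), "race": (0, 0.0), "diagnosis": (40, 1.5)})
        ds, truth = tp.simulate_cohort(cfg)
        clean, _ = tp.run_qc(ds)
        dx = truth.trait_effects["diagnosis"]
        app_like = dx["white"].add(dx["aa"]).idxmax()  # strongest planted up-effect
        summary, rho = trend_by_stage(clean, app_like, "cerad")
        med = summary.sort_values("stage")["median"].to_numpy()
        assert (np.diff(med) > -0.05).all()
        assert rho > 0.2

    def test_null_trend_near_zero(self, tiny_cohort):
        ds, truth = tiny_cohort
        clean, _ = tp.run_qc(ds)
        null = [p for p in clean.matrix.feature_ids
                if p not in set(sum((list(v) for v in truth.affected.values()), []))][0]
        _, rho = trend_by_stage(clean, null, "cerad")
        assert abs(rho) < 0.2

    def test_single_stage_errors(self, rng):
        ds = make_dataset(rng.normal(0, 1, (2, 20)), cerad=[2] * 20)
        with pytest.raises(ValidationError):
            trend_by_stage(ds, "P0", "cerad")
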