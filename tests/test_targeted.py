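"""APOE proteotyping and peptide-to-domain/analyte quantification."""

import numpy as np
import pandas as pd
import pytest

import tmtpipe as tp
from tmtpipe.core import TmtPipeError, ValidationError
from tmtpipe.simulate import APOE_PEPTIDE_ID, simulate_mapt_peptides
from tmtpipe.targeted import (
    AnalyteDef,
    RegionScheme,
    abeta_defs,
    assign_peptide_region,
    call_proteotype,
    concordance_report,
    mapt_scheme,
    quantify_ab_species,
    quantify_regions,
)


class TestRegionScheme:
    def test_shipped_mapt_domains(self):
        s = mapt_scheme()
        assert s.accession == "P10636-8" and s.length == 441
        assert s.region_names == ["N-terminal", "PRD", "MTBR", "C-terminal"]

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValidationError):
            RegionScheme("X", 100, [("a", 1, 50), ("b", 40, 100)])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            RegionScheme("X", 100, [("a", 1, 120)])


class TestAssignPeptideRegion:
    @pytest.mark.parametrize("start,end,expected", [
        (250, 260, "MTBR"),
        (1, 20, "N-terminal"),
        (120, 135, "PRD"),          # 7 residues N-terminal, 9 in PRD -> majority
        (127, 242, "PRD"),
        (369, 370, "MTBR"),         # exact tie -> more N-terminal region
    ])
    def test_assignment(self, start, end, expected):
        assert assign_peptide_region(start, end, mapt_scheme()) == expected

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValidationError):
            assign_peptide_region(430, 450, mapt_scheme())

    def test_total_and_deterministic(self):
        scheme = mapt_scheme()
        for start in range(1, 430, 13):
            r1 = assign_peptide_region(start, start + 11, scheme)
            r2 = assign_peptide_region(start, start + 11, scheme)
            assert r1 == r2 and r1 in scheme.region_names


class TestQuantifyRegions:
    def _single_peptide_fixture(self):
        meta = pd.DataFrame({
            "peptide_sequence": ["NTERM", "PRDPEP", "MTBRPEP", "CTERMPEP"],
            "accession": "P10636-8",
            "start": [5, 130, 250, 400],
            "end": [20, 145, 262, 415],
        }, index=pd.Index(["p1", "p2", "p3", "p4"], name="peptide_id"))
        vals = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
                            index=meta.index, columns=["sA", "sB"])
        return meta, tp.AbundanceMatrix(vals, "log2")

    def test_one_peptide_per_region_passthrough(self):
        meta, mat = self._single_peptide_fixture()
        q = quantify_regions(meta, mat, mapt_scheme())
        assert q.values.loc["MTBR", "sA"] == 5.0
        assert q.values.loc["C-terminal", "sB"] == 8.0
        assert (q.n_peptides.to_numpy() == 1).all()

    def test_duplicate_rows_deduplicated(self):
        meta, mat = self._single_peptide_fixture()
        meta2 = pd.concat([meta, meta.iloc[[0]].rename(index={"p1": "p1dup"})])
        mat2 = tp.AbundanceMatrix(pd.concat([mat.data, mat.data.iloc[[0]].rename(index={"p1": "p1dup"})]), "log2")
        q = quantify_regions(meta2, mat2, mapt_scheme())
        assert int(q.n_peptides.loc["N-terminal", "sA"]) == 1

    def test_sample_permutation_invariance(self):
        meta, mat = self._single_peptide_fixture()
        q1 = quantify_regions(meta, mat, mapt_scheme())
        perm = tp.AbundanceMatrix(mat.data[["sB", "sA"]], "log2")
        q2 = quantify_regions(meta, perm, mapt_scheme())
        pd.testing.assert_frame_equal(q1.values, q2.values[["sA", "sB"]])

    def test_planted_mtbr_effect_recovered(self):
        meta, mat, traits = simulate_mapt_peptides(n_per_group=60, region_ad_effects={"MTBR": 1.0}, seed=5)
        q = quantify_regions(meta, mat, mapt_scheme())
        ad = traits.data.index[traits.data["diagnosis"] == "AD"]
        ct = traits.data.index[traits.data["diagnosis"] == "Control"]
        diff = q.values[ad].mean(axis=1) - q.values[ct].mean(axis=1)
        assert diff["MTBR"] == pytest.approx(1.0, abs=0.1)
        for region in ("N-terminal", "PRD", "C-terminal"):
            assert abs(diff[region]) < 0.1


class TestQuantifyAbSpecies:
    def _fixture(self):
        meta = pd.DataFrame({
            "peptide_sequence": ["GAIIGLMVGGVV", "GAIIGLMVGGVVIA", "LVFFAEDVGSNK", "OTHER"],
            "accession": ["P05067", "P05067", "P05067", "P99999"],
            "start": [700, 700, 688, 10],
            "end": [711, 713, 699, 20],
        }, index=pd.Index(["ab40", "ab42", "internal", "other"], name="peptide_id"))
        vals = pd.DataFrame(np.arange(8.0).reshape(4, 2), index=meta.index, columns=["sA", "sB"])
        return meta, tp.AbundanceMatrix(vals, "log2")

    def test_c_terminus_rule(self):
        meta, mat = self._fixture()
        q, report = quantify_ab_species(meta, mat, abeta_defs())
        assert q.assignment["ab40"] == "Abeta40"
        assert q.assignment["ab42"] == "Abeta42"
        assert q.assignment["internal"] == ""
        assert report["n_unassigned"] == 1 and report["unassigned_ids"] == ["internal"]
        assert q.values.loc["Abeta42", "sA"] == 2.0

    def test_overlapping_defs_rejected(self):
        meta, mat = self._fixture()
        defs = [AnalyteDef("A", "P05067", 711), AnalyteDef("B", "P05067", 711)]
        with pytest.raises(ValidationError):
            quantify_ab_species(meta, mat, defs)


class TestProteotype:
    def test_clean_mixture_all_correct(self, rng):
        carriers = rng.normal(10, 0.3, 30)
        noncarriers = rng.normal(2, 0.3, 70)
        y = pd.Series(np.concatenate([carriers, noncarriers]),
                      index=[f"c{i}" for i in range(30)] + [f"n{i}" for i in range(70)])
        calls = call_proteotype(y)
        assert calls.table.loc[[f"c{i}" for i in range(30)], "predicted_carrier"].all()
        assert not calls.table.loc[[f"n{i}" for i in range(70)], "predicted_carrier"].any()

    def test_constant_abundance_no_bimodality(self):
        y = pd.Series(np.full(20, 5.0), index=[f"s{i}" for i in range(20)])
        with pytest.raises(TmtPipeError, match="bimodality"):
            call_proteotype(y)

    def test_weak_separation_aborts(self, rng):
        y = pd.Series(rng.normal(5, 0.3, 50), index=[f"s{i}" for i in range(50)])
        with pytest.raises(TmtPipeError, match="bimodality"):
            call_proteotype(y)

    def test_too_few_samples(self, rng):
        y = pd.Series(rng.normal(5, 2, 5), index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            call_proteotype(y)

    @pytest.mark.parametrize("rate", [0.0, 0.01, 0.02, 0.05])
    def test_concordance_equals_one_minus_planted_rate(self, rate):
        cfg = tp.SimConfig(seed=13, n_proteins=40, n_samples=400, n_batches=27, n_outliers=0,
                           mcar_rate=0.0, mnar_strength=0.0, apoe_error_rate=rate)
        ds, truth = tp.simulate_cohort(cfg)
        pep = np.log2(ds.matrix.data.loc[APOE_PEPTIDE_ID, ds.traits.donor_samples()])
        calls = call_proteotype(pep)
        rep = concordance_report(calls, ds.traits)
        assert rep["concordance"] == pytest.approx(1.0 - rate, abs=1e-12)
        assert rep["discordant_ids"] == sorted(truth.apoe_error_ids)

    def test_perfect_data_report(self, rng):
        y = pd.Series(np.r_[rng.normal(13, 0.2, 40), rng.normal(10, 0.2, 60)],
                      index=[f"s{i}" for i in range(100)])
        geno = ["e3/e4"] * 40 + ["e3/e3"] * 60
        traits = tp.TraitTable(pd.DataFrame({
            "sample_id": y.index, "batch": "b0", "apoe_genotype": geno}).set_index("sample_id"))
        rep = concordance_report(call_proteotype(y), traits)
        assert rep["concordance"] == 1.0
        assert rep["false_positive_ids"] == [] and rep["false_negative_ids"] == []
        assert rep["carrier_noncarrier_ratio"] == pytest.approx(8.0, rel=0.1)
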