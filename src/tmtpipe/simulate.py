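"""Synthetic multi-site TMT cohort generator with known ground truth.

The generator emulates the structure of a multi-center brain-proteome TMT
study: donors from several contributing sites are multiplexed into 16-channel
batches, one channel per batch carries a pooled global internal standard (GIS)
formed from that batch's samples, and every protein in every batch picks up a
multiplicative batch factor that dominates the raw variance. Donor traits
(sex, race, AD diagnosis, age, CERAD, Braak, APOE genotype) drive planted
log2-additive effects on configurable subsets of proteins: sex-chromosome-like
proteins with large sex effects, a handful of race-associated proteins, and
AD effect proteins whose effect sizes are correlated across race (matrisome-like
up, synaptic-like down). An APOE e4 allele-specific peptide row carries a
carrier-specific signal with a small planted genotype-record error rate.
Whole-sample outliers and MCAR+MNAR missingness complete the fixture.

Everything planted is recorded in :class:`GroundTruth` so each downstream
stage can be tested for recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, Dataset, Scale, TraitTable, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "inject_outliers", "inject_missingness", "APOE_PEPTIDE_ID"]

APOE_PEPTIDE_ID = "APOE4pep_LGADMEDVR"

TMT16_CHANNELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]

_SITES = ("Emory", "Mayo", "MountSinai", "Rush")


@dataclass
class SimConfig:
    """Generator settings; defaults define the reference study conditions.

    batch_sd and noise_sd are log2 units; apoe_delta is the carrier-vs-floor
    log2 offset of the allele-specific peptide (homozygotes get one extra
    log2 unit for allele dosage); apoe_error_rate is the fraction of donors
    whose *recorded* genotype contradicts their true carrier status.
    """

    n_proteins: int = 1000
    n_samples: int = 600
    n_batches: int = 40
    n_sites: int = 4
    gis_per_batch: int = 1
    batch_sd: float = 1.5
    site_sd: float = 1.0
    noise_sd: float = 0.5
    trait_effects: dict = field(default_factory=lambda: {
        "sex": (8, 3.0),
        "race": (12, 1.0),
        "diagnosis": (200, 0.75),
    })
    ad_effect_corr: float = 0.9
    frac_ad: float = 0.6
    frac_aa: float = 0.30
    frac_other_race: float = 0.15
    n_outliers: int = 3
    outlier_ids: Optional[list] = None
    outlier_shift: float = 8.0
    mcar_rate: float = 0.01
    mnar_strength: float = 0.5
    apoe_delta: float = 3.0
    apoe_floor: float = 10.0
    apoe_noise_sd: float = 0.25
    apoe_error_rate: float = 0.02
    gis_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_samples", "n_batches", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_ad", "frac_aa", "frac_other_race", "mcar_rate", "apoe_error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        channels_needed = int(np.ceil(self.n_samples / self.n_batches)) + self.gis_per_batch
        if channels_needed > len(TMT16_CHANNELS):
            raise ValidationError(
                f"design infeasible: {channels_needed} channels per batch needed "
                f"(samples + GIS) but a TMT batch has {len(TMT16_CHANNELS)}"
            )
        if self.gis_per_batch >= len(TMT16_CHANNELS):
            raise ValidationError("more GIS channels than TMT channels per batch")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    batch_effects: pd.DataFrame            # protein x batch log2 effects
    trait_effects: dict                    # factor -> per-protein planted effects
    affected: dict                         # factor -> list of protein ids
    outlier_ids: list
    outlier_profile: pd.Series             # shared per-feature log2 degradation direction
    missing_mechanism: pd.DataFrame        # protein x sample codes: 0 obs, 1 MCAR, 2 MNAR
    apoe_true_carrier: pd.Series           # donor-sample bool
    apoe_recorded_carrier: pd.Series
    apoe_error_ids: list
    apoe_homozygote_ids: list
    config: SimConfig

    def summary(self) -> dict:
        mech = self.missing_mechanism.to_numpy()
        return {
            "n_proteins": int(self.batch_effects.shape[0]),
            "n_batches": int(self.batch_effects.shape[1]),
            "affected": {k: list(v) for k, v in self.affected.items()},
            "outlier_ids": list(self.outlier_ids),
            "n_mcar_cells": int((mech == 1).sum()),
            "n_mnar_cells": int((mech == 2).sum()),
            "apoe_error_ids": list(self.apoe_error_ids),
            "apoe_homozygote_ids": list(self.apoe_homozygote_ids),
            "n_true_carriers": int(self.apoe_true_carrier.sum()),
        }


def _assign_design(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized assignment of donor samples to sites/batches/channels."""
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    batches = [f"b{b:03d}" for b in range(cfg.n_batches)]
    site_names = [_SITES[i % len(_SITES)] for i in range(cfg.n_sites)]
    batch_site = {b: site_names[i % cfg.n_sites] for i, b in enumerate(batches)}
    # round-robin over a random permutation => batches randomized wrt traits
    order = rng.permutation(cfg.n_samples)
    rows = []
    per_batch_count = {b: 0 for b in batches}
    for pos, idx in enumerate(order):
        b = batches[pos % cfg.n_batches]
        chan = TMT16_CHANNELS[cfg.gis_per_batch + per_batch_count[b]]
        per_batch_count[b] += 1
        rows.append((sample_ids[idx], b, batch_site[b], chan))
    df = pd.DataFrame(rows, columns=["sample_id", "batch", "site", "channel"]).set_index("sample_id")
    return df.loc[sample_ids]


def _donor_traits(cfg: SimConfig, rng: np.random.Generator, design: pd.DataFrame) -> pd.DataFrame:
    n = cfg.n_samples
    df = design.copy()
    df["donor_id"] = [f"D{i:04d}" for i in range(n)]
    df["is_gis"] = False
    df["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    race_draw = rng.random(n)
    race = np.where(race_draw < cfg.frac_aa, "AfricanAmerican",
                    np.where(race_draw < cfg.frac_aa + cfg.frac_other_race, "Other", "White"))
    df["race"] = race
    df["diagnosis"] = np.where(rng.random(n) < cfg.frac_ad, "AD", "Control")
    df["age"] = np.clip(rng.normal(75.0, 8.0, n), 50.0, 95.0).round(1)
    ad = df["diagnosis"].to_numpy() == "AD"
    # CERAD 1-4 and Braak 0-6 drawn conditionally on diagnosis so AD pathology
    # scores are stochastically higher, mirroring neuropathological staging.
    cerad = np.where(ad, rng.choice([2, 3, 4], n, p=[0.2, 0.35, 0.45]),
                     rng.choice([1, 2, 3], n, p=[0.65, 0.25, 0.10]))
    braak = np.where(ad, rng.choice([3, 4, 5, 6], n, p=[0.15, 0.25, 0.3, 0.3]),
                     rng.choice([0, 1, 2, 3], n, p=[0.3, 0.3, 0.25, 0.15]))
    df["cerad"] = cerad
    df["braak"] = braak
    # APOE alleles; e4 enriched in AD donors
    p_e4 = np.where(ad, 0.30, 0.12)
    a1_is_e4 = rng.random(n) < p_e4
    a2_is_e4 = rng.random(n) < p_e4
    others = rng.choice(["e2", "e3"], size=(n, 2), p=[0.1, 0.9])
    allele1 = np.where(a1_is_e4, "e4", others[:, 0])
    allele2 = np.where(a2_is_e4, "e4", others[:, 1])
    df["apoe_genotype"] = ["/".join(sorted((a, b))) for a, b in zip(allele1, allele2)]
    return df


def _planted_effects(cfg: SimConfig, rng: np.random.Generator, protein_ids: list[str],
                     mu: np.ndarray):
    """Draw per-protein planted trait effects (log2 units).

    Effects are planted on proteins below the 90th abundance percentile:
    the constant-sum loading normalization ties every protein to the column
    total, which is dominated by the few most abundant proteins, so planting
    effects there would leak a compositional offset into every null protein.
    Disease- and trait-responsive proteins are mid-abundance in practice.
    """
    n_p = len(protein_ids)
    eligible = np.where(mu < np.quantile(mu, 0.9))[0]
    pool = rng.permutation(eligible)
    cursor = 0
    affected: dict[str, list] = {}
    effects: dict[str, object] = {}

    def take(k: int) -> list[str]:
        nonlocal cursor
        k = min(k, len(pool) - cursor)
        ids = [protein_ids[i] for i in pool[cursor:cursor + k]]
        cursor += k
        return ids

    n_sex, sex_size = cfg.trait_effects.get("sex", (0, 0.0))
    ids = take(int(n_sex))
    # half female-high (X-linked-like), half male-high (Y-linked-like)
    signs = np.array([1.0 if i < len(ids) / 2 else -1.0 for i in range(len(ids))])
    effects["sex"] = pd.Series(signs * sex_size, index=ids, name="female_minus_male")
    affected["sex"] = ids

    n_race, race_size = cfg.trait_effects.get("race", (0, 0.0))
    ids = take(int(n_race))
    signs = rng.choice([-1.0, 1.0], size=len(ids))
    effects["race"] = pd.Series(signs * race_size, index=ids, name="aa_minus_other")
    affected["race"] = ids

    n_dx, dx_size = cfg.trait_effects.get("diagnosis", (0, 0.0))
    ids = take(int(n_dx))
    rho = float(np.clip(cfg.ad_effect_corr, 0.0, 1.0))
    shared = rng.normal(size=len(ids))
    e_w = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=len(ids))
    e_a = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=len(ids))
    effects["diagnosis"] = pd.DataFrame(
        {"white": dx_size * e_w, "aa": dx_size * e_a}, index=ids
    )
    affected["diagnosis"] = ids

    n_age, age_slope = cfg.trait_effects.get("age", (0, 0.0))
    ids = take(int(n_age))
    effects["age"] = pd.Series(np.full(len(ids), age_slope), index=ids, name="log2_per_year")
    affected["age"] = ids

    return effects, affected


def simulate_cohort(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a seeded synthetic cohort and its ground truth.

    The linear-scale abundance of protein p in sample s is
    ``2 ** (mu_p + batch(p, b_s) + trait effects + eps)`` with
    ``eps ~ Normal(0, noise_sd)``. GIS channels are the within-batch mean
    linear profile of their batch's donor samples times a small noise factor.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    protein_ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    design = _assign_design(cfg, rng)
    traits = _donor_traits(cfg, rng, design)
    mu = rng.normal(16.0, 1.5, size=cfg.n_proteins)
    effects, affected = _planted_effects(cfg, rng, protein_ids, mu)

    batches = sorted(traits["batch"].unique())
    # batch factor = site-shared profile + batch-specific profile: batches from
    # the same contributing site share processing structure, so sites form
    # distinct clusters in leading-PC space while every batch still carries
    # its own multiplicative signature.
    batch_site = traits.drop_duplicates("batch").set_index("batch")["site"]
    sites = sorted(batch_site.unique())
    site_prof = pd.DataFrame(
        rng.normal(0.0, cfg.site_sd, size=(cfg.n_proteins, len(sites))),
        index=protein_ids, columns=sites,
    )
    batch_eff = pd.DataFrame(
        rng.normal(0.0, cfg.batch_sd, size=(cfg.n_proteins, len(batches))),
        index=protein_ids, columns=batches,
    )
    batch_eff = batch_eff + site_prof.loc[:, batch_site.loc[batches]].to_numpy()

    batch_idx = pd.Index(batches).get_indexer(traits["batch"])
    log2y = mu[:, None] + batch_eff.to_numpy()[:, batch_idx]

    pidx = pd.Index(protein_ids)
    female = (traits["sex"].to_numpy() == "female").astype(float)
    rows = pidx.get_indexer(effects["sex"].index)
    log2y[rows, :] += np.outer(effects["sex"].to_numpy(), female)

    aa = (traits["race"].to_numpy() == "AfricanAmerican").astype(float)
    rows = pidx.get_indexer(effects["race"].index)
    log2y[rows, :] += np.outer(effects["race"].to_numpy(), aa)

    ad = (traits["diagnosis"].to_numpy() == "AD").astype(float)
    rows = pidx.get_indexer(effects["diagnosis"].index)
    dxe = effects["diagnosis"]
    log2y[rows, :] += np.outer(dxe["aa"].to_numpy(), ad * aa)
    log2y[rows, :] += np.outer(dxe["white"].to_numpy(), ad * (1.0 - aa))

    if len(effects["age"]):
        rows = pidx.get_indexer(effects["age"].index)
        age_c = traits["age"].to_numpy() - 75.0
        log2y[rows, :] += np.outer(effects["age"].to_numpy(), age_c)

    sys_log2 = log2y.copy()                   # systematic abundances, pre measurement noise
    log2y = log2y + rng.normal(0.0, cfg.noise_sd, size=log2y.shape)

    # APOE e4 allele-specific peptide row: carrier signal + dosage, no batch
    # effect (emulates the post-harmonization targeted peptide signal).
    geno = traits["apoe_genotype"]
    true_carrier = geno.str.contains("e4")
    homozygote = geno == "e4/e4"
    apoe_sys = (
        cfg.apoe_floor
        + cfg.apoe_delta * true_carrier.to_numpy().astype(float)
        + 1.0 * homozygote.to_numpy().astype(float)
    )
    apoe_log2 = apoe_sys + rng.normal(0.0, cfg.apoe_noise_sd, size=cfg.n_samples)

    # planted genotype-record errors: recorded genotype contradicts truth
    n_err = int(round(cfg.apoe_error_rate * cfg.n_samples))
    err_pos = rng.choice(cfg.n_samples, size=n_err, replace=False) if n_err else np.array([], dtype=int)
    recorded = geno.copy()
    for i in err_pos:
        recorded.iloc[i] = "e3/e3" if true_carrier.iloc[i] else "e3/e4"
    traits["apoe_genotype"] = recorded
    recorded_carrier = recorded.str.contains("e4")
    apoe_error_ids = [traits.index[i] for i in sorted(err_pos)]

    all_ids = protein_ids + [APOE_PEPTIDE_ID]
    full_log2 = np.vstack([log2y, apoe_log2[None, :]])
    donor_linear = pd.DataFrame(2.0 ** full_log2, index=all_ids, columns=traits.index)
    # systematic (noise-free) profiles: the material that enters the batch pool
    donor_systematic = pd.DataFrame(
        2.0 ** np.vstack([sys_log2, apoe_sys[None, :]]), index=all_ids, columns=traits.index
    )

    # planted whole-sample outliers (donor samples only): a shared degradation
    # profile (per-protein log2 perturbation with RMS = outlier_shift), the way
    # compromised samples share a handling/proteolysis signature. A uniform
    # column scaling would be silently removed by loading normalization and is
    # available separately via inject_outliers().
    if cfg.outlier_ids is not None:
        outlier_ids = list(cfg.outlier_ids)
        missing = [s for s in outlier_ids if s not in donor_linear.columns]
        if missing:
            raise ValidationError(f"unknown outlier sample ids: {missing}")
    else:
        k = min(cfg.n_outliers, cfg.n_samples)
        outlier_ids = sorted(rng.choice(traits.index.to_numpy(), size=k, replace=False).tolist())
    outlier_profile = pd.Series(rng.normal(0.0, 1.0, size=len(all_ids)), index=all_ids)
    if outlier_ids and cfg.outlier_shift != 0:
        factor = 2.0 ** (cfg.outlier_shift * outlier_profile.to_numpy())
        for s in outlier_ids:
            donor_linear[s] = donor_linear[s].to_numpy() * factor

    # GIS channels: within-batch pooled standard. The pool aggregates the
    # members' systematic abundances (pooling happens before the per-channel
    # measurement; planted outliers are channel-level failures, so they do
    # not contaminate the pool), and the GIS channel is measured with a small
    # noise of its own.
    gis_cols = {}
    gis_rows = []
    for b in batches:
        members = traits.index[traits["batch"] == b]
        pool_profile = donor_systematic.loc[:, members].mean(axis=1)
        for g in range(cfg.gis_per_batch):
            gid = f"GIS.{b}" if cfg.gis_per_batch == 1 else f"GIS.{b}.{g}"
            noise = 2.0 ** rng.normal(0.0, cfg.gis_noise_sd, size=len(all_ids))
            gis_cols[gid] = pool_profile.to_numpy() * noise
            gis_rows.append({
                "sample_id": gid, "donor_id": gid, "site": traits.loc[members[0], "site"],
                "batch": b, "channel": TMT16_CHANNELS[g], "is_gis": True,
                "sex": "unknown", "race": "unknown", "diagnosis": "unknown",
                "age": np.nan, "cerad": np.nan, "braak": np.nan, "apoe_genotype": "",
            })

    gis_df = pd.DataFrame(gis_cols, index=all_ids)
    matrix_df = pd.concat([donor_linear, gis_df], axis=1)
    gis_traits = pd.DataFrame(gis_rows).set_index("sample_id") if gis_rows else pd.DataFrame()
    traits_all = pd.concat([traits, gis_traits]) if len(gis_traits) else traits

    # MCAR + MNAR missingness (donor + GIS cells alike)
    mech = _missingness_codes(matrix_df, cfg.mcar_rate, cfg.mnar_strength, rng)
    matrix_df = matrix_df.mask(mech > 0)

    matrix = AbundanceMatrix(matrix_df, Scale.LINEAR)
    trait_table = TraitTable(traits_all)
    dataset = Dataset(matrix.subset_samples(trait_table.sample_ids), trait_table)

    truth = GroundTruth(
        batch_effects=batch_eff,
        trait_effects=effects,
        affected=affected,
        outlier_ids=list(outlier_ids),
        outlier_profile=outlier_profile,
        missing_mechanism=mech,
        apoe_true_carrier=true_carrier,
        apoe_recorded_carrier=recorded_carrier,
        apoe_error_ids=apoe_error_ids,
        apoe_homozygote_ids=list(traits.index[homozygote]),
        config=cfg,
    )
    logger.info(
        "simulate_cohort: %d proteins x %d samples (%d batches, %d GIS), %d outliers, %.2f%% missing",
        matrix.n_features, matrix.n_samples, len(batches), len(gis_cols),
        len(outlier_ids), 100.0 * matrix.missing_mask().mean(),
    )
    return dataset, truth


def _missingness_codes(linear_df: pd.DataFrame, mcar_rate: float, mnar_strength: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell missingness codes: 0 observed, 1 MCAR, 2 MNAR.

    MNAR drop probability is a logistic function of log2 abundance centered at
    the 2nd percentile of the matrix, scaled by ``mnar_strength`` — low-signal
    cells are preferentially censored, as in reporter-ion quantitation.
    """
    if not (0 <= mcar_rate <= 1):
        raise ValidationError("mcar_rate must be in [0, 1]")
    if mnar_strength < 0:
        raise ValidationError("mnar_strength must be >= 0")
    vals = np.log2(linear_df.to_numpy())
    codes = np.zeros(vals.shape, dtype=np.uint8)
    if mnar_strength > 0:
        tau = np.nanpercentile(vals, 2.0)
        p_mnar = mnar_strength / (1.0 + np.exp(vals - tau))
        codes[rng.random(vals.shape) < p_mnar] = 2
    if mcar_rate > 0:
        codes[(rng.random(vals.shape) < mcar_rate) & (codes == 0)] = 1
    return pd.DataFrame(codes, index=linear_df.index, columns=linear_df.columns)


def inject_outliers(dataset: Dataset, sample_ids: Sequence[str], shift: float) -> Dataset:
    """Shift the named samples by ``shift`` log2 units across all features."""
    unknown = [s for s in sample_ids if s not in dataset.matrix.data.columns]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    df = dataset.matrix.data.copy()
    if dataset.matrix.scale is Scale.LINEAR:
        df.loc[:, list(sample_ids)] *= 2.0 ** shift
    else:
        df.loc[:, list(sample_ids)] += shift
    return dataset.with_matrix(dataset.matrix.with_data(df))


def inject_missingness(dataset: Dataset, mcar_rate: float, mnar_strength: float, seed: int) -> Dataset:
    """Censor cells completely at random and preferentially at low abundance."""
    rng = np.random.default_rng(seed)
    df = dataset.matrix.data.copy()
    if dataset.matrix.scale is Scale.LINEAR:
        lin = df
    else:
        lin = 2.0 ** df
    if mcar_rate >= 1.0:
        mech = pd.DataFrame(np.ones(df.shape, dtype=np.uint8), index=df.index, columns=df.columns)
    else:
        mech = _missingness_codes(lin.fillna(lin.stack().median() if lin.notna().any().any() else 1.0),
                                  mcar_rate, mnar_strength, rng)
    out = df.mask(mech > 0)
    return dataset.with_matrix(dataset.matrix.with_data(out))


def simulate_mapt_peptides(
    n_per_group: int = 60,
    n_peptides_per_region: int = 5,
    region_ad_effects: Optional[dict] = None,
    noise_sd: float = 0.5,
    frac_aa: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, AbundanceMatrix, TraitTable]:
    """Peptide-level fixture for domain quantification on tau (P10636-8).

    Generates fully tryptic-like peptides inside each tau domain for a
    race x diagnosis balanced cohort (n_per_group donors per White/AA x
    AD/CT cell) and plants AD effects on the chosen regions only, e.g.
    ``{"MTBR": 1.0}``. Returns (peptide metadata, log2 abundance matrix,
    traits) ready for :func:`tmtpipe.targeted.quantify_regions`.
    """
    from .targeted import mapt_scheme

    rng = np.random.default_rng(seed)
    region_ad_effects = region_ad_effects or {}
    scheme = mapt_scheme()
    rows = []
    for name, rs, re_ in scheme.regions:
        width = re_ - rs + 1
        for j in range(n_peptides_per_region):
            length = int(rng.integers(8, 16))
            start = int(rng.integers(rs, max(rs + 1, re_ - length + 1)))
            end = min(start + length - 1, re_)
            rows.append((f"{name.replace('-', '')}_{j}", scheme.accession, start, end, name))
    meta = pd.DataFrame(rows, columns=["peptide_sequence", "accession", "start", "end", "_region"])
    meta.index = pd.Index(meta["peptide_sequence"], name="peptide_id")

    groups = [("White", "Control"), ("White", "AD"), ("AfricanAmerican", "Control"), ("AfricanAmerican", "AD")]
    sample_rows = []
    for g, (race, dx) in enumerate(groups):
        for i in range(n_per_group):
            sample_rows.append((f"S{g}_{i:03d}", "b000", race, dx))
    traits = pd.DataFrame(sample_rows, columns=["sample_id", "batch", "race", "diagnosis"]).set_index("sample_id")
    ad = (traits["diagnosis"] == "AD").to_numpy(dtype=float)

    base = rng.normal(10.0, 1.0, size=len(meta))
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(len(meta), len(traits)))
    for region, effect in region_ad_effects.items():
        rows_r = np.where(meta["_region"].to_numpy() == region)[0]
        vals[np.ix_(rows_r, np.where(ad > 0)[0])] += effect
    matrix = AbundanceMatrix(pd.DataFrame(vals, index=meta.index, columns=traits.index), Scale.LOG2)
    return meta.drop(columns="_region"), matrix, TraitTable(traits)
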