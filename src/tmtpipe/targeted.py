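"""Targeted protein-level analyses: APOE e4 proteotyping and domain quantification.

The apoE4 protein variant differs from apoE3 by a cysteine-to-arginine
substitution that creates an allele-specific tryptic peptide (LGADMEDVR), so
its reporter signal acts as a protein-level genotype ("proteotype") readout:
samples split into a high-signal carrier class and a low background class,
and disagreements with the recorded APOE genotype flag genotyping or sample
errors.

Domain-level quantification maps peptides onto tau (MAPT, isoform P10636-8)
regions — N-terminal (1-126), proline-rich domain (127-242), microtubule
binding region (243-369), C-terminal (370-441) — and onto the amyloid-beta
C-terminal species: a peptide contributes to Abeta40 or Abeta42 only if its
C-terminus coincides with the species-defining tryptic cleavage site on APP.
Region/analyte coordinates ship as editable YAML configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import AbundanceMatrix, Scale, TraitTable, TmtPipeError, ValidationError

logger = logging.getLogger("tmtpipe")

__all__ = [
    "RegionScheme",
    "AnalyteDef",
    "load_region_scheme",
    "load_analyte_defs",
    "mapt_scheme",
    "abeta_defs",
    "assign_peptide_region",
    "DomainQuant",
    "quantify_regions",
    "quantify_ab_species",
    "ProteotypeCall",
    "call_proteotype",
    "concordance_report",
]


@dataclass
class RegionScheme:
    """Ordered, non-overlapping residue regions of one protein accession."""

    accession: str
    length: int
    regions: list  # [(name, start, end)], 1-based inclusive

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.regions:
            if not (1 <= start <= end <= self.length):
                raise ValidationError(f"region {name!r} [{start},{end}] outside 1..{self.length}")
            if start <= prev_end:
                raise ValidationError(f"region {name!r} overlaps or is out of order")
            prev_end = end

    @property
    def region_names(self) -> list[str]:
        return [r[0] for r in self.regions]


@dataclass
class AnalyteDef:
    """A C-terminally defined analyte (e.g. Abeta40/Abeta42) on a parent protein."""

    name: str
    accession: str
    c_term_position: int
    terminal_sequence: str = ""


def load_region_scheme(path) -> RegionScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RegionScheme(
        accession=doc["accession"], length=int(doc["length"]),
        regions=[(r["name"], int(r["start"]), int(r["end"])) for r in doc["regions"]],
    )


def load_analyte_defs(path) -> list[AnalyteDef]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        AnalyteDef(d["name"], d["accession"], int(d["c_term_position"]), d.get("terminal_sequence", ""))
        for d in doc["analytes"]
    ]


def mapt_scheme() -> RegionScheme:
    """Shipped default: tau domains on MAPT isoform P10636-8."""
    with resources.files("tmtpipe.data").joinpath("mapt_p10636-8.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return RegionScheme(doc["accession"], int(doc["length"]),
                        [(r["name"], int(r["start"]), int(r["end"])) for r in doc["regions"]])


def abeta_defs() -> list[AnalyteDef]:
    """Shipped default: Abeta40/Abeta42 C-termini on APP (P05067, 770-aa numbering)."""
    with resources.files("tmtpipe.data").joinpath("abeta_app.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return [AnalyteDef(d["name"], d["accession"], int(d["c_term_position"]), d.get("terminal_sequence", ""))
            for d in doc["analytes"]]


def assign_peptide_region(start: int, end: int, scheme: RegionScheme) -> str:
    """Region for a peptide spanning residues [start, end] (1-based inclusive).

    Fully contained peptides take their region; spanning peptides go to the
    region holding the majority of their residues; an exact tie goes to the
    more N-terminal region.
    """
    if not (1 <= start <= end <= scheme.length):
        raise ValidationError(f"peptide [{start},{end}] outside protein 1..{scheme.length}")
    best_name, best_overlap = None, -1
    for name, rs, re_ in scheme.regions:
        overlap = max(0, min(end, re_) - max(start, rs) + 1)
        if overlap > best_overlap:  # strict '>' keeps the more N-terminal region on ties
            best_name, best_overlap = name, overlap
    if best_overlap < (end - start + 1):
        logger.info("assign_peptide_region: peptide %d-%d spans regions; assigned %s by majority",
                    start, end, best_name)
    return best_name


@dataclass
class DomainQuant:
    """Per-sample region/analyte abundances (log2) and contributing peptide counts."""

    values: pd.DataFrame       # region x sample, log2
    n_peptides: pd.DataFrame   # region x sample counts
    assignment: pd.Series      # peptide id -> region/analyte ("" = unassigned)


def _dedupe(meta: pd.DataFrame, matrix: AbundanceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    key = meta["peptide_sequence"].astype(str) + "@" + meta["start"].astype(str) + "-" + meta["end"].astype(str)
    dup = key.duplicated()
    if dup.any():
        logger.warning("quantify: %d duplicate peptide rows dropped", int(dup.sum()))
    data = matrix.data.loc[meta.index]
    return meta[~dup.to_numpy()], data[~dup.to_numpy()]


def quantify_regions(meta: pd.DataFrame, matrix: AbundanceMatrix, scheme: RegionScheme) -> DomainQuant:
    """Mean log2 peptide abundance per region per sample (pairwise-complete).

    ``meta`` carries peptide_sequence/accession/start/end aligned with the
    log2 peptide matrix rows. Peptides on other accessions are ignored.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("quantify_regions expects log2 peptide abundances")
    meta, data = _dedupe(meta, matrix)
    on_target = meta["accession"] == scheme.accession
    assignment = pd.Series("", index=meta.index, dtype=object, name="region")
    for pid in meta.index[on_target]:
        assignment.loc[pid] = assign_peptide_region(
            int(meta.loc[pid, "start"]), int(meta.loc[pid, "end"]), scheme
        )
    values, counts = {}, {}
    for region in scheme.region_names:
        members = assignment.index[assignment == region]
        if len(members) == 0:
            logger.warning("quantify_regions: no peptides map to region %r", region)
            continue
        block = data.loc[members]
        values[region] = block.mean(axis=0, skipna=True)
        counts[region] = block.notna().sum(axis=0)
    return DomainQuant(pd.DataFrame(values).T, pd.DataFrame(counts).T, assignment)


def quantify_ab_species(meta: pd.DataFrame, matrix: AbundanceMatrix,
                        defs: Optional[Sequence[AnalyteDef]] = None) -> tuple[DomainQuant, dict]:
    """Per-sample Abeta species abundances from C-terminus-matched peptides.

    A peptide is assigned to an analyte iff its C-terminal residue equals the
    analyte's defining position (and its sequence ends with the analyte's
    terminal sequence, when one is configured). Returns the quantification
    and a coverage report counting unassigned on-accession peptides.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("quantify_ab_species expects log2 peptide abundances")
    defs = list(defs) if defs is not None else abeta_defs()
    ends = [d.c_term_position for d in defs]
    if len(set((d.accession, d.c_term_position) for d in defs)) < len(defs):
        raise ValidationError("analyte definitions must have disjoint C-termini")
    meta, data = _dedupe(meta, matrix)
    assignment = pd.Series("", index=meta.index, dtype=object, name="analyte")
    for pid in meta.index:
        hits = [
            d.name for d in defs
            if meta.loc[pid, "accession"] == d.accession
            and int(meta.loc[pid, "end"]) == d.c_term_position
            and (not d.terminal_sequence or str(meta.loc[pid, "peptide_sequence"]).endswith(d.terminal_sequence))
        ]
        if len(hits) > 1:
            raise ValidationError(f"peptide {pid} matches multiple analytes: {hits}")
        if hits:
            assignment.loc[pid] = hits[0]
    values, counts = {}, {}
    for d in defs:
        members = assignment.index[assignment == d.name]
        if len(members) == 0:
            logger.warning("quantify_ab_species: no peptides match analyte %r", d.name)
            continue
        block = data.loc[members]
        values[d.name] = block.mean(axis=0, skipna=True)
        counts[d.name] = block.notna().sum(axis=0)
    on_acc = meta["accession"].isin({d.accession for d in defs})
    report = {
        "n_peptides_on_accession": int(on_acc.sum()),
        "n_assigned": int((assignment != "").sum()),
        "n_unassigned": int((on_acc & (assignment == "")).sum()),
        "unassigned_ids": list(assignment.index[on_acc & (assignment == "")]),
    }
    return DomainQuant(pd.DataFrame(values).T, pd.DataFrame(counts).T, assignment), report


@dataclass
class ProteotypeCall:
    table: pd.DataFrame        # per sample: abundance (log2), predicted_carrier
    threshold: float
    class_means: tuple
    separation: float


def _two_means_1d(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 1-D two-class k-means via the best split of the sorted values."""
    order = np.argsort(x)
    xs = x[order]
    n = x.size
    csum = np.cumsum(xs)
    total = csum[-1]
    csq = np.cumsum(xs ** 2)
    best_cost, best_j = np.inf, 1
    for j in range(1, n):
        m1 = csum[j - 1] / j
        m2 = (total - csum[j - 1]) / (n - j)
        cost = (csq[j - 1] - j * m1 * m1) + ((csq[-1] - csq[j - 1]) - (n - j) * m2 * m2)
        if cost < best_cost:
            best_cost, best_j = cost, j
    lo_mean = csum[best_j - 1] / best_j
    hi_mean = (total - csum[best_j - 1]) / (n - best_j)
    labels = np.zeros(n, dtype=bool)
    labels[order[best_j:]] = True
    return labels, float(lo_mean), float(hi_mean)


def call_proteotype(abundance: pd.Series, min_separation: float = 1.0) -> ProteotypeCall:
    """Predict APOE e4 carrier status from the allele-specific peptide signal.

    A two-class split (exact 1-D k-means) of the log2 abundances defines
    carrier (high) and non-carrier (low) classes; the decision threshold is
    the midpoint of the class means. If the class means are closer than
    ``min_separation`` log2 units the distribution is not bimodal and calling
    aborts rather than returning arbitrary labels.
    """
    y = abundance.dropna()
    if len(y) < 10:
        raise ValidationError(f"need >= 10 samples with signal, have {len(y)}")
    x = y.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise TmtPipeError("no bimodality: constant abundances; set a manual threshold")
    hi, lo_mean, hi_mean = _two_means_1d(x)
    separation = hi_mean - lo_mean
    if separation < min_separation:
        raise TmtPipeError(
            f"no bimodality: class separation {separation:.2f} < {min_separation} log2 units; "
            "set a manual threshold"
        )
    threshold = 0.5 * (lo_mean + hi_mean)
    table = pd.DataFrame({"abundance": y, "predicted_carrier": y > threshold})
    return ProteotypeCall(table, float(threshold), (lo_mean, hi_mean), float(separation))


def concordance_report(calls: ProteotypeCall, traits: TraitTable) -> dict:
    """Concordance of predicted carrier status against recorded APOE genotypes."""
    recorded = traits.apoe_carrier()
    pred = calls.table["predicted_carrier"]
    common = pred.index.intersection(recorded.index[recorded.notna()])
    if len(common) == 0:
        raise ValidationError("no called samples with recorded genotypes")
    rec = recorded.loc[common].astype(bool)
    prd = pred.loc[common]
    agree = prd == rec
    fp = sorted(common[prd & ~rec])   # proteotype carrier, genotype non-carrier
    fn = sorted(common[~prd & rec])
    lin = 2.0 ** calls.table["abundance"]
    carrier_mean = lin[pred].mean()
    noncarrier_mean = lin[~pred].mean()
    ratio = float(carrier_mean / noncarrier_mean) if noncarrier_mean > 0 else np.inf
    return {
        "n": int(len(common)),
        "concordance": float(agree.mean()),
        "false_positive_ids": fp,
        "false_negative_ids": fn,
        "discordant_ids": sorted(fp + fn),
        "carrier_noncarrier_ratio": ratio,
        "threshold_log2": calls.threshold,
    }
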