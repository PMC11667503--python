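"""Readers and writers for abundance matrices, trait tables and peptide tables.

All on-disk formats are plain TSV/CSV. Missing cells are empty strings or
"NA" on input and written back as "NA", which round-trips losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    AbundanceMatrix,
    AnalysisConfig,
    Dataset,
    Scale,
    TraitTable,
    ValidationError,
)

logger = logging.getLogger("tmtpipe")

_NA_VALUES = ["", "NA", "NaN", "nan"]

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_traits",
    "write_traits",
    "read_peptides",
    "write_peptides",
    "align_dataset",
    "load_config",
]


def _sep_for(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance(path: Union[str, Path], scale: Union[Scale, str] = Scale.LINEAR) -> AbundanceMatrix:
    """Read a feature x sample table (first column feature ids, header sample ids)."""
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise ValidationError(f"could not parse abundance table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValidationError(
                f"{path}: non-numeric cell(s) in column '{col}' at feature(s) {list(bad[:5])}"
            )
    matrix = AbundanceMatrix(df, Scale(scale))
    logger.info("read_abundance: %d features x %d samples from %s", matrix.n_features, matrix.n_samples, path)
    return matrix


def write_abundance(matrix: AbundanceMatrix, path: Union[str, Path]) -> None:
    sep = _sep_for(path)
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, na_rep="NA")


_SEX_MAP = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}
_RACE_MAP = {
    "white": "White", "w": "White", "nhw": "White", "caucasian": "White",
    "africanamerican": "AfricanAmerican", "african american": "AfricanAmerican",
    "african-american": "AfricanAmerican", "aa": "AfricanAmerican",
    "black": "AfricanAmerican", "black or african american": "AfricanAmerican",
    "other": "Other", "latino": "Other", "hispanic": "Other", "asian": "Other",
}
_DX_MAP = {
    "ad": "AD", "alzheimer": "AD", "alzheimers": "AD", "alzheimer's disease": "AD",
    "control": "Control", "ct": "Control", "ctl": "Control", "normal": "Control",
    "other": "Other",
}


def _normalize_enum(series: pd.Series, mapping: dict, colname: str) -> pd.Series:
    raw = series.astype(str).str.strip()
    lowered = raw.str.lower()
    out = lowered.map(mapping)
    unknown = out.isna() & (raw.str.len() > 0) & ~lowered.isin(["nan", "unknown", "na"])
    if unknown.any():
        cats = sorted(raw[unknown].unique().tolist())
        logger.warning("read_traits: unrecognized %s categories mapped to 'unknown': %s", colname, cats)
    return out.fillna("unknown")


def _normalize_apoe(series: pd.Series) -> pd.Series:
    """Normalize APOE genotypes like '3/4', 'e3/e4', 'E4/E3' to sorted 'e3/e4'."""

    def norm(v) -> str:
        s = str(v).strip().lower().replace("ε", "e")
        if s in ("", "nan", "na", "unknown"):
            return ""
        parts = [p.strip().lstrip("e") for p in s.replace("|", "/").split("/")]
        if len(parts) != 2 or not all(p in ("2", "3", "4") for p in parts):
            logger.warning("read_traits: unparseable APOE genotype %r treated as missing", v)
            return ""
        return "/".join(f"e{a}" for a in sorted(parts))

    return series.map(norm)


def read_traits(path: Union[str, Path]) -> TraitTable:
    """Read a sample trait table; requires sample_id and batch columns.

    Enumerated donor traits (sex, race, diagnosis) are normalized
    case-insensitively; unknown categories become "unknown" with a warning.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, dtype=str)
    for required in ("sample_id", "batch"):
        if required not in df.columns:
            raise ValidationError(f"{path}: missing required column '{required}'")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample_id {dups}")
    df = df.set_index("sample_id")
    if "sex" in df.columns:
        df["sex"] = _normalize_enum(df["sex"], _SEX_MAP, "sex")
    if "race" in df.columns:
        df["race"] = _normalize_enum(df["race"], _RACE_MAP, "race")
    if "diagnosis" in df.columns:
        df["diagnosis"] = _normalize_enum(df["diagnosis"], _DX_MAP, "diagnosis")
    if "apoe_genotype" in df.columns:
        df["apoe_genotype"] = _normalize_apoe(df["apoe_genotype"])
    if "is_gis" in df.columns:
        df["is_gis"] = df["is_gis"].astype(str).str.strip().str.lower().isin(["true", "1", "yes", "t"])
    table = TraitTable(df)
    logger.info("read_traits: %d samples from %s", len(table.sample_ids), path)
    return table


def write_traits(traits: TraitTable, path: Union[str, Path]) -> None:
    sep = _sep_for(path)
    traits.data.to_csv(path, sep=sep, na_rep="NA")


PEPTIDE_META_COLS = ["peptide_sequence", "accession", "start", "end"]


def read_peptides(path: Union[str, Path]) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """Read a peptide table: peptide_sequence, accession, start, end, then sample columns.

    Returns (metadata frame indexed by peptide key, log2-scale AbundanceMatrix
    over the same keys). Peptide keys are "sequence@start-end".
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    for col in PEPTIDE_META_COLS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required peptide column '{col}'")
    meta = df[PEPTIDE_META_COLS].copy()
    meta["start"] = meta["start"].astype(int)
    meta["end"] = meta["end"].astype(int)
    key = meta["peptide_sequence"].astype(str) + "@" + meta["start"].astype(str) + "-" + meta["end"].astype(str)
    meta.index = pd.Index(key, name="peptide_id")
    values = df.drop(columns=PEPTIDE_META_COLS)
    values.index = meta.index
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        logger.warning("read_peptides: %d duplicate peptide rows deduplicated: %s", len(dups), dups[:5])
        keep = ~meta.index.duplicated()
        meta, values = meta[keep], values[keep]
    return meta, AbundanceMatrix(values.astype(float), Scale.LOG2)


def write_peptides(meta: pd.DataFrame, matrix: AbundanceMatrix, path: Union[str, Path]) -> None:
    sep = _sep_for(path)
    out = pd.concat([meta.reset_index(drop=True), matrix.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def align_dataset(matrix: AbundanceMatrix, traits: TraitTable) -> Dataset:
    """Restrict matrix and traits to their common samples, in matrix order."""
    common = [s for s in matrix.sample_ids if s in set(traits.sample_ids)]
    if not common:
        raise ValidationError("matrix and trait table share no samples")
    dropped_m = matrix.n_samples - len(common)
    dropped_t = len(traits.sample_ids) - len(common)
    if dropped_m or dropped_t:
        logger.info("align_dataset: dropped %d matrix samples, %d trait rows", dropped_m, dropped_t)
    return Dataset(matrix.subset_samples(common), traits.subset(common))


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> AnalysisConfig:
    """Load AnalysisConfig from a flat YAML key/value file, with overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be flat key/value pairs")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**values)
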