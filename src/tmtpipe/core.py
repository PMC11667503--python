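"""Core data containers for TMT cohort analysis.

The two first-class objects are :class:`AbundanceMatrix` (features x samples,
linear reporter intensities or log2 abundances, NaN = missing) and
:class:`TraitTable` (one row per sample: batch/site/channel plus donor traits).
Every pipeline stage consumes and returns these, so invariants are enforced at
construction time rather than inside each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("tmtpipe")

__all__ = [
    "Scale",
    "AbundanceMatrix",
    "TraitTable",
    "Dataset",
    "AnalysisConfig",
    "TmtPipeError",
    "ValidationError",
]


class TmtPipeError(Exception):
    """Base class for pipeline errors."""


class ValidationError(TmtPipeError):
    """Raised when an input violates a container invariant."""


class Scale(str, Enum):
    LINEAR = "linear"
    LOG2 = "log2"


SEX_LEVELS = ("male", "female", "unknown")
RACE_LEVELS = ("White", "AfricanAmerican", "Other", "unknown")
DIAGNOSIS_LEVELS = ("AD", "Control", "Other", "unknown")


@dataclass
class AbundanceMatrix:
    """Dense feature x sample abundance grid with explicit missing values.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns. NaN marks
        a missing cell. Linear-scale values must be positive where present,
        log2-scale values finite where present.
    scale
        Either ``Scale.LINEAR`` (raw reporter intensities / ratios) or
        ``Scale.LOG2``.
    """

    data: pd.DataFrame
    scale: Scale = Scale.LINEAR

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("AbundanceMatrix.data must be a pandas DataFrame")
        self.scale = Scale(self.scale)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        present = ~np.isnan(vals)
        if self.scale is Scale.LINEAR:
            if np.any(vals[present] <= 0):
                raise ValidationError("linear-scale values must be > 0 where present")
        else:
            if np.any(~np.isfinite(vals[present])):
                raise ValidationError("log2-scale values must be finite where present")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data.to_numpy())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)

    def with_data(self, data: pd.DataFrame, scale: Optional[Scale] = None) -> "AbundanceMatrix":
        return AbundanceMatrix(data, self.scale if scale is None else scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        return AbundanceMatrix(self.data.loc[:, ids], self.scale)

    def subset_features(self, feature_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(feature_ids)
        return AbundanceMatrix(self.data.loc[ids, :], self.scale)


_TRAIT_DEFAULTS: dict[str, object] = {
    "donor_id": "",
    "site": "",
    "channel": "",
    "is_gis": False,
    "sex": "unknown",
    "race": "unknown",
    "diagnosis": "unknown",
    "age": np.nan,
    "cerad": np.nan,
    "braak": np.nan,
    "apoe_genotype": "",
}


@dataclass
class TraitTable:
    """Per-sample traits: TMT design (site/batch/channel/GIS) and donor traits.

    ``data`` is indexed by sample_id. Missing optional columns are added with
    neutral defaults so downstream code can rely on their presence.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("TraitTable.data must be a pandas DataFrame")
        df = self.data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id: {dups}")
        if "batch" not in df.columns:
            raise ValidationError("trait table requires a 'batch' column")
        batch = df["batch"].astype(str)
        if (batch.str.len() == 0).any() or batch.isin(["nan"]).any():
            bad = df.index[(batch.str.len() == 0) | batch.isin(["nan"])].tolist()
            raise ValidationError(f"empty batch label for samples: {bad}")
        df["batch"] = batch
        for col, default in _TRAIT_DEFAULTS.items():
            if col not in df.columns:
                df[col] = default
        df["is_gis"] = df["is_gis"].astype(bool)
        for col in ("age", "cerad", "braak"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "TraitTable":
        return TraitTable(self.data.loc[list(sample_ids)].copy())

    def gis_samples(self) -> list[str]:
        return list(self.data.index[self.data["is_gis"]])

    def donor_samples(self) -> list[str]:
        return list(self.data.index[~self.data["is_gis"]])

    def apoe_carrier(self) -> pd.Series:
        """Recorded APOE e4 carrier status (NaN where genotype missing)."""
        geno = self.data["apoe_genotype"].astype(str)
        out = pd.Series(np.nan, index=self.data.index, dtype=object)
        known = geno.str.len() > 0
        out[known] = geno[known].str.contains("e4")
        return out

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy())


@dataclass
class Dataset:
    """An AbundanceMatrix and its TraitTable over an identical, ordered sample set."""

    matrix: AbundanceMatrix
    traits: TraitTable

    def __post_init__(self) -> None:
        if self.matrix.sample_ids != self.traits.sample_ids:
            raise ValidationError(
                "matrix and traits must cover identical samples in the same order; "
                "use align_dataset() to reconcile them"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def copy(self) -> "Dataset":
        return Dataset(self.matrix.copy(), self.traits.copy())

    def with_matrix(self, matrix: AbundanceMatrix) -> "Dataset":
        return Dataset(matrix, self.traits.subset(matrix.sample_ids))

    def donor_view(self) -> "Dataset":
        """Dataset restricted to non-GIS samples (used for donor-level statistics)."""
        keep = self.traits.donor_samples()
        return Dataset(self.matrix.subset_samples(keep), self.traits.subset(keep))


@dataclass
class AnalysisConfig:
    """Tunable thresholds shared across stages.

    missing_max_frac: proteins with missing fraction >= this are dropped (strict
    "less than" retention rule). outlier_sd / outlier_pcs / outlier_max_iter
    parameterize iterative PCA outlier removal. bicor_c is the biweight tuning
    constant. min_per_group is the smallest per-group n for differential tests.
    """

    missing_max_frac: float = 0.5
    outlier_sd: float = 4.0
    outlier_pcs: int = 2
    outlier_max_iter: int = 10
    alpha: float = 0.05
    min_per_group: int = 3
    bicor_c: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.missing_max_frac <= 1):
            raise ValidationError("missing_max_frac must be in (0, 1]")
        if self.outlier_sd <= 0:
            raise ValidationError("outlier_sd must be > 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.outlier_pcs < 1:
            raise ValidationError("outlier_pcs must be >= 1")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
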