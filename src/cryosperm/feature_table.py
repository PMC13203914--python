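"""Per-observation feature table: data model, CSV I/O and preprocessing.

One row describes one semen sample: its donor, the cryopreservation
treatment it received, the donor's age, and 14 quantitative features —
CASA kinematics (TM, PM, VCL, VSL, VAP), mitochondrial membrane potential
(MMP), oxidative/nitrosative stress markers (LPO, ROS, NO), DNA
fragmentation indices (TUNEL-DFI, SCSA-DFI) and holotomography-derived
region volumes (whole cell, post-acrosomal/midpiece, nucleus).

The table is the universal currency of the pipeline: the synthetic cohort
generator emits one, the classification and ANOVA stages consume one.
Percentages live in [0, 100], volumes are strictly positive, and the two
subcellular volumes never exceed the whole-cell volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Canonical treatment labels. CTRL- is the HF-20 extender without
#: antioxidants, CTRL+ the commercial INRA Freeze extender; the four named
#: treatments are HF-20 plus the corresponding natural antioxidant extract.
TREATMENTS = ("Fresh", "CTRL-", "CTRL+", "Matcha", "Spirulina", "Horseradish", "Quercetin")
FROZEN_TREATMENTS = TREATMENTS[1:]

#: The 14 quantitative features, in canonical column order.
FEATURES = (
    "tm", "pm", "vcl", "vsl", "vap",
    "mmp",
    "lpo", "ros", "no",
    "tunel_dfi", "scsa_dfi",
    "vol_whole", "vol_mid", "vol_nuc",
)
PERCENT_FEATURES = ("tm", "pm", "tunel_dfi", "scsa_dfi")
VOLUME_FEATURES = ("vol_whole", "vol_mid", "vol_nuc")
METADATA_COLUMNS = ("donor_id", "treatment")
#: Numeric columns used for modelling: donor age plus the 14 features.
MODELLING_COLUMNS = ("age",) + FEATURES
ALL_COLUMNS = METADATA_COLUMNS + MODELLING_COLUMNS


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, label set, ordering)."""


def _canonical_treatment_lookup() -> dict[str, str]:
    lut = {}
    for t in TREATMENTS:
        lut[t.casefold()] = t
    # the Unicode minus sign sometimes used in print for CTRL-
    lut["ctrl−"] = "CTRL-"
    return lut


_TREATMENT_LUT = _canonical_treatment_lookup()


def canonical_treatment(label: str) -> str:
    """Normalise a treatment label (whitespace, case, Unicode minus)."""
    key = str(label).strip().replace("−", "-").casefold()
    try:
        return _TREATMENT_LUT[key]
    except KeyError:
        raise ValidationError(
            f"unknown treatment label {label!r}; legal labels are {list(TREATMENTS)}"
        ) from None


@dataclass(frozen=True)
class ObservationRecord:
    """One sample: metadata plus the 14 quantitative features."""

    donor_id: str
    treatment: str
    age: float
    tm: float
    pm: float
    vcl: float
    vsl: float
    vap: float
    mmp: float
    lpo: float
    ros: float
    no: float
    tunel_dfi: float
    scsa_dfi: float
    vol_whole: float
    vol_mid: float
    vol_nuc: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _validate_dataframe(df: pd.DataFrame) -> None:
    for col in ALL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    num = df[list(MODELLING_COLUMNS)]
    if len(df) and num.isna().any().any():
        col = num.columns[num.isna().any()][0]
        row = int(num.index[num[col].isna()][0])
        raise ValidationError(f"missing value in column {col!r} at row {row}")
    for col in PERCENT_FEATURES:
        bad = df.index[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise ValidationError(
                f"column {col!r} outside [0, 100] at row {int(bad[0])} "
                f"(value {df.loc[bad[0], col]})"
            )
    for col in VOLUME_FEATURES:
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(f"non-positive volume {col!r} at row {int(bad[0])}")
    for col in ("vol_mid", "vol_nuc"):
        bad = df.index[df[col] > df["vol_whole"]]
        if len(bad):
            raise ValidationError(
                f"{col!r} exceeds vol_whole at row {int(bad[0])}"
            )


class FeatureTable:
    """Validated, ordered collection of observation records.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical column
    set; construction validates every domain invariant and normalises the
    categorical labels.
    """

    feature_names: tuple[str, ...] = MODELLING_COLUMNS

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ALL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        df = df[list(ALL_COLUMNS)]
        df["donor_id"] = df["donor_id"].astype(str).str.strip()
        df["treatment"] = [canonical_treatment(t) for t in df["treatment"]]
        for col in MODELLING_COLUMNS:
            df[col] = pd.to_numeric(df[col])
        df = df.reset_index(drop=True)
        _validate_dataframe(df)
        self.df = df

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.df.equals(other.df)

    def records(self) -> Iterator[ObservationRecord]:
        for row in self.df.itertuples(index=False):
            yield ObservationRecord(**row._asdict())

    # -- modelling views ----------------------------------------------------
    def feature_matrix(self, include_age: bool = True) -> np.ndarray:
        """Numeric matrix used for multivariate modelling (rows × features)."""
        cols = list(MODELLING_COLUMNS) if include_age else list(FEATURES)
        return self.df[cols].to_numpy(dtype=float)

    def labels(self, column: str) -> np.ndarray:
        if column not in METADATA_COLUMNS:
            raise SchemaError(f"label column must be one of {METADATA_COLUMNS}, got {column!r}")
        return self.df[column].to_numpy(dtype=object)

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise SchemaError(f"unknown column {name!r}")
        return self.df[name].to_numpy()


def read_table(path) -> FeatureTable:
    """Read a feature-table CSV (comma separated, period decimal, UTF-8)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return FeatureTable(df)


def write_table(table: FeatureTable, path) -> None:
    """Write a CSV that round-trips numeric content to full precision."""
    table.df.to_csv(path, index=False)


def arcsine_transform(values, clip_tol: float = 1e-9) -> np.ndarray:
    """Variance-stabilising arcsine-square-root transform for percentages.

    Maps p in [0, 100] to arcsin(sqrt(p / 100)), i.e. onto [0, pi/2].
    Values outside the domain by at most ``clip_tol`` are clipped; larger
    excursions raise.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < -clip_tol) or np.any(v > 100 + clip_tol):
        bad = v[(v < -clip_tol) | (v > 100 + clip_tol)][0]
        raise ValidationError(f"percentage {bad} outside [0, 100]")
    v = np.clip(v, 0.0, 100.0)
    return np.arcsin(np.sqrt(v / 100.0))


class Standardizer:
    """Column-wise z-scoring fitted on a training subset only.

    Uses the n-1 (sample) standard deviation. Columns with zero variance on
    the fit set are flagged degenerate and transform to 0 rather than NaN.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "Standardizer":
        return self

    def fit(self, X, y=None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if X.shape[0] < 2:
            raise ValueError("z-score fit requires at least 2 rows")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        self.degenerate_ = self.sds_ == 0.0
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.means_.shape[0]:
            raise ValueError(
                f"column count {X.shape[-1]} does not match fit ({self.means_.shape[0]})"
            )
        safe_sd = np.where(self.degenerate_, 1.0, self.sds_)
        Z = (X - self.means_) / safe_sd
        Z[:, self.degenerate_] = 0.0
        return Z

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def zscore_fit(matrix) -> Standardizer:
    """Fit a :class:`Standardizer` on ``matrix`` (rows × features)."""
    return Standardizer().fit(matrix)


def zscore_apply(std: Standardizer, matrix) -> np.ndarray:
    """Apply a fitted :class:`Standardizer` to ``matrix``."""
    return std.transform(matrix)
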