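"""Core in-memory containers shared across pipeline stages.

The concentration table is a participants x mediators :class:`pandas.DataFrame`
of positive reals (assay units, pg/mL scale) in which ``NaN`` marks a
below-limit-of-detection nondetect.  :class:`MediatorMatrix` bundles that table
with the per-mediator limit of detection (LOD) so that censoring-aware stages
(imputation, detection filtering) have the information they need.

The participant table is a plain DataFrame indexed by participant id with a
``group`` label, a ``batch`` id, and the study covariates; see
:func:`validate_participants` for the expected columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariates used by default in the adjusted group comparisons.
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "smoking_current",
    "bmi",
    "cardiovascular",
    "pulmonary_vascular",
    "inhaled_steroid",
)

#: Columns a participant table must carry (beyond its participant-id index).
REQUIRED_PARTICIPANT_COLUMNS = ("group", "batch")


@dataclass
class MediatorMatrix:
    """Participants x mediators concentration table with censoring metadata.

    Parameters
    ----------
    values
        DataFrame indexed by participant id, one column per mediator.
        Non-missing entries must be strictly positive concentrations (or their
        log2 transform once :func:`sputumpanel.preprocess.log2_transform` has
        run -- see ``scale``).  ``NaN`` marks a below-LOD nondetect.
    lod
        Per-mediator limit of detection, same units as ``values``.  Required
        for every mediator that has missing entries.
    scale
        ``"raw"`` for concentrations, ``"log2"`` after log transformation.
    """

    values: pd.DataFrame
    lod: pd.Series = field(default=None)  # type: ignore[assignment]
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.lod is None:
            self.lod = pd.Series(np.nan, index=self.values.columns, dtype=float)
        self.lod = self.lod.reindex(self.values.columns).astype(float)
        self.values = self.values.astype(float)
        self._check()

    def _check(self) -> None:
        vals = self.values.to_numpy()
        if self.scale == "raw" and np.nanmin(vals, initial=np.inf) <= 0:
            bad = self.values.stack()[self.values.stack() <= 0]
            cell = bad.index[0]
            raise ValueError(
                f"non-positive concentration at participant {cell[0]!r}, "
                f"mediator {cell[1]!r}: {bad.iloc[0]}"
            )
        missing_per_mediator = self.values.isna().any(axis=0)
        no_lod = missing_per_mediator & self.lod.isna()
        if no_lod.any():
            raise ValueError(
                "mediators with missing entries but no LOD: "
                + ", ".join(no_lod.index[no_lod])
            )

    # -- convenience views ---------------------------------------------------

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, ``True`` where the value is a below-LOD nondetect."""
        return self.values.isna()

    @property
    def mediators(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participants(self) -> pd.Index:
        return self.values.index

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def detection_fraction(self) -> pd.Series:
        """Per-mediator fraction of participants with a detected value."""
        return 1.0 - self.values.isna().mean(axis=0)

    def copy(self) -> "MediatorMatrix":
        return MediatorMatrix(self.values.copy(), self.lod.copy(), self.scale)

    # -- CSV dialect ---------------------------------------------------------
    # participant_id first column, missing cell = empty string (RFC 4180).

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "participant_id"
        out.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path, lod: pd.Series | None = None, scale: str = "raw") -> "MediatorMatrix":
        values = pd.read_csv(path, index_col="participant_id")
        return cls(values, lod, scale)

    def lod_to_csv(self, path) -> None:
        out = self.lod.rename("lod").to_frame()
        out.index.name = "mediator"
        out.to_csv(path, na_rep="")

    @staticmethod
    def lod_from_csv(path) -> pd.Series:
        return pd.read_csv(path, index_col="mediator")["lod"]


def validate_participants(participants: pd.DataFrame, matrix: MediatorMatrix | None = None) -> pd.DataFrame:
    """Validate a participant table; return it unchanged.

    Checks: required columns present, unique ids, non-missing group labels,
    and (when ``matrix`` is given) row alignment with the mediator matrix.
    """
    for col in REQUIRED_PARTICIPANT_COLUMNS:
        if col not in participants.columns:
            raise ValueError(f"participant table missing required column {col!r}")
    if not participants.index.is_unique:
        raise ValueError("participant ids are not unique")
    if participants["group"].isna().any():
        raise ValueError("missing group label(s) in participant table")
    if matrix is not None and not participants.index.equals(matrix.participants):
        raise ValueError("participant table rows do not align with mediator matrix rows")
    return participants
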