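"""Core in-memory containers for the SWATH-MS analysis.

An :class:`ExpressionMatrix` is a proteins-by-acquisitions table of
quantitative values carrying an explicit scale flag (``raw`` peak areas or
``log2`` intensities); a :class:`SampleMetadata` records the design factors
of each acquisition (patient, sample-preparation day, MS run) together with
the clinical covariates used downstream (IGHV mutational status and percent,
white-blood-count class, gender).

Both are thin wrappers over :class:`pandas.DataFrame` that validate the
invariants every downstream stage relies on (unique ids, positive raw
values, consistent dimensions) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Scale = Literal["raw", "log2"]

#: IGHV germline-divergence cutoff (%) separating unmutated (<2%, UM, poor
#: prognosis) from mutated (>2%, M) CLL.
IGHV_CUTOFF_PERCENT = 2.0

METADATA_COLUMNS = (
    "patient_id",
    "prep_day",
    "ms_run",
    "ighv_status",
    "ighv_percent",
    "wbc_class",
    "gender",
)


class ValidationError(ValueError):
    """An input violates a documented container invariant."""


def ighv_status_from_percent(percent: float) -> str:
    """Dichotomise an IGHV mutation percentage at the 2% cutoff.

    Below 2% germline divergence the clone is classed unmutated (``UM``),
    above it mutated (``M``).  Exactly 2% is unclassifiable under the
    strict cutoff; it is assigned ``M`` (the boundary never arises with
    the generator's sampling scheme).
    """
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(f"ighv_percent must be in [0, 100], got {percent}")
    return "UM" if percent < IGHV_CUTOFF_PERCENT else "M"


@dataclass
class ExpressionMatrix:
    """Proteins x acquisitions quantitative table with a scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per acquisition.
        Missing measurements are ``NaN``.
    scale
        ``"raw"`` for peak-area intensities (strictly positive where
        observed) or ``"log2"`` for log2-transformed intensities.
    """

    values: pd.DataFrame
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "raw":
            observed = ~np.isnan(arr)
            if np.any(arr[observed] <= 0):
                raise ValidationError("raw-scale matrix contains non-positive observed values")
        self.values = self.values.astype(float)

    # -- convenience views -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())

    def copy_with(self, values: pd.DataFrame, scale: Scale | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, scale=self.scale if scale is None else scale)


@dataclass
class SampleMetadata:
    """Per-acquisition design factors and clinical covariates.

    One row per acquisition (matching the expression-matrix columns), with
    columns ``patient_id``, ``prep_day``, ``ms_run``, ``ighv_status``,
    ``ighv_percent``, ``wbc_class`` and ``gender``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate acquisition ids in metadata")
        t = self.table
        bad_status = set(t["ighv_status"].unique()) - {"M", "UM"}
        if bad_status:
            raise ValidationError(f"invalid ighv_status values: {sorted(bad_status)}")
        pct = t["ighv_percent"].astype(float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("ighv_percent outside [0, 100]")
        # status must be consistent with the 2% cutoff
        below = pct < IGHV_CUTOFF_PERCENT
        above = pct > IGHV_CUTOFF_PERCENT
        if (below & (t["ighv_status"] != "UM")).any():
            raise ValidationError("ighv_percent < 2 requires status UM")
        if (above & (t["ighv_status"] != "M")).any():
            raise ValidationError("ighv_percent > 2 requires status M")
        bad_wbc = set(t["wbc_class"].unique()) - {"low", "high"}
        if bad_wbc:
            raise ValidationError(f"invalid wbc_class values: {sorted(bad_wbc)}")
        bad_gender = set(t["gender"].unique()) - {"M", "F"}
        if bad_gender:
            raise ValidationError(f"invalid gender values: {sorted(bad_gender)}")
        combos = t[["patient_id", "prep_day", "ms_run"]]
        if combos.duplicated().any():
            raise ValidationError("duplicate (patient, prep_day, ms_run) combination")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def aligned_to(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        """Return metadata reordered to ``sample_ids`` (error on mismatch)."""
        ids = pd.Index(sample_ids)
        if not set(ids) == set(self.table.index):
            raise ValidationError("metadata acquisitions do not match matrix columns")
        return SampleMetadata(self.table.loc[ids])

    def factor(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise ValidationError(f"unknown metadata factor {name!r}")
        return self.table[name]


@dataclass
class DifferentialResult:
    """Per-protein inferential results for one factor or contrast.

    ``table`` is indexed by protein id with columns ``statistic`` (F or t),
    ``p_value``, ``q_value`` (Benjamini-Hochberg), ``effect`` (log2 group
    difference or partial correlation) and ``significant`` (q at or below
    the configured FDR threshold).
    """

    factor: str
    table: pd.DataFrame
    fdr_threshold: float = 0.10
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"statistic", "p_value", "q_value", "effect", "significant"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"result table missing columns: {sorted(missing)}")

    @property
    def significant_ids(self) -> set:
        sig = self.table["significant"].fillna(False)
        return set(self.table.index[sig.astype(bool)])

    @property
    def n_significant(self) -> int:
        return len(self.significant_ids)
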