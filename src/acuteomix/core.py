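"""Shared data structures used across the pipeline.

An :class:`OmicsMatrix` is a feature x sample matrix for one ome, with
missing cells encoded as NaN and optional per-feature metadata.  The sample
design is a plain :class:`pandas.DataFrame` with one row per sample; see
:data:`DESIGN_COLUMNS` and :func:`validate_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("CON", "EE", "RE")
TIMEPOINTS = ("pre", "15min", "3.5h", "24h")
POST_TIMEPOINTS = ("15min", "3.5h", "24h")
ARMS = ("Early", "Middle", "Late", "All")
ARM_TIMEPOINTS = {
    "Early": ("15min",),
    "Middle": ("3.5h",),
    "Late": ("24h",),
    "All": ("15min", "3.5h", "24h"),
}

#: Ome labels whose values are raw sequencing counts.
COUNT_OMES = frozenset({"rna", "atac"})
OMES = ("rna", "atac", "protein", "phospho", "metab")

DESIGN_COLUMNS = (
    "sample_id",
    "participant_id",
    "group",
    "timepoint",
    "sex",
    "age",
    "batch",
)


class AcuteomixError(Exception):
    """Base class for pipeline errors."""


class InvalidConfigError(AcuteomixError):
    pass


class RankDeficientError(AcuteomixError):
    """Raised when a model matrix is rank deficient; names offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(map(str, self.columns))}")


@dataclass
class OmicsMatrix:
    """One ome's feature x sample values plus feature metadata.

    Missing cells are NaN; ``mask`` is True where a value is missing.
    """

    values: pd.DataFrame
    ome: str
    feature_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise AcuteomixError(f"duplicate feature ids in {self.ome} matrix")
        if self.ome in COUNT_OMES:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr) < 0:
                raise AcuteomixError(f"negative counts in count ome {self.ome!r}")
        if self.feature_meta is not None:
            self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def is_count_ome(self) -> bool:
        return self.ome in COUNT_OMES

    def subset_features(self, keep) -> "OmicsMatrix":
        vals = self.values.loc[keep]
        meta = None if self.feature_meta is None else self.feature_meta.loc[vals.index]
        return OmicsMatrix(vals, self.ome, meta)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.reindex(values.index)
        return OmicsMatrix(values, self.ome, meta)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample design table; returns the (unmodified) table."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise AcuteomixError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise AcuteomixError("duplicate sample ids in design")
    if design.duplicated(subset=["participant_id", "timepoint"]).any():
        raise AcuteomixError("duplicate (participant, timepoint) rows in design")
    bad_group = set(design["group"]) - set(GROUPS)
    if bad_group:
        raise AcuteomixError(f"unknown groups: {bad_group}")
    bad_tp = set(design["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise AcuteomixError(f"unknown timepoints: {bad_tp}")
    pre_counts = (
        design[design["timepoint"] == "pre"].groupby("participant_id").size()
    )
    participants = design["participant_id"].unique()
    if not all(pre_counts.get(p, 0) == 1 for p in participants):
        raise AcuteomixError("every participant must have exactly one pre sample")
    return design


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
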