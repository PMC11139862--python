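"""Core in-memory containers shared by every analysis stage.

Expression is kept as a genes x samples :class:`pandas.DataFrame` wrapped in
:class:`ExpressionMatrix` so that the abundance scale (raw TPM vs log2 TPM)
travels with the values. Cohort metadata is a plain DataFrame validated by
:func:`validate_metadata`; one row per sequenced sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical longitudinal collection timepoints, in study order.
CANONICAL_TIMEPOINTS: tuple[str, ...] = (
    "0h", "6h", "24h", "48h", "72h", "28d", "6m", "12m",
)

#: Hours since enrolment for each canonical timepoint label.
TIMEPOINT_HOURS: dict[str, float] = {
    "0h": 0.0, "6h": 6.0, "24h": 24.0, "48h": 48.0, "72h": 72.0,
    "28d": 672.0, "6m": 4380.0, "12m": 8760.0,
}

#: Acute-phase timepoints (inpatient window, enrolment through 72 h).
ACUTE_TIMEPOINTS: tuple[str, ...] = ("0h", "6h", "24h", "48h", "72h")

METADATA_COLUMNS = (
    "sample_id", "subject_id", "timepoint", "hours",
    "group", "outcome", "age", "sex",
)


class ExpressionMatrixError(ValueError):
    """Invalid expression matrix (negative TPM, duplicated identifiers...)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table.

    Parameters
    ----------
    values
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as columns.
    transform_tag
        ``"raw_tpm"`` for non-negative TPM, ``"log2_tpm"`` after
        log transformation.
    """

    values: pd.DataFrame
    transform_tag: str = "raw_tpm"

    def __post_init__(self) -> None:
        if self.transform_tag not in ("raw_tpm", "log2_tpm"):
            raise ExpressionMatrixError(
                f"unknown transform_tag {self.transform_tag!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate sample ids: {dupes[:5]}")
        if self.transform_tag == "raw_tpm":
            arr = self.values.to_numpy(dtype=float)
            if arr.size and np.nanmin(arr) < 0:
                gi, si = np.unravel_index(np.nanargmin(arr), arr.shape)
                raise ExpressionMatrixError(
                    "negative abundance for gene "
                    f"{idx[gi]!r} in sample {cols[si]!r}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class GroundTruth:
    """Known generative state of a synthetic cohort.

    ``A_true`` (genes x K) and ``P_true`` (K x samples) are the non-negative
    amplitude and pattern matrices the expression was built from;
    ``outcome_effects`` records, per pattern, whether it was wired to 28-day
    mortality (prognostic at enrolment, dynamic later, or null) and the
    standardised died-vs-survived mean difference used.
    """

    A_true: pd.DataFrame
    P_true: pd.DataFrame
    outcome_effects: dict[int, dict] = field(default_factory=dict)
    noise_model: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.A_true.to_numpy() < 0).any():
            raise ValueError("A_true has negative entries")
        if (self.P_true.to_numpy() < 0).any():
            raise ValueError("P_true has negative entries")
        k = self.P_true.shape[0]
        bad = [i for i in self.outcome_effects if not 0 <= i < k]
        if bad:
            raise ValueError(f"outcome_effects refer to missing patterns {bad}")

    @property
    def n_patterns(self) -> int:
        return self.P_true.shape[0]


class MetadataError(ValueError):
    """Cohort metadata violates its contract."""


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a cohort metadata table.

    Checks the column set, timepoint labels, the uniqueness of
    (subject_id, timepoint) pairs, and that healthy donors carry the outcome
    ``not_applicable``. Sepsis rows with a missing outcome become
    ``"unknown"``. Returns a copy with the ``hours`` column (re)derived from
    the timepoint label.
    """
    missing = [c for c in METADATA_COLUMNS if c != "hours" and c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing columns {missing}")
    meta = meta.copy()
    bad_tp = sorted(set(meta["timepoint"]) - set(CANONICAL_TIMEPOINTS))
    if bad_tp:
        raise MetadataError(f"unknown timepoint labels {bad_tp}")
    meta["hours"] = meta["timepoint"].map(TIMEPOINT_HOURS)
    bad_grp = sorted(set(meta["group"]) - {"healthy", "sepsis"})
    if bad_grp:
        raise MetadataError(f"unknown group labels {bad_grp}")

    dup = meta.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        pairs = meta.loc[dup, ["subject_id", "timepoint"]].values.tolist()
        raise MetadataError(f"duplicate (subject, timepoint) pairs: {pairs[:5]}")

    healthy = meta["group"] == "healthy"
    bad_healthy = healthy & meta["outcome"].isin(["survived", "died", "unknown"])
    if bad_healthy.any():
        sid = meta.loc[bad_healthy, "sample_id"].iloc[0]
        raise MetadataError(
            f"healthy sample {sid!r} carries a mortality outcome; expected not_applicable"
        )
    meta.loc[healthy, "outcome"] = "not_applicable"
    sepsis = ~healthy
    blank = meta["outcome"].isna() | (meta["outcome"] == "")
    meta.loc[sepsis & blank, "outcome"] = "unknown"
    bad_out = sorted(
        set(meta.loc[sepsis, "outcome"]) - {"survived", "died", "unknown"}
    )
    if bad_out:
        raise MetadataError(f"unknown sepsis outcome labels {bad_out}")
    extra = [c for c in meta.columns if c not in METADATA_COLUMNS]
    return meta[[*METADATA_COLUMNS, *extra]]


def timepoint_sort_key(labels) -> np.ndarray:
    """Positions of timepoint labels along the canonical order."""
    order = {t: i for i, t in enumerate(CANONICAL_TIMEPOINTS)}
    return np.asarray([order[t] for t in labels])


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers (GMT-style)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)
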