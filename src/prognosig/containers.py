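"""Core in-memory containers: expression matrices, clinical tables,
reference probe sets and survival data.

Conventions
-----------
* An :class:`ExpressionMatrix` is stored probes x samples, matching the
  orientation of GEO series-matrix exports.  ``scale`` records whether the
  intensities are linear (MAS5-style, non-negative) or log2.  log2 is the
  canonical internal scale; :meth:`ExpressionMatrix.to_log2` floors linear
  intensities at 1 before transforming.
* A :class:`ClinicalTable` carries one row per sample with the covariates
  used by the multivariate screen (age, grade, AJCC stage) plus the
  right-censored endpoint (``time_months``, ``event``).  Unknown
  categorical values are preserved as missing, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import IngestError

LINEAR = "linear"
LOG2 = "log2"

#: columns a training-time clinical table must have fully observed
TRAINING_REQUIRED = ("age_years", "grade", "stage", "time_months", "event")

CLINICAL_COLUMNS = (
    "age_years",
    "gender",
    "grade",
    "stage",
    "time_months",
    "event",
    "endpoint",
    "adj_chemo",
    "adj_radio",
)


def _check_unique(ids: Iterable, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise IngestError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensity matrix with a scale annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.  Every
        cell must be present and numeric; missing values are an ingest
        error, not something propagated downstream.
    scale
        ``"linear"`` (non-negative MAS5-style intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise IngestError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise IngestError("expression matrix contains non-numeric cells")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise IngestError(
                "missing expression value at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if self.scale == LINEAR and (vals < 0).any():
            raise IngestError("negative intensity on linear scale")

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id) -> pd.Series:
        """Expression vector of one sample (indexed by probe id)."""
        return self.values[sample_id]

    def subset_probes(self, probe_ids: Sequence) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise IngestError(f"probes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.scale)

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise IngestError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale)

    # -- scale handling --------------------------------------------------
    def to_log2(self, floor: float = 1.0) -> "ExpressionMatrix":
        """Return the matrix on log2 scale (identity if already log2).

        Linear intensities are floored at ``floor`` before the log so a
        zero intensity maps to 0 rather than -inf.
        """
        if self.scale == LOG2:
            return self
        return ExpressionMatrix(np.log2(self.values.clip(lower=floor)), LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(np.exp2(self.values), LINEAR)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival endpoint."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise IngestError(f"clinical table lacks column {col!r}")
        t = pd.to_numeric(df["time_months"], errors="coerce")
        if t.isna().any():
            raise IngestError("non-numeric follow-up time")
        if (t < 0).any():
            bad = df.index[t < 0].tolist()
            raise IngestError(f"negative time_months for samples {bad[:5]}")
        ev = df["event"]
        if not ev.isin([0, 1]).all():
            bad = df.index[~ev.isin([0, 1])].tolist()
            raise IngestError(f"event not in {{0,1}} for samples {bad[:5]}")
        if "gender" in df.columns:
            ok = df["gender"].isin(["male", "female", "unknown"])
            if not ok.all():
                raise IngestError(
                    f"unrecognized gender values: "
                    f"{df.loc[~ok, 'gender'].unique().tolist()}"
                )

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def subset(self, sample_ids: Sequence) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise IngestError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def require_complete(self, columns: Sequence[str] = TRAINING_REQUIRED) -> None:
        """Raise if any training-required covariate is missing.

        The probe screen is multivariate (age, grade, stage enter every
        per-probe model), so training samples must have them observed.
        """
        for col in columns:
            if col not in self.data.columns:
                raise IngestError(f"clinical table lacks column {col!r}")
            vals = pd.to_numeric(self.data[col], errors="coerce")
            if vals.isna().any():
                bad = self.data.index[vals.isna()].tolist()
                raise IngestError(
                    f"missing or non-numeric {col!r} for samples {bad[:5]}"
                )


@dataclass
class ReferenceProbeSet:
    """Low-variance probes (nominally 100) used to median-center chips."""

    probe_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise IngestError("reference probe set is empty")
        _check_unique(self.probe_ids, "reference probe ids")

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class SurvivalData:
    """Right-censored survival outcomes with a named covariate matrix."""

    times: np.ndarray
    events: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        n = len(self.times)
        if len(self.events) != n or len(self.covariates) != n:
            raise ValueError("times, events and covariates must have equal length")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("events must be 0/1")
        if (self.times < 0).any():
            raise ValueError("negative survival time")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def as_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce ``y`` to ``(times, events)``.

    Accepts a ``(times, events)`` tuple, a structured array with
    ``time``/``event`` fields (scikit-survival convention), a
    :class:`SurvivalData`, or a :class:`ClinicalTable`.
    """
    if isinstance(y, SurvivalData):
        return y.times, y.events
    if isinstance(y, ClinicalTable):
        return y.times, y.events
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        tname = "time" if "time" in names else "futime"
        ename = "event" if "event" in names else "status"
        return np.asarray(y[tname], float), np.asarray(y[ename]).astype(int)
    times, events = y
    return np.asarray(times, dtype=float), np.asarray(events).astype(int)
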