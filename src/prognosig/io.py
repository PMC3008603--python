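"""Readers and writers for the tab-delimited interchange formats.

* Expression matrix: TSV, first column probe ids, header row sample ids.
* Clinical table: TSV with named columns (``sample_id``, ``age_years``,
  ``gender``, ``grade``, ``stage``, ``time_months``, ``event``, and
  optionally ``endpoint``, ``adj_chemo``, ``adj_radio``).
* Reference probe list: one probe id per line.
* Trained model: a single versioned JSON document.

Readers validate and reject; they never repair.  Scale auto-detection
follows the usual microarray heuristic: a matrix whose maximum value
exceeds 30 cannot plausibly be log2 intensities and is taken as linear.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CLINICAL_COLUMNS,
    LINEAR,
    LOG2,
    ClinicalTable,
    ExpressionMatrix,
    ReferenceProbeSet,
)
from .exceptions import IngestError, ModelIOError
from .model import SCHEMA_VERSION, SignatureModel

#: values above this cannot be log2 intensities
SCALE_AUTO_THRESHOLD = 30.0

_UNKNOWN = {"", "na", "nan", "unknown", "?", "none"}


def read_expression_matrix(path, scale_hint: str = "auto") -> ExpressionMatrix:
    """Read a probes x samples TSV into an :class:`ExpressionMatrix`.

    ``scale_hint`` is ``"linear"``, ``"log2"`` or ``"auto"`` (infer:
    max value > 30 implies linear).
    """
    if scale_hint not in ("auto", LINEAR, LOG2):
        raise ValueError(f"unknown scale hint {scale_hint!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad][0]
            raise IngestError(
                f"non-numeric expression value at probe {probe!r}, "
                f"sample {col!r} in {path}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise IngestError(f"missing expression values in {path}")
    if scale_hint == "auto":
        scale_hint = LINEAR if df.to_numpy().max() > SCALE_AUTO_THRESHOLD else LOG2
    return ExpressionMatrix(df, scale_hint)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def _parse_category(series: pd.Series, mapping: dict, col: str) -> pd.Series:
    out = []
    for v in series:
        key = str(v).strip().lower()
        if key in _UNKNOWN or (isinstance(v, float) and np.isnan(v)):
            out.append(mapping.get("__unknown__"))
        elif key in mapping:
            out.append(mapping[key])
        else:
            raise IngestError(f"unrecognized value {v!r} in column {col!r}")
    return pd.Series(out, index=series.index)


def read_clinical_table(path) -> ClinicalTable:
    """Read a per-sample clinical TSV.

    Unknown categories are preserved as unknown/NaN; negative follow-up
    times or event indicators outside {0, 1} are ingest errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise IngestError(f"clinical table {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    for col in ("age_years", "grade", "stage", "time_months"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "event" in df.columns:
        ev = pd.to_numeric(df["event"], errors="coerce")
        if ev.isna().any() or not ev.isin([0, 1]).all():
            bad = df.index[~ev.isin([0, 1])].tolist()
            raise IngestError(f"event not in {{0,1}} for samples {bad[:5]}")
        df["event"] = ev.astype(int)
    if "gender" in df.columns:
        df["gender"] = _parse_category(
            df["gender"],
            {"male": "male", "m": "male", "female": "female", "f": "female",
             "__unknown__": "unknown"},
            "gender",
        )
    for col in ("adj_chemo", "adj_radio"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            ok = df[col].isin([0, 1]) | df[col].isna()
            if not ok.all():
                raise IngestError(f"{col} must be 0/1/unknown")
    return ClinicalTable(df[[c for c in CLINICAL_COLUMNS if c in df.columns]])


def write_clinical_table(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_reference_probes(path) -> ReferenceProbeSet:
    """One probe id per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ReferenceProbeSet(ids)


def write_reference_probes(reference: ReferenceProbeSet, path) -> None:
    Path(path).write_text("\n".join(map(str, reference.probe_ids)) + "\n")


def save_model(model: SignatureModel, path) -> None:
    """Serialize a trained model as versioned JSON.

    JSON float round-tripping is exact in Python, so a reloaded model
    reproduces prognostic indices bit-for-bit.  Saving an untrained model
    is an error.
    """
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> SignatureModel:
    try:
        d = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelIOError(
            f"model schema version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    try:
        return SignatureModel.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"malformed model file {path}: {exc}") from exc


def write_predictions(predictions, path) -> None:
    """Tab-delimited report, one row per classified sample."""
    pd.DataFrame([p.as_row() for p in predictions]).to_csv(
        path, sep="\t", index=False
    )
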