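"""Preprocessing: low-intensity probe filtering, reference-set median
centering, and the percentile-rank transform.

The pipeline mirrors how a single-chip diagnostic assay must operate:
everything learned from the training cohort (the retained-probe list) is
stored and re-applied verbatim at prediction time, and every per-sample
step (log transform, median centering, within-sample percentile ranking)
is invariant to strictly increasing transforms of the intensities, which
is what makes the downstream rank-based index robust to laboratory scale
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOG2, ExpressionMatrix, ReferenceProbeSet
from .exceptions import IngestError, PrognosigError

DEFAULT_INTENSITY_THRESHOLD = 100.0
#: minimum fraction of the reference set that must be present on a chip
MIN_REFERENCE_FRACTION = 0.5


@dataclass
class PreprocessState:
    """What the trained pipeline remembers about preprocessing."""

    retained_probe_ids: list = field(default_factory=list)
    reference_probe_ids: list = field(default_factory=list)
    filter_threshold: float = DEFAULT_INTENSITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.filter_threshold < 0:
            raise ValueError("filter threshold must be >= 0")


def filter_low_intensity(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> tuple[ExpressionMatrix, PreprocessState]:
    """Drop probes whose median linear intensity is below ``threshold``.

    The rule is evaluated on the linear (MAS5) scale: a probe is excluded
    when its median intensity across samples is strictly below the
    threshold (default 100), so a probe sitting exactly at 100 is
    retained.  The retained-probe list is recorded in the returned
    :class:`PreprocessState` for reuse on prediction-time chips.
    """
    linear = matrix.to_linear()
    medians = linear.values.median(axis=1)
    keep = medians >= threshold
    if not keep.any():
        raise PrognosigError(
            f"intensity filter at {threshold} removed every probe"
        )
    retained = linear.values.index[keep].tolist()
    out = ExpressionMatrix(matrix.values.loc[retained], matrix.scale)
    return out, PreprocessState(
        retained_probe_ids=retained, filter_threshold=threshold
    )


def median_center_chips(
    matrix: ExpressionMatrix,
    reference: ReferenceProbeSet,
    min_fraction: float = MIN_REFERENCE_FRACTION,
) -> ExpressionMatrix:
    """Median-center each chip on the reference probe set (log2 scale).

    For every sample the log2 median over the reference probes present in
    the matrix is subtracted from all probes, so after centering the
    per-sample reference median is exactly 0.  Requires at least
    ``min_fraction`` of the reference probes to be present (the internal
    reference set is nominally 100 low-variance probes).
    """
    if matrix.scale != LOG2:
        raise ValueError("median centering operates on the log2 scale")
    present = [p for p in reference.probe_ids if p in matrix.values.index]
    if not present:
        raise IngestError("no reference probe found in matrix")
    frac = len(present) / len(reference)
    if frac < min_fraction:
        raise IngestError(
            f"only {len(present)}/{len(reference)} reference probes present "
            f"(< {min_fraction:.0%} floor)"
        )
    if len(present) < len(reference):
        warnings.warn(
            f"{len(reference) - len(present)} reference probes absent; "
            "centering on the remainder",
            stacklevel=2,
        )
    ref_median = matrix.values.loc[present].median(axis=0)
    return ExpressionMatrix(matrix.values.sub(ref_median, axis=1), LOG2)


def percentile_rank_transform(values) -> np.ndarray:
    """Map one sample's expression over a probe set to percentile ranks.

    The value with average rank r among m values maps to
    ``100 * (r - 1) / (m - 1)``: the minimum maps to 0.00, the maximum to
    100.00, and tied values share the average of the ranks they span.
    The output depends only on the ordering of the input, so any strictly
    increasing transform (log, scaling, offsets) leaves it unchanged.  A
    constant vector maps to all 50.00 by convention.
    """
    x = np.asarray(values, dtype=float)
    m = x.size
    if m < 2:
        raise ValueError("percentile ranks need at least 2 values")
    if np.ptp(x) == 0:
        return np.full(m, 50.0)
    r = stats.rankdata(x, method="average")
    return 100.0 * (r - 1.0) / (m - 1.0)


def percentile_rank_matrix(matrix: ExpressionMatrix, probe_ids) -> pd.DataFrame:
    """Within-sample percentile ranks over ``probe_ids``.

    Returns a samples x probes DataFrame (the orientation the metagene
    model consumes).  Ranking is within each sample across the signature
    probes; no cohort-level statistics enter, so a single chip can be
    transformed in isolation.
    """
    sub = matrix.subset_probes(probe_ids).values
    ranked = np.apply_along_axis(percentile_rank_transform, 0, sub.to_numpy(float))
    return pd.DataFrame(ranked.T, index=sub.columns, columns=sub.index)


def prepare_training_matrix(
    matrix: ExpressionMatrix,
    reference: ReferenceProbeSet | None = None,
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> tuple[ExpressionMatrix, PreprocessState]:
    """Standard training-time preprocessing chain.

    Linear input is log2-transformed (floored at intensity 1), probes
    below the intensity filter are dropped, and chips are median-centered
    on the reference set when one is given.
    """
    filtered, state = filter_low_intensity(matrix, intensity_threshold)
    out = filtered.to_log2()
    if reference is not None:
        out = median_center_chips(out, reference)
        state.reference_probe_ids = list(reference.probe_ids)
    return out, state


def prepare_prediction_matrix(
    matrix: ExpressionMatrix, state: PreprocessState
) -> ExpressionMatrix:
    """Apply stored training-time preprocessing to new chips.

    Uses the retained-probe list learned in training (never re-derives
    the filter from prediction data) and re-centers on the stored
    reference set if one was used.
    """
    present = [p for p in state.retained_probe_ids if p in matrix.values.index]
    missing = len(state.retained_probe_ids) - len(present)
    if missing:
        warnings.warn(f"{missing} retained probes absent from prediction matrix",
                      stacklevel=2)
    out = matrix.subset_probes(present).to_log2()
    if state.reference_probe_ids:
        out = median_center_chips(
            out, ReferenceProbeSet(list(state.reference_probe_ids))
        )
    return out
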