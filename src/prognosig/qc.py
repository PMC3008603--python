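"""Chip-level quality control.

Four metrics are computed per chip, each mapping onto a failure mode of
array hybridizations: nonspecific background binding, an aberrant
normalization (scale) factor, a poor signal-to-noise ratio, and unstable
replicate probes for the same gene.  A chip failing any configured window
is flagged and excluded from classifier evaluation.

Metric definitions (windows all configurable):

* ``background_estimate`` - mean log2 intensity of the dimmest 2% of
  probes on the chip.  Chips collapsed toward the intensity floor (heavy
  clipping, scanner failure) fall below the window.
* ``scale_factor`` - the chip's two-sided 2%-trimmed mean linear
  intensity divided by the cohort median of the same quantity; doubling a
  chip on the linear scale doubles its scale factor.
* ``signal_to_noise`` - log2 dynamic range (97.5th minus 2.5th
  percentile) of the cohort median chip, divided by the robust s.d.
  (1.4826 x MAD) of the chip's residual from that consensus chip.  A
  clean chip tracks the consensus tightly (high ratio, capped to stay
  finite); a noisy hybridization inflates the residual and the ratio
  drops.
* ``replicate_probe_cv`` - median coefficient of variation (linear
  scale) across genes interrogated by two or more probes; requires a
  probe-to-gene mapping and is reported as NaN (never flagged) without
  one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import QCError

_SNR_CAP = 1e6


@dataclass
class QCConfig:
    """Acceptance windows for the chip metrics."""

    background_window: tuple[float, float] = (2.0, 8.0)
    scale_factor_window: tuple[float, float] = (0.25, 4.0)
    min_signal_to_noise: float = 3.0
    max_replicate_probe_cv: float = 0.5
    background_fraction: float = 0.02
    trim_fraction: float = 0.02


@dataclass
class QCReport:
    """Per-chip metric values plus the list of failed metrics."""

    sample_id: object
    background_estimate: float
    scale_factor: float
    signal_to_noise: float
    replicate_probe_cv: float
    flags: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "background_estimate": self.background_estimate,
            "scale_factor": self.scale_factor,
            "signal_to_noise": self.signal_to_noise,
            "replicate_probe_cv": self.replicate_probe_cv,
            "flags": ";".join(self.flags),
            "pass": self.passed,
        }


def _trimmed_mean(x: np.ndarray, frac: float) -> float:
    x = np.sort(x)
    k = int(np.floor(frac * x.size))
    return float(x[k: x.size - k].mean()) if x.size > 2 * k else float(x.mean())


def _as_log2(linear: np.ndarray) -> np.ndarray:
    return np.log2(np.clip(linear, 1.0, None))


def qc_evaluate_chip(
    matrix: ExpressionMatrix,
    sample_id,
    config: QCConfig | None = None,
    probe_to_gene: dict | None = None,
) -> QCReport:
    """Evaluate one chip against the cohort in ``matrix``.

    The scale factor and the signal-to-noise consensus are relative to
    the cohort: the whole matrix provides the reference trimmed mean and
    the median chip.
    """
    config = config or QCConfig()
    if sample_id not in matrix.values.columns:
        raise QCError(f"sample {sample_id!r} not in matrix")
    linear = matrix.to_linear().values
    chip = linear[sample_id].to_numpy(float)
    if np.count_nonzero(chip > 0) <= 1:
        raise QCError("chip has <= 1 positive probe; metrics undefined")
    chip_log2 = _as_log2(chip)

    k = max(int(np.ceil(config.background_fraction * chip_log2.size)), 2)
    background = float(np.sort(chip_log2)[:k].mean())

    cohort_tmeans = [
        _trimmed_mean(linear[s].to_numpy(float), config.trim_fraction)
        for s in linear.columns
    ]
    scale_factor = (
        _trimmed_mean(chip, config.trim_fraction) / float(np.median(cohort_tmeans))
    )

    consensus = _as_log2(np.median(linear.to_numpy(float), axis=1))
    dynamic = float(np.percentile(consensus, 97.5) - np.percentile(consensus, 2.5))
    resid = chip_log2 - consensus
    noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    snr = min(dynamic / max(noise_sd, dynamic / _SNR_CAP), _SNR_CAP)

    rep_cv = np.nan
    if probe_to_gene:
        chip_s = linear[sample_id]
        genes = pd.Series(
            {p: probe_to_gene[p] for p in chip_s.index if p in probe_to_gene}
        )
        cvs = []
        for _, probes in genes.groupby(genes).groups.items():
            if len(probes) >= 2:
                v = chip_s.loc[list(probes)].to_numpy(float)
                if v.mean() > 0:
                    cvs.append(v.std(ddof=1) / v.mean())
        if cvs:
            rep_cv = float(np.median(cvs))

    flags = []
    lo, hi = config.background_window
    if not (lo <= background <= hi):
        flags.append("background_estimate")
    lo, hi = config.scale_factor_window
    if not (lo <= scale_factor <= hi):
        flags.append("scale_factor")
    if snr < config.min_signal_to_noise:
        flags.append("signal_to_noise")
    if np.isfinite(rep_cv) and rep_cv > config.max_replicate_probe_cv:
        flags.append("replicate_probe_cv")
    return QCReport(
        sample_id=sample_id,
        background_estimate=background,
        scale_factor=scale_factor,
        signal_to_noise=snr,
        replicate_probe_cv=rep_cv,
        flags=flags,
    )


def qc_evaluate_cohort(
    matrix: ExpressionMatrix,
    config: QCConfig | None = None,
    probe_to_gene: dict | None = None,
) -> pd.DataFrame:
    """QC every chip; one tab-separable row per chip."""
    rows = [
        qc_evaluate_chip(matrix, s, config, probe_to_gene).as_row()
        for s in matrix.sample_ids
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def passing_samples(report: pd.DataFrame) -> list:
    """Sample ids whose chips raised no QC flag."""
    return report.index[report["pass"]].tolist()
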