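"""The trained signature model and single-sample risk predictions.

A :class:`SignatureModel` is everything the deployed assay needs to score
one chip in isolation: the signature probe list, the two metagene
loadings with their per-probe rank centers, the metagene Cox
coefficients, the classification threshold (50th percentile of the
cross-validated training indices), the training index quantiles (used as
the index range for reproducibility summaries), the calibrated
between-site replicate s.d., and the preprocessing state (retained probe
list and reference set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NotFittedError
from .preprocess import PreprocessState

SCHEMA_VERSION = 1

#: between-site s.d. of the prognostic index calibrated on multi-site
#: replicate hybridizations of pooled RNA; default from the shipped
#: calibration of the colon assay
DEFAULT_REPLICATE_SD = 0.037


@dataclass
class SignatureModel:
    """Trained two-metagene prognostic classifier."""

    probe_ids: list
    loadings: np.ndarray            # (n_components, n_probes), unit-norm rows
    center: np.ndarray              # per-probe mean training rank
    metagene_betas: np.ndarray      # Cox coefficients of the metagene scores
    threshold: float | None = None  # prognostic-index classification cut
    training_index_quantiles: dict = field(default_factory=dict)
    replicate_sd: float | None = DEFAULT_REPLICATE_SD
    preprocess: PreprocessState = field(default_factory=PreprocessState)

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.center = np.asarray(self.center, dtype=float)
        self.metagene_betas = np.asarray(self.metagene_betas, dtype=float)
        k, m = self.loadings.shape
        if m != len(self.probe_ids) or len(self.center) != m:
            raise ValueError("loadings/center shape mismatch with probe_ids")
        if len(self.metagene_betas) != k:
            raise ValueError("one Cox coefficient per metagene required")
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loadings rows must be unit-norm")
        if (self.metagene_betas < 0).any():
            raise ValueError(
                "metagene coefficients must be >= 0 (sign convention: "
                "higher index => higher hazard)"
            )

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def is_trained(self) -> bool:
        return self.threshold is not None

    @property
    def training_index_range(self) -> float:
        """max - min of the cross-validated training indices."""
        q = self.training_index_quantiles
        if not q or 0 not in q or 100 not in q:
            raise NotFittedError("model lacks training index quantiles")
        return float(q[100] - q[0])

    def require_trained(self) -> None:
        if not self.is_trained:
            raise NotFittedError(
                "model has no classification threshold; train it first"
            )

    def to_dict(self) -> dict:
        self.require_trained()
        return {
            "schema_version": SCHEMA_VERSION,
            "probe_ids": list(self.probe_ids),
            "loadings": self.loadings.tolist(),
            "center": self.center.tolist(),
            "metagene_betas": self.metagene_betas.tolist(),
            "threshold": self.threshold,
            "training_index_quantiles": {
                str(k): v for k, v in self.training_index_quantiles.items()
            },
            "replicate_sd": self.replicate_sd,
            "preprocess": {
                "retained_probe_ids": list(self.preprocess.retained_probe_ids),
                "reference_probe_ids": list(self.preprocess.reference_probe_ids),
                "filter_threshold": self.preprocess.filter_threshold,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        pp = d["preprocess"]
        return cls(
            probe_ids=list(d["probe_ids"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            metagene_betas=np.asarray(d["metagene_betas"], dtype=float),
            threshold=d["threshold"],
            training_index_quantiles={
                float(k): v for k, v in d["training_index_quantiles"].items()
            },
            replicate_sd=d["replicate_sd"],
            preprocess=PreprocessState(
                retained_probe_ids=list(pp["retained_probe_ids"]),
                reference_probe_ids=list(pp["reference_probe_ids"]),
                filter_threshold=pp["filter_threshold"],
            ),
        )


@dataclass
class RiskPrediction:
    """Continuous prognostic index plus the binary risk call for one sample.

    ``risk_group`` is ``"high"`` iff the index is at or above the model
    threshold (a boundary index counts as high risk); ``ci95`` is the
    index +/- 1.96 times the calibrated replicate s.d.; ``borderline``
    marks calls whose confidence interval straddles the threshold.
    """

    sample_id: object
    prognostic_index: float
    ci95: tuple[float, float]
    risk_group: str
    borderline: bool = False

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "prognostic_index": self.prognostic_index,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "risk_group": self.risk_group,
            "borderline": self.borderline,
        }
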