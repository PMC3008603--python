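"""Multi-site replicate analysis and confidence-interval calibration.

The deployed assay scores single chips, so its measurement error is
quantified by hybridizing the same RNA pools repeatedly at multiple
laboratories: for each pool, the prognostic index is averaged per site
and the standard deviation across site means summarizes between-site
variation.  The mean of these s.d. values over pools becomes the
calibrated replicate s.d. carried by the model, from which single-sample
95% intervals are computed as index +/- 1.96 * s.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .exceptions import PrognosigError
from .model import SignatureModel
from .signature import prognostic_indices

REPLICATE_COLUMNS = ("sample_label", "site_label", "replicate", "prognostic_index")


def make_replicate_set(records) -> pd.DataFrame:
    """Validate a replicate table: one prognostic index per
    (sample, site, replicate)."""
    df = pd.DataFrame(records)
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"replicate set lacks columns {missing}")
    keys = df[["sample_label", "site_label", "replicate"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (sample, site, replicate) entries")
    return df[list(REPLICATE_COLUMNS)].copy()


def indices_from_replicates(
    matrix: ExpressionMatrix, manifest: pd.DataFrame, model: SignatureModel
) -> pd.DataFrame:
    """Score replicate chips and assemble a replicate set.

    ``manifest`` maps each chip (column of ``matrix``) to its
    (sample_label, site_label, replicate) via a ``chip_id`` column.
    """
    idx = prognostic_indices(model, matrix)
    df = manifest.copy()
    df["prognostic_index"] = df["chip_id"].map(idx)
    if df["prognostic_index"].isna().any():
        bad = df.loc[df["prognostic_index"].isna(), "chip_id"].tolist()
        raise PrognosigError(f"chips absent from matrix: {bad[:5]}")
    return make_replicate_set(df)


@dataclass
class StabilityReport:
    """Between-site index variation and the derived CI calibration."""

    per_sample: pd.DataFrame          # site means, between-site s.d. per pool
    mean_sd: float                    # average between-site s.d. over pools
    fraction_of_range: float | None   # mean_sd / training index range
    calibrated_ci_halfwidth: float    # 1.96 * mean_sd
    within_site_tests: pd.DataFrame   # per-site replicate-homogeneity p
    test_method: str

    @property
    def within_site_consistent(self) -> bool:
        """True when no site shows a significant replicate difference
        (all p > 0.05)."""
        p = self.within_site_tests["p_value"].dropna()
        return bool((p > 0.05).all())


def replicate_stability(
    replicates: pd.DataFrame,
    model: SignatureModel | None = None,
    test: str = "anova",
) -> StabilityReport:
    """Summarize replicate-hybridization stability of the index.

    Per sample pool: the mean index at each site, then the s.d. (ddof=1)
    across site means.  ``mean_sd`` averages these over pools and
    ``calibrated_ci_halfwidth = 1.96 * mean_sd`` is the single-sample
    95% CI halfwidth.  ``fraction_of_range`` expresses mean_sd relative
    to the range of the model's cross-validated training indices (None
    when no trained model is given).

    Within each site, replicate groups are compared with a one-way ANOVA
    across replicate numbers (``test="kruskal"`` for the rank-based
    alternative); p > 0.05 everywhere indicates no significant
    within-site replicate difference.
    """
    df = make_replicate_set(replicates)
    if df["site_label"].nunique() < 2:
        raise PrognosigError(
            "between-site s.d. undefined with a single site"
        )
    rows = []
    for sample, sub in df.groupby("sample_label", sort=True):
        site_means = sub.groupby("site_label")["prognostic_index"].mean()
        rows.append(
            {
                "sample_label": sample,
                "n_sites": len(site_means),
                "mean_index": float(sub["prognostic_index"].mean()),
                "site_sd": float(site_means.std(ddof=1)),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_label")
    mean_sd = float(per_sample["site_sd"].mean())

    stat_fn = stats.f_oneway if test == "anova" else stats.kruskal
    if test not in ("anova", "kruskal"):
        raise ValueError(f"unknown test {test!r}")
    test_rows = []
    for site, sub in df.groupby("site_label", sort=True):
        groups = [
            g["prognostic_index"].to_numpy(float)
            for _, g in sub.groupby("replicate")
        ]
        if len(groups) >= 2 and min(len(g) for g in groups) >= 2:
            with np.errstate(invalid="ignore"):
                try:
                    p = float(stat_fn(*groups).pvalue)
                except ValueError:
                    p = np.nan
        else:
            p = np.nan
        test_rows.append({"site_label": site, "p_value": p})

    fraction = None
    if model is not None:
        rng = model.training_index_range
        fraction = mean_sd / rng if rng > 0 else np.inf
    return StabilityReport(
        per_sample=per_sample,
        mean_sd=mean_sd,
        fraction_of_range=fraction,
        calibrated_ci_halfwidth=1.96 * mean_sd,
        within_site_tests=pd.DataFrame(test_rows).set_index("site_label"),
        test_method=test,
    )


def apply_calibration(model: SignatureModel, report: StabilityReport) -> SignatureModel:
    """Store a replicate calibration in the model (in place)."""
    model.replicate_sd = report.mean_sd
    return model


def prediction_interval(index: float, model: SignatureModel) -> tuple[float, float]:
    """95% interval for one prognostic index: index +/- 1.96 * s.d."""
    if model.replicate_sd is None:
        raise PrognosigError(
            "model has no calibrated replicate s.d.; run replicate_stability "
            "and apply_calibration, or set model.replicate_sd explicitly"
        )
    half = 1.96 * model.replicate_sd
    return (index - half, index + half)
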