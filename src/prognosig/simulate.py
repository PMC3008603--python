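"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a MAS5-normalized microarray study of a
right-censored recurrence endpoint:

* log-normal background intensities (probe-specific means on log2
  scale), including a designated block of low-variance, high-intensity
  reference probes and a planted fraction of probes below the
  100-intensity filter;
* a standard-normal latent risk factor per patient on which every
  informative probe loads (plus probe-level noise), entering an
  exponential proportional-hazards survival time together with clinical
  covariate effects (age, grade, stage);
* independent exponential censoring whose rate is solved numerically so
  the expected censored fraction matches the target;
* optional multi-site replicate chips with additive site and replicate
  noise on the log2 scale.

Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ClinicalTable, ExpressionMatrix, ReferenceProbeSet


@dataclass
class SimulationConfig:
    """Study-condition knobs for :func:`generate_cohort`.

    Defaults reproduce the standard test-bench cohort: n=200 patients,
    2000 probes of which 20 are informative at log-hazard 0.8 per s.d.
    of the latent risk factor, ~30% censoring, and a demographic mix
    (age 64 +/- 13.4, 53% male, stage distribution 12/31/33/24%)
    matching a multi-centre stage-1-4 colon cohort.
    """

    n_samples: int = 200
    n_probes: int = 2000
    n_informative: int = 20
    effect_size: float = 0.8          # log-hazard per s.d. of latent risk
    baseline_hazard: float = 0.01     # events / month
    censor_rate: float = 0.30         # target censored fraction
    age_effect: float = 0.01          # log-hazard per year (centered)
    grade_effect: float = 0.2
    stage_effect: float = 0.5
    stage_probs: tuple = (0.12, 0.31, 0.33, 0.24)
    male_fraction: float = 0.53
    age_mean: float = 64.0
    age_sd: float = 13.4
    signal_noise_sd: float = 0.5      # probe-level noise around the latent factor
    intensity_location: float = 8.0   # log2 mean of background probes
    intensity_scale: float = 1.0      # spread of probe means
    intensity_floor: float = 7.2      # min probe mean (keeps medians >= 100)
    sample_noise_sd: float = 0.4      # per-chip noise on log2 scale
    fraction_low_intensity: float = 0.10
    n_reference: int = 100
    reference_noise_sd: float = 0.05
    endpoint: str = "DFS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative cannot exceed n_probes")
        if not 0 < self.censor_rate < 1:
            raise ValueError("censor_rate must be strictly inside (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    informative_probe_ids: list
    low_intensity_probe_ids: list
    reference_probe_ids: list
    latent_risk: pd.Series            # per-sample latent factor
    true_linear_predictor: pd.Series  # full log-hazard (latent + covariates)
    true_risk_half: pd.Series         # "high"/"low" split at the median
    config: SimulationConfig = field(repr=False, default=None)


def _solve_censor_rate(rates: np.ndarray, target: float) -> float:
    """Censoring rate of an independent exponential such that the
    expected censored fraction E[lc / (li + lc)] equals the target."""

    def frac(lc):
        return float(np.mean(lc / (rates + lc))) - target

    lo, hi = 1e-12, 1e-12
    while frac(max(hi, 1e-12)) < 0:
        hi = max(hi * 10, 1e-9)
        if hi > 1e9:
            raise ValueError("cannot reach target censor rate")
    return float(optimize.brentq(frac, lo, hi))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Simulate an expression cohort with proportional-hazards outcome.

    Returns a linear-scale (MAS5-like) :class:`ExpressionMatrix`, a
    complete :class:`ClinicalTable` and the generating
    :class:`GroundTruth`.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    sample_ids = [f"S{i+1:04d}" for i in range(c.n_samples)]

    # --- probe universe -------------------------------------------------
    n_low = int(round(c.fraction_low_intensity * c.n_probes))
    n_bg = c.n_probes - n_low
    probe_ids = [f"P{i+1:05d}_at" for i in range(c.n_probes)]
    ref_ids = [f"REF{i+1:04d}_at" for i in range(c.n_reference)]
    informative = list(rng.choice(probe_ids[:n_bg], c.n_informative, replace=False))
    low_ids = probe_ids[n_bg:]

    bg_means = np.maximum(
        rng.normal(c.intensity_location, c.intensity_scale, n_bg),
        c.intensity_floor,
    )
    low_means = rng.normal(4.5, 0.2, n_low)     # linear ~23, safely below 100
    ref_means = rng.normal(9.0, 0.2, c.n_reference)

    # --- latent risk and expression ------------------------------------
    u = rng.standard_normal(c.n_samples)
    log2 = np.empty((c.n_probes + c.n_reference, c.n_samples))
    log2[:n_bg] = bg_means[:, None] + rng.normal(
        0, c.sample_noise_sd, (n_bg, c.n_samples)
    )
    inf_pos = {p: i for i, p in enumerate(probe_ids[:n_bg])}
    for p in informative:
        i = inf_pos[p]
        log2[i] = (
            bg_means[i]
            + u  # unit loading on the latent factor
            + rng.normal(0, c.signal_noise_sd, c.n_samples)
        )
    log2[n_bg: c.n_probes] = low_means[:, None] + rng.normal(
        0, min(c.sample_noise_sd, 0.3), (n_low, c.n_samples)
    )
    log2[c.n_probes:] = ref_means[:, None] + rng.normal(
        0, c.reference_noise_sd, (c.n_reference, c.n_samples)
    )
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log2), index=probe_ids + ref_ids, columns=sample_ids
        ),
        "linear",
    )

    # --- clinical covariates --------------------------------------------
    age = np.clip(rng.normal(c.age_mean, c.age_sd, c.n_samples), 25, 95)
    gender = np.where(
        rng.random(c.n_samples) < c.male_fraction, "male", "female"
    )
    grade = rng.choice([1, 2, 3], c.n_samples, p=[0.2, 0.55, 0.25])
    stage = rng.choice([1, 2, 3, 4], c.n_samples, p=c.stage_probs)

    eta = (
        c.effect_size * u
        + c.age_effect * (age - c.age_mean)
        + c.grade_effect * (grade - 2.0)
        + c.stage_effect * (stage - 2.5)
    )
    rates = c.baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0 / rates)
    lc = _solve_censor_rate(rates, c.censor_rate)
    C = rng.exponential(1.0 / lc, c.n_samples)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "age_years": age,
                "gender": gender,
                "grade": grade,
                "stage": stage,
                "time_months": time,
                "event": event,
                "endpoint": c.endpoint,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        informative_probe_ids=informative,
        low_intensity_probe_ids=low_ids,
        reference_probe_ids=ref_ids,
        latent_risk=pd.Series(u, index=sample_ids),
        true_linear_predictor=pd.Series(eta, index=sample_ids),
        true_risk_half=pd.Series(
            np.where(eta >= np.median(eta), "high", "low"), index=sample_ids
        ),
        config=c,
    )
    return expr, clinical, truth


def reference_probe_set(truth: GroundTruth) -> ReferenceProbeSet:
    return ReferenceProbeSet(list(truth.reference_probe_ids))


def generate_replicates(
    base_sample: pd.Series,
    n_sites: int,
    n_replicates: int,
    site_noise_sd: float,
    replicate_noise_sd: float,
    seed: int,
    sample_label: str = "pool",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Replicate chips of one RNA pool across laboratories.

    A site effect is drawn once per site and chip noise once per
    replicate, both additive on the log2 scale.  Returns the replicate
    matrix (log2) and a manifest with chip_id / sample_label /
    site_label / replicate columns.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if site_noise_sd < 0 or replicate_noise_sd < 0:
        raise ValueError("noise s.d. must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_sample, dtype=float)
    cols = {}
    manifest = []
    site_effects = rng.normal(0, site_noise_sd, n_sites) if site_noise_sd > 0 \
        else np.zeros(n_sites)
    for s in range(n_sites):
        for r in range(n_replicates):
            noise = (
                rng.normal(0, replicate_noise_sd, base.size)
                if replicate_noise_sd > 0 else 0.0
            )
            chip_id = f"{sample_label}_site{s+1}_rep{r+1}"
            cols[chip_id] = base + site_effects[s] + noise
            manifest.append(
                {
                    "chip_id": chip_id,
                    "sample_label": sample_label,
                    "site_label": f"site{s+1}",
                    "replicate": r + 1,
                }
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=base_sample.index), "log2"
    )
    return matrix, pd.DataFrame(manifest)
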