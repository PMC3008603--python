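"""Training and application of the two-metagene prognostic signature.

The algorithm is a supervised principal-components survival classifier:

1. **Screen** every probe with a multivariate Cox model containing the
   probe's (log2) expression plus age, grade and AJCC stage; a probe is
   selected when its Wald p-value is below ``alpha`` (default 0.002), so
   each signature gene is prognostic over and above the clinical
   covariates.
2. **Stabilize** the selection with leave-one-out cross-validation: the
   screen and the metagene model are refit with each sample held out, and
   probes selected in at least ``freq_threshold`` (default 20%) of rounds
   form the signature.  Each round also scores its held-out sample,
   yielding honest out-of-sample prognostic indices.
3. **Retrain on ranks**: expression over the signature probes is
   converted to within-sample percentile ranks (0.00-100.00), the ranks
   are mean-centered per probe, and the first two principal components
   ("metagenes") are extracted.  A two-covariate Cox fit on the metagene
   scores gives the weights beta1, beta2.
4. **Score**: the prognostic index of a sample is the metagene Cox
   linear predictor  beta1*s1 + beta2*s2,  with component signs fixed so
   that every beta is non-negative - a higher index always means a
   higher estimated hazard of recurrence.
5. **Classify**: the threshold is the 50th percentile of the LOOCV
   held-out training indices; an index at or above it is called high
   risk (ties go to high risk, the conservative side for treatment
   decisions).

Because scoring uses only within-sample ranks, the index of a trained
model is invariant to any strictly increasing per-sample transform of
the intensities - the robustness property that lets single chips from
different laboratories be scored without cohort renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from . import _coxkernels as _k
from .containers import ClinicalTable, ExpressionMatrix, SurvivalData
from .cox import fit_cox
from .exceptions import ConvergenceError, PrognosigError
from .model import DEFAULT_REPLICATE_SD, RiskPrediction, SignatureModel
from .preprocess import PreprocessState, percentile_rank_transform

DEFAULT_ALPHA = 0.002
DEFAULT_FREQ_THRESHOLD = 0.20
CLINICAL_COVARIATES = ("age_years", "grade", "stage")


# ---------------------------------------------------------------------------
# probe screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-probe multivariate Cox screen outcome."""

    table: pd.DataFrame  # coefficient, se, wald_p, converged, selected, reason
    alpha: float

    @property
    def selected_probes(self) -> list:
        return self.table.index[self.table["selected"]].tolist()

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


class _ScreenArrays:
    """Matrix/clinical data flattened to arrays for the JIT screen."""

    def __init__(self, matrix: ExpressionMatrix, clinical: ClinicalTable):
        if matrix.scale != "log2":
            raise ValueError("screening expects log2 expression")
        clinical = clinical.subset(matrix.sample_ids)
        clinical.require_complete()
        self.probe_ids = np.asarray(matrix.probe_ids, dtype=object)
        self.sample_ids = list(matrix.sample_ids)
        self.expr = np.ascontiguousarray(matrix.values.to_numpy(float).T)
        self.x_clin = clinical.data[list(CLINICAL_COVARIATES)].to_numpy(float)
        self.times = clinical.times
        self.events = clinical.events

    def subset(self, rows: np.ndarray) -> "_ScreenArrays":
        out = object.__new__(_ScreenArrays)
        out.probe_ids = self.probe_ids
        out.sample_ids = [self.sample_ids[i] for i in rows]
        out.expr = self.expr[rows]
        out.x_clin = self.x_clin[rows]
        out.times = self.times[rows]
        out.events = self.events[rows]
        return out


def _screen_arrays(arr: _ScreenArrays, alpha: float, ties: str) -> pd.DataFrame:
    n = len(arr.times)
    if arr.events.sum() < 10:
        raise PrognosigError(
            f"screen requires >= 10 events, got {int(arr.events.sum())}"
        )
    order = np.argsort(arr.times, kind="stable")
    expr = np.ascontiguousarray(arr.expr[order])
    x_clin = np.ascontiguousarray(arr.x_clin[order])
    t = np.ascontiguousarray(arr.times[order])
    e = np.ascontiguousarray(arr.events[order].astype(np.int64))

    variable = np.ptp(expr, axis=0) > 0
    clin_fit = fit_cox(
        SurvivalData(t, e, pd.DataFrame(x_clin, columns=CLINICAL_COVARIATES)),
        ties=ties,
    )
    betas, ses, codes, _ = _k.screen_kernel(
        np.ascontiguousarray(expr[:, variable]),
        x_clin,
        t,
        e,
        clin_fit.coefficients.to_numpy(),
        ties == "efron",
        100,
        1e-9,
    )
    G = len(arr.probe_ids)
    coef = np.full(G, np.nan)
    se = np.full(G, np.nan)
    p = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)
    reason = np.full(G, "", dtype=object)
    reason[~variable] = "constant expression"
    coef[variable] = betas
    se[variable] = ses
    conv_v = codes == 0
    converged[variable] = conv_v
    with np.errstate(invalid="ignore"):
        z = betas / ses
    p_v = 2.0 * stats.norm.sf(np.abs(z))
    p[variable] = np.where(conv_v, p_v, np.nan)
    idx = np.flatnonzero(variable)
    reason[idx[codes == 2]] = "separation / divergent fit"
    reason[idx[codes == 1]] = "max iterations reached"
    selected = converged & (p < alpha)
    return pd.DataFrame(
        {
            "coefficient": coef,
            "se": se,
            "wald_p": p,
            "converged": converged,
            "selected": selected,
            "reason": reason,
        },
        index=pd.Index(arr.probe_ids, name="probe_id"),
    )


def screen_probes(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = DEFAULT_ALPHA,
    ties: str = "efron",
) -> ScreenResult:
    """Multivariate Cox screen of every probe.

    Each probe gets its own fit with covariates {probe expression, age,
    grade, stage}; ``selected`` is True when the fit converged and the
    probe's two-sided Wald p is below ``alpha``.  Probes whose fit
    diverges (separation) are marked unselected with a reason; the screen
    never aborts on a degenerate probe.
    """
    table = _screen_arrays(_ScreenArrays(matrix, clinical), alpha, ties)
    return ScreenResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# metagene model fitting
# ---------------------------------------------------------------------------

def _rank_rows(expr: np.ndarray) -> np.ndarray:
    """Within-row percentile ranks, rows = samples, columns = probes."""
    n, m = expr.shape
    if m < 2:
        raise ValueError("need at least 2 probes to rank")
    r = stats.rankdata(expr, method="average", axis=1)
    out = 100.0 * (r - 1.0) / (m - 1.0)
    flat = np.ptp(expr, axis=1) == 0
    if flat.any():
        out[flat] = 50.0
    return out


def _fit_metagene(
    ranks: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_components: int = 2,
    ties: str = "efron",
    warn_degenerate: bool = True,
):
    """PCA on probe-centered ranks + Cox on the component scores.

    Returns ``(loadings, center, betas)`` with unit-norm loading rows and
    the sign convention beta >= 0 for every retained component.
    """
    center = ranks.mean(axis=0)
    rc = ranks - center
    u, s, vt = np.linalg.svd(rc, full_matrices=False)
    tol = max(s[0], 1.0) * 1e-8 if s.size else 0.0
    k = int(min(n_components, np.sum(s > tol), ranks.shape[1]))
    if k == 0:
        raise PrognosigError("rank matrix has no variance; cannot fit metagenes")
    if k < n_components and warn_degenerate:
        warnings.warn(
            f"only {k} non-degenerate principal component(s); "
            "falling back to a reduced metagene model",
            stacklevel=2,
        )
    loadings = vt[:k].copy()
    # deterministic orientation before the supervised sign fix
    for j in range(k):
        if loadings[j, np.argmax(np.abs(loadings[j]))] < 0:
            loadings[j] = -loadings[j]
    scores = rc @ loadings.T
    fit = fit_cox(
        SurvivalData(
            times, events,
            pd.DataFrame(scores, columns=[f"metagene_{j+1}" for j in range(k)]),
        ),
        ties=ties,
    )
    betas = fit.coefficients.to_numpy().copy()
    # flipping a component's sign flips its Cox coefficient exactly, so
    # the hazard-increasing orientation can be imposed after the fit
    for j in range(k):
        if betas[j] < 0:
            betas[j] = -betas[j]
            loadings[j] = -loadings[j]
    return loadings, center, betas


def train_metagene_model(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    probes,
    n_components: int = 2,
    ties: str = "efron",
    loocv_indices: pd.Series | None = None,
    preprocess: PreprocessState | None = None,
    replicate_sd: float | None = DEFAULT_REPLICATE_SD,
) -> SignatureModel:
    """Fit the rank-based two-metagene model on a chosen probe set.

    When ``loocv_indices`` (held-out prognostic indices from the LOOCV
    trainer) are supplied, the classification threshold is set to their
    50th percentile and the training index quantiles are stored.
    """
    probes = list(probes)
    if len(probes) < 3:
        raise ValueError("metagene model needs at least 3 probes")
    clinical = clinical.subset(matrix.sample_ids)
    expr = matrix.subset_probes(probes).values.to_numpy(float).T
    ranks = _rank_rows(expr)
    loadings, center, betas = _fit_metagene(
        ranks, clinical.times, clinical.events, n_components, ties
    )
    threshold = None
    quantiles: dict = {}
    if loocv_indices is not None:
        vals = np.asarray(loocv_indices.dropna(), dtype=float)
        threshold = float(np.percentile(vals, 50))
        quantiles = {
            float(q): float(np.percentile(vals, q))
            for q in (0, 5, 25, 50, 75, 95, 100)
        }
    return SignatureModel(
        probe_ids=probes,
        loadings=loadings,
        center=center,
        metagene_betas=betas,
        threshold=threshold,
        training_index_quantiles=quantiles,
        replicate_sd=replicate_sd,
        preprocess=preprocess or PreprocessState(retained_probe_ids=probes),
    )


# ---------------------------------------------------------------------------
# LOOCV stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Per-probe LOOCV selection frequencies and held-out indices."""

    selection_frequency: pd.Series    # per probe, in [0, 1]
    loocv_indices: pd.Series          # held-out prognostic index per sample
    freq_threshold: float
    n_rounds: int
    empty_rounds: int = 0

    @property
    def stable_probes(self) -> list:
        f = self.selection_frequency
        return f.index[f >= self.freq_threshold].tolist()


def loocv_stability_selection(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = DEFAULT_ALPHA,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    n_components: int = 2,
    ties: str = "efron",
) -> StabilityResult:
    """Leave-one-out stability selection with honest held-out scoring.

    Each round repeats the full training recipe - probe screen, then
    rank-based metagene fit on that round's selected probes - without the
    held-out sample, and scores the held-out sample with the round's own
    model.  Selection frequency is the fraction of rounds in which a
    probe passed the screen; a round selecting no probe is recorded as
    empty (its held-out index is missing) without changing denominators.
    """
    arr = _ScreenArrays(matrix, clinical)
    n = len(arr.sample_ids)
    if n < 20:
        raise PrognosigError(f"LOOCV needs >= 20 samples, got {n}")
    counts = np.zeros(len(arr.probe_ids))
    held_out = pd.Series(np.nan, index=pd.Index(arr.sample_ids, name="sample_id"))
    empty = 0
    all_rows = np.arange(n)
    for i in range(n):
        rows = np.delete(all_rows, i)
        sub = arr.subset(rows)
        table = _screen_arrays(sub, alpha, ties)
        sel = table["selected"].to_numpy()
        counts += sel
        sel_idx = np.flatnonzero(sel)
        if len(sel_idx) == 0:
            empty += 1
            continue
        ranks = _rank_rows(sub.expr[:, sel_idx])
        try:
            loadings, center, betas = _fit_metagene(
                ranks, sub.times, sub.events, n_components, ties,
                warn_degenerate=False,
            )
        except (ConvergenceError, PrognosigError):
            empty += 1
            continue
        x_held = arr.expr[i, sel_idx]
        r_held = percentile_rank_transform(x_held) if len(sel_idx) >= 2 else None
        if r_held is None:
            empty += 1
            continue
        s = loadings @ (r_held - center)
        held_out.iloc[i] = float(betas @ s)
    freq = pd.Series(
        counts / n, index=pd.Index(arr.probe_ids, name="probe_id"),
        name="selection_frequency",
    )
    return StabilityResult(
        selection_frequency=freq,
        loocv_indices=held_out,
        freq_threshold=freq_threshold,
        n_rounds=n,
        empty_rounds=empty,
    )


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def compute_prognostic_index(model: SignatureModel, x) -> float:
    """Prognostic index of one sample.

    ``x`` is the sample's expression over the signature probes (a Series
    indexed by probe id, or an array in model probe order).  The value is
    the metagene Cox linear predictor of the within-sample percentile
    ranks:  sum_j beta_j * <loadings_j, rank(x) - center>.
    """
    if isinstance(x, pd.Series):
        missing = [p for p in model.probe_ids if p not in x.index]
        if missing:
            raise PrognosigError(
                f"missing signature probes: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        x = x.loc[model.probe_ids].to_numpy(float)
    else:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != len(model.probe_ids):
            raise PrognosigError(
                f"expected {len(model.probe_ids)} signature values, "
                f"got {x.shape[0]}"
            )
    r = percentile_rank_transform(x)
    s = model.loadings @ (r - model.center)
    return float(model.metagene_betas @ s)


def prognostic_indices(model: SignatureModel, matrix: ExpressionMatrix) -> pd.Series:
    """Prognostic index for every sample of a matrix (any scale: the
    within-sample rank transform absorbs monotone rescaling)."""
    sub = matrix.subset_probes(model.probe_ids).values
    vals = {
        s: compute_prognostic_index(model, sub[s].to_numpy(float))
        for s in sub.columns
    }
    return pd.Series(vals, name="prognostic_index")


def classify(model: SignatureModel, x, sample_id=None) -> RiskPrediction:
    """Risk call for one sample: high risk iff index >= threshold.

    Every valid input yields a call - there is no unclassifiable zone -
    but calls whose 95% CI (index +/- 1.96 * calibrated replicate s.d.)
    straddles the threshold are annotated as borderline.
    """
    model.require_trained()
    index = compute_prognostic_index(model, x)
    sd = model.replicate_sd or 0.0
    ci = (index - 1.96 * sd, index + 1.96 * sd)
    return RiskPrediction(
        sample_id=sample_id,
        prognostic_index=index,
        ci95=ci,
        risk_group="high" if index >= model.threshold else "low",
        borderline=bool(ci[0] < model.threshold <= ci[1]),
    )


def classify_matrix(model: SignatureModel, matrix: ExpressionMatrix) -> list:
    sub = matrix.subset_probes(model.probe_ids).values
    return [
        classify(model, sub[s].to_numpy(float), sample_id=s) for s in sub.columns
    ]


# ---------------------------------------------------------------------------
# gene-set overlap significance
# ---------------------------------------------------------------------------

def signature_overlap_significance(
    set_a, set_b, universe_size: int, overlap: int | None = None
) -> float:
    """Upper-tail hypergeometric probability of a gene-set overlap.

    P(X >= k) where X counts the intersection of a random |A|-subset and
    a random |B|-subset of a universe of ``universe_size`` genes;
    computed by exact summation of the hypergeometric pmf in log space.
    With ``overlap=None`` k is the observed |A intersect B|.
    """
    a, b = len(set(set_a)), len(set(set_b))
    if a > universe_size or b > universe_size:
        raise ValueError("set larger than universe")
    if overlap is None:
        k = len(set(set_a) & set(set_b))
    else:
        k = int(overlap)
        if k > min(a, b):
            raise ValueError(
                f"overlap {k} exceeds min(|A|, |B|) = {min(a, b)}"
            )
    if k <= max(0, a + b - universe_size):
        return 1.0

    def lchoose(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    js = np.arange(k, min(a, b) + 1)
    log_terms = (
        lchoose(a, js) + lchoose(universe_size - a, b - js)
        - lchoose(universe_size, b)
    )
    return float(np.exp(logsumexp(log_terms)))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MetageneRiskClassifier(BaseEstimator):
    """Survival-supervised two-metagene risk classifier.

    scikit-learn-style estimator wrapping the full training recipe:
    multivariate Cox probe screen, LOOCV stability selection, and the
    rank-based two-metagene model with a median-index threshold.

    Parameters
    ----------
    alpha : float, default 0.002
        Per-probe Wald significance level of the multivariate screen.
    freq_threshold : float, default 0.20
        Minimum LOOCV selection frequency for a probe to enter the
        signature.
    n_components : int, default 2
        Number of metagenes (principal components of the signature
        ranks); falls back automatically when a component is degenerate.
    ties : {"efron", "breslow"}, default "efron"
        Tie handling of every Cox fit.
    replicate_sd : float, default 0.037
        Calibrated between-site s.d. of the index, used for prediction
        confidence intervals (recalibrate with the reproducibility
        module when multi-site replicates are available).

    Attributes
    ----------
    model_ : SignatureModel
        The trained, serializable signature.
    screen_ : ScreenResult
        Full-data screen (diagnostics; selection uses the LOOCV rounds).
    stability_ : StabilityResult
        Per-probe LOOCV selection frequencies and held-out indices.
    threshold_ : float
        50th percentile of the LOOCV held-out indices.

    Examples
    --------
    >>> clf = MetageneRiskClassifier()
    >>> clf.fit(expr_log2, clinical)            # doctest: +SKIP
    >>> clf.decision_function(expr_log2)[:3]    # doctest: +SKIP
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
        n_components: int = 2,
        ties: str = "efron",
        replicate_sd: float = DEFAULT_REPLICATE_SD,
    ):
        self.alpha = alpha
        self.freq_threshold = freq_threshold
        self.n_components = n_components
        self.ties = ties
        self.replicate_sd = replicate_sd

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _coerce_matrix(X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):  # samples x probes
            return ExpressionMatrix(X.T, "log2")
        raise TypeError(
            "X must be an ExpressionMatrix or a samples-by-probes DataFrame"
        )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y: ClinicalTable, preprocess: PreprocessState | None = None):
        """Train the signature.

        Parameters
        ----------
        X
            Preprocessed log2 expression: an :class:`ExpressionMatrix`
            or a samples-by-probes DataFrame.
        y
            :class:`ClinicalTable` with complete age/grade/stage and the
            survival endpoint for every training sample.
        preprocess
            Optional preprocessing state (retained probes, reference
            set) to embed in the trained model for deployment.
        """
        matrix = self._coerce_matrix(X)
        if not isinstance(y, ClinicalTable):
            raise TypeError("y must be a ClinicalTable")
        self.screen_ = screen_probes(matrix, y, self.alpha, self.ties)
        self.stability_ = loocv_stability_selection(
            matrix, y, self.alpha, self.freq_threshold, self.n_components,
            self.ties,
        )
        stable = self.stability_.stable_probes
        if len(stable) < 3:
            raise PrognosigError(
                f"only {len(stable)} probes stable at frequency >= "
                f"{self.freq_threshold}; cannot train a metagene model"
            )
        self.model_ = train_metagene_model(
            matrix,
            y,
            stable,
            n_components=self.n_components,
            ties=self.ties,
            loocv_indices=self.stability_.loocv_indices,
            preprocess=preprocess,
            replicate_sd=self.replicate_sd,
        )
        self.probe_ids_ = list(self.model_.probe_ids)
        self.threshold_ = self.model_.threshold
        self.loocv_indices_ = self.stability_.loocv_indices
        self.selection_frequency_ = self.stability_.selection_frequency
        return self

    def decision_function(self, X) -> np.ndarray:
        """Prognostic index per sample (higher = higher hazard)."""
        self._check_fitted()
        return prognostic_indices(self.model_, self._coerce_matrix(X)).to_numpy()

    def predict(self, X) -> np.ndarray:
        """1 for high risk (index >= threshold), 0 for low risk."""
        self._check_fitted()
        return (self.decision_function(X) >= self.model_.threshold).astype(int)

    def predict_risk(self, X) -> list:
        """Full :class:`RiskPrediction` records (index, CI, call)."""
        self._check_fitted()
        return classify_matrix(self.model_, self._coerce_matrix(X))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise PrognosigError(
                "MetageneRiskClassifier is not fitted; call fit first"
            )
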