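"""Empirical-Bayes error-model scoring and the post-filter stack.

Per-site sequencing/alignment error is modelled as a beta-binomial fitted to a
panel of normals; a case sample's alt count is scored as

    EBscore = -log10 P(X >= alt_count),  X ~ BetaBinomial(depth, alpha, beta).

High scores mean the observed support is implausible under the site's error
distribution.  A score cutoff is calibrated on labelled calls by maximising
Youden's J on the ROC curve, and candidate calls are then passed through the
full reason-coded filter stack (depth, germline-VAF, EBscore, read-position,
supporting-read and mappability rules; a stricter brain-only variant when no
matched normal exists).

The scoring here pools strands: the count tables carry no per-strand counts,
so the strand-aware decomposition of the original empirical-Bayes formulation
collapses to a single beta-binomial per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, psi
from sklearn import metrics

from .errors import (
    CalibrationError,
    InsufficientPanelError,
    InvalidInputError,
    InvalidParameterError,
)

#: Calibrated default EBscore cutoff: calls with score <= cutoff are rejected.
DEFAULT_EB_CUTOFF = 2.396

#: Terminal read window (bp) used by the upstream read-position artifact flag.
READ_END_WINDOW = 10


@dataclass
class BetaBinomialModel:
    """Fitted per-site error distribution from a panel of normals."""

    alpha: float
    beta: float
    n_panel: int
    pooled_error: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("alpha and beta must be positive")

    @property
    def mean_error(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def _betabinom_negll_grad(
    params: np.ndarray, alts: np.ndarray, depths: np.ndarray, binom_const: float
) -> tuple[float, np.ndarray]:
    """Negative beta-binomial log-likelihood and its gradient in (log a, log b).

    Written directly in gammaln/digamma form: orders of magnitude faster than
    going through the frozen-distribution machinery, and exact.
    """
    a, b = np.exp(params)
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return np.inf, np.zeros(2)
    ll = binom_const + np.sum(
        gammaln(alts + a)
        + gammaln(depths - alts + b)
        - gammaln(depths + a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )
    common = psi(a + b) - psi(depths + a + b)
    d_a = np.sum(psi(alts + a) - psi(a) + common) * a
    d_b = np.sum(psi(depths - alts + b) - psi(b) + common) * b
    if not np.isfinite(ll):
        return np.inf, np.zeros(2)
    return -ll, -np.array([d_a, d_b])


def fit_site_error_model(
    alt_counts,
    depths,
    pseudocount: float = 0.1,
) -> BetaBinomialModel:
    """Maximum-likelihood beta-binomial fit to panel alt counts at one site.

    Method-of-moments initialisation, then L-BFGS-B with analytic gradients
    on (log alpha, log beta).  An all-zero panel returns the floor model
    ``alpha = pseudocount, beta = mean depth`` so the error mean stays
    strictly positive.
    """
    alts = np.asarray(alt_counts, dtype=float)
    deps = np.asarray(depths, dtype=float)
    usable = deps > 0
    alts, deps = alts[usable], deps[usable]
    if len(deps) < 2:
        raise InsufficientPanelError("need >= 2 panel samples with positive depth")
    if (alts < 0).any() or (alts > deps).any():
        raise InvalidInputError("alt counts must lie in [0, depth]")

    pooled = float(alts.sum() / deps.sum())
    n_panel = int(len(deps))
    depth_mean = float(deps.mean())

    if alts.sum() == 0:
        return BetaBinomialModel(pseudocount, depth_mean, n_panel, 0.0)

    # method-of-moments start: match the pooled mean, guess concentration from
    # the spread of per-sample fractions
    fracs = alts / deps
    var = float(fracs.var())
    m = max(pooled, 1e-8)
    if var > m * (1 - m) / depth_mean:
        s = max(m * (1 - m) / var - 1.0, 2.0)
    else:
        s = 2.0 * depth_mean  # near-binomial: high concentration
    x0 = np.log([m * s, (1 - m) * s])

    binom_const = float(
        np.sum(gammaln(deps + 1) - gammaln(alts + 1) - gammaln(deps - alts + 1))
    )
    res = optimize.minimize(
        _betabinom_negll_grad,
        x0,
        args=(alts, deps, binom_const),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-20.0, 25.0)] * 2,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    a, b = np.exp(res.x)
    return BetaBinomialModel(float(a), float(b), n_panel, pooled)


def compute_eb_score(alt_count: int, depth: int, model: BetaBinomialModel) -> float:
    """-log10 of the beta-binomial upper tail P(X >= alt_count).

    Evaluated as a log-space sum of pmf terms, so deep tails at high depth do
    not underflow.  alt_count = 0 gives score 0 (tail probability 1).
    """
    if not 0 <= alt_count <= depth:
        raise InvalidInputError("alt_count must lie in [0, depth]")
    if alt_count == 0:
        return 0.0
    k = np.arange(alt_count, depth + 1)
    log_tail = logsumexp_stable(stats.betabinom.logpmf(k, depth, model.alpha, model.beta))
    score = -log_tail / math.log(10)
    return max(0.0, float(score))


def eb_score_curve(depth: int, model: BetaBinomialModel) -> np.ndarray:
    """EBscores for every alt count 0..depth at once.

    Uses a reverse cumulative log-sum-exp over the pmf, so the whole score
    curve costs one pmf evaluation.
    """
    logpmf = stats.betabinom.logpmf(np.arange(depth + 1), depth, model.alpha, model.beta)
    rev_tail = np.logaddexp.accumulate(logpmf[::-1])[::-1]  # log P(X >= k)
    scores = -rev_tail / math.log(10)
    scores[0] = 0.0
    return np.maximum(scores, 0.0)


def logsumexp_stable(logs: np.ndarray) -> float:
    m = np.max(logs)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(logs - m).sum()))


# ---------------------------------------------------------------------------
# ROC calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    roc_points: list[tuple[float, float]]  # (1 - specificity, sensitivity)
    auc: float
    cutoff: float
    youden: float


def calibrate_cutoff(scores, labels) -> CalibrationResult:
    """ROC over all distinct score thresholds; cutoff maximises Youden's J.

    A call is classified positive when its score >= threshold.  Among
    thresholds attaining the maximal sensitivity + specificity, the smallest
    is reported.  AUC is by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise CalibrationError("calibration needs at least one true and one false label")
    fpr, tpr, thresholds = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    j = tpr - fpr
    jmax = j.max()
    attaining = np.flatnonzero(j >= jmax - 1e-12)
    finite = [i for i in attaining if np.isfinite(thresholds[i])]
    idx = min(finite, key=lambda i: thresholds[i]) if finite else attaining[0]
    cutoff = float(thresholds[idx])
    return CalibrationResult(
        roc_points=list(zip(map(float, fpr), map(float, tpr))),
        auc=auc,
        cutoff=cutoff,
        youden=float(jmax),
    )


# ---------------------------------------------------------------------------
# Post-filter stack
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    """A candidate SNV with its score, artifact flags and filter verdict."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    eb_score: float = 0.0
    read_position_flag: bool = False
    mappability_flag: bool = False
    raw_alt_count: int | None = None  # pre-MQ/BQ-filter support, for retention
    filter_status: str = "PASS"
    reason_codes: set[str] = field(default_factory=set)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


#: Filter thresholds per mode: (minimum depth, germline-suspect VAF bound).
_MODE_THRESHOLDS = {"matched": (35, 0.40), "brain_only": (100, 0.20)}

#: FILTER field codes for serialisation.
REASON_VCF_CODES = {
    "min_depth": "MINDEPTH",
    "germline_vaf": "GERMVAF",
    "eb_score": "EBSCORE",
    "read_position": "READPOS",
    "min_support": "SUPPORT",
    "mappability": "MAPP",
}


def apply_post_filters(
    calls: list[VariantCall],
    mode: str = "matched",
    eb_cutoff: float = DEFAULT_EB_CUTOFF,
    use_eb: bool = True,
) -> list[VariantCall]:
    """Apply the reason-coded rejection stack in place and return the calls.

    matched mode: depth < 35 (min_depth), VAF >= 40% (germline_vaf),
    EBscore <= cutoff (eb_score), all supporting reads at read ends
    (read_position), < 3 quality alt reads or <= 50% of raw support retained
    (min_support), mappability flag (mappability).  brain_only mode tightens
    to depth < 100 and VAF >= 20%.  Reasons are recomputed from scratch, so
    the operation is idempotent and order-independent.
    """
    if mode not in _MODE_THRESHOLDS:
        raise InvalidParameterError(f"unknown filtering mode {mode!r}")
    if eb_cutoff < 0:
        raise InvalidParameterError("eb_cutoff must be >= 0")
    min_depth, vaf_bound = _MODE_THRESHOLDS[mode]
    for call in calls:
        reasons: set[str] = set()
        if call.depth < min_depth:
            reasons.add("min_depth")
        if call.vaf >= vaf_bound:
            reasons.add("germline_vaf")
        if use_eb and call.eb_score <= eb_cutoff:
            reasons.add("eb_score")
        if call.read_position_flag:
            reasons.add("read_position")
        if call.alt_count < 3 or (
            call.raw_alt_count is not None
            and call.raw_alt_count > 0
            and call.alt_count / call.raw_alt_count <= 0.5
        ):
            reasons.add("min_support")
        if call.mappability_flag:
            reasons.add("mappability")
        call.reason_codes = reasons
        call.filter_status = "FAIL" if reasons else "PASS"
    return calls
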