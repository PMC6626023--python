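"""Beta-binomial error model, EBscore, ROC calibration and the filter stack."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from somamosaic.ebfilter import (
    BetaBinomialModel,
    VariantCall,
    apply_post_filters,
    calibrate_cutoff,
    compute_eb_score,
    eb_score_curve,
    fit_site_error_model,
)
from somamosaic.errors import (
    CalibrationError,
    InsufficientPanelError,
    InvalidInputError,
    InvalidParameterError,
)

# ---------------------------------------------------------------------------
# Independent oracle: hand-written beta-binomial log-pmf and tail
# ---------------------------------------------------------------------------


def bb_logpmf_oracle(k, n, a, b):
    k, n = np.asarray(k, dtype=float), float(n)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def bb_tail_score_oracle(alt, depth, a, b):
    """-log10 P(X >= alt) by direct log-space summation."""
    if alt == 0:
        return 0.0
    logs = bb_logpmf_oracle(np.arange(alt, depth + 1), depth, a, b)
    m = logs.max()
    return max(0.0, -(m + math.log(np.exp(logs - m).sum())) / math.log(10))


def bb_loglik_oracle(alts, deps, a, b):
    return float(sum(bb_logpmf_oracle(k, n, a, b) for k, n in zip(alts, deps)))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


class TestFitSiteErrorModel:
    def test_fit_matches_grid_search_oracle(self):
        """MLE at least as good as a (mean, concentration) grid, mean ~ pooled."""
        alts = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        deps = [500] * 10
        model = fit_site_error_model(alts, deps)
        assert model.pooled_error == pytest.approx(0.001)
        assert model.mean_error == pytest.approx(0.001, rel=0.2)
        best_grid = -np.inf
        for m in np.geomspace(1e-4, 1e-2, 40):
            for s in np.geomspace(10, 1e6, 40):
                best_grid = max(best_grid, bb_loglik_oracle(alts, deps, m * s, (1 - m) * s))
        fitted_ll = bb_loglik_oracle(alts, deps, model.alpha, model.beta)
        assert fitted_ll >= best_grid - 1e-3

    def test_all_zero_panel_gives_positive_floor(self):
        model = fit_site_error_model([0] * 8, [600] * 8, pseudocount=0.1)
        assert model.mean_error > 0
        assert model.mean_error == pytest.approx(0.1 / (0.1 + 600))

    def test_insufficient_panel(self):
        with pytest.raises(InsufficientPanelError):
            fit_site_error_model([1], [500])
        with pytest.raises(InsufficientPanelError):
            fit_site_error_model([1, 2], [0, 0])

    def test_parameter_recovery_on_average(self):
        """Panels drawn from BetaBinomial(2, 1998): fitted error mean recovers
        the true 0.001 in aggregate over 100 seeds."""
        means = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            deps = np.maximum(1, r.poisson(600, 21))
            alts = r.binomial(deps, r.beta(2, 1998, 21))
            means.append(fit_site_error_model(alts, deps).mean_error)
        assert np.mean(means) == pytest.approx(0.001, rel=0.5)
        assert np.median(means) == pytest.approx(0.001, rel=0.5)


# ---------------------------------------------------------------------------
# EB score
# ---------------------------------------------------------------------------


class TestComputeEbScore:
    MODEL = BetaBinomialModel(alpha=1.0, beta=999.0, n_panel=21, pooled_error=0.001)

    def test_zero_alt_is_zero_score(self):
        assert compute_eb_score(0, 584, self.MODEL) == 0.0

    def test_tail_summation_oracle(self):
        got = compute_eb_score(5, 100, self.MODEL)
        want = bb_tail_score_oracle(5, 100, 1.0, 999.0)
        assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_in_alt_count(self):
        scores = [compute_eb_score(k, 100, self.MODEL) for k in range(101)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_curve_matches_scalar(self):
        curve = eb_score_curve(300, self.MODEL)
        for alt in (0, 1, 7, 50, 300):
            assert curve[alt] == pytest.approx(compute_eb_score(alt, 300, self.MODEL), abs=1e-9)

    def test_alt_exceeding_depth(self):
        with pytest.raises(InvalidInputError):
            compute_eb_score(101, 100, self.MODEL)

    def test_invalid_model(self):
        with pytest.raises(InvalidParameterError):
            BetaBinomialModel(0.0, 10.0, 5, 0.0)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


class TestCalibrateCutoff:
    def test_perfect_separation(self):
        res = calibrate_cutoff([5, 6, 7, 1, 2, 3], [True, True, True, False, False, False])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)
        assert 3 < res.cutoff <= 5

    def test_null_scores_give_half_auc(self):
        r = np.random.default_rng(0)
        scores = r.random(1000)
        labels = r.random(1000) < 0.5
        res = calibrate_cutoff(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_cutoff([1, 2, 3], [True, True, True])

    def test_cutoff_attains_exhaustive_max_youden(self):
        r = np.random.default_rng(3)
        scores = np.concatenate([r.normal(3, 1.5, 60), r.normal(0, 1.5, 60)])
        labels = np.array([True] * 60 + [False] * 60)
        res = calibrate_cutoff(scores, labels)
        # exhaustive scan over all distinct thresholds (>= classifies positive)
        best = max(
            ((scores[labels] >= t).mean() + (scores[~labels] < t).mean() - 1)
            for t in np.unique(scores)
        )
        got = (scores[labels] >= res.cutoff).mean() + (scores[~labels] < res.cutoff).mean() - 1
        assert got == pytest.approx(best, abs=1e-12)
        assert res.youden == pytest.approx(best, abs=1e-12)

    def test_synthetic_reenactment_auc_exceeds_0_9(self):
        """54 labelled calls (true mosaics vs error-only sites) scored against
        panel models separate cleanly: AUC > 0.9."""
        r = np.random.default_rng(7)
        scores, labels = [], []
        for i in range(54):
            true = i < 27
            deps = np.maximum(1, r.poisson(584, 21))
            alts = r.binomial(deps, 0.002)
            model = fit_site_error_model(alts, deps)
            depth = max(1, int(r.poisson(584)))
            p = 0.002 + (r.uniform(0.01, 0.05) if true else 0.0)
            scores.append(compute_eb_score(int(r.binomial(depth, p)), depth, model))
            labels.append(true)
        res = calibrate_cutoff(scores, labels)
        assert res.auc > 0.9


# ---------------------------------------------------------------------------
# Filter stack
# ---------------------------------------------------------------------------


def _call(depth=500, alt=10, score=5.0, **kw):
    return VariantCall("chrS", 1, "C", "T", depth, alt, eb_score=score, **kw)


class TestApplyPostFilters:
    def test_min_depth_rule(self):
        call = _call(depth=30, alt=6)
        apply_post_filters([call])
        assert call.filter_status == "FAIL" and call.reason_codes == {"min_depth"}

    def test_germline_vaf_boundary(self):
        fail = _call(depth=500, alt=225)  # vaf 0.45
        ok = _call(depth=1000, alt=399)  # vaf 0.399
        apply_post_filters([fail, ok])
        assert "germline_vaf" in fail.reason_codes
        assert "germline_vaf" not in ok.reason_codes

    def test_eb_score_boundary(self):
        at = _call(score=2.396)
        above = _call(score=2.40)
        apply_post_filters([at, above])
        assert at.reason_codes == {"eb_score"}
        assert above.filter_status == "PASS"

    def test_brain_only_mode_tightens(self):
        call = _call(depth=80, alt=4, score=5.0)
        apply_post_filters([call], mode="brain_only")
        assert "min_depth" in call.reason_codes
        vafcall = _call(depth=500, alt=120, score=5.0)  # vaf 0.24
        apply_post_filters([vafcall], mode="brain_only")
        assert "germline_vaf" in vafcall.reason_codes
        apply_post_filters([vafcall], mode="matched")
        assert vafcall.filter_status == "PASS"

    def test_support_and_flag_rules(self):
        weak = _call(alt=2)
        lost = _call(alt=5, raw_alt_count=11)  # retention 5/11 <= 50%
        pos = _call(read_position_flag=True)
        mapp = _call(mappability_flag=True)
        apply_post_filters([weak, lost, pos, mapp])
        assert "min_support" in weak.reason_codes
        assert "min_support" in lost.reason_codes
        assert pos.reason_codes == {"read_position"}
        assert mapp.reason_codes == {"mappability"}

    def test_idempotent(self):
        calls = [_call(depth=30, alt=2, score=1.0), _call()]
        apply_post_filters(calls)
        first = [(c.filter_status, set(c.reason_codes)) for c in calls]
        apply_post_filters(calls)
        assert [(c.filter_status, set(c.reason_codes)) for c in calls] == first

    def test_fail_iff_reasons(self):
        calls = [_call(depth=d, alt=a, score=s)
                 for d, a, s in [(30, 2, 1.0), (500, 10, 5.0), (500, 250, 9.0)]]
        apply_post_filters(calls)
        for c in calls:
            assert (c.filter_status == "FAIL") == bool(c.reason_codes)

    def test_unknown_mode(self):
        with pytest.raises(InvalidParameterError):
            apply_post_filters([_call()], mode="tumor")
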