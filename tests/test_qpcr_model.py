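"""Two-step qPCR model: link functions, joint likelihood, fitting."""

import dataclasses
import math

import numpy as np
import pytest

from ednaquant import (
    McmcConfig,
    QpcrParams,
    ReactionRecord,
    fit_qpcr,
    qpcr_ct_moments,
    qpcr_detection_prob,
    qpcr_log_likelihood,
)

PARAMS = QpcrParams(phi0=1.5, phi1=2.2, beta0=38.0, beta1=-3.32,
                    gamma0=-1.2, gamma1=-0.25)


class TestDetectionProb:
    @pytest.mark.parametrize(
        "phi0,phi1,c,expected",
        [(0.0, 2.0, 0.0, 0.5), (1.0, 2.0, -0.5, 0.5), (0.0, 2.0, 50.0, 1.0)],
    )
    def test_logistic_values(self, phi0, phi1, c, expected):
        p = QpcrParams(phi0, phi1, 38.0, -3.32, 0.0, 0.0)
        assert qpcr_detection_prob(p, c) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_concentration(self):
        grid = np.linspace(-4, 6, 50)
        probs = [qpcr_detection_prob(PARAMS, c) for c in grid]
        assert np.all(np.diff(probs) > 0)


class TestCtMoments:
    def test_mean_on_calibration_line(self):
        mean, _ = qpcr_ct_moments(PARAMS, 3.0)
        assert mean == pytest.approx(38.0 - 3.32 * 3, abs=1e-12)

    def test_sd_with_zero_slope_is_flat(self):
        p = QpcrParams(1.0, 1.0, 38.0, -3.32, -1.2, 0.0)
        for c in (-2.0, 0.0, 5.0):
            assert qpcr_ct_moments(p, c)[1] == pytest.approx(math.exp(-1.2), abs=1e-12)

    def test_sd_grows_as_concentration_falls(self):
        _, sd = qpcr_ct_moments(PARAMS, -1.0)
        assert sd == pytest.approx(math.exp(-0.95), abs=1e-9)

    def test_sd_is_log_linear(self):
        # exact identity at any two points: log sd differences scale with c
        (_, s1), (_, s2) = qpcr_ct_moments(PARAMS, 1.0), qpcr_ct_moments(PARAMS, 4.0)
        assert math.log(s2) - math.log(s1) == pytest.approx(
            PARAMS.gamma1 * 3.0, abs=1e-9
        )


def _rec(sid, stype, conc, rep, ct):
    return ReactionRecord("a", sid, stype, rep, ct=ct, nominal_conc=conc)


class TestLogLikelihood:
    def test_detected_well_at_the_ct_mode(self):
        c = 2.0
        mu, sd = qpcr_ct_moments(PARAMS, c)
        theta = qpcr_detection_prob(PARAMS, c)
        rec = _rec("S1", "standard", 100.0, 1, mu)
        ll = qpcr_log_likelihood(PARAMS, {}, [rec])
        expected = math.log(theta) - math.log(sd * math.sqrt(2 * math.pi))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_single_non_detect_at_half_probability(self):
        p = QpcrParams(0.0, 2.0, 38.0, -3.32, 0.0, 0.0)
        rec = _rec("E1", "unknown", None, 1, None)
        assert qpcr_log_likelihood(p, {"E1": 0.0}, [rec]) == pytest.approx(
            math.log(0.5), abs=1e-12
        )

    def test_decomposes_into_per_replicate_terms(self):
        recs = [
            _rec("E1", "unknown", None, 1, 35.2),
            _rec("E1", "unknown", None, 2, None),
            _rec("E1", "unknown", None, 3, 34.8),
        ]
        table = {"E1": 0.7}
        full = qpcr_log_likelihood(PARAMS, table, recs)
        parts = sum(qpcr_log_likelihood(PARAMS, table, [r]) for r in recs)
        assert full == pytest.approx(parts, rel=1e-12)
        # removing one replicate removes exactly its term
        without = qpcr_log_likelihood(PARAMS, table, recs[1:])
        only = qpcr_log_likelihood(PARAMS, table, recs[:1])
        assert full - without == pytest.approx(only, rel=1e-10)

    def test_continuous_mode_ignores_non_detects(self):
        det = _rec("E1", "unknown", None, 1, 35.2)
        miss = _rec("E1", "unknown", None, 2, None)
        both = qpcr_log_likelihood(PARAMS, {"E1": 0.7}, [det, miss],
                                   mode="continuous_only")
        assert both == pytest.approx(
            qpcr_log_likelihood(PARAMS, {"E1": 0.7}, [det], mode="continuous_only"),
            rel=1e-12,
        )

    def test_missing_sample_errors(self):
        with pytest.raises(ValueError, match="E9"):
            qpcr_log_likelihood(PARAMS, {}, [_rec("E9", "unknown", None, 1, 30.0)])


def _standard_plate():
    """Deterministic standards near the calibration line."""
    recs = []
    for i, e in enumerate(range(0, 6), 1):
        for k in (1, 2):
            ct = 38.0 - 3.32 * e + (0.1 if k == 1 else -0.1)
            recs.append(_rec(f"S{i}", "standard", 10.0 ** e, k, ct))
    return recs


class TestFit:
    def test_all_non_detect_unknown_pushed_below_threshold(self, fast_mcmc):
        recs = _standard_plate() + [
            _rec("E1", "unknown", None, k, None) for k in (1, 2, 3)
        ]
        post, ests = fit_qpcr(recs, mcmc_config=fast_mcmc, mode="two_step")
        est = next(e for e in ests if e.sample_id == "E1")
        assert 10.0 ** est.log10_c_median < 1e-3
        assert not est.is_detect

    def test_continuous_mode_flags_prior_driven_unknown(self, fast_mcmc):
        recs = _standard_plate() + [
            _rec("E1", "unknown", None, k, None) for k in (1, 2, 3)
        ]
        post, ests = fit_qpcr(recs, mcmc_config=fast_mcmc, mode="continuous_only")
        est = next(e for e in ests if e.sample_id == "E1")
        assert est.prior_driven
        # posterior is the prior: quantiles near Normal(0, 3)
        assert est.log10_c_median == pytest.approx(0.0, abs=0.4)
        assert est.ci_width == pytest.approx(2 * 1.96 * 3.0, abs=1.2)
        assert "phi0" not in post.draws

    def test_detected_unknown_recovers_its_concentration(self, fast_mcmc):
        cts = [38.0 - 3.32 * 1.5 + d for d in (-0.05, 0.0, 0.1)]
        recs = _standard_plate() + [
            _rec("E1", "unknown", None, k, ct) for k, ct in enumerate(cts, 1)
        ]
        _, ests = fit_qpcr(recs, mcmc_config=fast_mcmc)
        est = next(e for e in ests if e.sample_id == "E1")
        assert est.log10_c_median == pytest.approx(1.5, abs=0.25)
        assert est.ci_low < 1.5 < est.ci_high

    def test_all_non_detect_standards_rejected(self, fast_mcmc):
        recs = [
            _rec(f"S{i}", "standard", 10.0 ** -i, 1, None) for i in (1, 2, 3)
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_qpcr(recs, mcmc_config=fast_mcmc)

    def test_negative_controls_excluded_unless_asked(self, qpcr_plate, fast_mcmc):
        post, ests = fit_qpcr(qpcr_plate, mcmc_config=fast_mcmc)
        assert not any(e.sample_id.startswith("NTC") for e in ests)
        post, ests = fit_qpcr(qpcr_plate, mcmc_config=fast_mcmc,
                              include_controls=True)
        assert any(e.sample_id.startswith("NTC") for e in ests)

    def test_same_seed_identical_posterior(self, qpcr_plate, fast_mcmc):
        p1, _ = fit_qpcr(qpcr_plate, mcmc_config=fast_mcmc)
        p2, _ = fit_qpcr(qpcr_plate, mcmc_config=fast_mcmc)
        assert np.array_equal(p1.draws["beta1"], p2.draws["beta1"])
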