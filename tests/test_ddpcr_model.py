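"""Binomial/cloglog model: link functions, likelihood, diagnostics, fitting."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from ednaquant import (
    DdpcrParams,
    DropletRecord,
    McmcConfig,
    cloglog,
    ddpcr_log_likelihood,
    droplet_volume_from_intercept,
    efficiency_from_slope,
    fit_ddpcr,
    inverse_cloglog,
    poisson_estimate,
)

LN10 = math.log(10.0)


class TestCloglog:
    def test_zero_at_one_minus_exp_minus_one(self):
        assert cloglog(1.0 - math.exp(-1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_half(self):
        assert cloglog(0.5) == pytest.approx(math.log(math.log(2.0)), abs=1e-12)

    @pytest.mark.parametrize("p", [1e-6, 0.5, 1.0 - 1e-6])
    def test_round_trip_at_extremes(self, p):
        assert inverse_cloglog(cloglog(p)) == pytest.approx(p, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1.0 - 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_property(self, p):
        assert inverse_cloglog(cloglog(p)) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            cloglog(p)


class TestPoissonEstimate:
    def test_zero_positives_means_zero(self):
        assert poisson_estimate(0, 20000, 0.00085) == 0.0

    def test_inverse_of_forward_map(self):
        # W/U = 1 - exp(-0.85) with V = 0.00085 inverts to 1000 copies/uL
        u = 1_000_000
        w = round(u * (1.0 - math.exp(-0.85)))
        assert poisson_estimate(w, u, 0.00085) == pytest.approx(1000.0, rel=1e-5)

    def test_saturated_well_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            poisson_estimate(100, 100, 0.00085)


class TestDiagnostics:
    def test_droplet_volume_from_printed_intercepts(self):
        assert droplet_volume_from_intercept(-7.07) == pytest.approx(0.00085, abs=5e-6)
        assert droplet_volume_from_intercept(-7.54) == pytest.approx(0.00053, abs=5e-6)
        assert droplet_volume_from_intercept(0.0) == 1.0

    def test_efficiency_examples(self):
        assert efficiency_from_slope(LN10) == pytest.approx(1.0, abs=1e-12)
        assert efficiency_from_slope(2.3) == pytest.approx(0.9989, abs=1e-4)
        assert efficiency_from_slope(1.1513) == pytest.approx(0.5, abs=1e-4)


def _rec(w, u, sid="E1", stype="unknown", conc=None, rep=1):
    return DropletRecord("a", sid, stype, rep, w, u, nominal_conc=conc)


class TestLogLikelihood:
    def test_single_replicate_binomial_arithmetic(self):
        # omega = 0.5 needs kappa0 + kappa1*c = cloglog(0.5); U=2, W=1
        params = DdpcrParams(cloglog(0.5), 1.0)
        ll = ddpcr_log_likelihood(params, {"E1": 0.0}, [_rec(1, 2)])
        assert ll == pytest.approx(math.log(0.5), abs=1e-10)

    def test_two_identical_replicates_double_the_term(self):
        params = DdpcrParams(-7.0, LN10)
        recs = [_rec(9, 20000, rep=1), _rec(9, 20000, rep=2)]
        one = ddpcr_log_likelihood(params, {"E1": 0.0}, recs[:1])
        both = ddpcr_log_likelihood(params, {"E1": 0.0}, recs)
        assert both == pytest.approx(2 * one, rel=1e-12)

    def test_matches_per_replicate_scipy_sum(self):
        params = DdpcrParams(-7.07, 2.303)
        c = {"E1": 1.3}
        recs = [_rec(w, u, rep=i + 1)
                for i, (w, u) in enumerate([(40, 19000), (55, 21000), (47, 20000),
                                            (60, 20500), (38, 19500)])]
        omega = inverse_cloglog(params.kappa0 + params.kappa1 * c["E1"])
        expected = sum(
            binom.logpmf(r.positive_droplets, r.total_droplets, omega) for r in recs
        )
        assert ddpcr_log_likelihood(params, c, recs) == pytest.approx(
            expected, rel=1e-9
        )

    def test_unmatched_sample_errors(self):
        with pytest.raises(ValueError, match="E1"):
            ddpcr_log_likelihood(DdpcrParams(-7.0, 2.3), {}, [_rec(1, 100)])


class TestBinomialMleMatchesPoissonFormula:
    """With kappa fixed at (ln V, ln 10) the binomial MLE for a single well
    reproduces the vendor Poisson formula — the two formulations agree."""

    @pytest.mark.parametrize("w,u", [(1, 20000), (170, 18650), (9000, 20000)])
    def test_single_well_consistency(self, w, u):
        v = 0.00085
        params = DdpcrParams(math.log(v), LN10)
        rec = _rec(w, u)

        res = minimize_scalar(
            lambda c: -ddpcr_log_likelihood(params, {"E1": c}, [rec]),
            bounds=(-8.0, 8.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert 10.0 ** res.x == pytest.approx(poisson_estimate(w, u, v), rel=1e-6)


class TestFit:
    def test_recovers_kappa_and_unknowns(self, ddpcr_plate, fast_mcmc):
        post, ests = fit_ddpcr(ddpcr_plate, mcmc_config=fast_mcmc)
        k0 = np.median(post.flat("kappa0"))
        k1 = np.median(post.flat("kappa1"))
        assert k0 == pytest.approx(math.log(0.00085), abs=0.3)
        assert k1 == pytest.approx(LN10, abs=0.3)
        assert {e.sample_id for e in ests} == {"ENV1", "ENV2", "ENV3", "ENV4", "ABS1"}

    def test_all_zero_unknown_is_non_detect(self, ddpcr_plate, fast_mcmc):
        _, ests = fit_ddpcr(ddpcr_plate, mcmc_config=fast_mcmc)
        absent = next(e for e in ests if e.sample_id == "ABS1")
        assert 10.0 ** absent.log10_c_median < 1e-3
        assert not absent.is_detect

    def test_same_seed_reproduces_draws(self, ddpcr_plate, fast_mcmc):
        post1, _ = fit_ddpcr(ddpcr_plate, mcmc_config=fast_mcmc)
        post2, _ = fit_ddpcr(ddpcr_plate, mcmc_config=fast_mcmc)
        assert np.array_equal(post1.draws["kappa0"], post2.draws["kappa0"])

    def test_replicate_pooling_narrows_interval(self, ddpcr_params, fast_mcmc):
        """A sample fitted with 3 pooled replicates has a narrower CI than
        from any one of its replicates alone (information sharing)."""
        std = [
            _rec(w, 20000, sid=f"S{i}", stype="standard", conc=10.0 ** e)
            for i, (e, w) in enumerate([(-1, 2), (0, 17), (1, 170), (2, 1640)], 1)
        ]
        reps = [_rec(w, 20000, sid="E1", rep=k) for k, w in enumerate([14, 20, 17], 1)]
        fixed = dataclasses.replace(ddpcr_params)

        def width(records):
            _, ests = fit_ddpcr(
                records, mcmc_config=fast_mcmc, fixed_params=fixed
            )
            return ests[0].ci_width

        pooled = width(std + reps)
        singles = [width(std + [r]) for r in reps]
        assert all(pooled <= s + 0.02 for s in singles)

    def test_requires_two_distinct_standard_concentrations(self, fast_mcmc):
        recs = [
            _rec(10, 20000, sid="S1", stype="standard", conc=1.0, rep=k)
            for k in (1, 2)
        ]
        with pytest.raises(ValueError, match="distinct"):
            fit_ddpcr(recs, mcmc_config=fast_mcmc)

    def test_all_zero_standards_unidentifiable(self, fast_mcmc):
        recs = [
            _rec(0, 20000, sid=f"S{i}", stype="standard", conc=10.0 ** -i)
            for i in (3, 4)
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_ddpcr(recs, mcmc_config=fast_mcmc)

    def test_saturated_wells_excluded_with_warning(self, ddpcr_plate, fast_mcmc):
        recs = ddpcr_plate + [_rec(500, 500, sid="SAT")]
        with pytest.warns(UserWarning, match="saturated"):
            post, ests = fit_ddpcr(recs, mcmc_config=fast_mcmc)
        # the sample's only well was saturated, so it drops out of the fit
        assert "SAT" not in {e.sample_id for e in ests}
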