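"""Standalone logistic sensitivity analysis.

Fits the Bernoulli detection layer alone — Z ~ Bernoulli(theta) with
logit(theta) = phi0 + phi1 * log10 C — to binary outcomes from standards,
and compares fitted detection-probability curves between platforms
(e.g. ddPCR vs qPCR over the low-concentration range where they differ).
A qPCR well counts as detected when it reports a Ct; a ddPCR well when it
has at least ``droplet_threshold`` positive droplets (default one single
positive droplet).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DropletRecord, PosteriorResult, ReactionRecord
from .mcmc import McmcConfig, normal_logpdf, run_ensemble
from .qpcr_model import QpcrPriors

__all__ = [
    "DetectionCurve",
    "default_grid",
    "binary_outcomes",
    "fit_detection_logistic",
    "detection_curve",
    "c50",
    "detection_difference",
]


@dataclass(frozen=True)
class DetectionCurve:
    """Posterior detection-probability curve over a log10-concentration grid.

    ``theta`` holds posterior medians, ``theta_low``/``theta_high`` the
    2.5/97.5% bands.  ``theta_draws`` (draw x grid) is retained so that
    curve differences propagate paired posterior uncertainty.
    """

    assay_id: str
    method: str
    grid: np.ndarray
    theta: np.ndarray
    theta_low: np.ndarray
    theta_high: np.ndarray
    theta_draws: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 1 or not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        for arr in (self.theta, self.theta_low, self.theta_high):
            a = np.asarray(arr)
            if a.shape != g.shape:
                raise ValueError("curve arrays must match the grid")
            if np.any((a < 0) | (a > 1)):
                raise ValueError("detection probabilities must lie in [0, 1]")


def default_grid() -> np.ndarray:
    """log10 C from -3 to 2 in 0.1 steps — the range where ddPCR and qPCR
    sensitivities differ."""
    return np.round(np.arange(-3.0, 2.0 + 1e-9, 0.1), 10)


def binary_outcomes(records, droplet_threshold: int = 1):
    """(log10_c, z) pairs from standard records of either platform."""
    out = []
    for r in records:
        if r.sample_type != "standard":
            continue
        if isinstance(r, DropletRecord):
            z = int(r.positive_droplets >= droplet_threshold)
        else:
            z = int(r.detected)
        out.append((math.log10(r.nominal_conc), z))
    return out


def fit_detection_logistic(
    outcomes,
    priors: QpcrPriors | None = None,
    mcmc_config: McmcConfig | None = None,
) -> PosteriorResult:
    """Posterior for (phi0, phi1) from (log10_c, z) pairs.

    Reuses the two-step model's phi priors (one detection model, two entry
    points).  All-identical outcomes leave the slope prior-driven; a
    single distinct concentration is rejected as unidentifiable.
    """
    priors = priors or QpcrPriors()
    config = mcmc_config or McmcConfig()
    arr = np.asarray(list(outcomes), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("outcomes must be nonempty (log10_c, z) pairs")
    c, z = arr[:, 0], arr[:, 1]
    if len(np.unique(c)) < 2:
        raise ValueError("need outcomes at >= 2 distinct concentrations")
    if len(np.unique(z)) < 2:
        warnings.warn(
            "all outcomes identical: the slope is prior-driven", stacklevel=2
        )

    # Bernoulli outcomes at the same concentration collapse to binomial
    # counts, so the likelihood cost is per distinct concentration
    cu, inv = np.unique(c, return_inverse=True)
    n1 = np.bincount(inv, weights=z)
    n0 = np.bincount(inv, weights=1.0 - z)

    loc0, scl0 = priors.phi0
    loc1, scl1 = priors.phi1

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        p0, p1 = theta[:, 0], theta[:, 1]
        lp = normal_logpdf(p0, loc0, scl0) + np.where(
            p1 > 0, normal_logpdf(p1, loc1, scl1), -np.inf
        )
        x = p0[:, None] + p1[:, None] * cu
        ll = np.sum(
            n1 * (-np.logaddexp(0.0, -x)) + n0 * (-np.logaddexp(0.0, x)), axis=1
        )
        return np.where(np.isfinite(lp), lp + ll, -np.inf)

    return run_ensemble(
        log_prob,
        init_center=np.array([loc0, 1.0]),
        init_scale=np.array([0.5, 0.3]),
        param_names=["phi0", "phi1"],
        config=config,
        lower=np.array([-np.inf, 0.0]),
    )


def detection_curve(
    posterior: PosteriorResult,
    assay_id: str,
    method: str,
    grid: np.ndarray | None = None,
) -> DetectionCurve:
    """Evaluate the posterior detection curve on a grid."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    p0 = posterior.flat("phi0")[:, None]
    p1 = posterior.flat("phi1")[:, None]
    draws = 1.0 / (1.0 + np.exp(-(p0 + p1 * grid[None, :])))
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975], axis=0)
    return DetectionCurve(
        assay_id=assay_id, method=method, grid=grid,
        theta=med, theta_low=lo, theta_high=hi, theta_draws=draws,
    )


def c50(phi0: float, phi1: float) -> float:
    """Concentration (copies/μL) at which detection probability is 0.5:
    10^(-phi0/phi1)."""
    if phi1 == 0:
        raise ValueError("phi1 must be nonzero")
    return 10.0 ** (-phi0 / phi1)


def detection_difference(curve_a: DetectionCurve, curve_b: DetectionCurve):
    """Pointwise theta_a - theta_b with a credible band from paired draws.

    Positive values mean method a detects better.  Returns a dict of
    arrays {grid, delta, delta_low, delta_high}.
    """
    if curve_a.grid.shape != curve_b.grid.shape or not np.allclose(
        curve_a.grid, curve_b.grid
    ):
        raise ValueError("curves must share an identical grid")
    if curve_a.theta_draws is not None and curve_b.theta_draws is not None:
        na, nb = len(curve_a.theta_draws), len(curve_b.theta_draws)
        n = min(na, nb)
        diff = curve_a.theta_draws[:n] - curve_b.theta_draws[:n]
        lo, med, hi = np.quantile(diff, [0.025, 0.5, 0.975], axis=0)
    else:
        med = curve_a.theta - curve_b.theta
        lo = np.full_like(med, np.nan)
        hi = np.full_like(med, np.nan)
    return {
        "grid": curve_a.grid.copy(),
        "delta": med,
        "delta_low": lo,
        "delta_high": hi,
    }
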