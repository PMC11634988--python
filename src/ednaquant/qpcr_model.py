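"""Bayesian two-step (hurdle) quantification for qPCR.

The model couples a Bernoulli detection layer with a continuous Ct layer:

* Z ~ Bernoulli(theta), logit(theta) = phi0 + phi1 * log10 C
* Y | Z=1 ~ Normal(mu, sigma), mu = beta0 + beta1 * log10 C,
  sigma = exp(gamma0 + gamma1 * log10 C)

Standards (known C) and unknowns (latent log10 C, one per sample shared
by its technical replicates) are fit jointly, so non-detected replicates
still carry information about an unknown's concentration through the
detection layer.  ``mode="continuous_only"`` ablates the detection layer:
only detected Ct values enter, and samples with no detected replicate
fall back to their prior (flagged ``prior_driven``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data_model import (
    Assay,
    ConcentrationEstimate,
    PosteriorResult,
    QpcrParams,
    ReactionRecord,
    default_assay,
)
from .ddpcr_model import _record_log10_c, _split_records, _summarise
from .mcmc import McmcConfig, normal_logpdf, run_ensemble

__all__ = [
    "QpcrPriors",
    "qpcr_detection_prob",
    "qpcr_ct_moments",
    "qpcr_log_likelihood",
    "fit_qpcr",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

MODES = ("two_step", "continuous_only")


@dataclass(frozen=True)
class QpcrPriors:
    """Weakly informative priors centred on PCR physics.

    beta1 is centred at the perfect-efficiency dilution slope -3.32
    (= -1/log10(2)) and truncated negative; phi1 is truncated positive.
    Each (loc, scale) pair parameterises a Normal.
    """

    phi0: tuple[float, float] = (0.0, 5.0)
    phi1: tuple[float, float] = (1.0, 2.0)
    beta0: tuple[float, float] = (40.0, 10.0)
    beta1: tuple[float, float] = (-3.32, 2.0)
    gamma0: tuple[float, float] = (0.0, 2.0)
    gamma1: tuple[float, float] = (0.0, 1.0)
    log10_c: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        for name in ("phi0", "phi1", "beta0", "beta1", "gamma0", "gamma1", "log10_c"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"prior scale for {name} must be > 0")


def qpcr_detection_prob(params: QpcrParams, log10_c: float) -> float:
    """Detection probability theta = logit^-1(phi0 + phi1 * log10 C)."""
    return float(expit(params.phi0 + params.phi1 * log10_c))


def qpcr_ct_moments(params: QpcrParams, log10_c: float) -> tuple[float, float]:
    """Mean and SD of the Ct distribution at a given log10 concentration."""
    mean = params.beta0 + params.beta1 * log10_c
    sd = math.exp(params.gamma0 + params.gamma1 * log10_c)
    return float(mean), float(sd)


def qpcr_log_likelihood(
    params: QpcrParams,
    log10_c_by_sample: Mapping[str, float],
    records: Sequence[ReactionRecord],
    mode: str = "two_step",
) -> float:
    """Joint log-likelihood of a set of wells.

    Each well contributes Z*log(theta) + (1-Z)*log(1-theta) (two-step
    mode only) plus, when detected, the Normal log-density of its Ct.
    Standards use their nominal concentration, unknowns the supplied
    latent value.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    total = 0.0
    for rec in records:
        c = _record_log10_c(rec, log10_c_by_sample)
        if mode == "two_step":
            x = params.phi0 + params.phi1 * c
            # log sigmoid / log(1-sigmoid), stable in both tails
            total += -np.logaddexp(0.0, -x) if rec.detected else -np.logaddexp(0.0, x)
        if rec.detected:
            mu, sd = qpcr_ct_moments(params, c)
            total += -math.log(sd) - _LOG_SQRT_2PI - 0.5 * ((rec.ct - mu) / sd) ** 2
    return float(total)


_PARAM_NAMES = ("phi0", "phi1", "beta0", "beta1", "gamma0", "gamma1")
_CONT_NAMES = ("beta0", "beta1", "gamma0", "gamma1")


def fit_qpcr(
    records: Sequence[ReactionRecord],
    priors: QpcrPriors | None = None,
    mcmc_config: McmcConfig | None = None,
    mode: str = "two_step",
    assay: Assay | None = None,
    include_controls: bool = False,
    fixed_params: QpcrParams | None = None,
) -> tuple[PosteriorResult, list[ConcentrationEstimate]]:
    """Fit calibration parameters and latent unknown concentrations.

    Returns the posterior (phi/beta/gamma draws — phi omitted in
    ``continuous_only`` mode — plus one ``log10_C[<sample>]`` per
    unknown) and per-sample concentration summaries.  Convergence is
    reported, not enforced: check ``posterior.converged``.  With
    ``fixed_params`` only the latents are sampled.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    priors = priors or QpcrPriors()
    config = mcmc_config or McmcConfig()
    assay = assay or default_assay()

    standards, unknowns, sample_ids = _split_records(records, include_controls)
    detected_std_concs = {r.nominal_conc for r in standards if r.detected}
    if fixed_params is None:
        if len({r.nominal_conc for r in standards}) < 2:
            raise ValueError("need standards at >= 2 distinct concentrations")
        if len(detected_std_concs) < 2:
            raise ValueError(
                "standards detected at < 2 distinct concentrations: "
                "calibration curve unidentifiable"
            )

    fit_records = standards + unknowns
    z = np.array([r.detected for r in fit_records], dtype=float)
    ct = np.array([r.ct if r.detected else np.nan for r in fit_records])
    ct0 = np.where(np.isnan(ct), 0.0, ct)
    is_std = np.array([r.sample_type == "standard" for r in fit_records])
    c_known = np.array(
        [math.log10(r.nominal_conc) if s else 0.0 for r, s in zip(fit_records, is_std)]
    )
    idx = {sid: i for i, sid in enumerate(sample_ids)}
    latent_of = np.array(
        [-1 if s else idx[r.sample_id] for r, s in zip(fit_records, is_std)]
    )
    det = z.astype(bool)

    two_step = mode == "two_step"
    global_names = (
        () if fixed_params is not None else (_PARAM_NAMES if two_step else _CONT_NAMES)
    )
    n_glob = len(global_names)
    n_latent = len(sample_ids)
    loc = {n: getattr(priors, n)[0] for n in _PARAM_NAMES}
    scl = {n: getattr(priors, n)[1] for n in _PARAM_NAMES}

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        nw = theta.shape[0]
        if fixed_params is not None:
            phi0 = np.full(nw, fixed_params.phi0)
            phi1 = np.full(nw, fixed_params.phi1)
            beta0 = np.full(nw, fixed_params.beta0)
            beta1 = np.full(nw, fixed_params.beta1)
            gamma0 = np.full(nw, fixed_params.gamma0)
            gamma1 = np.full(nw, fixed_params.gamma1)
            lp = np.zeros(nw)
        else:
            cols = {n: theta[:, i] for i, n in enumerate(global_names)}
            beta0, beta1 = cols["beta0"], cols["beta1"]
            gamma0, gamma1 = cols["gamma0"], cols["gamma1"]
            lp = sum(normal_logpdf(cols[n], loc[n], scl[n]) for n in global_names)
            lp = np.where(beta1 < 0, lp, -np.inf)
            if two_step:
                phi0, phi1 = cols["phi0"], cols["phi1"]
                lp = np.where(phi1 > 0, lp, -np.inf)
            else:
                phi0 = phi1 = None
        latents = theta[:, n_glob:]
        if n_latent:
            lp = lp + normal_logpdf(latents, *priors.log10_c).sum(axis=1)
            c_rec = np.where(is_std, c_known, latents[:, latent_of])
        else:
            c_rec = np.broadcast_to(c_known, (nw, len(c_known)))
        ll = np.zeros(nw)
        if two_step or fixed_params is not None and mode == "two_step":
            x = phi0[:, None] + phi1[:, None] * c_rec
            ll += np.sum(
                z * (-np.logaddexp(0.0, -x)) + (1.0 - z) * (-np.logaddexp(0.0, x)),
                axis=1,
            )
        mu = beta0[:, None] + beta1[:, None] * c_rec
        log_sd = np.clip(gamma0[:, None] + gamma1[:, None] * c_rec, -20.0, 20.0)
        dens = -log_sd - _LOG_SQRT_2PI - 0.5 * ((ct0 - mu) / np.exp(log_sd)) ** 2
        ll += np.sum(dens[:, det], axis=1) if det.any() else 0.0
        return np.where(np.isfinite(lp), lp + ll, -np.inf)

    init_c, init_s, names, lower, upper = _initial_state(
        fit_records, is_std, det, ct, c_known, sample_ids, priors, global_names
    )
    posterior = run_ensemble(
        log_prob, init_c, init_s, names, config, lower=lower, upper=upper
    )
    method = "qpcr_two_step" if two_step else "qpcr_continuous"
    prior_driven = frozenset()
    if not two_step:
        has_detect = {sid: False for sid in sample_ids}
        for r, s in zip(fit_records, is_std):
            if not s and r.detected:
                has_detect[r.sample_id] = True
        prior_driven = frozenset(s for s, d in has_detect.items() if not d)
    estimates = _summarise(posterior, sample_ids, assay, method, prior_driven)
    return posterior, estimates


def _initial_state(fit_records, is_std, det, ct, c_known, sample_ids, priors,
                   global_names):
    # crude standards regression for a warm start
    xs = c_known[is_std & det]
    ys = ct[is_std & det]
    if len(np.unique(xs)) >= 2:
        b1, b0 = np.polyfit(xs, ys, 1)
        b1 = min(float(b1), -0.5)
        b0 = float(b0)
        resid_sd = float(np.std(ys - (b0 + b1 * xs))) or 0.3
    else:
        b0, b1, resid_sd = 38.0, -3.32, 0.3
    start = {
        "phi0": 1.0, "phi1": 1.5,
        "beta0": b0, "beta1": b1,
        "gamma0": math.log(max(resid_sd, 0.05)), "gamma1": 0.0,
    }
    jitter = {"phi0": 0.3, "phi1": 0.2, "beta0": 0.3, "beta1": 0.1,
              "gamma0": 0.2, "gamma1": 0.05}
    names = list(global_names)
    center = [start[n] for n in names]
    scale = [jitter[n] for n in names]
    lower = [0.0 if n == "phi1" else -np.inf for n in names]
    upper = [0.0 if n == "beta1" else np.inf for n in names]

    mean_ct: dict[str, list[float]] = {sid: [] for sid in sample_ids}
    for r, s in zip(fit_records, is_std):
        if not s and r.detected and r.sample_id in mean_ct:
            mean_ct[r.sample_id].append(r.ct)
    for sid in sample_ids:
        cts = mean_ct[sid]
        if cts:
            c0 = float(np.clip((np.mean(cts) - b0) / b1, -6.0, 8.0))
        else:
            c0 = -3.0
        names.append(f"log10_C[{sid}]")
        center.append(c0)
        scale.append(0.3)
        lower.append(-np.inf)
        upper.append(np.inf)
    return (np.array(center), np.array(scale), names,
            np.array(lower), np.array(upper))
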