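"""Bayesian binomial/cloglog concentration estimation for ddPCR.

Positive-droplet counts W out of U droplets follow
W ~ Binomial(U, omega) with cloglog(omega) = kappa0 + kappa1 * log10 C,
the Poisson-partitioning relationship linearised by the complementary
log-log link.  Standards of known concentration inform (kappa0, kappa1),
which in turn inform every unknown sample's latent log10 C; a sample's
technical replicates share one latent concentration, so information is
pooled across wells instead of averaging per-well Poisson estimates.

At 100% assay efficiency kappa0 = ln(droplet volume V) and
kappa1 = ln 10, which yields the two calibration diagnostics
:func:`droplet_volume_from_intercept` and :func:`efficiency_from_slope`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .data_model import (
    Assay,
    ConcentrationEstimate,
    DdpcrParams,
    DropletRecord,
    PosteriorResult,
    default_assay,
)
from .mcmc import McmcConfig, normal_logpdf, run_ensemble

__all__ = [
    "DdpcrPriors",
    "cloglog",
    "inverse_cloglog",
    "poisson_estimate",
    "ddpcr_log_likelihood",
    "fit_ddpcr",
    "droplet_volume_from_intercept",
    "efficiency_from_slope",
]

LN10 = math.log(10.0)


def cloglog(p: float) -> float:
    """Complementary log-log transform ln(-ln(1-p)) for p in (0,1)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"cloglog requires 0 < p < 1, got {p}")
    return math.log(-math.log1p(-p))


def inverse_cloglog(x: float) -> float:
    """Inverse transform 1 - exp(-exp(x)); maps the real line into (0,1)."""
    return -math.expm1(-math.exp(x))


def poisson_estimate(positive: int, total: int, droplet_volume_ul: float) -> float:
    """Per-well Poisson concentration C = -ln(1 - W/U) / V (copies/μL).

    This is the default formula of ddPCR vendor software, applied to a
    single well with no pooling across replicates.  Saturated wells
    (W = U) have no finite estimate.
    """
    if droplet_volume_ul <= 0:
        raise ValueError("droplet_volume_ul must be > 0")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    if positive == total:
        raise ValueError(
            f"all {total} droplets positive: saturated well, estimate is infinite"
        )
    if positive == 0:
        return 0.0
    return -math.log1p(-positive / total) / droplet_volume_ul


def droplet_volume_from_intercept(kappa0: float) -> float:
    """Implied droplet volume exp(kappa0) in μL (kappa0 = ln V at 100%
    efficiency)."""
    return math.exp(kappa0)


def efficiency_from_slope(kappa1: float) -> float:
    """Assay efficiency kappa1 / ln 10; equals 1 for a perfect assay."""
    return kappa1 / LN10


@dataclass(frozen=True)
class DdpcrPriors:
    """Weakly informative priors centred on the manufacturer droplet
    volume and perfect efficiency; kappa1 is truncated positive."""

    kappa0_loc: float = math.log(0.00085)
    kappa0_scale: float = 1.0
    kappa1_loc: float = LN10
    kappa1_scale: float = 0.5
    log10_c_loc: float = 0.0
    log10_c_scale: float = 3.0

    def __post_init__(self) -> None:
        if min(self.kappa0_scale, self.kappa1_scale, self.log10_c_scale) <= 0:
            raise ValueError("prior scales must be > 0")


def ddpcr_log_likelihood(
    params: DdpcrParams,
    log10_c_by_sample: Mapping[str, float],
    records: Sequence[DropletRecord],
) -> float:
    """Binomial log-likelihood of droplet counts given each sample's
    log10 concentration (standards use their nominal value).

    Replicates of a sample share one omega through its single latent
    concentration, so the total is a plain sum of per-well binomial
    log-pmfs.
    """
    total = 0.0
    for rec in records:
        c = _record_log10_c(rec, log10_c_by_sample)
        eta = params.kappa0 + params.kappa1 * c
        lam = math.exp(min(eta, 50.0))
        log_omega = math.log(-math.expm1(-lam)) if lam > 1e-300 else math.log(1e-300)
        w, u = rec.positive_droplets, rec.total_droplets
        total += (
            gammaln(u + 1) - gammaln(w + 1) - gammaln(u - w + 1)
            + (w * log_omega if w else 0.0)
            + (u - w) * (-lam)
        )
    return float(total)


def _record_log10_c(rec, table: Mapping[str, float]) -> float:
    if rec.sample_type == "standard":
        return math.log10(rec.nominal_conc)
    try:
        return table[rec.sample_id]
    except KeyError:
        raise ValueError(
            f"no latent/nominal concentration for sample {rec.sample_id!r}"
        ) from None


def _split_records(records, include_controls: bool):
    standards = [r for r in records if r.sample_type == "standard"]
    latent_types = {"unknown"} | ({"negative_control"} if include_controls else set())
    unknowns = [r for r in records if r.sample_type in latent_types]
    sample_ids = sorted({r.sample_id for r in unknowns})
    return standards, unknowns, sample_ids


def fit_ddpcr(
    records: Sequence[DropletRecord],
    priors: DdpcrPriors | None = None,
    mcmc_config: McmcConfig | None = None,
    assay: Assay | None = None,
    include_controls: bool = False,
    fixed_params: DdpcrParams | None = None,
) -> tuple[PosteriorResult, list[ConcentrationEstimate]]:
    """Jointly fit (kappa0, kappa1) and every unknown's latent log10 C.

    Standards anchor the calibration line; unknowns (and, with
    ``include_controls``, negative controls) each get one latent
    concentration shared by their replicates.  Saturated wells (W = U)
    are excluded with a warning.  With ``fixed_params`` the calibration
    is pinned and only the latents are sampled (degenerate-prior mode).
    Returns the posterior plus 2.5/50/97.5% summaries per sample.
    """
    priors = priors or DdpcrPriors()
    config = mcmc_config or McmcConfig()
    assay = assay or default_assay()

    saturated = [r for r in records if r.positive_droplets == r.total_droplets]
    if saturated:
        warnings.warn(
            f"excluding {len(saturated)} saturated well(s) (W = U) from the fit",
            stacklevel=2,
        )
        records = [r for r in records if r.positive_droplets < r.total_droplets]

    standards, unknowns, sample_ids = _split_records(records, include_controls)
    std_concs = {r.nominal_conc for r in standards}
    if fixed_params is None:
        if len(std_concs) < 2:
            raise ValueError("need standards at >= 2 distinct concentrations")
        if all(r.positive_droplets == 0 for r in standards):
            raise ValueError("all standards have zero positive droplets: "
                             "calibration line unidentifiable")

    fit_records = standards + unknowns
    w = np.array([r.positive_droplets for r in fit_records], dtype=float)
    u = np.array([r.total_droplets for r in fit_records], dtype=float)
    binom_const = float(np.sum(gammaln(u + 1) - gammaln(w + 1) - gammaln(u - w + 1)))
    is_std = np.array([r.sample_type == "standard" for r in fit_records])
    c_known = np.array(
        [math.log10(r.nominal_conc) if s else 0.0 for r, s in zip(fit_records, is_std)]
    )
    idx = {sid: i for i, sid in enumerate(sample_ids)}
    latent_of = np.array(
        [-1 if s else idx[r.sample_id] for r, s in zip(fit_records, is_std)]
    )

    n_latent = len(sample_ids)
    n_kappa = 0 if fixed_params is not None else 2
    ndim = n_kappa + n_latent
    if ndim == 0:
        raise ValueError("nothing to fit: no free parameters")

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        if fixed_params is not None:
            k0 = np.full(theta.shape[0], fixed_params.kappa0)
            k1 = np.full(theta.shape[0], fixed_params.kappa1)
            latents = theta
            lp = np.zeros(theta.shape[0])
        else:
            k0, k1 = theta[:, 0], theta[:, 1]
            latents = theta[:, 2:]
            lp = normal_logpdf(k0, priors.kappa0_loc, priors.kappa0_scale) + np.where(
                k1 > 0,
                normal_logpdf(k1, priors.kappa1_loc, priors.kappa1_scale),
                -np.inf,
            )
        if n_latent:
            lp = lp + normal_logpdf(
                latents, priors.log10_c_loc, priors.log10_c_scale
            ).sum(axis=1)
            c_rec = np.where(is_std, c_known, latents[:, latent_of])
        else:
            c_rec = np.broadcast_to(c_known, (theta.shape[0], len(c_known)))
        eta = k0[:, None] + k1[:, None] * c_rec
        lam = np.exp(np.clip(eta, -690.0, 50.0))
        log_omega = np.log(-np.expm1(-lam))
        ll = binom_const + np.sum(w * log_omega - (u - w) * lam, axis=1)
        return np.where(np.isfinite(lp), lp + ll, -np.inf)

    init_c, init_s, names = _initial_state(
        fit_records, is_std, sample_ids, priors, fixed_params, assay
    )
    lower = np.full(ndim, -np.inf)
    if fixed_params is None:
        lower[1] = 0.0
    posterior = run_ensemble(
        log_prob, init_c, init_s, names, config, lower=lower
    )
    estimates = _summarise(posterior, sample_ids, assay, "ddpcr")
    return posterior, estimates


def _initial_state(fit_records, is_std, sample_ids, priors, fixed_params, assay):
    names: list[str] = []
    center: list[float] = []
    scale: list[float] = []
    if fixed_params is None:
        k0, k1 = _kappa_least_squares(fit_records, is_std, priors)
        names += ["kappa0", "kappa1"]
        center += [k0, k1]
        scale += [0.1, 0.05]
    by_sample: dict[str, list] = {sid: [] for sid in sample_ids}
    for r, s in zip(fit_records, is_std):
        if not s and r.sample_id in by_sample:
            by_sample[r.sample_id].append(r)
    for sid in sample_ids:
        recs = by_sample[sid]
        w_tot = sum(r.positive_droplets for r in recs)
        u_tot = sum(r.total_droplets for r in recs)
        if w_tot == 0 or u_tot == 0:
            c0 = -4.0
        else:
            conc = poisson_estimate(min(w_tot, u_tot - 1), u_tot, assay.droplet_volume_ul)
            c0 = float(np.clip(math.log10(conc) if conc > 0 else -4.0, -6.0, 8.0))
        names.append(f"log10_C[{sid}]")
        center.append(c0)
        scale.append(0.3)
    return np.array(center), np.array(scale), names


def _kappa_least_squares(fit_records, is_std, priors):
    xs, ys = [], []
    for r, s in zip(fit_records, is_std):
        if s and 0 < r.positive_droplets < r.total_droplets:
            xs.append(math.log10(r.nominal_conc))
            ys.append(cloglog(r.positive_droplets / r.total_droplets))
    if len(set(xs)) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        if slope > 0.1:
            return float(intercept), float(slope)
    return priors.kappa0_loc, priors.kappa1_loc


def _summarise(
    posterior: PosteriorResult, sample_ids, assay: Assay, method: str,
    prior_driven: frozenset[str] = frozenset(),
) -> list[ConcentrationEstimate]:
    out = []
    for sid in sample_ids:
        d = posterior.flat(f"log10_C[{sid}]")
        lo, med, hi = np.quantile(d, [0.025, 0.5, 0.975])
        out.append(
            ConcentrationEstimate(
                sample_id=sid,
                assay_id=assay.assay_id,
                method=method,
                log10_c_median=float(med),
                log10_c_mean=float(d.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                prior_driven=sid in prior_driven,
            )
        )
    return out
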