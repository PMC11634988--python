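"""Ensemble-MCMC plumbing shared by the qPCR and ddPCR fitters.

Sampling uses an affine-invariant ensemble sampler (emcee) with a
vectorised log-posterior: one call evaluates the whole half-ensemble, so a
fit costs a few thousand small numpy broadcasts.  Walkers are treated as
chains for diagnostics (rhat / bulk ESS via arviz), which is the standard
way to feed ensemble output to convergence checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import arviz as az
import emcee
import numpy as np

from .data_model import PosteriorResult

__all__ = ["McmcConfig", "run_ensemble", "normal_logpdf"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def normal_logpdf(x, loc, scale):
    """Normal log-density without scipy dispatch overhead (hot path)."""
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI


@dataclass(frozen=True)
class McmcConfig:
    """Sampler budget.

    ``n_draws`` post-warmup iterations are kept per walker; every walker is
    reported as a chain, so the posterior always carries at least
    ``min_walkers`` chains of ``n_draws`` draws each.
    """

    n_draws: int = 3500
    n_warmup: int = 2000
    min_walkers: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.n_warmup < 0:
            raise ValueError("invalid sampler budget")

    def n_walkers(self, ndim: int) -> int:
        # emcee's stretch move needs > 2*ndim walkers; keep it even
        n = max(self.min_walkers, 2 * ndim + 2)
        return n + (n % 2)


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init_center: np.ndarray,
    init_scale: np.ndarray,
    param_names: Sequence[str],
    config: McmcConfig,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> PosteriorResult:
    """Sample a log-posterior and package draws + diagnostics.

    ``log_prob`` must accept an (n_walkers, ndim) array and return a length
    n_walkers vector.  Walkers start at ``init_center`` jittered by
    ``init_scale``, clipped strictly inside any (lower, upper) bounds so no
    walker starts at zero prior density.
    """
    ndim = len(init_center)
    if ndim != len(param_names):
        raise ValueError("param_names and init_center length mismatch")
    nwalkers = config.n_walkers(ndim)
    rng = np.random.default_rng(config.seed)

    p0 = init_center + init_scale * rng.standard_normal((nwalkers, ndim))
    if lower is not None:
        p0 = np.maximum(p0, lower + 1e-6)
    if upper is not None:
        p0 = np.minimum(p0, upper - 1e-6)

    lp0 = log_prob(p0)
    if not np.all(np.isfinite(lp0)):
        # fall back to the (valid) centre for walkers that jittered out
        bad = ~np.isfinite(lp0)
        p0[bad] = init_center + 1e-4 * init_scale * rng.standard_normal(
            (bad.sum(), ndim)
        )

    # differential-evolution moves mix far better than the default stretch
    # move once latent concentrations push ndim past ~20
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, config.n_warmup + config.n_draws, progress=False)

    chain = sampler.get_chain(discard=config.n_warmup)  # (draw, walker, dim)
    chain = np.moveaxis(chain, 0, 1)  # (walker=chain, draw, dim)

    draws = {name: chain[:, :, i].copy() for i, name in enumerate(param_names)}
    ds = az.convert_to_dataset({k: v for k, v in draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(ds)
        ess_ds = az.ess(ds)
    rhat = {k: float(rhat_ds[k].values) for k in param_names}
    ess = {k: float(ess_ds[k].values) for k in param_names}

    return PosteriorResult(
        draws=draws,
        n_chains=nwalkers,
        n_iter=config.n_draws,
        rhat=rhat,
        ess=ess,
        seed=config.seed,
    )
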