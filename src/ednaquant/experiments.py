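"""Simulation experiments: parameter recovery, matched-precision
comparisons, and grid-posterior oracles.

These are the computations behind the analysis scripts: generate plates
from known truth, fit them, and summarise how well the truth is
recovered or how the platforms/model variants compare.  Problem sizes
default to a single plate (8 standards x 3 replicates, 20 unknowns x 3
replicates), replicated over independent seeds.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import Assay, DdpcrParams, QpcrParams
from .ddpcr_model import ddpcr_log_likelihood, fit_ddpcr
from .mcmc import McmcConfig
from .qpcr_model import fit_qpcr, qpcr_log_likelihood
from .synthetic_data import (
    SimulationDesign,
    default_ddpcr_params,
    default_design,
    default_qpcr_params,
    simulate_ddpcr,
    simulate_qpcr,
)

__all__ = [
    "recovery_design",
    "run_parameter_recovery",
    "run_matched_precision",
    "grid_posterior",
    "tv_distance_to_grid",
]

#: qPCR plates in recovery experiments use a 52-cycle assay so the Normal
#: Ct layer is never censored and the fitted model matches the generator
RECOVERY_ASSAY = Assay("assay1", max_cycles=52)

QPCR_TRUTH = {
    "phi0": 1.5, "phi1": 2.2, "beta0": 38.0, "beta1": -3.32,
    "gamma0": -1.2, "gamma1": -0.25,
}
DDPCR_TRUTH = {"kappa0": math.log(0.00085), "kappa1": math.log(10.0)}


def recovery_design(platform: str, seed: int) -> SimulationDesign:
    """Default standards plus 20 unknowns, no blank samples.

    Unknown truths are drawn from the fitters' latent prior
    Normal(0, 3): credible-interval coverage is only a calibrated check
    when the simulation truth is drawn from the prior the model uses,
    so recovery experiments use the self-consistent distribution rather
    than the narrower field-like default.
    """
    return dataclasses.replace(
        default_design(platform, seed=seed),
        n_unknown_samples=20,
        unknown_mean=0.0,
        unknown_sd=3.0,
        n_absent_samples=0,
        n_negative_controls=0,
    )


def run_parameter_recovery(
    platform: str,
    n_datasets: int = 20,
    base_seed: int = 0,
    mcmc_config: McmcConfig | None = None,
) -> pd.DataFrame:
    """Simulate+fit ``n_datasets`` independent plates from known truth.

    Returns one row per (dataset, parameter) with the true value, the
    posterior 95% credible interval, and whether the truth is covered.
    """
    truth = QPCR_TRUTH if platform == "qpcr" else DDPCR_TRUTH
    rows = []
    for i in range(n_datasets):
        seed = base_seed + i
        design = recovery_design(platform, seed=seed)
        cfg = dataclasses.replace(mcmc_config or McmcConfig(), seed=seed)
        if platform == "qpcr":
            records = simulate_qpcr(default_qpcr_params(), design, RECOVERY_ASSAY)
            post, _ = fit_qpcr(records, mcmc_config=cfg, assay=RECOVERY_ASSAY)
        else:
            records = simulate_ddpcr(default_ddpcr_params(), design)
            post, _ = fit_ddpcr(records, mcmc_config=cfg)
        for name, true_val in truth.items():
            lo, hi = np.quantile(post.flat(name), [0.025, 0.975])
            rows.append(
                {
                    "platform": platform,
                    "dataset": i,
                    "parameter": name,
                    "truth": true_val,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "covered": bool(lo <= true_val <= hi),
                    "converged": post.converged,
                }
            )
    return pd.DataFrame(rows)


def _matched_truths(seed: int, n_low: int = 16, high: tuple[float, ...] = (4.0,) * 3):
    rng = np.random.default_rng(seed)
    low = rng.normal(-1.0, 1.5, n_low)
    return tuple(float(c) for c in low) + high


def run_matched_precision(
    n_seeds: int = 20,
    base_seed: int = 0,
    mcmc_config: McmcConfig | None = None,
) -> pd.DataFrame:
    """Matched qPCR/ddPCR simulation: same latent truths on both platforms.

    Per seed, simulates one qPCR and one ddPCR plate whose unknowns share
    identical true log10 concentrations (16 drawn from the eDNA-like
    Normal(-1, 1.5) plus three at 10^4 copies/μL), fits the ddPCR model
    and both qPCR model variants, and returns one row per (seed, sample)
    with the three CI widths and the true concentration.
    """
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        truths = _matched_truths(seed * 7919 + 13)
        cfg = dataclasses.replace(mcmc_config or McmcConfig(), seed=seed)

        def design(platform):
            return dataclasses.replace(
                default_design(platform, seed=seed),
                unknown_log10_concs=truths,
                n_absent_samples=0,
                n_negative_controls=0,
            )

        qrecs = simulate_qpcr(default_qpcr_params(), design("qpcr"), RECOVERY_ASSAY)
        drecs = simulate_ddpcr(default_ddpcr_params(), design("ddpcr"))
        _, est_d = fit_ddpcr(drecs, mcmc_config=cfg)
        _, est_two = fit_qpcr(qrecs, mcmc_config=cfg, assay=RECOVERY_ASSAY)
        _, est_cont = fit_qpcr(
            qrecs, mcmc_config=cfg, mode="continuous_only", assay=RECOVERY_ASSAY
        )
        by_id = lambda ests: {e.sample_id: e for e in ests}
        d, two, cont = by_id(est_d), by_id(est_two), by_id(est_cont)
        for j, c_true in enumerate(truths, start=1):
            sid = f"ENV{j}"
            rows.append(
                {
                    "seed": seed,
                    "sample_id": sid,
                    "true_log10_c": c_true,
                    "width_ddpcr": d[sid].ci_width,
                    "width_qpcr_two_step": two[sid].ci_width,
                    "width_qpcr_continuous": cont[sid].ci_width,
                }
            )
    return pd.DataFrame(rows)


def grid_posterior(
    log_lik: Callable[[float], float],
    grid: np.ndarray,
    prior_loc: float = 0.0,
    prior_scale: float = 3.0,
) -> np.ndarray:
    """Normalised posterior density of a single latent log10 C on a grid.

    Brute-force oracle: evaluates likelihood x Normal prior pointwise and
    normalises by the trapezoid rule.
    """
    grid = np.asarray(grid, dtype=float)
    log_post = np.array([log_lik(float(c)) for c in grid])
    log_post += -0.5 * ((grid - prior_loc) / prior_scale) ** 2
    log_post -= log_post.max()
    dens = np.exp(log_post)
    dens /= np.trapezoid(dens, grid)
    return dens


def tv_distance_to_grid(
    draws: np.ndarray, grid: np.ndarray, density: np.ndarray, n_bins: int = 16
) -> float:
    """Total-variation distance between sampled draws and a grid density.

    Bins are equal-probability intervals of the grid posterior (plus open
    tails), so every bin carries comparable mass and the statistic is not
    dominated by empty regions.
    """
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (density[1:] + density[:-1]) * np.diff(grid)
    )])
    cdf /= cdf[-1]
    probs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.interp(probs, cdf, grid)
    grid_mass = np.diff(np.concatenate([[0.0], probs, [1.0]]))
    counts = np.histogram(draws, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]
    emp_mass = counts / counts.sum()
    return 0.5 * float(np.abs(emp_mass - grid_mass).sum())
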