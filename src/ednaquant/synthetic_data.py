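"""Synthetic qPCR / ddPCR plate generator.

Simulates plates with exactly the generative structure the fitting models
assume: a Bernoulli(logit^-1) detection hurdle plus a Normal Ct layer for
qPCR, and Binomial droplet counts with a cloglog(log10 C) success
probability for ddPCR.  Serves as ground truth for parameter-recovery and
precision experiments in place of field plates.

Default designs mirror a typical standards/environmental layout: 10-fold
serial dilutions (10^-1..10^6 copies/μL for qPCR, 10^-3..10^4 for ddPCR),
technical triplicates, ~20,000 droplets per ddPCR reaction, environmental
unknowns at low concentration, plus truly absent samples and negative
controls that can never amplify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    Assay,
    DdpcrParams,
    DropletRecord,
    QpcrParams,
    ReactionRecord,
    default_assay,
)

__all__ = [
    "SimulationDesign",
    "default_design",
    "default_qpcr_params",
    "default_ddpcr_params",
    "simulate_qpcr",
    "simulate_ddpcr",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Layout of one simulated plate.

    ``unknown_log10_concs`` fixes the true latent log10 concentrations of
    the environmental samples; when None, ``n_unknown_samples`` of them are
    drawn from Normal(unknown_mean, unknown_sd) — centred near 10^-1
    copies/μL, typical of eDNA.  ``n_absent_samples`` adds true zeros
    (labelled "unknown"; they can never amplify), ``n_negative_controls``
    adds no-template controls.
    """

    standard_concs: tuple[float, ...]
    n_standard_reps: int = 3
    unknown_log10_concs: tuple[float, ...] | None = None
    n_unknown_samples: int = 30
    unknown_mean: float = -1.0
    unknown_sd: float = 1.5
    n_unknown_reps: int = 3
    n_absent_samples: int = 5
    n_negative_controls: int = 2
    droplets_mean: int = 20000
    droplets_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(c > 0 for c in self.standard_concs):
            raise ValueError("standard concentrations must be > 0")
        if self.n_standard_reps < 1 or self.n_unknown_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.droplets_mean < 1:
            raise ValueError("droplets_mean must be >= 1")
        if self.droplets_dispersion < 0:
            raise ValueError("droplets_dispersion must be >= 0")


def default_design(platform: str, seed: int = 0) -> SimulationDesign:
    """Standard plate layout for a platform.

    qPCR standards span 10^-1..10^6 copies/μL, ddPCR 10^-3..10^4 (eight
    decade steps each), in triplicate; 30 unknowns with log10 C ~
    Normal(-1, 1.5) and 5 absent samples.
    """
    if platform == "qpcr":
        concs = tuple(10.0 ** e for e in range(-1, 7))
    elif platform == "ddpcr":
        concs = tuple(10.0 ** e for e in range(-3, 5))
    else:
        raise ValueError(f"platform must be 'qpcr' or 'ddpcr', got {platform!r}")
    return SimulationDesign(standard_concs=concs, seed=seed)


def default_qpcr_params() -> QpcrParams:
    """Generator truth for qPCR fixtures (perfect-efficiency slope -3.32;
    Ct scatter grows as concentration falls)."""
    return QpcrParams(
        phi0=1.5, phi1=2.2, beta0=38.0, beta1=-3.32, gamma0=-1.2, gamma1=-0.25
    )


def default_ddpcr_params() -> DdpcrParams:
    """Generator truth for ddPCR fixtures: kappa0 = ln(0.00085 μL),
    kappa1 = ln 10 (100% efficiency)."""
    return DdpcrParams(kappa0=math.log(0.00085), kappa1=math.log(10.0))


def _sample_plan(design: SimulationDesign, rng: np.random.Generator):
    """Yield (sample_id, sample_type, nominal_conc, true_log10_c, n_reps).

    true_log10_c is -inf for absent samples and controls.
    """
    plan = []
    for i, conc in enumerate(design.standard_concs, start=1):
        plan.append((f"STD{i}", "standard", conc, math.log10(conc), design.n_standard_reps))
    if design.unknown_log10_concs is not None:
        truths = list(design.unknown_log10_concs)
    else:
        truths = list(
            rng.normal(design.unknown_mean, design.unknown_sd, design.n_unknown_samples)
        )
    for j, c in enumerate(truths, start=1):
        plan.append((f"ENV{j}", "unknown", None, float(c), design.n_unknown_reps))
    for j in range(1, design.n_absent_samples + 1):
        plan.append((f"ABS{j}", "unknown", None, -math.inf, design.n_unknown_reps))
    for j in range(1, design.n_negative_controls + 1):
        plan.append((f"NTC{j}", "negative_control", None, -math.inf, design.n_unknown_reps))
    return plan


def _check_finite(*values: float) -> None:
    if not all(math.isfinite(v) for v in values):
        raise ValueError("model parameters must be finite")


def simulate_qpcr(
    params: QpcrParams, design: SimulationDesign, assay: Assay | None = None
) -> list[ReactionRecord]:
    """Simulate a qPCR plate from the two-step (hurdle) model.

    Each well at log10 concentration c detects with probability
    logit^-1(phi0 + phi1*c); detected wells draw Ct from
    Normal(beta0 + beta1*c, exp(gamma0 + gamma1*c)) truncated to
    (0, max_cycles] — values censored past the cycle cap come back as
    non-detects, mimicking the instrument.  Deterministic given the
    design seed.
    """
    _check_finite(params.phi0, params.phi1, params.beta0, params.beta1,
                  params.gamma0, params.gamma1)
    assay = assay or default_assay()
    rng = np.random.default_rng(design.seed)
    records: list[ReactionRecord] = []
    for sample_id, stype, nominal, c, n_reps in _sample_plan(design, rng):
        for k in range(1, n_reps + 1):
            ct: float | None = None
            if math.isfinite(c):
                theta = 1.0 / (1.0 + math.exp(-(params.phi0 + params.phi1 * c)))
                if rng.random() < theta:
                    mu = params.beta0 + params.beta1 * c
                    sd = math.exp(params.gamma0 + params.gamma1 * c)
                    draw = rng.normal(mu, sd)
                    # instrument censoring: out-of-window wells report no Ct
                    if 0.0 < draw <= assay.max_cycles:
                        ct = float(draw)
            records.append(
                ReactionRecord(
                    assay_id=assay.assay_id,
                    sample_id=sample_id,
                    sample_type=stype,
                    nominal_conc=nominal,
                    replicate_index=k,
                    ct=ct,
                )
            )
    return records


def simulate_ddpcr(
    params: DdpcrParams, design: SimulationDesign, assay: Assay | None = None
) -> list[DropletRecord]:
    """Simulate a ddPCR plate from the binomial/cloglog model.

    Droplet totals U scatter around ``droplets_mean`` (Normal with CV
    ``droplets_dispersion``, floored at 1,000); positives are
    W ~ Binomial(U, omega) with omega = 1 - exp(-exp(kappa0 + kappa1*c)).
    Absent samples and controls have omega = 0.
    """
    _check_finite(params.kappa0, params.kappa1)
    assay = assay or default_assay()
    rng = np.random.default_rng(design.seed)
    records: list[DropletRecord] = []
    for sample_id, stype, nominal, c, n_reps in _sample_plan(design, rng):
        for k in range(1, n_reps + 1):
            u_draw = rng.normal(
                design.droplets_mean, design.droplets_dispersion * design.droplets_mean
            )
            u = max(1000, int(round(u_draw)))
            if math.isfinite(c):
                omega = -math.expm1(-math.exp(params.kappa0 + params.kappa1 * c))
                w = int(rng.binomial(u, omega))
            else:
                w = 0
            records.append(
                DropletRecord(
                    assay_id=assay.assay_id,
                    sample_id=sample_id,
                    sample_type=stype,
                    nominal_conc=nominal,
                    replicate_index=k,
                    positive_droplets=w,
                    total_droplets=u,
                )
            )
    return records
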