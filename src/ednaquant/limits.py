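"""Closed-form limits of detection and quantification.

The lower limit C_lt is set by the smallest detectable signal: one DNA
copy in the pooled qPCR reaction volume, or one positive droplet among
all droplets read in ddPCR,

    ln C_lt = cloglog(1/U) - ln V            (ddPCR)
    C_lt    = 1 / (n * reaction volume)      (qPCR)

and ddPCR additionally has an upper limit C_ut where only one droplet
remains negative:

    ln C_ut = cloglog((U-1)/U) - ln V.

Technical replicates pool: n replicates of U droplets behave as one pool
of n*U independent end-point partitions, so both ddPCR limits use the
pooled droplet total and all limits shrink as 1/n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .ddpcr_model import cloglog

__all__ = [
    "LimitResult",
    "qpcr_lower_limit",
    "ddpcr_lower_limit",
    "ddpcr_upper_limit",
    "limit_vs_replicates",
]


@dataclass(frozen=True)
class LimitResult:
    """Limits for one platform/replicate configuration (copies/μL).

    ``c_ut`` is None for qPCR, which has no upper limit.
    """

    platform: str
    n_replicates: int
    c_lt: float
    c_ut: float | None = None
    total_droplets: int | None = None
    droplet_volume_ul: float | None = None
    reaction_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.c_lt <= 0:
            raise ValueError("c_lt must be > 0")
        if self.c_ut is not None and self.c_ut < self.c_lt:
            raise ValueError("c_ut must be >= c_lt")


def qpcr_lower_limit(reaction_volume_ul: float = 20.0, n_replicates: int = 1) -> float:
    """One DNA copy across the pooled replicate volume: 1/(n*V_rxn).

    For a single 20 μL reaction this is 0.05 = 10^-1.3 copies/μL.
    """
    if reaction_volume_ul <= 0:
        raise ValueError("reaction_volume_ul must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return 1.0 / (n_replicates * reaction_volume_ul)


def _check_droplets(total_droplets: int, droplet_volume_ul: float) -> None:
    if total_droplets < 2:
        raise ValueError("total_droplets must be >= 2")
    if droplet_volume_ul <= 0:
        raise ValueError("droplet_volume_ul must be > 0")


def ddpcr_lower_limit(
    total_droplets: int = 20000,
    droplet_volume_ul: float = 0.00085,
    n_replicates: int = 1,
) -> float:
    """One positive droplet among the n*U droplets read (copies/μL)."""
    _check_droplets(total_droplets, droplet_volume_ul)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    u_total = n_replicates * total_droplets
    return math.exp(cloglog(1.0 / u_total) - math.log(droplet_volume_ul))


def ddpcr_upper_limit(
    total_droplets: int = 20000, droplet_volume_ul: float = 0.00085
) -> float:
    """All but one droplet positive (copies/μL)."""
    _check_droplets(total_droplets, droplet_volume_ul)
    u = total_droplets
    return math.exp(cloglog((u - 1) / u) - math.log(droplet_volume_ul))


def limit_vs_replicates(
    platform: str,
    n_max: int = 10,
    total_droplets: int = 20000,
    droplet_volume_ul: float = 0.00085,
    reaction_volume_ul: float = 20.0,
) -> pd.DataFrame:
    """Limits for n = 1..n_max replicates as a tidy table.

    c_lt decreases (and, for ddPCR, c_ut increases) as replicates pool.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rows = []
    for n in range(1, n_max + 1):
        if platform == "qpcr":
            res = LimitResult(
                platform="qpcr",
                n_replicates=n,
                c_lt=qpcr_lower_limit(reaction_volume_ul, n),
                reaction_volume_ul=reaction_volume_ul,
            )
        elif platform == "ddpcr":
            res = LimitResult(
                platform="ddpcr",
                n_replicates=n,
                c_lt=ddpcr_lower_limit(total_droplets, droplet_volume_ul, n),
                c_ut=ddpcr_upper_limit(n * total_droplets, droplet_volume_ul),
                total_droplets=total_droplets,
                droplet_volume_ul=droplet_volume_ul,
            )
        else:
            raise ValueError(f"platform must be 'qpcr' or 'ddpcr', got {platform!r}")
        rows.append(res)
    return pd.DataFrame(
        [
            {
                "platform": r.platform,
                "n_replicates": r.n_replicates,
                "c_lt": r.c_lt,
                "c_ut": float("nan") if r.c_ut is None else r.c_ut,
            }
            for r in rows
        ]
    )
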