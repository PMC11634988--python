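"""Domain types and tabular I/O for qPCR / ddPCR plate data.

Concentrations are expressed in copies per microlitre of reaction volume
throughout (20 μL reactions by default); latent concentrations are carried
on the log10 scale wherever they enter a model.

Plate exports are plain CSV with a header row.  Column order is free on
input (header-keyed) and fixed on output so that result tables diff cleanly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "ReactionRecord",
    "DropletRecord",
    "QpcrParams",
    "DdpcrParams",
    "ConcentrationEstimate",
    "PosteriorResult",
    "SchemaError",
    "ValidationError",
    "default_assay",
    "read_qpcr_table",
    "read_ddpcr_table",
    "write_estimates",
    "records_to_frame",
    "NON_DETECT_TOKENS",
    "NON_DETECT_OUT",
    "DETECT_THRESHOLD",
]

#: ct tokens accepted as "no amplification" on input; output always uses NON_DETECT_OUT
NON_DETECT_TOKENS = frozenset({"NA", "Undetermined", ""})
NON_DETECT_OUT = "NA"

#: posterior-median concentration below this (copies/μL) is reported as non-detect
DETECT_THRESHOLD = 1e-3

SAMPLE_TYPES = ("standard", "unknown", "negative_control")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant."""


@dataclass(frozen=True)
class Assay:
    """One PCR assay and the physical constants its models need.

    ``droplet_volume_ul`` is the ddPCR partition volume V (the BioRad
    nominal is ~0.00085 μL); ``max_cycles`` is the qPCR cycle cap that
    censors Ct values.
    """

    assay_id: str
    reaction_volume_ul: float = 20.0
    max_cycles: int = 45
    droplet_volume_ul: float = 0.00085

    def __post_init__(self) -> None:
        if self.reaction_volume_ul <= 0:
            raise ValueError("reaction_volume_ul must be > 0")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet_volume_ul must be > 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


def default_assay(assay_id: str = "assay1") -> Assay:
    """A 20 μL, 45-cycle assay with the nominal 0.00085 μL droplet volume."""
    return Assay(assay_id=assay_id)


@dataclass(frozen=True)
class ReactionRecord:
    """One qPCR well: its sample identity and Ct outcome.

    ``ct`` is None for a non-detect; the binary detection outcome Z is
    derived (``detected``) rather than stored.
    """

    assay_id: str
    sample_id: str
    sample_type: str
    replicate_index: int
    ct: float | None = None
    nominal_conc: float | None = None

    def __post_init__(self) -> None:
        _check_sample_fields(self)
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise ValidationError(f"ct must be finite and > 0, got {self.ct}")

    @property
    def detected(self) -> bool:
        """Z: True iff the well crossed threshold (ct recorded)."""
        return self.ct is not None


@dataclass(frozen=True)
class DropletRecord:
    """One ddPCR well: positive droplets W out of U total."""

    assay_id: str
    sample_id: str
    sample_type: str
    replicate_index: int
    positive_droplets: int
    total_droplets: int
    nominal_conc: float | None = None

    def __post_init__(self) -> None:
        _check_sample_fields(self)
        if self.total_droplets <= 0:
            raise ValidationError(
                f"total_droplets must be > 0, got {self.total_droplets}"
            )
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValidationError(
                f"need 0 <= positive_droplets <= total_droplets, got "
                f"W={self.positive_droplets}, U={self.total_droplets}"
            )

    @property
    def detected(self) -> bool:
        return self.positive_droplets >= 1


def _check_sample_fields(rec) -> None:
    if rec.sample_type not in SAMPLE_TYPES:
        raise ValidationError(
            f"sample_type must be one of {SAMPLE_TYPES}, got {rec.sample_type!r}"
        )
    if rec.sample_type == "standard":
        if rec.nominal_conc is None or not rec.nominal_conc > 0:
            raise ValidationError(
                f"standard sample {rec.sample_id!r} requires nominal_conc > 0"
            )
    if rec.replicate_index < 1:
        raise ValidationError("replicate_index must be >= 1")


@dataclass(frozen=True)
class QpcrParams:
    """Calibration parameters of the two-step qPCR model.

    (phi0, phi1): logistic intercept/slope of detection probability vs
    log10 C; (beta0, beta1): Ct mean intercept/slope (beta1 = -3.32 at
    100% amplification efficiency); (gamma0, gamma1): log-scale
    intercept/slope of the Ct standard deviation.
    """

    phi0: float
    phi1: float
    beta0: float
    beta1: float
    gamma0: float
    gamma1: float

    def __post_init__(self) -> None:
        vals = (self.phi0, self.phi1, self.beta0, self.beta1, self.gamma0, self.gamma1)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("qPCR parameters must be finite")
        if self.phi1 <= 0:
            raise ValueError("phi1 must be > 0 (detection increases with concentration)")
        if self.beta1 >= 0:
            raise ValueError("beta1 must be < 0 (Ct decreases with concentration)")


@dataclass(frozen=True)
class DdpcrParams:
    """cloglog intercept/slope (kappa0, kappa1).

    At 100% assay efficiency kappa0 = ln(droplet volume) and
    kappa1 = ln(10).
    """

    kappa0: float
    kappa1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kappa0) and math.isfinite(self.kappa1)):
            raise ValueError("ddPCR parameters must be finite")
        if self.kappa1 <= 0:
            raise ValueError("kappa1 must be > 0")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Posterior summary of one sample's latent log10 concentration."""

    sample_id: str
    assay_id: str
    method: str  # qpcr_two_step | qpcr_continuous | ddpcr
    log10_c_median: float
    log10_c_mean: float
    ci_low: float
    ci_high: float
    prior_driven: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.log10_c_median <= self.ci_high:
            raise ValueError("need ci_low <= median <= ci_high")

    @property
    def ci_width(self) -> float:
        """Quantification precision: 97.5% − 2.5% quantile, orders of magnitude."""
        return self.ci_high - self.ci_low

    @property
    def is_detect(self) -> bool:
        """Detect iff posterior median concentration >= 1e-3 copies/μL."""
        return 10.0 ** self.log10_c_median >= DETECT_THRESHOLD


@dataclass
class PosteriorResult:
    """MCMC draws plus convergence diagnostics.

    ``draws`` maps a parameter name to an array shaped (chain, draw);
    latent concentrations are named ``log10_C[<sample_id>]``.
    """

    draws: dict[str, np.ndarray]
    n_chains: int
    n_iter: int
    rhat: dict[str, float]
    ess: dict[str, float]
    seed: int

    @property
    def converged(self) -> bool:
        """True only when max rhat < 1.05 and min ess >= 400."""
        if not self.rhat:
            return False
        return max(self.rhat.values()) < 1.05 and min(self.ess.values()) >= 400

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        return np.asarray(self.draws[name]).reshape(-1)


# ---------------------------------------------------------------------------
# Tabular I/O

_QPCR_COLS = ["assay_id", "sample_id", "sample_type", "nominal_conc", "replicate", "ct"]
_DDPCR_COLS = [
    "assay_id",
    "sample_id",
    "sample_type",
    "nominal_conc",
    "replicate",
    "positive_droplets",
    "total_droplets",
]
_EST_COLS = [
    "sample_id",
    "assay_id",
    "method",
    "log10_c_median",
    "log10_c_mean",
    "ci_low",
    "ci_high",
    "ci_width",
    "is_detect",
]


def _read_table(source, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_conc(token: str, row: int) -> float | None:
    if token.strip() == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"row {row}: cannot parse nominal_conc {token!r}") from None


def read_qpcr_table(
    source: str | Path | IO[str], assay_registry: Mapping[str, Assay]
) -> list[ReactionRecord]:
    """Read a qPCR plate CSV into validated records.

    ``ct`` accepts numerals or the non-detect tokens "NA", "Undetermined",
    or empty.  A detected Ct above the assay's cycle cap is rejected.
    """
    df = _read_table(source, _QPCR_COLS)
    records: list[ReactionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        assay = _lookup_assay(assay_registry, row.assay_id, i)
        token = str(row.ct).strip()
        ct = None if token in NON_DETECT_TOKENS else _parse_ct(token, i)
        if ct is not None and ct > assay.max_cycles:
            raise ValidationError(
                f"row {i}: ct {ct} exceeds max_cycles {assay.max_cycles} "
                f"of assay {assay.assay_id!r}"
            )
        try:
            records.append(
                ReactionRecord(
                    assay_id=row.assay_id,
                    sample_id=row.sample_id,
                    sample_type=row.sample_type,
                    nominal_conc=_parse_conc(row.nominal_conc, i),
                    replicate_index=int(row.replicate),
                    ct=ct,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return records


def _parse_ct(token: str, row: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"row {row}: cannot parse ct {token!r}") from None


def _lookup_assay(registry: Mapping[str, Assay], assay_id: str, row: int) -> Assay:
    try:
        return registry[assay_id]
    except KeyError:
        raise ValidationError(f"row {row}: unknown assay_id {assay_id!r}") from None


def read_ddpcr_table(
    source: str | Path | IO[str], assay_registry: Mapping[str, Assay]
) -> list[DropletRecord]:
    """Read a ddPCR plate CSV (positive/total droplet counts) into records."""
    df = _read_table(source, _DDPCR_COLS)
    records: list[DropletRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        _lookup_assay(assay_registry, row.assay_id, i)
        try:
            records.append(
                DropletRecord(
                    assay_id=row.assay_id,
                    sample_id=row.sample_id,
                    sample_type=row.sample_type,
                    nominal_conc=_parse_conc(row.nominal_conc, i),
                    replicate_index=int(row.replicate),
                    positive_droplets=int(row.positive_droplets),
                    total_droplets=int(row.total_droplets),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return records


def records_to_frame(records: Iterable[ReactionRecord | DropletRecord]) -> pd.DataFrame:
    """Records to a plate-schema DataFrame (inverse of the readers)."""
    rows = []
    for r in records:
        base = {
            "assay_id": r.assay_id,
            "sample_id": r.sample_id,
            "sample_type": r.sample_type,
            "nominal_conc": "" if r.nominal_conc is None else repr(r.nominal_conc),
            "replicate": r.replicate_index,
        }
        if isinstance(r, ReactionRecord):
            base["ct"] = NON_DETECT_OUT if r.ct is None else repr(r.ct)
        else:
            base["positive_droplets"] = r.positive_droplets
            base["total_droplets"] = r.total_droplets
        rows.append(base)
    cols = _QPCR_COLS if rows and "ct" in rows[0] else _DDPCR_COLS
    return pd.DataFrame(rows, columns=cols)


def write_records(
    records: Sequence[ReactionRecord | DropletRecord], sink: str | Path | IO[str]
) -> None:
    """Write records back to the canonical plate CSV schema."""
    if not records:
        raise ValueError("no records to write")
    records_to_frame(records).to_csv(sink, index=False)


def write_estimates(
    estimates: Sequence[ConcentrationEstimate], sink: str | Path | IO[str]
) -> None:
    """Write the estimates table; (sample_id, method) must be unique."""
    if not estimates:
        raise ValueError("no estimates to write")
    keys = [(e.sample_id, e.method) for e in estimates]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (sample_id, method) pairs: {dupes}")
    df = pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "assay_id": e.assay_id,
                "method": e.method,
                "log10_c_median": f"{e.log10_c_median:.6f}",
                "log10_c_mean": f"{e.log10_c_mean:.6f}",
                "ci_low": f"{e.ci_low:.6f}",
                "ci_high": f"{e.ci_high:.6f}",
                "ci_width": f"{e.ci_width:.6f}",
                "is_detect": e.is_detect,
            }
            for e in estimates
        ],
        columns=_EST_COLS,
    )
    df.to_csv(sink, index=False)


def read_estimates(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read an estimates table written by :func:`write_estimates`."""
    df = _read_table(source, _EST_COLS)
    for col in ("log10_c_median", "log10_c_mean", "ci_low", "ci_high", "ci_width"):
        df[col] = df[col].astype(float)
    df["is_detect"] = df["is_detect"].map({"True": True, "False": False})
    return df
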