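"""Simulate one matched pair of qPCR and ddPCR plates.

Both plates share the same environmental truth: 30 unknown samples with
log10 C drawn from Normal(-1, 1.5), 5 truly absent samples, 2 no-template
controls, and decade-spaced standards in triplicate (10^-1..10^6
copies/μL for qPCR, 10^-3..10^4 for ddPCR).  Writes the plate CSVs that
the downstream fitting scripts consume.
"""

import dataclasses
from pathlib import Path

import numpy as np

from ednaquant import (
    default_ddpcr_params,
    default_design,
    default_qpcr_params,
    simulate_ddpcr,
    simulate_qpcr,
)
from ednaquant.data_model import write_records
from ednaquant.experiments import RECOVERY_ASSAY

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(SEED)
truths = tuple(float(c) for c in rng.normal(-1.0, 1.5, 30))

for platform, params, sim in [
    ("qpcr", default_qpcr_params(), simulate_qpcr),
    ("ddpcr", default_ddpcr_params(), simulate_ddpcr),
]:
    design = dataclasses.replace(
        default_design(platform, seed=SEED), unknown_log10_concs=truths
    )
    records = sim(params, design, RECOVERY_ASSAY)
    path = OUT / f"{platform}_plate.csv"
    write_records(records, path)
    n_detect = sum(r.detected for r in records)
    print(f"{platform}: {len(records)} wells ({n_detect} with signal) -> {path}")

np.savetxt(OUT / "true_log10_concs.csv", truths, header="true_log10_c", comments="")
print(f"true unknown concentrations -> {OUT / 'true_log10_concs.csv'}")
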