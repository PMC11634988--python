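import dataclasses

import pytest

from ednaquant import (
    Assay,
    McmcConfig,
    default_ddpcr_params,
    default_design,
    default_qpcr_params,
    simulate_ddpcr,
    simulate_qpcr,
)


@pytest.fixture
def qpcr_params():
    return default_qpcr_params()


@pytest.fixture
def ddpcr_params():
    return default_ddpcr_params()


@pytest.fixture
def fast_mcmc():
    """Reduced sampler budget for unit tests that do not assert convergence."""
    return McmcConfig(n_warmup=600, n_draws=1000, seed=0)


@pytest.fixture
def small_qpcr_design():
    """Compact plate: 5 standards x 2 reps, 4 unknowns x 3 reps."""
    base = default_design("qpcr", seed=11)
    return dataclasses.replace(
        base,
        standard_concs=tuple(10.0 ** e for e in range(0, 5)),
        n_standard_reps=2,
        n_unknown_samples=4,
        n_absent_samples=1,
        n_negative_controls=1,
    )


@pytest.fixture
def small_ddpcr_design():
    base = default_design("ddpcr", seed=12)
    return dataclasses.replace(
        base,
        standard_concs=tuple(10.0 ** e for e in range(-2, 3)),
        n_standard_reps=2,
        n_unknown_samples=4,
        n_absent_samples=1,
        n_negative_controls=1,
    )


@pytest.fixture
def qpcr_plate(qpcr_params, small_qpcr_design):
    return simulate_qpcr(qpcr_params, small_qpcr_design, Assay("assay1"))


@pytest.fixture
def ddpcr_plate(ddpcr_params, small_ddpcr_design):
    return simulate_ddpcr(ddpcr_params, small_ddpcr_design, Assay("assay1"))
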