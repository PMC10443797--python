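import logging

import pytest

from dmrescue.pipeline import RunConfig, analyze_cohort
from dmrescue.synthetic import SimParams, simulate_cohort

logging.getLogger("dmrescue").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def det_full_rescue():
    """Deterministic cohort in the complete-rescue limit."""
    params = SimParams(noise_sd_psi=0.0, rescue_fraction_expr=1.0,
                       rescue_fraction_splice=1.0, seed=1)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def det_null():
    """Deterministic cohort in the no-rescue (null) limit."""
    params = SimParams(noise_sd_psi=0.0, rescue_fraction_expr=0.0,
                       rescue_fraction_splice=0.0, seed=1)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def det_full_rescue_analyzed(det_full_rescue):
    counts, psi, meta, clin, truth = det_full_rescue
    res = analyze_cohort(counts, psi, meta, clin, RunConfig())
    return res, truth


@pytest.fixture(scope="session")
def det_null_analyzed(det_null):
    counts, psi, meta, clin, truth = det_null
    res = analyze_cohort(counts, psi, meta, clin, RunConfig())
    return res, truth


@pytest.fixture(scope="session")
def stochastic_cohort():
    """Small noisy cohort for pipeline-level checks."""
    params = SimParams(n_genes=400, n_events=150, seed=11)
    return simulate_cohort(params)
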