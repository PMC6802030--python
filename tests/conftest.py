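"""Shared fixtures.

The heavy session fixtures run the baseline equilibrium experiments once
(200 replicates, 500 burn-in + 5,000-window iterations at lag load 0.2,
mean mutation size 0.1, shape 1/2, infinite populations) and are shared by
the equilibrium-property tests.  The abiotic fixture's paired conflict runs
double as the baseline conflict results.
"""

from __future__ import annotations

import pytest

from fgmconflict import ScenarioConfig, run_replicates

BASELINE = dict(
    lag_load=0.2,
    omega=0.5,
    mean_size=0.1,
    n_iterations=5000,
    burn_in=500,
    n_replicates=200,
)


@pytest.fixture(scope="session")
def baseline_standard():
    """Standard-regime equilibrium results at baseline parameters."""
    return run_replicates(ScenarioConfig(regime="standard", seed=11, **BASELINE))


@pytest.fixture(scope="session")
def baseline_abiotic():
    """Abiotic-control equilibrium results at baseline parameters.

    ``.paired`` carries the paired conflict runs, which serve as the
    baseline conflict results throughout the suite.
    """
    return run_replicates(ScenarioConfig(regime="abiotic_matched", seed=13, **BASELINE))


@pytest.fixture(scope="session")
def baseline_conflict(baseline_abiotic):
    """Baseline two-party conflict results (paired runs of the control)."""
    return baseline_abiotic.paired


@pytest.fixture(scope="session")
def power_vs_f(baseline_conflict):
    """Aggregated power (mean, se) across relative selection strengths f."""
    out = {1.0: baseline_conflict.power()}
    # the slower party sets the adaptation timescale: use the automatic
    # burn-in 250 / min(omega) for the asymmetric cells
    params = {**BASELINE, "burn_in": None}
    for i, f in enumerate((2.0, 4.0)):
        res = run_replicates(
            ScenarioConfig(regime="conflict", f=f, seed=21 + i, **params)
        )
        out[f] = res.power()
    return out


@pytest.fixture(scope="session")
def power_vs_r(baseline_conflict):
    """Aggregated power (mean, se) across relative mutational inputs r."""
    out = {1: baseline_conflict.power()}
    for i, r in enumerate((2, 4)):
        res = run_replicates(
            ScenarioConfig(regime="conflict", r=r, seed=31 + i, **BASELINE)
        )
        out[r] = res.power()
    return out
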