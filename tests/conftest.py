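import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tumorboost as tb

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")

SCENARIO_SEED = 1
EVAL_SEED = 7


@pytest.fixture(scope="session")
def scenario():
    """Canonical change-point layout at kappa = 0.7, ~500 het SNPs per flank."""
    table, truth, specs = tb.table1_scenario(kappa=0.7, snps_per_region=500, seed=SCENARIO_SEED)
    return table, truth, specs


@pytest.fixture(scope="session")
def scenario_calls(scenario):
    table, _, _ = scenario
    return tb.genotype_normal(table.beta_n)


@pytest.fixture(scope="session")
def scenario_track(scenario, scenario_calls):
    table, _, _ = scenario
    return tb.normalize_pair(table, scenario_calls)


@pytest.fixture(scope="session")
def scenario_report(scenario, scenario_calls, scenario_track):
    """Full detectability report for every change point of the scenario."""
    table, _, specs = scenario
    tracks = {
        "tcn": table.tcn(),
        "dh_raw": tb.dh(table.beta_t),
        "dh_norm": tb.dh(scenario_track.beta_t_norm),
    }
    config = tb.EvalConfig(n_sampled=250, n_boot=100, bin_sizes=(1, 2, 4), seed=EVAL_SEED)
    import pandas as pd

    reports = []
    for spec in specs:
        rep, _ = tb.evaluate_changepoint(
            tracks, table.position, scenario_calls, spec, config, chromosome=table.chromosome
        )
        reports.append(rep)
    return pd.concat(reports, ignore_index=True)


@pytest.fixture
def diploid_pair():
    """A 10^4-SNP all-diploid pair with the default signal structure."""
    config = tb.SimConfig(n_snps=10_000, seed=42)
    return tb.simulate_pair(config)
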