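"""Shared fixtures: one default synthetic experiment reused across tests."""

import pytest

from amplimhc.genotyping import FilterConfig, filter_cascade
from amplimhc.simulate import SimulationConfig, primer_sets_for, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """Reference study conditions: 40 individuals, 3 loci x 20 alleles,
    depth 3000, 5% chimeras, 2% errors, 1% contamination, 6 replicated
    individuals."""
    cfg = SimulationConfig(seed=0)
    registry, truth, table = simulate_experiment(cfg)
    return cfg, registry, truth, table


@pytest.fixture(scope="session")
def default_calls(default_experiment):
    cfg, registry, truth, table = default_experiment
    psets = primer_sets_for(cfg.n_loci)
    fcfg = FilterConfig(
        max_expected_alleles={ps: 2 * len(loci) for ps, loci in psets.items()}
    )
    calls = filter_cascade(table, registry.founders, fcfg)
    return calls, psets, fcfg
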