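import pytest

from transqc.seqformats import Thresholds
from transqc import simgen


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def scenario() -> simgen.Scenario:
    """The standard benchmark: 50 genes, 150 derived transcripts,
    40 injected chimeras (10 per type), no mutations."""
    return simgen.build_scenario(
        n_genes=50, n_per_gene=3, chimeras_per_type=10, mutation_rate=0.0, seed=42
    )


@pytest.fixture(scope="session")
def scenario_hits(scenario):
    return simgen.truth_to_hits(scenario.truth, scenario.refs)
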