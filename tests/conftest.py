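import pytest

from amplitype.demux import SampleSheet, build_index_scheme
from amplitype.panel import load_panel
from amplitype.simulate import (SimConfig, simulate_cohort, simulate_reads,
                                simulate_references)


@pytest.fixture(scope="session")
def panel():
    return load_panel("malaria_host_v1")


@pytest.fixture(scope="session")
def scheme():
    return build_index_scheme(10, 10, seed=11)


@pytest.fixture(scope="session")
def refs(panel):
    return simulate_references(panel, seed=11)


@pytest.fixture(scope="session")
def small_pool(panel, scheme, refs):
    """An error-free 8-sample pool with uniform 60x depth, plus its truth."""
    config = SimConfig(n_samples=8, mean_depth=60.0, error_rate=0.0,
                       depth_multipliers={}, seed=11)
    truth = simulate_cohort(panel, config)
    sheet = SampleSheet.from_scheme(
        [t.sample_id for t in truth], scheme,
        sex={t.sample_id: t.sex for t in truth},
    )
    reads, log = simulate_reads(truth, refs, panel, config, sheet)
    return {
        "config": config,
        "truth": truth,
        "sheet": sheet,
        "reads": reads,
        "log": log,
    }
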