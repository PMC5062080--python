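import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refgap.assembly_core import Assembly, ScaffoldRecord
from refgap.synthetic_scenario import ScenarioConfig, generate_scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_assembly(seqs: dict[str, str], name: str = "test") -> Assembly:
    return Assembly(records=[ScaffoldRecord(i, s) for i, s in seqs.items()], name=name)


@pytest.fixture(scope="session")
def noise_free_scenario():
    """3 chromosomes x 200 kb, 5 excisions of 8-15 kb, no noise, no breaks."""
    return generate_scenario(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def broken_scenario():
    """No excisions, 4 breaks/chromosome, 3 markers/scaffold, some flips."""
    return generate_scenario(
        ScenarioConfig(
            seed=17, n_excised=0, n_scaffold_breaks=4,
            markers_per_scaffold=3, flip_fraction=0.4,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
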