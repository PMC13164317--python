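import json

import pytest
from hypothesis import HealthCheck, settings

from nbhub import SyntheticSpec, simulate
from nbhub import io as nbio

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def preset(tmp_path_factory):
    """The full synthetic study preset (seed 42) plus its ground-truth ledger."""
    outdir = tmp_path_factory.mktemp("preset")
    ledger = simulate(SyntheticSpec(seed=42), outdir)
    return outdir, ledger


@pytest.fixture(scope="session")
def preset_cores(preset):
    outdir, ledger = preset
    return {
        core: nbio.read_interaction_table(outdir / "cores" / f"{core}.txt", focal=core)
        for core in ledger["core_names"]
    }
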