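import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_map():
    from satdyn.delspace import Feature, PlasmidMap

    # the canonical miniature layout: origin, rep, marker, accessory
    return PlasmidMap(60, (
        Feature("oriV", "origin", (0, 6)),
        Feature("repA", "rep_gene", (10, 10)),
        Feature("aadA", "marker", (25, 5)),
        Feature("gfp", "accessory", (35, 15)),
    ))
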