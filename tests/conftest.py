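import numpy as np
import pytest
from hypothesis import settings

from lactoref import AnalytePanel, CowRecord, default_registry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def small_cohort(registry):
    """A tiny hand-built cohort: 6 healthy postpartum cows with full panels."""
    rng = np.random.default_rng(2024)
    cows, panels = [], []
    for i in range(6):
        cow = CowRecord(cow_id=f"c{i}", farm_id="1", parity=3, dfc=5,
                        rectal_temp=38.6, pregnant=False)
        values = {spec.name: float(max(rng.normal(spec.mean["postpartum"],
                                                  spec.sd["postpartum"]), 1e-6))
                  for spec in registry}
        values["PCV"] = min(values["PCV"], 0.6)
        values["BHB"] = 0.5
        values["Ca"] = 2.5
        cows.append(cow)
        panels.append(AnalytePanel(cow_id=cow.cow_id, values=values))
    return cows, panels
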