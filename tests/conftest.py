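import pytest

import nestsim as ns


@pytest.fixture(scope="session")
def run_scenario():
    """Run a built-in scenario by id, caching trajectories across tests."""
    cache = {}

    def _run(scenario_id: str) -> ns.Trajectory:
        if scenario_id not in cache:
            cache[scenario_id] = ns.simulate(ns.get_scenario(scenario_id))
        return cache[scenario_id]

    return _run


@pytest.fixture(scope="session")
def unmanaged_ref(run_scenario):
    """The 2010-2050 unmanaged reference run (constant at capacity)."""
    return run_scenario("unmanaged_2010")
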