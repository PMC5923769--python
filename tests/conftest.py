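import pytest

import frackrisk as fr


@pytest.fixture(scope="session")
def registry():
    return fr.load_default_registry()


@pytest.fixture(scope="session")
def drinking_run(registry):
    """One shared 1000-trial seeded drinking-water Monte Carlo run."""
    return fr.run_monte_carlo(
        registry,
        fr.drinking_water_scenario(),
        fr.drinking_water_factors(),
        n_trials=1000,
        seed=17,
    )
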