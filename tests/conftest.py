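import pytest

from amadorims import (
    DEFAULT_MRM_SPECIES,
    SimulationScenario,
    build_mrm_table,
    class_mass_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return class_mass_catalog()


@pytest.fixture(scope="session")
def default_method():
    return build_mrm_table()


@pytest.fixture()
def base_scenario():
    """Six-species scenario at mid-curve amounts with default noise."""
    return SimulationScenario(
        species_amounts={name: 5.0 for name in DEFAULT_MRM_SPECIES},
        seed=20180607,
    )


def integration_window(scenario, species):
    rt = scenario.retention_times[species]
    halfwidth = 8 * scenario.peak_width_sigma
    return (rt - halfwidth, rt + halfwidth)
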