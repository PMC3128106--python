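import pytest

from lipidgen import workbench_io
from lipidgen.phenotypes import HDL
from lipidgen.synthetic_cohorts import PopulationScenario, simulate_study


@pytest.fixture(scope="session")
def fixture_set():
    return workbench_io.load_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest single-SNP cohort with a real HDL-C effect, reused across tests."""
    scenario = PopulationScenario(
        population="EA",
        study="SIM",
        n_participants=2000,
        snp_freqs={"rsX": 0.3},
        snp_effects={("rsX", HDL): 2.0},
        medication_rate=0.1,
        medication_offset={"LDL-C": -30.0},
        seed=42,
    )
    return simulate_study(scenario)
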