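import pytest

from probefit.pipeline import run_scoring
from probefit.synth import LandscapeSpec, generate_landscape, worked_toy_target


@pytest.fixture(scope="session")
def kinase_fixture():
    return worked_toy_target("five_compound_kinase")


@pytest.fixture(scope="session")
def kinase_run(kinase_fixture):
    return run_scoring(list(kinase_fixture.measurements), kinase_fixture.smiles)


@pytest.fixture(scope="session")
def small_landscape():
    spec = LandscapeSpec(n_targets=8, n_compounds=40, seed=11)
    return generate_landscape(spec)


@pytest.fixture(scope="session")
def small_landscape_run(small_landscape):
    return run_scoring(small_landscape.to_measurements(), small_landscape.smiles)
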