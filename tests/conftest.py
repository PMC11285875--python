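import pytest

from rhodocarb import carbonate, synthetic, tracer


@pytest.fixture(scope="session")
def constants_15():
    return carbonate.compute_constants(15.0, 35.0)


@pytest.fixture(scope="session")
def constants_25():
    return carbonate.compute_constants(25.0, 35.0)


@pytest.fixture(scope="session")
def state_25(constants_25):
    return carbonate.solve_system(
        25.0, 35.0, constants_25, ph=8.1, total_alkalinity=2300e-6
    )


@pytest.fixture()
def noise_free_config():
    return synthetic.GeneratorConfig(
        seed=11, dry_mass_cv=0.0, biological_cv=0.0, noise_cv=0.0, o2_cv=0.0
    )


@pytest.fixture()
def noise_free_pervial(noise_free_config):
    table = synthetic.generate(noise_free_config)
    return tracer.process_table(table)
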