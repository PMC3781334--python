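import pytest
from hypothesis import HealthCheck, settings

import stressclust as sc

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return sc.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def design(config):
    return sc.generate_design(config)


@pytest.fixture(scope="session")
def dataset(config, design):
    """(matrix, truth) for the default synthetic study at seed 1."""
    return sc.generate_expression(config, design)


@pytest.fixture(scope="session")
def calls_table(dataset, design):
    matrix, _ = dataset
    return sc.call_comparisons(matrix, design)


@pytest.fixture(scope="session")
def labeled_groups(calls_table):
    profiles = sc.assign_profiles(calls_table)
    return sc.label_groups(profiles)


@pytest.fixture(scope="session")
def noiseless_dataset(design):
    cfg = sc.GeneratorConfig(seed=7, noise_cv=1e-12)
    return cfg, sc.generate_expression(cfg, sc.generate_design(cfg))


@pytest.fixture(scope="session")
def promoter_scan(config, dataset):
    """Promoters for the default study plus the scan of the built-in PWM set."""
    _, truth = dataset
    pwms = sc.default_pwms()
    promoters, tss = sc.generate_promoters(config, truth, pwms)
    tss_map = dict(zip(tss["name"], tss["start"]))
    scan = sc.scan_promoters(pwms, promoters, tss_map)
    return promoters, tss, scan, truth
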