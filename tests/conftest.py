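import pytest

import firestream as fs


@pytest.fixture(scope="session")
def null_config():
    """Default study conditions: 7 pre + 3 post years, no fire effect."""
    return fs.SyntheticConfig(seed=123)


@pytest.fixture(scope="session")
def null_site(null_config):
    return fs.simulate_site(null_config)


@pytest.fixture(scope="session")
def effect_config():
    """Study conditions with the injected season-specific fire effect."""
    return fs.SyntheticConfig(seed=123, delta_summer=0.5, delta_winter=-0.3)


@pytest.fixture(scope="session")
def effect_site(effect_config):
    return fs.simulate_site(effect_config)


@pytest.fixture(scope="session")
def effect_weekly(effect_site):
    series, windows = effect_site
    return fs.compute_weekly_series(series, windows)


def make_csv(path, rows, header="date,twater,tair,precip,pet"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def csv_factory(tmp_path):
    def factory(rows, name="site.csv", header="date,twater,tair,precip,pet"):
        return make_csv(tmp_path / name, rows, header)

    return factory
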