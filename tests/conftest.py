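import pandas as pd
import pytest

from umamikit.datasets import reference_species_means
from umamikit.io import load_config


@pytest.fixture(scope="session")
def config():
    """(ThresholdRegistry, PotencyConfig) from the packaged defaults."""
    return load_config()


@pytest.fixture(scope="session")
def registry(config):
    return config[0]


@pytest.fixture(scope="session")
def potency(config):
    return config[1]


@pytest.fixture(scope="session")
def reference_summary() -> pd.DataFrame:
    """Published species-mean concentrations for the six bivalve species."""
    return reference_species_means()


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
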