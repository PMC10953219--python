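import pathlib

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA_DIR = pathlib.Path(__file__).resolve().parents[1] / "src" / "genefam" / "data"


@pytest.fixture(scope="session")
def data_dir() -> pathlib.Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def family_data():
    """One synthetic family shared by recovery tests."""
    from genefam.synthetic import FamilyConfig, simulate_family

    return simulate_family(FamilyConfig(), seed=7)


@pytest.fixture(scope="session")
def survey_genes(data_dir):
    import pandas as pd

    return pd.read_csv(data_dir / "survey_genes.tsv", sep="\t",
                       dtype={"chromosome": str})


@pytest.fixture(scope="session")
def tandem_pairs(data_dir):
    import pandas as pd

    return pd.read_csv(data_dir / "survey_tandem_pairs.tsv", sep="\t",
                       dtype={"chr_1": str, "chr_2": str})


@pytest.fixture(scope="session")
def segmental_pairs(data_dir):
    import pandas as pd

    return pd.read_csv(data_dir / "survey_segmental_pairs.tsv", sep="\t",
                       dtype={"chr_1": str, "chr_2": str})
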