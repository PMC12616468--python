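import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from co2ionome.data_model import COLUMNS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_row(**overrides):
    """A valid database row; override any field."""
    row = {
        "entry_id": "e1",
        "source_id": "s1",
        "species": "Triticum aestivum",
        "cultivar": None,
        "genus": "Triticum",
        "family": "Poaceae",
        "pathway": "C3",
        "tissue_label": "grain",
        "nutrient": "Zn",
        "ambient_ppm": 380.0,
        "elevated_ppm": 550.0,
        "response_ambient": 30.0,
        "response_elevated": 27.0,
        "n_replicates": 4,
        "study_type": "FACE",
        "container": "field",
        "country": None,
        "year": 2015,
        "timepoint_rank": None,
        "is_primary_edible_part": True,
    }
    for name in COLUMNS:
        row.setdefault(name, None)
    row.update(overrides)
    return row


def rows_to_csv(rows, path):
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)
    return path


@pytest.fixture
def entry_row():
    return make_row


@pytest.fixture
def db_csv(tmp_path):
    def _write(rows, name="db.csv"):
        return rows_to_csv(rows, tmp_path / name)
    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
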