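from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from redsearch.alphabets import get_alphabet
from redsearch.db_index import build_index
from redsearch.simulate import generate_protein_db


@pytest.fixture(scope="session")
def murphy10():
    return get_alphabet("murphy.10")


@pytest.fixture(scope="session")
def all20():
    return get_alphabet("all.20")


@pytest.fixture(scope="session")
def small_index(murphy10):
    """A 20-record random database index shared across read-only tests."""
    recs = generate_protein_db(20, (40, 90), rng_seed=42)
    return build_index(recs, murphy10)


@pytest.fixture()
def scheme():
    from redsearch.align import default_scheme

    return default_scheme()
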