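import json
from pathlib import Path

import numpy as np
import pytest

from cytodiv import make_fixture_suite
from cytodiv.fcs import read_config

FIXTURE_SEED = 20


@pytest.fixture(scope="session")
def fixture_seed() -> int:
    return FIXTURE_SEED


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory) -> dict[str, Path]:
    """The canned synthetic scenarios, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def drifted_config(fixture_suite):
    return read_config(fixture_suite["drifted-with-beads"] / "config.yaml")


@pytest.fixture(scope="session")
def five_blob(fixture_suite) -> tuple[np.ndarray, int]:
    d = fixture_suite["five-blob"]
    pts = np.loadtxt(d / "points.csv", delimiter=",", skiprows=1)
    truth = json.loads((d / "truth.json").read_text())
    return pts, truth["k"]
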