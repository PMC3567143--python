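import numpy as np
import pytest

from foldspace.structures_io import DomainStructure
from foldspace.synthetic_data import build_template


@pytest.fixture(scope="session")
def helix_bundle_120() -> DomainStructure:
    coords, seq = build_template("helix_bundle", 120)
    return DomainStructure("hb120", "A", coords, seq)


@pytest.fixture(scope="session")
def sandwich_120() -> DomainStructure:
    coords, seq = build_template("sandwich_jellyroll_like", 120)
    return DomainStructure("sw120", "A", coords, seq)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_domain(id: str, coords: np.ndarray, sequence: str | None = None) -> DomainStructure:
    if sequence is None:
        sequence = "A" * len(coords)
    return DomainStructure(id, "A", coords, sequence)
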