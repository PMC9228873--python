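import numpy as np
import pytest

from motiondda import (
    AugmentationConfig,
    ProtocolSpec,
    build_database,
    emulate_protocol,
    split_database,
)
from motiondda.shapes import group_by_label


@pytest.fixture(scope="session")
def protocol_motions():
    """One full emulated collection protocol (540 motions)."""
    return emulate_protocol(ProtocolSpec(), rng_seed=0)


@pytest.fixture(scope="session")
def label_pools(protocol_motions):
    return group_by_label(protocol_motions)


@pytest.fixture(scope="session")
def xyr_database(label_pools):
    """A full code-XYR database with its split assigned."""
    db = build_database(label_pools, AugmentationConfig(database_code="XYR"), rng_seed=1)
    split_database(db, rng_seed=2)
    return db


@pytest.fixture(scope="session")
def source_motion(protocol_motions):
    """A single clean source motion (first Cube of the protocol)."""
    return next(m for m in protocol_motions if m.label == "Cube")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
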