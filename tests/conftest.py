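"""Shared fixtures: small equilibrated systems reused across test modules.

The expensive DPD runs (globule generation, reconstructions) are
session-scoped so each is paid for once.
"""

import numpy as np
import pytest

from chromdpd import (
    ReconstructionConfig,
    contacts_from_conformation,
    generate_globule,
    moore_curve,
    reconstruct,
)


@pytest.fixture(scope="session")
def moore3():
    return moore_curve(3)


@pytest.fixture(scope="session")
def globule64():
    return generate_globule(64, seed=11)


@pytest.fixture(scope="session")
def globule128():
    return generate_globule(128, seed=11)


@pytest.fixture(scope="session")
def globule512():
    """The desk-scale gold-standard globule used by the accuracy checks."""
    return generate_globule(512, seed=21)


@pytest.fixture(scope="session")
def contacts128(globule128):
    return contacts_from_conformation(globule128, 1.0)


@pytest.fixture(scope="session")
def recon128(globule128, contacts128):
    """One full-contact reconstruction of the 128-bead globule."""
    cfg = ReconstructionConfig(seed=7)
    return reconstruct(contacts128, chains=globule128.chains, cfg=cfg)[0]
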