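"""Shared fixtures.

The expensive objects (descriptor matrices, the trained default bundle, the
default 542-compound synthetic roster) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import pytest

from pmtscreen import features as ft
from pmtscreen import ml
from pmtscreen import simulate as sim
from pmtscreen.io import CompoundRecord


def record(smiles: str, cid: str = "X", origin: str = "undefined") -> CompoundRecord:
    return CompoundRecord(compound_id=cid, name=cid, smiles=smiles, origin=origin)


@pytest.fixture(scope="session")
def default_spec() -> sim.GeneratorSpec:
    return sim.GeneratorSpec(seed=42)


@pytest.fixture(scope="session")
def training_data(default_spec):
    """Default planted-rule training set (n=400, seed 42)."""
    return sim.generate_training_set(default_spec)


@pytest.fixture(scope="session")
def bundle(training_data):
    feats, labels, _ = training_data
    return ml.train(feats, labels, seed=42)


@pytest.fixture(scope="session")
def roster_and_truth(default_spec):
    return sim.generate_roster(default_spec)


@pytest.fixture(scope="session")
def roster_descriptors(roster_and_truth):
    roster, _ = roster_and_truth
    return ft.descriptor_matrix(roster)
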