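from __future__ import annotations

import random

import pytest

from pigmentnet import (
    InteractionRecord,
    SignallingNetwork,
    build_network,
    printed_paths_fixture,
    table1_fixture,
)


@pytest.fixture(scope="session")
def table1_net() -> SignallingNetwork:
    return table1_fixture()


@pytest.fixture(scope="session")
def printed_net() -> SignallingNetwork:
    return printed_paths_fixture()


def network_from_edges(edges: list[tuple[str, str]]) -> SignallingNetwork:
    """Build a SignallingNetwork from a bare edge list (type 'activates')."""
    records = [InteractionRecord(u, v, "activates") for u, v in edges]
    return build_network(records)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20150429)
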