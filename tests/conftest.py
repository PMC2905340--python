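from __future__ import annotations

import numpy as np
import pytest

from spermnet import InteractionRecord, SignalingNetwork

SIGNS = ("activation", "inhibition")


def random_network(rng: np.random.Generator, n_max: int = 15, *, allow_self_loops: bool = False) -> SignalingNetwork:
    """Random small digraph with random signed edges (for oracle checks)."""
    n = int(rng.integers(2, n_max + 1))
    labels = [f"n{i:02d}" for i in range(n)]
    density = rng.uniform(0.05, 0.4)
    edges = set()
    for s in labels:
        for t in labels:
            if s == t and not allow_self_loops:
                continue
            if rng.random() < density:
                edges.add((s, t, SIGNS[int(rng.integers(0, 2))]))
    return SignalingNetwork(frozenset(labels), frozenset(edges))


def random_records(rng: np.random.Generator, n_max: int = 12) -> list[InteractionRecord]:
    """Random record table (may contain duplicates and self-interactions)."""
    n = int(rng.integers(2, n_max + 1))
    labels = [f"n{i:02d}" for i in range(n)]
    m = int(rng.integers(1, 3 * n))
    recs = []
    for _ in range(m):
        s, t = rng.choice(labels, size=2, replace=True)
        recs.append(
            InteractionRecord(
                source=str(s),
                interaction=SIGNS[int(rng.integers(0, 2))],
                target=str(t),
                species="human" if rng.random() < 0.7 else "mouse",
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def triangle():
    """Directed 3-cycle a→b→c→a, all activation."""
    return SignalingNetwork(
        frozenset("abc"),
        frozenset({("a", "b", "activation"), ("b", "c", "activation"), ("c", "a", "activation")}),
        name="triangle",
    )


@pytest.fixture
def chain4():
    """Directed chain a→b→c→d."""
    return SignalingNetwork(
        frozenset("abcd"),
        frozenset({("a", "b", "activation"), ("b", "c", "activation"), ("c", "d", "activation")}),
        name="chain4",
    )


@pytest.fixture
def out_star():
    """Hub h pointing at six leaves."""
    leaves = [f"l{i}" for i in range(6)]
    return SignalingNetwork(
        frozenset(["h", *leaves]),
        frozenset(("h", leaf, "activation") for leaf in leaves),
        name="out_star",
    )
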