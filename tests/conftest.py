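"""Shared fixtures and independent oracles.

``naive_b_connected`` is the reference for B-connectivity: the fixed point of
"repeat: add the head of every hyperedge whose tail is fully contained in the
current set".  It shares no code with the traversal it checks.
"""

from __future__ import annotations

import random

import pytest

from brelax import DirectedHypergraph
from brelax.synthetic import GeneratorConfig, generate_random_hypergraph, toy_fixtures


def naive_b_connected(h: DirectedHypergraph, source) -> frozenset:
    """Fixed-point evaluation of the B-connectivity definition."""
    current = set(source)
    changed = True
    while changed:
        changed = False
        for tail, head in h.hyperedges.values():
            if tail <= current and not head <= current:
                current |= head
                changed = True
    return frozenset(current)


def random_order_b_visit(h: DirectedHypergraph, source, rng: random.Random):
    """B-visit with a randomly permuted processing order; used to show the
    output sets are independent of queue discipline."""
    count = {}
    connected = set(source)
    traversed = set()
    queue = list(source)
    while queue:
        v = queue.pop(rng.randrange(len(queue)))
        for eid in h.edges_with_tail_member(v):
            count[eid] = count.get(eid, 0) + 1
            if count[eid] == len(h.tail(eid)):
                head = h.head(eid)
                queue.extend(head - connected)
                connected |= head
                traversed.add(eid)
    restrictive = {e for e, c in count.items() if 0 < c < len(h.tail(e))}
    return frozenset(connected), frozenset(restrictive), frozenset(traversed)


@pytest.fixture(scope="session")
def toy1():
    return toy_fixtures()["toy1"][0]


@pytest.fixture(scope="session")
def relax3():
    return toy_fixtures()["relax3"][0]


def make_random_hypergraph(seed: int, n: int = 20, m: int = 30, **kw):
    cfg = GeneratorConfig(n_nodes=n, n_hyperedges=m, seed=seed, **kw)
    return generate_random_hypergraph(cfg)[0]


@pytest.fixture
def random_hypergraphs():
    """Factory yielding seeded random hypergraphs of a given size."""
    return make_random_hypergraph
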