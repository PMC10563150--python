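import numpy as np
import networkx as nx
import pytest

from phagepaths import fixtures
from phagepaths.flow_model import (
    SINK,
    SOURCE,
    ConstraintOrigin,
    InexactFlowNetwork,
    SubpathConstraint,
)

ST = "st"  # name of the split vertex in hand-built networks


def make_network(arc_specs, st_vertex=ST, alpha=1.2, covmax=10.0):
    """Build an InexactFlowNetwork from {(u, v): (lower, upper, we)}."""
    g = nx.DiGraph()
    g.add_node(SOURCE)
    g.add_node(SINK)
    for (u, v), (lo, hi, we) in arc_specs.items():
        g.add_edge(u, v, lower=lo, upper=hi, we=we, orients=("+", "+"), overlap=0)
    return InexactFlowNetwork(
        digraph=g, st_vertex=st_vertex, alpha=alpha, covmax=covmax
    )


def random_mifd_instance(rng):
    """A random layered DAG with 4-8 vertices, small intervals and 0-2
    random subpath constraints; None when the draw exceeds 12 arcs."""
    n_mid = int(rng.integers(2, 7))
    n_layers = int(rng.integers(1, min(3, n_mid) + 1))
    labels = [f"v{i}" for i in range(n_mid)]
    layer_of = {v: int(rng.integers(0, n_layers)) for v in labels}
    layers = [[v for v in labels if layer_of[v] == L] for L in range(n_layers)]
    layers = [l for l in layers if l]
    seq = [[SOURCE]] + layers + [[SINK]]
    arcs = []
    for i in range(len(seq) - 1):
        for u in seq[i]:
            for j in range(i + 1, len(seq)):
                for v in seq[j]:
                    if rng.random() < 0.5:
                        arcs.append((u, v))
    for i, layer in enumerate(seq[1:-1], start=1):
        for v in layer:
            if not any(a[1] == v for a in arcs):
                arcs.append((seq[i - 1][int(rng.integers(len(seq[i - 1])))], v))
            if not any(a[0] == v for a in arcs):
                arcs.append((v, seq[i + 1][int(rng.integers(len(seq[i + 1])))]))
    if not any(a[0] == SOURCE for a in arcs):
        arcs.append((SOURCE, seq[1][0]))
    if not any(a[1] == SINK for a in arcs):
        arcs.append((seq[-2][-1], SINK))
    arcs = sorted(set(arcs))
    if len(arcs) > 12:
        return None
    specs = {}
    for a in arcs:
        lo = int(rng.integers(0, 5))
        hi = lo + int(rng.integers(0, 5))
        specs[a] = (lo, hi, lo + rng.random() * (hi - lo))
    net = make_network(specs)
    g = net.digraph
    cons = []
    for _ in range(int(rng.integers(0, 3))):
        u, v = arcs[int(rng.integers(len(arcs)))]
        vu = ST if u == SOURCE else u
        vv = ST if v == SINK else v
        if rng.random() < 0.5:
            cons.append(SubpathConstraint((vu, vv), ConstraintOrigin.PAIR_EVIDENCE))
        else:
            succ = list(g.successors(v)) if v != SINK else []
            if succ:
                w = succ[int(rng.integers(len(succ)))]
                vw = ST if w == SINK else w
                cons.append(
                    SubpathConstraint((vu, v, vw), ConstraintOrigin.TRIPLE_EVIDENCE)
                )
    return net, cons


@pytest.fixture
def figure3():
    return fixtures.make_figure3_component()


@pytest.fixture
def mosaic2():
    return fixtures.make_mosaic_scenario(n_variants=2, seed=3)


@pytest.fixture
def case2_scenario():
    return fixtures.make_case2_scenario(seed=0)


def rotations_equal(a: str, b: str) -> bool:
    """String equality up to rotation (circular sequences)."""
    return len(a) == len(b) and a in b + b


def circular_equal(a: str, b: str) -> bool:
    """Equality up to rotation and reverse complement."""
    from phagepaths.genome_paths import reverse_complement

    return rotations_equal(a, b) or rotations_equal(reverse_complement(a), b)
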