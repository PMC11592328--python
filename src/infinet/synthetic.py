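"""Synthetic directed scale-free networks and enumerable micro-fixtures.

The generator emulates the gross structure of large curated interaction
networks: a sparse directed graph with a heavy-tailed in-degree
distribution (preferential attachment), a designated red activator panel of
modest-degree nodes whose Erdös shell contains the top hubs, a blue panel
drawn from mid-degree nodes, and
a configurable fraction of nodes with no path to the hub (its own small
component), mirroring the stable-white set observed on real networks.
Defaults follow the published network scale: mean out-degree 7.3
(292,191 links over 40,079 nodes) and a hub-unreachable fraction of 0.18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from infinet.network import (
    DirectedNetwork,
    NodePanel,
    TransitionMatrices,
    build_transition_matrices,
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic network generator."""

    N: int
    mean_out_degree: float = 7.3
    attachment_exponent: float = 1.0
    disconnected_fraction: float = 0.18
    n_red: int = 10
    n_blue: int = 6
    red_degree_factor: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("synthetic networks need at least 4 nodes")
        if not (0.0 <= self.disconnected_fraction < 1.0):
            raise ValueError("disconnected_fraction must be in [0, 1)")
        if self.mean_out_degree >= self.N:
            raise ValueError("mean degree must be smaller than the node count")
        if self.mean_out_degree <= 0:
            raise ValueError("mean degree must be positive")
        if self.n_red + self.n_blue >= self.N:
            raise ValueError("panel sizes must leave variable nodes")


def _pa_edges(
    rng: np.random.Generator,
    n: int,
    n_edges: int,
    gamma: float,
    offset: int,
) -> list[tuple[int, int]]:
    """Directed preferential-attachment component on nodes offset..offset+n-1.

    New nodes point at existing nodes with probability proportional to
    (in-degree + 1)**gamma; a 3-node seed cycle keeps the component weakly
    connected and free of dangling seed nodes.  The edge count is topped up
    with preferential extra links to approach ``n_edges``.
    """
    if n < 2:
        return []
    m0 = min(n, 3)
    edges = [(i, (i + 1) % m0) for i in range(m0)] if m0 >= 2 else []
    existing = set(edges)
    indeg = np.zeros(n, dtype=np.float64)
    for _, v in edges:
        indeg[v] += 1
    new_nodes = list(range(m0, n))
    if new_nodes:
        remaining = max(n_edges - len(edges), 0)
        base, extra = divmod(remaining, len(new_nodes))
        for pos, t in enumerate(new_nodes):
            m_t = max(1, min(base + (1 if pos < extra else 0), t))
            w = (indeg[:t] + 1.0) ** gamma
            targets = rng.choice(t, size=m_t, replace=False, p=w / w.sum())
            for v in targets:
                edges.append((t, int(v)))
                existing.add((t, int(v)))
                indeg[v] += 1
    # top up with preferential extra links to reach the target count
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        u = int(rng.integers(n))
        w = (indeg + 1.0) ** gamma
        v = int(rng.choice(n, p=w / w.sum()))
        if u == v or (u, v) in existing:
            continue
        edges.append((u, v))
        existing.add((u, v))
        indeg[v] += 1
    return [(u + offset, v + offset) for u, v in edges]


def generate_network(spec: SyntheticSpec) -> tuple[DirectedNetwork, NodePanel]:
    """Generate a synthetic network with red-hub and blue panels.

    The main component holds (1 - disconnected_fraction) * N nodes; the
    remainder forms a hub-unreachable component of its own (or isolated
    singletons when too small).  The red panel holds n_red modest-degree
    nodes of the main component (in-degree near red_degree_factor times the
    mean); the blue panel is sampled from the mid in-degree range.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    N = spec.N
    n_iso = int(round(spec.disconnected_fraction * N))
    n_main = N - n_iso
    if n_main < max(4, spec.n_red + spec.n_blue + 2):
        raise ValueError(
            "main component too small for the requested panels; "
            "reduce disconnected_fraction or panel sizes"
        )
    main_target = int(round(spec.mean_out_degree * n_main))
    iso_target = int(round(spec.mean_out_degree * n_iso)) if n_iso >= 2 else 0
    edges = _pa_edges(rng, n_main, main_target, spec.attachment_exponent, 0)
    edges += _pa_edges(rng, n_iso, iso_target, spec.attachment_exponent, n_main)
    names = [f"n{i:05d}" for i in range(N)]
    net = DirectedNetwork(
        node_names=names,
        edges=np.asarray(edges, dtype=np.int64).reshape(len(edges), 2),
        name_to_index={name: i for i, name in enumerate(names)},
    )
    indeg_main = np.bincount(
        net.edges[net.edges[:, 1] < n_main, 1], minlength=n_main
    )
    # Red panel: modest-degree activator nodes (in-degree near
    # red_degree_factor * mean degree).  Real activator panels are not the
    # top network hubs: the top hubs sit in the panel's Erdös shell, which
    # is what makes a small blue barrage able to outrace the red cascade.
    target = spec.red_degree_factor * spec.mean_out_degree
    closest = np.lexsort((np.arange(n_main), np.abs(indeg_main - target)))
    red = np.sort(closest[: spec.n_red])
    by_degree = np.lexsort((np.arange(n_main), -indeg_main))
    lo, hi = int(0.30 * n_main), int(0.70 * n_main)
    window = np.setdiff1d(by_degree[lo:hi], red)
    blue = np.sort(rng.choice(window, size=spec.n_blue, replace=False))
    labels = {int(i): "red-hub" for i in red}
    labels.update({int(i): "blue-panel" for i in blue})
    return net, NodePanel(fixed_red=red, fixed_blue=blue, labels=labels)


@dataclass
class Fixture:
    """A micro-network with documented exact expected behavior."""

    name: str
    net: DirectedNetwork
    panel: NodePanel | None
    description: str
    _tm: TransitionMatrices | None = field(default=None, repr=False)

    def matrices(self) -> TransitionMatrices:
        if self._tm is None:
            self._tm = build_transition_matrices(self.net)
        return self._tm


def _net(pairs: list[tuple[str, str]]) -> DirectedNetwork:
    return DirectedNetwork.from_named_edges(pairs)


def fixture_catalog() -> dict[str, Fixture]:
    """Named micro-networks used as exact oracles throughout the suite."""
    cat: dict[str, Fixture] = {}

    net = _net([("a", "b"), ("b", "a")])
    cat["two_cycle"] = Fixture(
        "two_cycle", net, None,
        "Symmetric 2-cycle: inversion is the identity, PageRank is uniform.",
    )

    net = _net([("hub", f"l{i}") for i in range(1, 5)])
    cat["out_star"] = Fixture(
        "out_star", net, NodePanel.from_names(net, red=["hub"], blue=[]),
        "5-node out-star, hub pinned red: every leaf sees a positive field, "
        "so all leaves are red after one sweep (fr = 1 everywhere); the hub "
        "has CheiRank index K* = 1.",
    )

    net = _net([(f"l{i}", "hub") for i in range(1, 5)])
    cat["in_star"] = Fixture(
        "in_star", net, NodePanel.from_names(net, red=["hub"], blue=[]),
        "5-node in-star, hub pinned red: the coupling is symmetrized, so "
        "leaves still turn red; the hub has PageRank index K = 1.",
    )

    net = _net([("a", "b"), ("b", "c")])
    cat["dangling_chain"] = Fixture(
        "dangling_chain", net, None,
        "3-node chain a->b->c: node c is dangling (zero column in S~, "
        "uniform column in S).",
    )

    net = _net(
        [("r", "v1"), ("v1", "v2"), ("b", "v2"), ("v2", "v3"), ("v3", "v1"),
         ("w1", "w2"), ("w2", "w3"), ("w3", "w1")]
    )
    cat["two_component"] = Fixture(
        "two_component", net, NodePanel.from_names(net, red=["r"], blue=["b"]),
        "8-node graph with two weakly connected components; all pinned nodes "
        "sit in the first, so w1..w3 have no path to any pinned node and stay "
        "white in every realization.",
    )

    ring = [(f"c{i}", f"c{i % 7 + 1}") for i in range(1, 8)]
    net = _net([("hub", "leaf"), ("hub", "bridge"), ("bridge", "c1")] + ring)
    cat["bottleneck"] = Fixture(
        "bottleneck", net, NodePanel.from_names(net, red=["hub"], blue=[]),
        "10-node bottleneck: a pinned red hub reaches a 7-node ring community "
        "only through a single bridge node.  With the bridge as single "
        "initial blue, in every realization where the bridge converges blue "
        "the community ends non-red (once the bridge turns red it can never "
        "return to blue, so community red implies bridge red).",
    )

    ring = [(f"v{i}", f"v{i % 6 + 1}") for i in range(1, 7)]
    net = _net([("r", "v1"), ("r", "v2"), ("b", "v4"), ("b", "v5")] + ring)
    cat["contested"] = Fixture(
        "contested", net, NodePanel.from_names(net, red=["r"], blue=["b"]),
        "8-node ring with a pinned red and a pinned blue feeder on opposite "
        "sides: final colors depend on the sweep order, giving fractional "
        "fr(i) values suited to exhaustive sweep-order enumeration "
        "(6 variable nodes).",
    )
    return cat
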