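"""Directed network ingestion and Markov-chain transition matrices.

Conventions: the adjacency matrix has ``A[i, j] = 1`` iff there is a link
j -> i, all diagonal elements are zero (self-links are dropped on ingestion)
and parallel duplicate links collapse to a single unweighted link.  The
column-normalized matrix ``S~`` keeps all-zero columns at dangling nodes
(nodes without outgoing links); the proper column-stochastic matrix ``S``
replaces those columns by the uniform vector 1/N and is only used for
ranking, never for the spin dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """Raised for malformed or empty network / panel files."""


@dataclass
class DirectedNetwork:
    """A directed graph with dense 0-based node indices and a name map.

    ``edges`` is an (m, 2) integer array of (source, target) index pairs,
    free of self-loops and duplicates; node indices cover 0..N-1.
    """

    node_names: list[str]
    edges: np.ndarray
    name_to_index: dict[str, int] = field(repr=False)

    @property
    def N(self) -> int:
        return len(self.node_names)

    @property
    def n_links(self) -> int:
        return int(self.edges.shape[0])

    @classmethod
    def from_named_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "DirectedNetwork":
        """Build a network from (source name, target name) pairs.

        Node order is first-appearance order.  Self-loops and duplicate
        pairs are silently dropped (a count is logged).  ``extra_nodes``
        registers isolated nodes that appear in no edge.
        """
        name_to_index: dict[str, int] = {}
        names: list[str] = []

        def idx(name: str) -> int:
            i = name_to_index.get(name)
            if i is None:
                i = len(names)
                name_to_index[name] = i
                names.append(name)
            return i

        seen: set[tuple[int, int]] = set()
        edges: list[tuple[int, int]] = []
        n_self = n_dup = 0
        for src, dst in pairs:
            u, v = idx(src), idx(dst)
            if u == v:
                n_self += 1
                continue
            if (u, v) in seen:
                n_dup += 1
                continue
            seen.add((u, v))
            edges.append((u, v))
        for name in extra_nodes:
            idx(name)
        if not names:
            raise EdgeListError("network is empty: no nodes found")
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate link(s)", n_self, n_dup
            )
        arr = np.asarray(edges, dtype=np.int64).reshape(len(edges), 2)
        return cls(node_names=names, edges=arr, name_to_index=name_to_index)

    def index_of(self, name: str) -> int:
        try:
            return self.name_to_index[name]
        except KeyError:
            raise KeyError(f"node {name!r} is not in the network") from None

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.N)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.N)


@dataclass
class NodePanel:
    """Permanently pinned activator ("red") and repressor ("blue") nodes.

    ``labels`` may carry free-form group tags per node index (e.g. a global
    index within a curated panel, or subgroup tags).
    """

    fixed_red: np.ndarray
    fixed_blue: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_red = np.asarray(self.fixed_red, dtype=np.int64)
        self.fixed_blue = np.asarray(self.fixed_blue, dtype=np.int64)
        if np.intersect1d(self.fixed_red, self.fixed_blue).size:
            raise ValueError("fixed red and fixed blue sets must be disjoint")

    @classmethod
    def from_names(
        cls,
        net: DirectedNetwork,
        red: Sequence[str],
        blue: Sequence[str],
        labels: dict[str, str] | None = None,
    ) -> "NodePanel":
        panel = cls(
            fixed_red=np.array([net.index_of(n) for n in red], dtype=np.int64),
            fixed_blue=np.array([net.index_of(n) for n in blue], dtype=np.int64),
            labels={net.index_of(k): v for k, v in (labels or {}).items()},
        )
        panel.validate(net)
        return panel

    def validate(self, net: DirectedNetwork) -> None:
        for arr, role in ((self.fixed_red, "red"), (self.fixed_blue, "blue")):
            if arr.size and (arr.min() < 0 or arr.max() >= net.N):
                raise ValueError(f"{role} panel refers to nodes outside the network")

    @property
    def pinned(self) -> np.ndarray:
        return np.union1d(self.fixed_red, self.fixed_blue)


@dataclass
class TransitionMatrices:
    """Adjacency and Markov transition matrices of a directed network.

    - ``A``: sparse adjacency indicator, A[i, j] = 1 iff edge j -> i,
      zero diagonal.
    - ``S_tilde``: column-normalized adjacency; columns of dangling nodes
      (no out-links) are all zero.
    - ``dangling``: boolean mask of dangling nodes.  The column-stochastic
      matrix S (dangling columns replaced by uniform 1/N) is represented
      implicitly; apply it with :meth:`s_matvec` or materialize it for small
      networks with :meth:`s_dense`.
    - ``W``: symmetric coupling S~ + S~^T used by the spin dynamics.
    """

    A: sp.csr_matrix
    S_tilde: sp.csr_matrix
    dangling: np.ndarray
    W: sp.csr_matrix

    @property
    def N(self) -> int:
        return self.A.shape[0]

    def s_matvec(self, v: np.ndarray) -> np.ndarray:
        """Apply the column-stochastic matrix S to a vector."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (self.N,):
            raise ValueError(f"vector has shape {v.shape}, expected ({self.N},)")
        out = self.S_tilde @ v
        dangling_mass = float(v[self.dangling].sum())
        if dangling_mass:
            out = out + dangling_mass / self.N
        return out

    def s_dense(self) -> np.ndarray:
        """Materialize S as a dense array (small networks / tests only)."""
        S = self.S_tilde.toarray()
        S[:, self.dangling] = 1.0 / self.N
        return S


def _parse_tsv(lines: Iterable[str]) -> tuple[list[tuple[str, str]], list[str]]:
    pairs = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {ln}: expected at least 2 columns (source, target), "
                f"got {len(tokens)}"
            )
        # a third interaction-type column is accepted and ignored
        pairs.append((tokens[0], tokens[1]))
    return pairs, []


def _parse_sif(lines: Iterable[str]) -> tuple[list[tuple[str, str]], list[str]]:
    pairs = []
    lone: list[str] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 1:
            lone.append(tokens[0])  # SIF allows lone-node records
            continue
        if len(tokens) == 2:
            raise EdgeListError(
                f"line {ln}: SIF record has a relation but no target node"
            )
        src = tokens[0]
        # tokens[1] is the relation type, accepted and ignored;
        # multi-target lines expand to one pair per target
        pairs.extend((src, dst) for dst in tokens[2:])
    return pairs, lone


def load_edge_list(path: str | Path, format: str | None = None) -> DirectedNetwork:
    """Read a directed network from a TSV edge list or a SIF file.

    ``format`` is ``"tsv"`` or ``"sif"``; when omitted it is inferred from
    the file suffix (``.sif`` -> SIF, anything else -> TSV).  Comment lines
    starting with ``#`` and blank lines are skipped.  Self-loops and
    duplicate links are dropped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    lines = path.read_text().splitlines()
    parser = _parse_sif if format == "sif" else _parse_tsv
    pairs, lone = parser(lines)
    if not pairs and not lone:
        raise EdgeListError(f"{path}: file contains no network records")
    return DirectedNetwork.from_named_edges(pairs, extra_nodes=lone)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Emit the canonical two-column TSV edge list (source, target names)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges:
            fh.write(f"{net.node_names[u]}\t{net.node_names[v]}\n")


def load_panel(path: str | Path, net: DirectedNetwork) -> NodePanel:
    """Read a panel TSV: columns name, role in {red, blue}, optional label."""
    red: list[str] = []
    blue: list[str] = []
    labels: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {ln}: panel record needs at least (name, role)"
            )
        name, role = tokens[0], tokens[1].lower()
        if role == "red":
            red.append(name)
        elif role == "blue":
            blue.append(name)
        else:
            raise EdgeListError(f"line {ln}: unknown role {tokens[1]!r}")
        if len(tokens) > 2:
            labels[name] = tokens[2]
    if not red and not blue:
        raise EdgeListError(f"{path}: panel file contains no records")
    return NodePanel.from_names(net, red, blue, labels)


def write_panel(net: DirectedNetwork, panel: NodePanel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i in panel.fixed_red:
            label = panel.labels.get(int(i), "")
            fh.write(f"{net.node_names[i]}\tred{chr(9) + label if label else ''}\n")
        for i in panel.fixed_blue:
            label = panel.labels.get(int(i), "")
            fh.write(f"{net.node_names[i]}\tblue{chr(9) + label if label else ''}\n")


def invert_network(net: DirectedNetwork) -> DirectedNetwork:
    """Return the network with every link direction reversed."""
    return DirectedNetwork(
        node_names=list(net.node_names),
        edges=net.edges[:, ::-1].copy(),
        name_to_index=dict(net.name_to_index),
    )


def build_transition_matrices(net: DirectedNetwork) -> TransitionMatrices:
    """Build A, S~ (zero dangling columns) and W = S~ + S~^T."""
    N = net.N
    if net.n_links:
        src = net.edges[:, 0]
        dst = net.edges[:, 1]
        A = sp.csr_matrix(
            (np.ones(len(src)), (dst, src)), shape=(N, N), dtype=np.float64
        )
    else:
        A = sp.csr_matrix((N, N), dtype=np.float64)
    out_deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = out_deg == 0
    inv = np.zeros(N)
    inv[~dangling] = 1.0 / out_deg[~dangling]
    S_tilde = (A @ sp.diags(inv)).tocsr()
    W = (S_tilde + S_tilde.T).tocsr()
    W.sort_indices()
    return TransitionMatrices(A=A, S_tilde=S_tilde, dangling=dangling, W=W)
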