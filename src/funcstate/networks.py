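"""Weighted undirected network data model, file I/O and synthetic generators.

The canonical in-memory object is :class:`WeightedNetwork`: a node-labelled,
symmetric, nonnegative weight matrix ``W`` with zero diagonal. Node order is
first-appearance order in the input file (or generator order) and every matrix
downstream is indexed by it, so outputs are deterministic.

Two plain-text dialects are supported:

* weighted edge list — tab-separated ``node  node  weight`` rows, no header,
  ``#`` comments; duplicate undirected edges are summed, self-loops rejected;
* dense adjacency — CSV with a header row of node labels.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import GenerationError, ParseError, ValidationError

__all__ = [
    "WeightedNetwork",
    "GeneratorSpec",
    "read_network",
    "write_network",
    "generate",
    "sbm_block_sizes",
    "TOPOLOGIES",
]

_SYMMETRY_TOL = 1e-8
_WEIGHT_FMT = "%.17g"  # 17 significant digits round-trip any double exactly


@dataclasses.dataclass(frozen=True)
class WeightedNetwork:
    """Undirected weighted graph as a labelled symmetric matrix.

    Parameters
    ----------
    node_labels:
        Opaque node identifiers in canonical (first-appearance) order.
    weights:
        Symmetric N x N nonnegative matrix ``W``; ``W[i, j]`` is the link
        intensity between nodes ``i`` and ``j``; the diagonal is zero.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))
        n = len(self.node_labels)
        if n < 2:
            raise ValidationError(f"network needs at least 2 nodes, got {n}")
        if w.shape != (n, n):
            raise ValidationError(f"weight matrix shape {w.shape} does not match {n} labels")
        if len(set(self.node_labels)) != n:
            raise ValidationError("duplicate node labels")
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite weights")
        if np.any(w < 0):
            raise ValidationError("negative weights")
        if np.any(np.diag(w) != 0):
            raise ValidationError("self-loops (nonzero diagonal) are not allowed")
        if not np.allclose(w, w.T, rtol=0, atol=_SYMMETRY_TOL):
            raise ValidationError("weight matrix is not symmetric within tolerance")
        # enforce exact symmetry so spectral code sees a symmetric operator
        object.__setattr__(self, "weights", (w + w.T) / 2.0)
        self.weights.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths ``K_i = sum_j W_ij``."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """Sum of edge weights, each undirected edge counted once."""
        return float(self.weights.sum() / 2.0)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def n_components(self) -> int:
        ncomp, _ = connected_components(self.weights > 0, directed=False)
        return int(ncomp)

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Edges as ``(label_i, label_j, weight)`` with ``i < j`` in canonical order."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [
            (self.node_labels[i], self.node_labels[j], float(self.weights[i, j]))
            for i, j in zip(ii, jj)
        ]

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Same nodes, new weight matrix (re-validated)."""
        return WeightedNetwork(self.node_labels, weights)

    def with_node_order(self, node_labels: Sequence[str]) -> "WeightedNetwork":
        """Same labelled graph with rows/columns permuted to the given order."""
        if set(node_labels) != set(self.node_labels) or len(node_labels) != self.n_nodes:
            raise ValidationError("node_labels must be a permutation of the existing labels")
        pos = {lab: i for i, lab in enumerate(self.node_labels)}
        perm = np.array([pos[lab] for lab in node_labels])
        return WeightedNetwork(tuple(node_labels), self.weights[np.ix_(perm, perm)])

    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[str, str, float]], node_labels: Sequence[str] | None = None
    ) -> "WeightedNetwork":
        """Build from an undirected edge list; duplicate edges are summed.

        Node order is first appearance within ``edges`` unless ``node_labels``
        fixes it explicitly.
        """
        if node_labels is None:
            order: dict[str, int] = {}
            for a, b, _ in edges:
                for lab in (str(a), str(b)):
                    if lab not in order:
                        order[lab] = len(order)
            labels = list(order)
        else:
            labels = [str(x) for x in node_labels]
            order = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for a, b, wt in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            i, j = order[a], order[b]
            w[i, j] += wt
            w[j, i] += wt
        return cls(tuple(labels), w)


# ---------------------------------------------------------------------------
# File I/O


def read_network(path: str | Path, format: str = "edgelist") -> WeightedNetwork:
    """Read a network file.

    ``format='edgelist'``: TSV rows ``node<TAB>node<TAB>weight``; '#' comments
    and blank lines ignored; duplicate undirected edges summed; self-loops and
    non-positive weights rejected. ``format='adjacency'``: CSV, header row of
    labels, square symmetric body.

    Disconnected networks are accepted (validity is structural); operations
    that need connectivity raise their own errors.
    """
    path = Path(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "adjacency":
        return _read_adjacency(path)
    raise ValidationError(f"unknown format {format!r}")


def _read_edgelist(path: Path) -> WeightedNetwork:
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            a, b, wtxt = parts
            try:
                w = float(wtxt)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: weight {wtxt!r} is not a number") from exc
            if not np.isfinite(w) or w <= 0:
                raise ValidationError(f"{path}:{lineno}: weight must be positive, got {wtxt}")
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on node {a!r}")
            edges.append((a, b, w))
    if not edges:
        raise ParseError(f"{path}: empty edge list")
    return WeightedNetwork.from_edges(edges)


def _read_adjacency(path: Path) -> WeightedNetwork:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ParseError(f"{path}:1: missing header row of labels")
        labels = [h.strip() for h in header.split(",")]
        try:
            body = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed adjacency body ({exc})") from exc
    n = len(labels)
    if body.shape != (n, n):
        raise ParseError(f"{path}: body shape {body.shape} does not match {n} header labels")
    if not np.allclose(body, body.T, rtol=0, atol=_SYMMETRY_TOL):
        raise ValidationError(f"{path}: adjacency asymmetric beyond tolerance {_SYMMETRY_TOL}")
    return WeightedNetwork(tuple(labels), body)


def write_network(net: WeightedNetwork, path: str | Path, format: str = "edgelist") -> None:
    """Write a network file in the given dialect.

    The edge list round-trips weights bit-exactly (17 significant digits).
    """
    path = Path(path)
    if format == "edgelist":
        buf = io.StringIO()
        for a, b, w in net.edge_list():
            buf.write(f"{a}\t{b}\t{_WEIGHT_FMT % w}\n")
        path.write_text(buf.getvalue())
    elif format == "adjacency":
        buf = io.StringIO()
        buf.write(",".join(net.node_labels) + "\n")
        np.savetxt(buf, net.weights, delimiter=",", fmt=_WEIGHT_FMT)
        path.write_text(buf.getvalue())
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Synthetic generators

TOPOLOGIES = (
    "random_geometric",
    "barabasi_albert",
    "watts_strogatz",
    "stochastic_block",
    "two_cliques",
    "path",
    "complete",
)

_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "random_geometric": ("radius",),
    "barabasi_albert": ("m",),
    "watts_strogatz": ("k", "p"),
    "stochastic_block": (),
    "two_cliques": (),
    "path": (),
    "complete": (),
}

_MAX_RETRIES = 200


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic network draw.

    ``parameters`` are topology-specific, e.g. ``radius`` for
    ``random_geometric``, ``m`` for ``barabasi_albert``, ``k``/``p`` for
    ``watts_strogatz``, ``n_blocks``/``p_intra``/``p_inter`` for
    ``stochastic_block`` (defaults 4, 1e-3, 0.5), ``clique_size`` /
    ``bridge_weight`` for ``two_cliques``. An optional ``weights`` entry
    ``{"distribution": "uniform"|"loguniform", "low": .., "high": ..}``
    replaces the default unit weights with seeded random draws.
    """

    topology: str
    n_nodes: int
    seed: int
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        missing = [p for p in _REQUIRED_PARAMS[self.topology] if p not in self.parameters]
        if missing:
            raise ValidationError(f"topology {self.topology!r} requires parameters {missing}")


def sbm_block_sizes(n_nodes: int, n_blocks: int) -> list[int]:
    """Deterministic near-even split of ``n_nodes`` into ``n_blocks`` blocks."""
    base, rem = divmod(n_nodes, n_blocks)
    return [base + (1 if b < rem else 0) for b in range(n_blocks)]


def _draw_graph(spec: GeneratorSpec, seed: int) -> nx.Graph:
    n, p = spec.n_nodes, spec.parameters
    t = spec.topology
    if t == "random_geometric":
        return nx.random_geometric_graph(n, p["radius"], seed=seed)
    if t == "barabasi_albert":
        return nx.barabasi_albert_graph(n, int(p["m"]), seed=seed)
    if t == "watts_strogatz":
        return nx.watts_strogatz_graph(n, int(p["k"]), p["p"], seed=seed)
    if t == "stochastic_block":
        n_blocks = int(p.get("n_blocks", 4))
        p_intra = float(p.get("p_intra", 1e-3))
        p_inter = float(p.get("p_inter", 0.5))
        sizes = sbm_block_sizes(n, n_blocks)
        probs = np.full((n_blocks, n_blocks), p_inter)
        np.fill_diagonal(probs, p_intra)
        return nx.stochastic_block_model(sizes, probs.tolist(), seed=seed)
    if t == "two_cliques":
        c = int(p.get("clique_size", 4))
        g = nx.disjoint_union(nx.complete_graph(c), nx.complete_graph(c))
        g.add_edge(0, c, weight=float(p.get("bridge_weight", 1.0)))
        return g
    if t == "path":
        return nx.path_graph(n)
    if t == "complete":
        return nx.complete_graph(n)
    raise AssertionError(t)


def generate(spec: GeneratorSpec) -> WeightedNetwork:
    """Draw a connected synthetic network; deterministic given the spec's seed.

    Disconnected draws are resampled with a deterministically shifted seed, up
    to a bounded retry count; exhaustion raises :class:`GenerationError`.
    Weights are unit unless the spec carries a ``weights`` distribution.
    """
    for attempt in range(_MAX_RETRIES):
        try:
            g = _draw_graph(spec, spec.seed + attempt)
        except nx.NetworkXError as exc:  # e.g. impossible parameter combo
            raise GenerationError(f"{spec.topology} with {spec.parameters}: {exc}") from exc
        if nx.is_connected(g):
            return _to_network(g, spec)
    raise GenerationError(
        f"no connected draw of {spec.topology} (n={spec.n_nodes}, params={spec.parameters}) "
        f"within {_MAX_RETRIES} attempts"
    )


def _to_network(g: nx.Graph, spec: GeneratorSpec) -> WeightedNetwork:
    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w[index[u], index[v]] = w[index[v], index[u]] = float(data.get("weight", 1.0))
    wspec = spec.parameters.get("weights")
    if wspec is not None:
        rng = np.random.default_rng([spec.seed, 0x5EED])
        ii, jj = np.nonzero(np.triu(w, k=1))
        dist = wspec.get("distribution", "uniform")
        low, high = float(wspec.get("low", 0.0)), float(wspec.get("high", 1.0))
        if dist == "uniform":
            draws = rng.uniform(low, high, size=len(ii))
        elif dist == "loguniform":
            draws = np.exp(rng.uniform(np.log(low), np.log(high), size=len(ii)))
        elif dist == "degree_product":
            # organized heterogeneity: link weight grows with endpoint degrees
            # (thick trunk cords between hubs, thin peripheral ones), akin to
            # conductance-weighted transport networks
            gamma = float(wspec.get("gamma", 1.0))
            deg = (w > 0).sum(axis=1).astype(float)
            draws = (deg[ii] * deg[jj]) ** gamma
        else:
            raise ValidationError(f"unknown weight distribution {dist!r}")
        w[ii, jj] = draws
        w[jj, ii] = draws
    return WeightedNetwork(tuple(f"n{index[u]}" for u in nodes), w)
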