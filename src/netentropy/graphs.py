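"""Interaction-network container, generators and topology diagnostics.

Networks here are undirected, unweighted and connected: the substrate on
which the expression-weighted random walk of :mod:`netentropy.entropy` is
defined.  Generators produce Erdős–Rényi G(V, M) graphs and Barabási–Albert
scale-free graphs matched in size and mean degree, the two topology classes
whose perturbation response is contrasted throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_edge_list",
    "write_edge_list",
    "generate_er",
    "generate_scale_free",
    "degree_matched_rewire",
    "topology_report",
]


class NetworkInputError(ValueError):
    """Raised for malformed or degenerate network input."""


class GenerationError(RuntimeError):
    """Raised when a random-graph generator cannot satisfy its contract."""


@dataclass(frozen=True)
class Network:
    """Undirected, connected, simple graph over string node identifiers.

    Parameters
    ----------
    node_ids : list of str
        Node identifiers in lexicographic order; all indexing is positional
        with respect to this list.
    adjacency : scipy.sparse.csr_matrix
        Symmetric binary V x V adjacency with zero diagonal.
    """

    node_ids: tuple[str, ...]
    adjacency: sp.csr_matrix
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    # -- basic structure -------------------------------------------------
    @property
    def V(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.V

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise NetworkInputError(f"node {node!r} not in network") from None

    def neighbors(self, node: str) -> list[str]:
        i = self.index(node)
        row = self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]
        return [self.node_ids[j] for j in row]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_scipy_sparse_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids)))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        """Build from an undirected simple graph; restricts to the largest
        connected component, ties broken to the component containing the
        lexicographically smallest node."""
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_nodes() < 2:
            raise NetworkInputError("network needs at least 2 connected nodes")
        comps = [sorted(c, key=str) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: (-len(c), str(c[0])))
        keep = comps[0]
        if len(keep) < 2:
            raise NetworkInputError("largest component has fewer than 2 nodes")
        nodes = sorted((str(n) for n in keep))
        sub = g.subgraph(keep)
        adj = nx.to_scipy_sparse_array(
            nx.relabel_nodes(sub, {n: str(n) for n in keep}),
            nodelist=nodes,
            dtype=np.float64,
            format="csr",
        )
        adj.data[:] = 1.0
        return cls(tuple(nodes), sp.csr_matrix(adj))

    def subgraph(self, nodes) -> "Network":
        """Largest connected component of the induced subgraph."""
        keep = [n for n in nodes if n in self._index]
        return Network.from_networkx(self.to_networkx().subgraph(keep))


def _generated_names(V: int) -> dict[int, str]:
    width = max(4, len(str(V)))
    return {i: f"n{i + 1:0{width}d}" for i in range(V)}


def read_edge_list(path) -> Network:
    """Read a two-column, headerless TSV edge list.

    Self-edges and duplicate edges are dropped (and counted in the log);
    only the maximally connected component is returned.
    """
    edges = []
    n_self = n_dup = 0
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise NetworkInputError(
                    f"{path}:{lineno}: expected two tab-separated identifiers"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
    if not edges:
        raise NetworkInputError(f"{path}: no usable edges")
    if n_self or n_dup:
        logger.info(
            "read_edge_list: dropped %d self-edges and %d duplicates", n_self, n_dup
        )
    g = nx.Graph(edges)
    net = Network.from_networkx(g)
    logger.info(
        "read_edge_list: %d nodes, %d edges in largest component", net.V, net.n_edges
    )
    return net


def write_edge_list(net: Network, path) -> None:
    """Write the same TSV dialect read_edge_list consumes (each edge once)."""
    coo = sp.triu(net.adjacency).tocoo()
    with open(path, "w") as fh:
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\n")


def generate_er(V: int, mean_degree: float, seed: int) -> Network:
    """Erdős–Rényi G(V, M) graph with M = round(V*mean_degree/2) edges.

    The edge count (rather than edge probability) is fixed so mean degree is
    matched exactly before extraction of the largest connected component.
    Redraws up to 20 times if the component holds < 90% of the nodes.
    """
    if V < 3:
        raise NetworkInputError("V must be >= 3")
    if not (1 < mean_degree <= V - 1):
        raise NetworkInputError("mean_degree must lie in (1, V-1]")
    M = int(round(V * mean_degree / 2.0))
    M = min(M, V * (V - 1) // 2)
    names = _generated_names(V)
    for attempt in range(20):
        g = nx.gnm_random_graph(V, M, seed=seed + 100_003 * attempt)
        net = Network.from_networkx(nx.relabel_nodes(g, names))
        if net.V >= 0.9 * V:
            logger.info(
                "generate_er: V=%d (requested %d), <k>=%.3f", net.V, V, net.mean_degree
            )
            return net
    raise GenerationError(
        f"ER(V={V}, <k>={mean_degree}): largest component < 0.9 V after 20 redraws"
    )


def generate_scale_free(V: int, mean_degree: float, seed: int) -> Network:
    """Barabási–Albert preferential-attachment graph, m = round(mean_degree/2).

    Connected by construction with exactly m*(V-m) edges, hence realised mean
    degree 2*m*(V-m)/V, slightly below the target for finite V.
    """
    if V < 3:
        raise NetworkInputError("V must be >= 3")
    m = int(round(mean_degree / 2.0))
    if m < 1:
        raise NetworkInputError("mean_degree/2 must round to >= 1")
    if m >= V:
        raise NetworkInputError("m = round(mean_degree/2) must be < V")
    g = nx.barabasi_albert_graph(V, m, seed=seed)
    return Network.from_networkx(nx.relabel_nodes(g, _generated_names(V)))


def degree_matched_rewire(net: Network, n_swaps: int, seed: int) -> Network:
    """Randomise wiring by double-edge swaps, preserving every degree exactly.

    Swap candidates that would create a self-edge or a multi-edge are
    skipped and counted.  The result is restricted to its largest connected
    component (swaps can fragment the graph).
    """
    if n_swaps < 1:
        raise NetworkInputError("n_swaps must be >= 1")
    rng = np.random.default_rng(seed)
    coo = sp.triu(net.adjacency).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(coo.row, coo.col)]
    edge_set = set(edges)
    n_skipped = 0
    n_edges = len(edges)
    for _ in range(n_swaps):
        a, b = rng.integers(0, n_edges, size=2)
        if a == b:
            n_skipped += 1
            continue
        (u, v), (x, y) = edges[a], edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed new edges: (u, x) and (v, y)
        if len({u, v, x, y}) < 4:
            n_skipped += 1
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            n_skipped += 1
            continue
        edge_set.discard(edges[a])
        edge_set.discard(edges[b])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a], edges[b] = e1, e2
    logger.info("degree_matched_rewire: %d/%d swaps skipped", n_skipped, n_swaps)
    g = nx.Graph(
        (net.node_ids[i], net.node_ids[j]) for i, j in edge_set
    )
    g.add_nodes_from(net.node_ids)
    return Network.from_networkx(g)


def _log_binned_slope(degrees: np.ndarray, n_bins: int = 12):
    """Least-squares slope of the log-binned log-log degree distribution."""
    kmin, kmax = degrees.min(), degrees.max()
    if kmax <= kmin:
        return float("nan"), []
    edges = np.unique(np.geomspace(kmin, kmax + 1, n_bins + 1))
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    density = counts / widths
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = density > 0
    if ok.sum() < 3:
        return float("nan"), []
    slope = np.polyfit(np.log10(centers[ok]), np.log10(density[ok]), 1)[0]
    pts = [
        {"k": float(c), "density": float(d)}
        for c, d in zip(centers[ok], density[ok])
    ]
    return float(slope), pts


def _hill_mle_exponent(degrees: np.ndarray, kmin: int | None = None) -> float:
    """Closed-form discrete power-law exponent estimate for k >= kmin.

    Defaults kmin to the smallest observed degree (>= 2): below it the
    distribution is shaped by the generator's attachment floor, not the tail.
    """
    if kmin is None:
        kmin = max(2, int(degrees.min()))
    tail = degrees[degrees >= kmin]
    if tail.size < 10:
        return float("nan")
    return float(1.0 + tail.size / np.sum(np.log(tail / (kmin - 0.5))))


def topology_report(net: Network, mle: bool = False) -> dict:
    """Topology diagnostics: degree histogram, power-law slope estimate,
    clustering coefficient and the summary degrees annotated on sweep plots
    (node count ``nn``, mean degree ``avK``, median degree ``medK``).
    """
    k = net.degrees
    hist = {int(d): int(c) for d, c in zip(*np.unique(k, return_counts=True))}
    slope, pts = _log_binned_slope(k)
    report = {
        "nn": net.V,
        "n_edges": net.n_edges,
        "avK": float(net.mean_degree),
        "medK": float(np.median(k)),
        "max_degree": int(k.max()),
        "degree_histogram": hist,
        "powerlaw_slope_lsq": slope,
        "log_binned_points": pts,
        "mean_clustering": float(nx.average_clustering(net.to_networkx())),
    }
    if mle:
        report["powerlaw_exponent_mle"] = _hill_mle_exponent(k)
    return report


def topology_report_json(net: Network, **kw) -> str:
    return json.dumps(topology_report(net, **kw), indent=2)
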