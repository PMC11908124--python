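"""Protein structure networks, community detection, and suboptimal paths.

A protein structure network (PSN) has one node per residue and an edge for
every residue pair passing the gates (spatial contact and/or a minimum
correlation magnitude).  Edges carry two attributes:

- ``weight`` = -ln|c_ij|, a *distance*: strongly coupled pairs are short.
  Shortest paths under this weight are the optimal allosteric routes, and a
  path's length L (sum of weights) measures coupling strength end to end.
- ``corr`` = |c_ij|, an *affinity*, used when scoring partitions by
  modularity in community detection.

Community detection is divisive Girvan–Newman: repeatedly remove the edge
of highest (weighted shortest-path) betweenness, record the partition
sequence, and return the partition of maximal modularity.  Suboptimal path
enumeration returns the k shortest simple source→sink paths in
non-decreasing length (Yen-style), with deterministic lexicographic
tie-breaking throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .core import AtomSelection, StructureModel, TrajectoryEnsemble
from .correlation import CorrelationMatrix

__all__ = [
    "ContactMap",
    "ProteinStructureNetwork",
    "CommunityPartition",
    "PathEnsemble",
    "PathLengthDistribution",
    "contact_map",
    "build_psn",
    "girvan_newman",
    "optimal_path",
    "suboptimal_paths",
    "path_length_distribution",
    "node_participation",
]

CORRELATION_FLOOR = 1e-6


@dataclass
class ContactMap:
    """Boolean residue contact matrix with the definition that produced it."""

    mask: np.ndarray
    cutoff: float
    mode: str = "mean"                   # "mean" or "occupancy"
    occupancy_threshold: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("contact map must be symmetric")
        np.fill_diagonal(m, False)
        self.mask = m


def contact_map(
    source: TrajectoryEnsemble | StructureModel,
    selection: AtomSelection,
    cutoff: float = 5.0,
    mode: str = "mean",
    occupancy_threshold: float = 0.75,
) -> ContactMap:
    """Residue contacts from Cα distances.

    ``mean`` mode places an edge where the mean-structure distance is within
    ``cutoff``; ``occupancy`` mode where the instantaneous distance is within
    ``cutoff`` in at least ``occupancy_threshold`` of the frames.
    """
    from scipy.spatial.distance import pdist, squareform

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode == "mean":
        if isinstance(source, TrajectoryEnsemble):
            coords = source.frames[:, selection.indices].mean(axis=0)
        else:
            coords = source.coords[selection.indices]
        dist = squareform(pdist(coords))
        mask = dist <= cutoff
    elif mode == "occupancy":
        if not 0 < occupancy_threshold <= 1:
            raise ValueError("occupancy threshold must be in (0, 1]")
        if not isinstance(source, TrajectoryEnsemble):
            raise ValueError("occupancy mode needs a trajectory")
        x = source.frames[:, selection.indices]
        n = x.shape[1]
        hits = np.zeros((n, n))
        for f in range(x.shape[0]):
            hits += squareform(pdist(x[f])) <= cutoff
        mask = hits / x.shape[0] >= occupancy_threshold
    else:
        raise ValueError(f"unknown contact mode {mode!r}")
    np.fill_diagonal(mask, False)
    return ContactMap(mask=mask, cutoff=cutoff, mode=mode,
                      occupancy_threshold=occupancy_threshold if mode == "occupancy" else None)


@dataclass
class ProteinStructureNetwork:
    """Residue graph with -ln|c| edge weights and its gate parameters."""

    graph: nx.Graph
    contact_cutoff: float | None = None
    correlation_threshold: float | None = None
    labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def write_edge_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        lab = self.labels
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append({
                "res_a": lab[u] if lab else u,
                "res_b": lab[v] if lab else v,
                "correlation": d["corr"],
                "weight": d["weight"],
            })
        pd.DataFrame(rows, columns=["res_a", "res_b", "correlation", "weight"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def build_psn(
    corr: CorrelationMatrix,
    contacts: ContactMap | None = None,
    correlation_threshold: float | None = None,
    correlation_floor: float = CORRELATION_FLOOR,
) -> ProteinStructureNetwork:
    """Gate residue pairs and weight the surviving edges by -ln|c_ij|.

    An edge (i, j) exists iff the pair is in contact (when a contact map is
    given) and |c_ij| >= ``correlation_threshold`` (when a threshold is
    given).  |c_ij| is floored at ``correlation_floor`` before the log so
    weights stay finite; pairs below the floor are dropped.
    """
    c = corr.values
    n = corr.n_residues
    if contacts is not None and contacts.mask.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: correlation is {n}x{n}, "
            f"contact map is {contacts.mask.shape[0]}x{contacts.mask.shape[0]}")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    absc = np.abs(c)
    for i in range(n):
        for j in range(i + 1, n):
            if contacts is not None and not contacts.mask[i, j]:
                continue
            a = absc[i, j]
            if correlation_threshold is not None and a < correlation_threshold:
                continue
            if a < correlation_floor:
                continue
            G.add_edge(i, j, corr=float(a), weight=float(max(0.0, -np.log(min(a, 1.0)))))
    return ProteinStructureNetwork(
        graph=G,
        contact_cutoff=contacts.cutoff if contacts is not None else None,
        correlation_threshold=correlation_threshold,
        labels=corr.labels,
    )


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Node → community labels plus the modularity that selected them."""

    labels: dict[Hashable, int]
    modularity: float
    dendrogram: list[tuple[Hashable, Hashable]] = field(default_factory=list)
    partitions: list[list[frozenset]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def as_array(self, order: Sequence[Hashable] | None = None) -> np.ndarray:
        nodes = order if order is not None else sorted(self.labels)
        return np.array([self.labels[n] for n in nodes])


def _components(G: nx.Graph) -> list[frozenset]:
    return sorted((frozenset(c) for c in nx.connected_components(G)), key=min)


def _graph_of(network: ProteinStructureNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, ProteinStructureNetwork) else network


def girvan_newman(
    network: ProteinStructureNetwork | nx.Graph,
    distance_attr: str = "weight",
    affinity_attr: str = "corr",
) -> CommunityPartition:
    """Divisive community detection with a modularity-selected cut.

    Betweenness is computed on weighted shortest paths (``distance_attr``);
    partitions along the removal sequence are scored by modularity using the
    ``affinity_attr`` edge attribute (pairs without it count as weight 1).
    Ties in betweenness are broken by the lexicographically smallest edge.
    """
    orig = _graph_of(network)
    if orig.number_of_nodes() == 0:
        raise ValueError("network is empty")
    G = orig.copy()
    partitions = [_components(G)]
    removals: list[tuple[Hashable, Hashable]] = []
    while G.number_of_edges() > 0:
        bt = nx.edge_betweenness_centrality(G, weight=distance_attr)
        best = max(bt.values())
        candidates = [tuple(sorted(e)) for e, b in bt.items()
                      if b >= best - 1e-12 * max(1.0, abs(best))]
        edge = min(candidates)
        G.remove_edge(*edge)
        removals.append(edge)
        comps = _components(G)
        if len(comps) > len(partitions[-1]):
            partitions.append(comps)

    from networkx.algorithms.community import modularity as nx_modularity

    best_q, best_part = -np.inf, partitions[0]
    for part in partitions:
        try:
            q = nx_modularity(orig, part, weight=affinity_attr)
        except ZeroDivisionError:  # graph with no edges
            q = 0.0
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    labels: dict[Hashable, int] = {}
    for k, comm in enumerate(sorted(best_part, key=min)):
        for node in comm:
            labels[node] = k
    return CommunityPartition(labels=labels, modularity=float(best_q),
                              dendrogram=removals, partitions=partitions)


# ---------------------------------------------------------------------------
# Optimal and suboptimal paths
# ---------------------------------------------------------------------------

@dataclass
class PathEnsemble:
    """Ranked source→sink simple paths, ascending by length L."""

    paths: list[tuple]
    lengths: np.ndarray
    source: Hashable = None
    sink: Hashable = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.paths) != self.lengths.size:
            raise ValueError("paths and lengths disagree")
        if len(self.paths) == 0:
            raise ValueError("path ensemble is empty")
        if np.any(np.diff(self.lengths) < -1e-12):
            raise ValueError("lengths must be non-decreasing")

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def optimal(self) -> tuple:
        return self.paths[0]

    def write_tsv(self, path, labels: Sequence[str] | None = None) -> None:
        import pandas as pd

        rows = []
        for rank, (p, L) in enumerate(zip(self.paths, self.lengths), start=1):
            nodes = "-".join(labels[n] if labels else str(n) for n in p)
            rows.append({"rank": rank, "length": L, "path": nodes})
        pd.DataFrame(rows, columns=["rank", "length", "path"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def _path_length(G: nx.Graph, path: Sequence, weight: str) -> float:
    return float(sum(G[u][v].get(weight, 1.0) for u, v in zip(path[:-1], path[1:])))


def _validate_query(G: nx.Graph, source, sink) -> None:
    if source == sink:
        raise ValueError("source and sink must differ")
    for node in (source, sink):
        if node not in G:
            raise ValueError(f"node {node!r} not in network")


def suboptimal_paths(
    network: ProteinStructureNetwork | nx.Graph,
    source: Hashable,
    sink: Hashable,
    k: int = 100,
    weight: str = "weight",
) -> PathEnsemble:
    """The k shortest simple source→sink paths, ties broken lexicographically.

    Paths are ordered by (L, node sequence); fewer than k are returned when
    the graph has fewer simple paths.  Raises if source and sink are
    disconnected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    G = _graph_of(network)
    _validate_query(G, source, sink)
    try:
        gen = nx.shortest_simple_paths(G, source, sink, weight=weight)
        collected: list[tuple[float, tuple]] = []
        kth_len = np.inf
        for p in gen:
            L = _path_length(G, p, weight)
            if len(collected) >= k and L > kth_len + 1e-12:
                break
            collected.append((L, tuple(p)))
            if len(collected) >= k:
                kth_len = sorted(L for L, _ in collected)[k - 1]
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"no path between {source!r} and {sink!r}") from exc
    collected.sort(key=lambda t: (t[0], t[1]))
    collected = collected[:k]
    return PathEnsemble(paths=[p for _, p in collected],
                        lengths=np.array([L for L, _ in collected]),
                        source=source, sink=sink)


def optimal_path(network: ProteinStructureNetwork | nx.Graph,
                 source: Hashable, sink: Hashable,
                 weight: str = "weight") -> tuple[tuple, float]:
    """Minimum-length simple path; lexicographically smallest among ties."""
    pe = suboptimal_paths(network, source, sink, k=1, weight=weight)
    return pe.paths[0], float(pe.lengths[0])


@dataclass
class PathLengthDistribution:
    """Histogram and KDE summary of a path-length ensemble."""

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    peak: float          # center of the max-count bin (leftmost on ties)
    kde_peak: float      # mode of a Gaussian KDE, secondary statistic

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts}).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def path_length_distribution(ensemble: PathEnsemble,
                             bin_width: float = 0.05) -> PathLengthDistribution:
    """Fixed-width histogram anchored at the minimum length, plus a KDE mode."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    L = ensemble.lengths
    lo = float(L.min())
    span = float(L.max()) - lo
    n_bins = max(1, int(np.floor(span / bin_width + 1e-12)) + 1)
    idx = np.minimum((np.floor((L - lo) / bin_width + 1e-12)).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    peak = float(centers[int(np.argmax(counts))])
    if span > 1e-12 and L.size > 1:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(L)
        grid = np.linspace(lo - bin_width, lo + span + bin_width, 512)
        kde_peak = float(grid[int(np.argmax(kde(grid)))])
    else:
        kde_peak = lo
    return PathLengthDistribution(bin_centers=centers, counts=counts,
                                  bin_width=bin_width, peak=peak, kde_peak=kde_peak)


def node_participation(ensemble: PathEnsemble) -> dict[Hashable, int]:
    """Number of paths passing through each node (source/sink appear in all)."""
    counts: dict[Hashable, int] = {}
    for p in ensemble.paths:
        for node in p:
            counts[node] = counts.get(node, 0) + 1
    return counts
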