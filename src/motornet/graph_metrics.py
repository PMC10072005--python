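"""Small-world properties of binary brain networks.

For each binarized network the five base properties are computed —
clustering coefficient C, characteristic path length L, global efficiency
GE, local efficiency LE and transitivity T — plus the normalized ratios
γ = C/C_rand, λ = L/L_rand and small-worldness δ = γ/λ, where C_rand and
L_rand are averaged over an ensemble (default 100) of degree-preserving
Maslov–Sneppen rewirings of the same network.  A small-world network shows
γ > 1, λ ≈ 1 and δ > 1.

Conventions (matching the Brain Connectivity Toolbox):

* a node of degree < 2 contributes C_i = 0;
* L averages shortest-path lengths over *reachable* ordered pairs only, and
  the reachable fraction is reported alongside (a fragmented network at a
  high sparseness threshold would otherwise make L infinite);
* GE uses 1/∞ = 0 for unreachable pairs;
* LE is the plain mean over nodes of the global efficiency of each node's
  neighbour-induced subgraph.

Each metric curve over the threshold sweep is aggregated into a scalar by
trapezoidal integration (the metric "AUC"), giving threshold-independent
subject features.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork

__all__ = [
    "NodeMetrics",
    "SmallWorldMetrics",
    "NormalizedMetrics",
    "MetricProfile",
    "BASE_METRICS",
    "NORMALIZED_METRICS",
    "ALL_METRICS",
    "clustering_coefficient",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "random_reference",
    "normalized_small_world",
    "metric_auc",
    "subject_profile",
]

BASE_METRICS = ("C", "L", "GE", "LE", "T")
NORMALIZED_METRICS = ("gamma", "lambda", "delta")
ALL_METRICS = BASE_METRICS + NORMALIZED_METRICS


@dataclass
class NodeMetrics:
    """Per-node quantities behind the clustering coefficient."""

    degree: np.ndarray  # K_i
    neighbor_edges: np.ndarray  # e_i: edges among node i's neighbours
    clustering: np.ndarray  # C_i = 2 e_i / (K_i (K_i − 1)), 0 when K_i < 2


@dataclass
class SmallWorldMetrics:
    C: float
    L: float
    GE: float
    LE: float
    T: float
    m: int
    reachable_fraction: float


@dataclass
class NormalizedMetrics:
    gamma: float
    lam: float
    delta: float
    c_rand: float
    l_rand: float
    n_random: int


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(float)


def clustering_coefficient(net: BinaryNetwork | np.ndarray) -> tuple[float, NodeMetrics]:
    """Mean node clustering coefficient C and its per-node pieces.

    ``e_i`` (edges among neighbours of i) comes from the diagonal of A³:
    ``2 e_i = (A³)_ii``.
    """
    a = _adj(net)
    k = a.sum(axis=1)
    two_e = np.einsum("ij,jk,ki->i", a, a, a)  # 2·e_i per node
    e = two_e / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, two_e / denom, 0.0)
    return float(ci.mean()), NodeMetrics(degree=k, neighbor_edges=e, clustering=ci)


def shortest_paths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths in edge counts (∞ if unreachable).

    Breadth-first search over the whole graph at once via boolean matrix
    powers — at most diameter-many tiny matmuls, far cheaper than a sparse
    solver for the ≤22-node networks this pipeline handles.
    """
    a = _adj(net) > 0
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = a.copy()
    d = 1
    while d <= n:
        new = frontier & ~reached
        if not new.any():
            break
        dist[new] = d
        reached |= new
        frontier = (frontier.astype(np.uint8) @ a.astype(np.uint8)) > 0
        d += 1
    return dist


def characteristic_path_length(dist: np.ndarray) -> tuple[float, float]:
    """Mean shortest-path length over reachable ordered pairs.

    Returns ``(L, reachable_fraction)``; L is NaN when no pair is reachable
    (empty graph).
    """
    m = dist.shape[0]
    off = ~np.eye(m, dtype=bool)
    finite = np.isfinite(dist) & off
    n_pairs = m * (m - 1)
    if n_pairs == 0 or not finite.any():
        return float("nan"), 0.0
    return float(dist[finite].mean()), float(finite.sum() / n_pairs)


def global_efficiency(dist: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/∞ = 0)."""
    m = dist.shape[0]
    if m < 2:
        return 0.0
    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].sum() / (m * (m - 1)))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph.

    A node with fewer than two neighbours contributes 0.
    """
    a = _adj(net)
    m = a.shape[0]
    total = 0.0
    for i in range(m):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency(shortest_paths(sub))
    return total / m


def transitivity(net: BinaryNetwork | np.ndarray) -> float:
    """Ratio of closed triples (3 × triangles) to connected triples."""
    a = _adj(net)
    k = a.sum(axis=1)
    closed = np.einsum("ij,jk,ki->", a, a, a)  # 6 × triangle count
    triples = (k * (k - 1)).sum()  # 2 × number of connected triples
    if triples == 0:
        return 0.0
    return float(closed / triples)


def small_world_metrics(net: BinaryNetwork | np.ndarray) -> SmallWorldMetrics:
    """All five base properties of one binary network."""
    a = _adj(net)
    c, _ = clustering_coefficient(a)
    dist = shortest_paths(a)
    l, frac = characteristic_path_length(dist)
    return SmallWorldMetrics(
        C=c,
        L=l,
        GE=global_efficiency(dist),
        LE=local_efficiency(a),
        T=transitivity(a),
        m=a.shape[0],
        reachable_fraction=frac,
    )


def random_reference(
    net: BinaryNetwork, seed: int, swaps_per_edge: int = 10
) -> BinaryNetwork:
    """Degree-preserving randomization by Maslov–Sneppen double-edge swaps.

    Attempts ``swaps_per_edge`` swaps per edge (igraph's simple rewiring,
    which rejects self-loops and multi-edges), so the output has exactly the
    input's degree sequence.  Deterministic for a given seed.  A network with
    fewer than two edges cannot be rewired and is returned unchanged with a
    warning.
    """
    n = net.n_nodes
    m = net.n_edges
    if m < 2:
        warnings.warn("fewer than 2 edges: returning the input unchanged")
        return BinaryNetwork(adjacency=net.adjacency.copy(), threshold=net.threshold)
    i, j = np.nonzero(np.triu(net.adjacency, k=1))
    g = ig.Graph(n, list(zip(i.tolist(), j.tolist())))
    ig.set_random_number_generator(random.Random(int(seed)))
    g.rewire(n=swaps_per_edge * m, mode="simple")
    ig.set_random_number_generator(random)  # restore the module default
    adj = np.zeros((n, n), dtype=np.uint8)
    for a, b in g.get_edgelist():
        adj[a, b] = adj[b, a] = 1
    return BinaryNetwork(adjacency=adj, threshold=net.threshold)


def normalized_small_world(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    base: SmallWorldMetrics | None = None,
) -> NormalizedMetrics:
    """γ, λ and δ against an ensemble of degree-matched random references.

    Ensemble members use independent child seeds spawned from ``seed``.  If
    the ensemble mean C or L is zero (or undefined) the ratios are NaN.
    ``base`` may carry precomputed metrics of ``net`` to avoid recomputation.
    """
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    if base is None:
        base = small_world_metrics(net)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31)
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    for r, s in enumerate(child_seeds):
        ref = random_reference(net, seed=int(s), swaps_per_edge=swaps_per_edge)
        cs[r], _ = clustering_coefficient(ref.adjacency)
        ls[r], _ = characteristic_path_length(shortest_paths(ref.adjacency))
    c_rand = float(cs.mean())
    l_rand = float(np.nanmean(ls)) if np.isfinite(ls).any() else float("nan")
    gamma = base.C / c_rand if c_rand > 0 else float("nan")
    lam = base.L / l_rand if (np.isfinite(l_rand) and l_rand > 0) else float("nan")
    delta = gamma / lam if np.isfinite(lam) and lam != 0 else float("nan")
    return NormalizedMetrics(
        gamma=gamma, lam=lam, delta=delta, c_rand=c_rand, l_rand=l_rand, n_random=n_random
    )


def metric_auc(values, grid) -> float:
    """Trapezoidal integral of one metric curve over the threshold grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values and grid must have equal length")
    if values.size < 2:
        raise ValueError("need at least two grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))


@dataclass
class MetricProfile:
    """One subject's metric curves over the sweep plus their AUC features."""

    subject_id: str
    thresholds: np.ndarray
    curves: pd.DataFrame  # index: threshold, columns: metric names
    auc: pd.Series  # index: "<metric>_AUC"

    def feature_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update(self.auc.to_dict())
        return row


def subject_profile(
    networks: list[BinaryNetwork],
    n_random: int = 100,
    seed: int = 0,
    subject_id: str = "subject",
    swaps_per_edge: int = 10,
) -> MetricProfile:
    """Evaluate all metrics on every network of one subject's sweep.

    With ``n_random = 0`` the normalized metrics (γ, λ, δ) are skipped and
    only the five base properties and their AUCs are produced — useful when
    downstream analyses need only C/L/GE/LE/T features.
    """
    if not networks:
        raise ValueError("networks must be non-empty")
    thresholds = np.array([net.threshold for net in networks])
    cols = ALL_METRICS if n_random > 0 else BASE_METRICS
    rows = np.full((len(networks), len(cols)), np.nan)
    for idx, net in enumerate(networks):
        base = small_world_metrics(net)
        vals = [base.C, base.L, base.GE, base.LE, base.T]
        if n_random > 0:
            norm = normalized_small_world(
                net,
                n_random=n_random,
                seed=int(np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31)),
                swaps_per_edge=swaps_per_edge,
                base=base,
            )
            vals += [norm.gamma, norm.lam, norm.delta]
        rows[idx] = vals
    curves = pd.DataFrame(rows, index=pd.Index(thresholds, name="threshold"), columns=list(cols))
    auc = pd.Series(
        {f"{m}_AUC": metric_auc(curves[m].to_numpy(), thresholds) for m in cols}
    )
    return MetricProfile(
        subject_id=subject_id, thresholds=thresholds, curves=curves, auc=auc
    )
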