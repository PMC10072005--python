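"""Functional-connectivity matrices and proportional thresholding.

Channels are network nodes.  Pairwise Pearson correlations of the
preprocessed series are Fisher-Z transformed (variance stabilization /
normality), the diagonal is zeroed, and the weighted matrix is binarized by
*proportional* thresholding: at sparseness threshold ``t`` the strongest
``(1 − t)`` fraction of |Z| values becomes edges, so every subject's network
has the same edge count and group comparisons are not confounded by overall
connectivity strength.  The default sweep covers t = 0.30 … 0.70 in steps of
0.01 (41 networks); by construction the edge sets are nested along the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import HemodynamicRecording

__all__ = [
    "ZMatrix",
    "BinaryNetwork",
    "correlation_matrix",
    "fisher_z",
    "zmatrix_from_recording",
    "proportional_threshold",
    "threshold_sweep",
    "default_threshold_grid",
]

_CLIP = 1.0 - 1e-7


@dataclass
class ZMatrix:
    """Symmetric Fisher-Z connectivity matrix with zero diagonal."""

    z: np.ndarray
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be square")
        if not np.isfinite(self.z).all():
            raise ValueError("z contains non-finite entries")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.labels is None:
            self.labels = [f"Ch{i + 1}" for i in range(self.z.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency at one proportional threshold."""

    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def correlation_matrix(recording: HemodynamicRecording) -> np.ndarray:
    """Pearson correlation between each pair of channels.

    A constant channel has undefined correlations; its row and column are set
    to 0 (diagonal kept at 1) with a warning rather than failing.
    """
    if recording.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    data = recording.data
    sds = data.std(axis=1)
    scale = np.maximum(np.abs(data.mean(axis=1)), 1.0)
    constant = np.flatnonzero(sds <= 1e-12 * scale)
    if constant.size:
        warnings.warn(
            f"constant channel(s) {constant.tolist()}: correlations set to 0"
        )
        data = data.copy()
        # give them unit variance noise-free placeholder to avoid 0/0; zero after
        data[constant] = 0.0
        data[constant, 0] = 1.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r):
    """Fisher's variance-stabilizing transform, ``z = atanh(r)``.

    ``r`` is clipped to ±(1 − 1e−7) first so perfectly correlated pairs map
    to a large finite value instead of infinity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return out if out.ndim else float(out)


def zmatrix_from_recording(recording: HemodynamicRecording) -> ZMatrix:
    """Correlation → Fisher Z → zero diagonal, as one step."""
    z = fisher_z(correlation_matrix(recording))
    np.fill_diagonal(z, 0.0)
    return ZMatrix(z=np.asarray(z), labels=list(recording.channel_labels))


def _ranked_pairs(zmat: ZMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by descending |z|, ties by (row, col)."""
    i, j = np.triu_indices(zmat.n_nodes, k=1)
    absz = np.abs(zmat.z[i, j])
    order = np.lexsort((j, i, -absz))
    return i[order], j[order]


def _n_keep(threshold: float, n_pairs: int) -> int:
    return int(np.floor((1.0 - threshold) * n_pairs + 0.5))


def proportional_threshold(zmat: ZMatrix, threshold: float) -> BinaryNetwork:
    """Binarize by keeping the strongest ``(1 − threshold)`` fraction of |Z|.

    The number of retained edges is ``round((1 − t)·n(n−1)/2)``.  Ties at the
    cut are broken deterministically by ascending (row, column) index, which
    makes sweeps reproducible and their edge sets nested.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    n = zmat.n_nodes
    i, j = _ranked_pairs(zmat)
    keep = _n_keep(threshold, i.size)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[i[:keep], j[:keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, threshold=float(threshold))


def default_threshold_grid(
    lo: float = 0.3, hi: float = 0.7, step: float = 0.01
) -> np.ndarray:
    """Inclusive threshold grid; defaults give the 41-point 0.30…0.70 sweep."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


def threshold_sweep(
    zmat: ZMatrix, lo: float = 0.3, hi: float = 0.7, step: float = 0.01
) -> list[BinaryNetwork]:
    """One binary network per grid point, endpoints inclusive.

    The pair ranking is computed once, so the sweep is consistent:
    the network at a higher threshold is a subgraph of any lower one.
    """
    grid = default_threshold_grid(lo, hi, step)
    n = zmat.n_nodes
    i, j = _ranked_pairs(zmat)
    nets = []
    for t in grid:
        keep = _n_keep(float(t), i.size)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[i[:keep], j[:keep]] = 1
        adj |= adj.T
        nets.append(BinaryNetwork(adjacency=adj, threshold=float(t)))
    return nets
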