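"""Shared-frequency adjacency matrices and small-world network metrics.

Two channels are connected in a given second when their significant
frequency sets intersect; a diagonal entry is set when the channel has at
least one detected oscillation.  From each 19x19 binary matrix the analysis
derives:

- network size: electrodes with at least one inter-electrode connection
  (a lone oscillating electrode is not a network),
- number of connections: nonzero cells of the full matrix (maximum 361);
  the undirected edge count m = (count - trace)/2 feeds the graph
  algorithms,
- the Watts-Strogatz clustering coefficient C and the average shortest path
  length L over the electrodes present (unreachable pairs excluded),
- C and L expressed as fractions of their means over uniform G(n, m) random
  graphs with the same size and edge count, and the small-world index
  SWI = C_rel / L_rel (the raw ratio C_raw / L_raw is reported alongside).

Degenerate matrices (no inter-electrode connection) use the conventions
C = 0, L = 1, SWI = 0; relative metrics are then undefined and flagged as
missing (NaN), and per-epoch averaging skips missing values metric-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .montage import N_CHANNELS
from .spectral import PeakSet

MAX_CONNECTIONS = N_CHANNELS * N_CHANNELS  # 361


@dataclass
class NetworkMetrics:
    """Raw and random-graph-normalised characteristics of one network.

    Fields are floats so that per-epoch and per-window averages share the
    container; missing (undefined) values are NaN.
    """

    network_size: float
    n_connections: float  # nonzero cells of the full 19x19 matrix
    n_edges: float  # undirected inter-electrode edges
    C_raw: float
    L_raw: float
    C_rel: float
    L_rel: float
    SWI: float
    SWI_raw: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_adjacency(peaks: PeakSet | np.ndarray, window: int = 0) -> np.ndarray:
    """Adjacency matrix of one second from per-channel frequency sets.

    ``peaks`` may be a :class:`PeakSet` (with ``window`` selecting the
    second) or a boolean (n_channels, n_freqs) presence matrix.  Entry
    (i, j), i != j, is 1 iff channels i and j share at least one significant
    frequency; entry (i, i) is 1 iff channel i has any detected oscillation.
    """
    if isinstance(peaks, PeakSet):
        presence = peaks.mask[window]
    else:
        presence = np.asarray(peaks, dtype=bool)
    return (presence @ presence.T) > 0


def adjacency_series(peaks: PeakSet) -> np.ndarray:
    """All per-second adjacency matrices of an epoch: (n_windows, 19, 19)."""
    m = peaks.mask
    return np.einsum("tcf,tdf->tcd", m, m, optimize=True) > 0


def _off_diagonal(adj: np.ndarray) -> np.ndarray:
    off = np.array(adj, dtype=bool)
    np.fill_diagonal(off, False)
    return off


def network_size(adj: np.ndarray) -> int:
    """Number of electrodes with at least one inter-electrode connection."""
    return int((_off_diagonal(adj).sum(axis=1) > 0).sum())


def count_connections(adj: np.ndarray) -> int:
    """Nonzero cells of the full matrix (ordered pairs plus diagonal)."""
    return int(np.count_nonzero(adj))


def edge_count(adj: np.ndarray) -> int:
    """Undirected inter-electrode edge count m."""
    return int(_off_diagonal(adj).sum()) // 2


def clustering_coefficient(adj: np.ndarray) -> float:
    """Watts-Strogatz clustering averaged over the electrodes present.

    Per present node with degree k >= 2: realised links among its
    neighbours divided by k(k-1)/2; nodes of degree 1 contribute 0.
    Degenerate networks (size < 2) return 0.
    """
    off = _off_diagonal(adj)
    deg = off.sum(axis=1)
    present = deg > 0
    if present.sum() < 2:
        return 0.0
    sub = off[np.ix_(present, present)].astype(float)
    k = sub.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", sub, sub, sub) / 2.0
    possible = k * (k - 1) / 2.0
    local = np.divide(
        triangles, possible, out=np.zeros_like(triangles), where=possible > 0
    )
    return float(local.mean())


def average_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path distance over reachable pairs of present nodes.

    Unreachable pairs (separate components) are excluded, which keeps L
    finite for disconnected networks.  Degenerate networks return 1.
    """
    off = _off_diagonal(adj)
    present = off.sum(axis=1) > 0
    if present.sum() < 2:
        return 1.0
    sub = off[np.ix_(present, present)]
    dist = shortest_path(csr_matrix(sub), method="D", unweighted=True)
    mask = np.isfinite(dist) & ~np.eye(len(dist), dtype=bool)
    if not mask.any():
        return 1.0
    return float(dist[mask].mean())


class RandomReference:
    """Seeded cache of mean C and L over uniform G(n, m) random graphs.

    The reference for a given (n, m) is the average of
    :func:`clustering_coefficient` and :func:`average_path_length` over
    ``n_rand`` graphs drawn uniformly among all graphs with exactly n nodes
    and m edges, under the same present-node / reachable-pair conventions as
    the observed networks.  Draws are seeded per (n, m) so results do not
    depend on evaluation order.
    """

    def __init__(self, n_rand: int = 50, seed: int = 0) -> None:
        self.n_rand = int(n_rand)
        self.seed = int(seed)
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def mean_metrics(self, n: int, m: int) -> tuple[float, float]:
        if n < 2:
            raise ValueError("random reference needs n >= 2 nodes")
        max_m = n * (n - 1) // 2
        if not 0 <= m <= max_m:
            raise ValueError(f"impossible edge count m={m} for n={n}")
        key = (n, m)
        if key not in self._cache:
            self._cache[key] = self._compute(n, m)
        return self._cache[key]

    def _compute(self, n: int, m: int) -> tuple[float, float]:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(n, m))
        )
        iu, ju = np.triu_indices(n, k=1)
        n_pairs = iu.size
        c_vals = np.empty(self.n_rand)
        l_vals = np.empty(self.n_rand)
        for r in range(self.n_rand):
            pick = rng.choice(n_pairs, size=m, replace=False)
            adj = np.zeros((n, n), dtype=bool)
            adj[iu[pick], ju[pick]] = True
            adj |= adj.T
            c_vals[r] = clustering_coefficient(adj)
            l_vals[r] = average_path_length(adj)
        return float(c_vals.mean()), float(l_vals.mean())


def random_reference(
    n: int, m: int, n_rand: int = 50, seed: int = 0
) -> tuple[float, float]:
    """Mean (C, L) of ``n_rand`` uniform G(n, m) graphs (seeded)."""
    return RandomReference(n_rand=n_rand, seed=seed).mean_metrics(n, m)


def normalized_metrics(
    adj: np.ndarray, reference: RandomReference | None = None
) -> NetworkMetrics:
    """Full metric set of one adjacency matrix.

    C_rel = C_raw / mean C_rand and L_rel = L_raw / mean L_rand against the
    G(n, m) reference; SWI = C_rel / L_rel.  For degenerate networks the
    caption conventions apply (C = 0, L = 1, SWI = 0) and the relative
    metrics are NaN.  C_rel (and hence SWI) is also NaN when the reference
    mean clustering is 0.
    """
    reference = reference or RandomReference()
    adj = np.asarray(adj, dtype=bool)
    size = network_size(adj)
    count = count_connections(adj)
    m = edge_count(adj)
    if size < 2:
        return NetworkMetrics(
            network_size=size, n_connections=count, n_edges=m,
            C_raw=0.0, L_raw=1.0, C_rel=np.nan, L_rel=np.nan,
            SWI=0.0, SWI_raw=0.0,
        )
    c_raw = clustering_coefficient(adj)
    l_raw = average_path_length(adj)
    c_rand, l_rand = reference.mean_metrics(size, m)
    c_rel = c_raw / c_rand if c_rand > 0 else np.nan
    l_rel = l_raw / l_rand
    swi = c_rel / l_rel if np.isfinite(c_rel) else np.nan
    return NetworkMetrics(
        network_size=size, n_connections=count, n_edges=m,
        C_raw=c_raw, L_raw=l_raw, C_rel=c_rel, L_rel=l_rel,
        SWI=swi, SWI_raw=c_raw / l_raw,
    )


def series_metrics(
    adjacencies: np.ndarray, reference: RandomReference | None = None
) -> list[NetworkMetrics]:
    """Metrics for every second of an epoch, deduplicating repeated matrices.

    Steady oscillatory activity produces long runs of identical per-second
    matrices; metrics are computed once per distinct matrix.
    """
    reference = reference or RandomReference()
    adjacencies = np.asarray(adjacencies, dtype=bool)
    n_sec, n_nodes = adjacencies.shape[0], adjacencies.shape[1]
    flat = adjacencies.reshape(n_sec, -1)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    per_unique = [
        normalized_metrics(u.reshape(n_nodes, n_nodes), reference) for u in uniq
    ]
    return [per_unique[i] for i in inverse]


def epoch_metrics(seconds: list[NetworkMetrics]) -> NetworkMetrics:
    """Arithmetic mean of each metric over the seconds of one epoch.

    NaN (missing) values are skipped per metric; a metric missing in every
    second stays missing in the epoch value.
    """
    if not seconds:
        raise ValueError("epoch_metrics needs at least one second")
    out: dict[str, float] = {}
    for f in fields(NetworkMetrics):
        vals = np.array([getattr(s, f.name) for s in seconds], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[f.name] = float(finite.mean()) if finite.size else np.nan
    return NetworkMetrics(**out)
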