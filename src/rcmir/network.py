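"""Mutual-information co-expression networks with clustering-coefficient
threshold selection (the RC-miR construction).

The chain is: equal-frequency discretization of normalized expression ->
plug-in mutual information between miRNA pairs -> mapping of MI onto a
[0, 1) correlation-like similarity -> scan of binarization thresholds tau,
comparing the network's average local clustering coefficient C(tau) against
the Erdos-Renyi expectation Cr(tau) for the same node/edge counts -> the
selected tau* binarizes the similarity matrix into an adjacency matrix whose
connected components (size >= 2) are the reported miRNA clusters.

The rationale of the threshold rule: for a density-matched random graph
C ~ Cr, so a large |C - Cr| indicates non-random local structure.  tau* is
the smallest grid value at which that gap is maximal, i.e. the densest of
the maximally non-random networks along the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class NoThresholdError(RuntimeError):
    """No grid point satisfies the gap condition (e.g. all similarities tie).

    Callers that want a network anyway may pass ``fallback_tau`` to
    :func:`select_threshold`, which is used verbatim when the scan fails.
    """


def equal_frequency_discretize(values, nbins: int) -> np.ndarray:
    """Assign each value to one of ``nbins`` equal-occupancy bins.

    Values are ranked (ties broken by stable order of occurrence) and the
    sorted sequence is cut into contiguous blocks whose sizes differ by at
    most one, the earlier bins taking the extra elements.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    if nbins > n:
        raise ValueError(f"nbins={nbins} exceeds number of values ({n})")
    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, nbins)
    sizes = np.full(nbins, base)
    sizes[:extra] += 1
    labels_sorted = np.repeat(np.arange(nbins), sizes)
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels


def mutual_information(bins_x, bins_y) -> float:
    """Plug-in mutual information (nats) of two discrete label vectors.

    I = sum_xy p(x,y) ln[p(x,y) / (p(x) p(y))] over the empirical joint
    table; non-negative, 0 iff the empirical labels are independent.
    """
    bins_x = np.asarray(bins_x)
    bins_y = np.asarray(bins_y)
    if bins_x.shape != bins_y.shape:
        raise ValueError("label vectors must have equal length")
    n = len(bins_x)
    _, xi = np.unique(bins_x, return_inverse=True)
    _, yi = np.unique(bins_y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(max(0.0, np.sum(joint[nz] * np.log(joint[nz] / outer[nz]))))


def mi_to_similarity(i_nats: float) -> float:
    """Map MI (nats) onto [0, 1): s = sqrt(1 - exp(-2 I)).

    This is the classic MI-to-correlation mapping (exact for bivariate
    Gaussians), monotone in I with s(0) = 0 and s -> 1 as I -> infinity.
    """
    if i_nats < 0:
        raise ValueError("mutual information must be non-negative")
    return float(np.sqrt(1.0 - np.exp(-2.0 * i_nats)))


def similarity_matrix(values: pd.DataFrame, nbins: int | None = None) -> pd.DataFrame:
    """MI-derived similarity between every pair of rows of an expression table.

    ``values`` is miRNA x sample (normalized expression).  Each row is
    discretized with equal-frequency binning; off-diagonal entries are
    mi_to_similarity(MI) and the diagonal is 1.  Default bin count is
    floor(sqrt(n_samples)), but at least 2.
    """
    n_samples = values.shape[1]
    if nbins is None:
        nbins = max(2, int(np.floor(np.sqrt(n_samples))))
    arr = values.to_numpy(dtype=float)
    labels = np.vstack([equal_frequency_discretize(row, nbins) for row in arr])
    n = len(labels)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = mi_to_similarity(
                mutual_information(labels[i], labels[j])
            )
    return pd.DataFrame(s, index=values.index, columns=values.index)


def adjacency(s: pd.DataFrame, tau_star: float) -> pd.DataFrame:
    """Binarize a similarity matrix: a_ij = 1 iff i != j and s_ij > tau (strict)."""
    if not 0.0 <= tau_star <= 1.0:
        raise ValueError("tau_star must lie in [0, 1]")
    a = (s.to_numpy() > tau_star).astype(np.int8)
    np.fill_diagonal(a, 0)
    return pd.DataFrame(a, index=s.index, columns=s.columns)


def clustering_coefficient(a: pd.DataFrame | np.ndarray, nodes=None) -> float:
    """Average local (Watts-Strogatz) clustering coefficient.

    C_i = (edges among neighbors of i) / C(deg_i, 2), with C_i = 0 for
    degree < 2; the mean runs over ``nodes`` (all nodes by default).
    """
    arr = a.to_numpy() if isinstance(a, pd.DataFrame) else np.asarray(a)
    arr = arr.astype(float)
    n = arr.shape[0]
    if n == 0:
        raise ValueError("empty node set")
    deg = arr.sum(axis=1)
    # triangles through each node: diag(A^3)/2
    tri = np.einsum("ij,jk,ki->i", arr, arr, arr) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(deg >= 2, tri / (deg * (deg - 1) / 2.0), 0.0)
    if nodes is None:
        return float(local.mean())
    nodes = np.asarray(nodes)
    if nodes.size == 0:
        return 0.0
    return float(local[nodes].mean())


def expected_random_clustering(n_nodes: int, n_edges: int) -> float:
    """Erdos-Renyi expectation of the clustering coefficient: the edge density.

    For G(n, m) the probability that two neighbors of a node are themselves
    connected is the edge density p = 2m / (n (n - 1)).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceeds complete-graph count {max_edges}")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


@dataclass
class ThresholdScan:
    """Full record of a threshold scan: per-tau statistics and the pick."""

    tau_grid: np.ndarray
    C: np.ndarray
    Cr: np.ndarray
    d: np.ndarray = field(init=False)
    tau_star: float = np.nan

    def __post_init__(self) -> None:
        self.d = np.abs(self.C - self.Cr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.tau_grid, "C": self.C, "Cr": self.Cr, "d": self.d}
        )


def default_tau_grid(step: float = 0.01) -> np.ndarray:
    """The scan grid 0.01, 0.02, ..., 0.99."""
    n = int(round((0.99 - 0.01) / step)) + 1
    return np.round(np.linspace(0.01, 0.99, n), 10)


def select_threshold(
    s: pd.DataFrame,
    grid: np.ndarray | None = None,
    fallback_tau: float | None = None,
) -> ThresholdScan:
    """Scan binarization thresholds and pick tau* by the clustering-gap rule.

    For each tau the adjacency at tau is built and, over nodes of degree >= 1,
    the average local clustering C(tau) and its random expectation Cr(tau)
    (edge density of the same sub-network) are computed.  tau* is the smallest
    grid tau achieving the global maximum of the gap d = |C - Cr|, considered
    only among taus whose network retains at least one edge.  (A density-
    matched random graph has C ~ Cr, so the largest gap marks the most
    non-random network; taking the smallest such tau keeps the densest of the
    equally non-random networks.)

    Raises :class:`NoThresholdError` when the gap is zero everywhere an edge
    survives (e.g. all off-diagonal similarities equal), unless
    ``fallback_tau`` is given, in which case that value is recorded as tau*.
    """
    if grid is None:
        grid = default_tau_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("tau grid must be strictly ascending")
    if grid[0] < 0.01 - 1e-12 or grid[-1] > 0.99 + 1e-12:
        raise ValueError("tau grid must lie within [0.01, 0.99]")

    arr = s.to_numpy()
    m = len(grid)
    C = np.zeros(m)
    Cr = np.zeros(m)
    n_edges = np.zeros(m, dtype=np.int64)
    for v, tau in enumerate(grid):
        a = (arr > tau).astype(float)
        np.fill_diagonal(a, 0)
        deg = a.sum(axis=1)
        connected = np.flatnonzero(deg >= 1)
        n_edges[v] = int(a.sum()) // 2
        if len(connected) < 3:
            # clustering needs a neighbor pair; a lone edge has C undefined
            # and Cr = 1 by density, a guaranteed spurious gap
            C[v] = 0.0
            Cr[v] = 0.0
            continue
        C[v] = clustering_coefficient(a, nodes=connected)
        Cr[v] = expected_random_clustering(len(connected), n_edges[v])

    scan = ThresholdScan(tau_grid=grid, C=C, Cr=Cr)
    d = scan.d
    # candidate set of Eq-style decrease points: d strictly drops at the next
    # grid value and the network still has an edge
    cand = np.flatnonzero((n_edges[:-1] >= 1) & (d[:-1] > d[1:]))
    cand = cand[d[cand] > 0]
    if cand.size:
        best = cand[int(np.argmax(d[cand]))]  # argmax returns first on ties
        scan.tau_star = float(grid[best])
        return scan
    if fallback_tau is not None:
        scan.tau_star = float(fallback_tau)
        return scan
    raise NoThresholdError(
        "no tau shows a strict decrease of the |C - Cr| gap (degenerate "
        "similarities); pass fallback_tau to force a threshold"
    )


@dataclass
class ClusterSet:
    """Connected components of an adjacency matrix, split by size.

    ``clusters`` holds components with >= 2 members ordered by (size
    descending, lexicographically smallest member); ``singletons`` the
    isolated ids, sorted.
    """

    clusters: list[list[str]]
    singletons: list[str]

    def as_dict(self) -> dict:
        return {"clusters": self.clusters, "singletons": self.singletons}


def extract_clusters(a: pd.DataFrame) -> ClusterSet:
    """Connected components of the thresholded network as miRNA clusters."""
    g = nx.from_numpy_array(a.to_numpy())
    mapping = dict(enumerate(a.index))
    g = nx.relabel_nodes(g, mapping)
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters = sorted(
        (c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0])
    )
    singletons = sorted(c[0] for c in comps if len(c) == 1)
    return ClusterSet(clusters=[list(c) for c in clusters], singletons=singletons)


def edge_list(s: pd.DataFrame, a: pd.DataFrame) -> pd.DataFrame:
    """Edges of the thresholded network with their similarities (source < target)."""
    arr = a.to_numpy()
    ii, jj = np.nonzero(np.triu(arr, k=1))
    return pd.DataFrame(
        {
            "source": [a.index[i] for i in ii],
            "target": [a.columns[j] for j in jj],
            "similarity": [s.iat[i, j] for i, j in zip(ii, jj)],
        }
    )
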