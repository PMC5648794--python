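"""Nuclear architecture descriptors from global and cluster graphs.

Global graphs (51 descriptors) are built on nuclear centroids: the Voronoi
diagram (bounded cells only), the Delaunay triangulation, the Euclidean
minimum spanning tree, plus k-nearest-neighbour and fixed-radius density
statistics.  Cluster graphs (26 descriptors) are built on the centroids of
mean-shift nuclear clusters and summarise coarser architecture.

Statistical conventions
-----------------------
* ``std`` is the sample standard deviation (n-1 denominator) everywhere.
* ``minmax_ratio`` = min/max of the summarised quantity, in (0, 1].
* ``disorder`` = 1 - 1/(1 + sigma/mu), a bounded coefficient-of-variation
  transform in [0, 1); 0 iff the values are constant, and scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.spatial import Delaunay, Voronoi, cKDTree
from scipy.spatial.distance import cdist

from .core_io import KNN_KS, NEIGHBOR_RADII, NucleiSet, feature_names

__all__ = [
    "disorder",
    "minmax_ratio",
    "GlobalGraphConfig",
    "ClusterGraphConfig",
    "ClusterGraph",
    "global_graph_features",
    "build_cluster_graph",
    "cluster_graph_features",
    "prim_mst",
]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def disorder(values) -> float:
    """Bounded heterogeneity statistic 1 - 1/(1 + sigma/mu).

    ``sigma`` is the sample (n-1) standard deviation; a single value or a
    zero-mean input yields 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("disorder() needs at least one value")
    mu = v.mean()
    if mu == 0:
        return 0.0
    sigma = v.std(ddof=1) if v.size > 1 else 0.0
    return 1.0 - 1.0 / (1.0 + sigma / mu)


def minmax_ratio(values) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("minmax_ratio() needs at least one value")
    vmax = v.max()
    if vmax == 0:
        return 1.0 if v.min() == 0 else np.nan
    return float(v.min() / vmax)


def _agg4(values) -> tuple[float, float, float, float]:
    """(mean, sample std, min/max ratio, disorder) of a value list."""
    v = np.asarray(values, dtype=float)
    std = v.std(ddof=1) if v.size > 1 else 0.0
    return float(v.mean()), float(std), minmax_ratio(v), disorder(v)


# ---------------------------------------------------------------------------
# Minimum spanning tree (Prim, lexicographic tie-break)
# ---------------------------------------------------------------------------

def prim_mst(points: np.ndarray) -> list[tuple[int, int, float]]:
    """Euclidean MST edges of a point set as (i, j, length), i < j.

    Prim's algorithm grown from node 0; equal-weight frontier edges are broken
    by the smallest (tree-node, new-node) index pair, making the tree
    deterministic under ties.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        return []
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best_dist = d[0].copy()
    best_from = np.zeros(n, dtype=int)
    best_dist[0] = np.inf
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        cand = np.where(~in_tree)[0]
        w = best_dist[cand]
        jmin = w.min()
        ties = cand[w == jmin]
        # lexicographic on (tree index, new index)
        j = ties[np.lexsort((ties, best_from[ties]))[0]]
        i = int(best_from[j])
        a, b = (i, int(j)) if i < j else (int(j), i)
        edges.append((a, b, float(d[i, j])))
        in_tree[j] = True
        closer = d[j] < best_dist
        # strict < keeps the earlier (lexicographically smaller) parent on ties
        best_dist = np.where(closer & ~in_tree, d[j], best_dist)
        best_from = np.where(closer & ~in_tree, j, best_from)
        best_dist[in_tree] = np.inf
    return edges


# ---------------------------------------------------------------------------
# Global graph features (51)
# ---------------------------------------------------------------------------

@dataclass
class GlobalGraphConfig:
    knn_ks: tuple[int, ...] = KNN_KS
    neighbor_radii: tuple[int, ...] = NEIGHBOR_RADII
    coverage_radius: float = 40.0   # px, for the covered-area fraction


def _voronoi_stats(points: np.ndarray) -> dict[str, float]:
    """Area/perimeter/chord statistics over bounded Voronoi cells only."""
    out: dict[str, float] = {}
    vor = Voronoi(points)
    areas, perims, chords = [], [], []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue  # unbounded (hull-adjacent) cell: excluded, not clipped
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        area = 0.5 * abs(np.sum(x * y1 - x1 * y))
        side = np.hypot(x1 - x, y1 - y)
        areas.append(area)
        perims.append(side.sum())
        chords.extend(side.tolist())
    names = ("area", "perimeter", "chord")
    if not areas:
        for metric in names:
            for agg in ("mean", "std", "minmax_ratio", "disorder"):
                out[f"graph_global.voronoi.{metric}_{agg}"] = np.nan
        return out
    for metric, vals in zip(names, (areas, perims, chords)):
        m, s, r, d = _agg4(vals)
        out[f"graph_global.voronoi.{metric}_mean"] = m
        out[f"graph_global.voronoi.{metric}_std"] = s
        out[f"graph_global.voronoi.{metric}_minmax_ratio"] = r
        out[f"graph_global.voronoi.{metric}_disorder"] = d
    return out


def _delaunay_stats(points: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    tri = Delaunay(points)
    edges = set()
    areas = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        u, v = b - a, c - a
        areas.append(0.5 * abs(u[0] * v[1] - u[1] * v[0]))
        for i in range(3):
            u, v = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((u, v))
    sides = [float(np.linalg.norm(points[u] - points[v])) for u, v in sorted(edges)]
    for metric, vals in (("side", sides), ("area", areas)):
        m, s, r, d = _agg4(vals)
        out[f"graph_global.delaunay.{metric}_mean"] = m
        out[f"graph_global.delaunay.{metric}_std"] = s
        out[f"graph_global.delaunay.{metric}_minmax_ratio"] = r
        out[f"graph_global.delaunay.{metric}_disorder"] = d
    return out


def _coverage_fraction(points: np.ndarray, image_size: tuple[int, int], radius: float) -> float:
    """Fraction of image pixels within ``radius`` of some centroid."""
    w, h = image_size
    mask = np.zeros((h, w), dtype=bool)
    from skimage.draw import disk

    for x, y in points:
        rr, cc = disk((y, x), radius, shape=(h, w))
        mask[rr, cc] = True
    return float(mask.mean())


def global_graph_features(
    nuclei: NucleiSet, config: GlobalGraphConfig | None = None
) -> dict[str, float]:
    """The 51 global-graph architecture descriptors, in registry order."""
    config = config or GlobalGraphConfig()
    names = feature_names("graph_global")
    pts = nuclei.centroids
    n = len(pts)

    degenerate = n < 4
    if not degenerate:
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            degenerate = True
    if degenerate:
        warnings.warn(
            f"spot {nuclei.spot_id}: fewer than 4 non-collinear centroids; "
            "global graph features are NaN"
        )
        return {name: np.nan for name in names}

    out: dict[str, float] = {}
    out.update(_voronoi_stats(pts))
    out.update(_delaunay_stats(pts))

    mst_lengths = [e[2] for e in prim_mst(pts)]
    m, s, r, d = _agg4(mst_lengths)
    out["graph_global.mst.edge_mean"] = m
    out["graph_global.mst.edge_std"] = s
    out["graph_global.mst.edge_minmax_ratio"] = r
    out["graph_global.mst.edge_disorder"] = d

    tree = cKDTree(pts)
    for k in config.knn_ks:
        if n < k + 1:
            for agg in ("mean", "std", "disorder"):
                out[f"graph_global.density.nn{k}_dist_{agg}"] = np.nan
            continue
        dist, _ = tree.query(pts, k=k + 1)
        dk = dist[:, k]  # distance to the k-th neighbour (excluding self)
        out[f"graph_global.density.nn{k}_dist_mean"] = float(dk.mean())
        out[f"graph_global.density.nn{k}_dist_std"] = float(dk.std(ddof=1))
        out[f"graph_global.density.nn{k}_dist_disorder"] = disorder(dk)

    for radius in config.neighbor_radii:
        counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in pts], dtype=float)
        out[f"graph_global.density.neighbors_r{radius}_mean"] = float(counts.mean())
        out[f"graph_global.density.neighbors_r{radius}_std"] = float(counts.std(ddof=1))
        out[f"graph_global.density.neighbors_r{radius}_disorder"] = disorder(counts)

    w, h = nuclei.image_size
    out["graph_global.density.nuclei_count"] = float(n)
    out["graph_global.density.nuclei_per_10kpx2"] = float(n / (w * h) * 1e4)
    out["graph_global.density.area_fraction_r40"] = _coverage_fraction(
        pts, nuclei.image_size, config.coverage_radius
    )

    return {name: out[name] for name in names}


# ---------------------------------------------------------------------------
# Cluster graph
# ---------------------------------------------------------------------------

@dataclass
class ClusterGraphConfig:
    bandwidth: float = 40.0        # px, flat-kernel mean-shift bandwidth
    alpha: float = 0.5             # decay exponent of the linking rule
    link_threshold: float = 0.1    # clusters u,v linked iff d(u,v)^(-alpha) >= threshold


@dataclass
class ClusterGraph:
    """Mean-shift nuclear clusters and the deterministic link graph on them."""

    clusters: list[dict] = field(default_factory=list)  # {"member_ids": [...], "centroid": (x, y)}
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    image_size: tuple[int, int] = (0, 0)

    @property
    def centroids(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 2))
        return np.array([c["centroid"] for c in self.clusters])

    def membership(self) -> dict[str, int]:
        return {
            nid: ci for ci, c in enumerate(self.clusters) for nid in c["member_ids"]
        }


def flat_meanshift_labels(pts: np.ndarray, bandwidth: float) -> np.ndarray:
    """Flat-kernel mean-shift clustering of 2-D points (deterministic).

    Every point climbs to the mean of the points within ``bandwidth`` of its
    current position until convergence; converged modes within one bandwidth
    of each other are merged greedily in decreasing order of support (ties by
    point index), and each point is assigned to its nearest retained mode.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if n == 1:
        return np.zeros(1, dtype=int)
    modes = pts.copy()
    for _ in range(300):
        within = cdist(modes, pts) <= bandwidth
        new = (within @ pts) / within.sum(axis=1, keepdims=True)
        if np.abs(new - modes).max() < 1e-3 * bandwidth:
            modes = new
            break
        modes = new
    support = (cdist(modes, pts) <= bandwidth).sum(axis=1)
    order = np.lexsort((np.arange(n), -support))
    keep: list[int] = []
    suppressed = np.zeros(n, dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed |= np.linalg.norm(modes - modes[i], axis=1) < bandwidth
    centers = modes[keep]
    raw = np.argmin(cdist(pts, centers), axis=1)
    # relabel in order of first appearance for determinism
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(int(r), len(relabel))
    return labels


def build_cluster_graph(
    nuclei: NucleiSet, config: ClusterGraphConfig | None = None
) -> ClusterGraph:
    """Cluster nuclei by flat-kernel mean-shift and link nearby clusters.

    Edge rule: clusters u, v are connected iff d(u, v)^(-alpha) >= threshold,
    i.e. iff d(u, v) <= threshold^(-1/alpha).  Deterministic given config.
    """
    if len(nuclei) == 0:
        raise ValueError("build_cluster_graph needs at least one nucleus")
    config = config or ClusterGraphConfig()
    pts = nuclei.centroids
    ids = [n.nucleus_id for n in nuclei.nuclei]

    labels = flat_meanshift_labels(pts, config.bandwidth)

    clusters = []
    for lab in sorted(set(labels.tolist())):
        member_idx = np.where(labels == lab)[0]
        centroid = pts[member_idx].mean(axis=0)
        clusters.append(
            {"member_ids": [ids[i] for i in member_idx], "centroid": tuple(centroid)}
        )

    centroids = np.array([c["centroid"] for c in clusters])
    edges = []
    max_dist = config.link_threshold ** (-1.0 / config.alpha)
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            d = float(np.linalg.norm(centroids[i] - centroids[j]))
            if d > 0 and d <= max_dist:
                edges.append((i, j, d))
    return ClusterGraph(clusters=clusters, edges=edges, image_size=nuclei.image_size)


# ---------------------------------------------------------------------------
# Cluster graph features (26)
# ---------------------------------------------------------------------------

def _component_weighted(G: nx.Graph, per_component) -> tuple[float, float, float, float, int]:
    """(mean eccentricity, diameter, radius, mean path length, central count).

    Path metrics are computed per connected component (hop counts) and
    averaged with component node counts as weights; singleton components
    contribute zeros.  ``central count`` is the number of nodes whose
    eccentricity equals their component's radius.
    """
    n = G.number_of_nodes()
    if n == 0:
        return 0.0, 0.0, 0.0, 0.0, 0
    ecc_sum = 0.0
    diam_w = 0.0
    rad_w = 0.0
    apl_w = 0.0
    central = 0
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        k = sub.number_of_nodes()
        if k == 1:
            central += 1
            continue
        ecc = nx.eccentricity(sub)
        vals = np.array(list(ecc.values()), dtype=float)
        ecc_sum += vals.sum()
        diam = vals.max()
        rad = vals.min()
        diam_w += k * diam
        rad_w += k * rad
        apl_w += k * nx.average_shortest_path_length(sub)
        central += int((vals == rad).sum())
    return ecc_sum / n, diam_w / n, rad_w / n, apl_w / n, central


def cluster_graph_features(
    cg: ClusterGraph, image_size: tuple[int, int] | None = None
) -> dict[str, float]:
    """The 26 cluster-graph descriptors, in registry order.

    Edgeless graphs yield 0 for all path/eccentricity features by convention.
    Clustering coefficients: C = mean local transitivity over all nodes,
    D = global transitivity (3 x triangles / connected triples), E = mean
    local transitivity restricted to nodes of degree >= 2.
    """
    image_size = image_size or cg.image_size
    w, h = image_size
    k = len(cg.clusters)
    if k == 0:
        raise ValueError("cluster graph has no clusters")

    G = nx.Graph()
    G.add_nodes_from(range(k))
    G.add_weighted_edges_from(cg.edges, weight="length")
    degrees = np.array([G.degree(i) for i in range(k)], dtype=float)

    out: dict[str, float] = {}
    out["graph_cluster.node_count"] = float(k)
    out["graph_cluster.edge_count"] = float(G.number_of_edges())
    out["graph_cluster.degree_mean"] = float(degrees.mean())

    ecc_mean, diam, rad, apl, central = _component_weighted(G, None)
    out["graph_cluster.eccentricity_mean"] = ecc_mean
    out["graph_cluster.diameter"] = diam
    out["graph_cluster.radius"] = rad

    # induced subgraph on the ceil(0.9 k) largest-degree nodes
    order = np.lexsort((np.arange(k), -degrees))
    keep = order[: int(np.ceil(0.9 * k))]
    sub = G.subgraph(keep.tolist())
    ecc90, diam90, rad90, _, _ = _component_weighted(sub, None)
    out["graph_cluster.eccentricity_mean_core90"] = ecc90
    out["graph_cluster.diameter_core90"] = diam90
    out["graph_cluster.radius_core90"] = rad90

    out["graph_cluster.path_length_mean"] = apl
    out["graph_cluster.clustering_c"] = float(nx.average_clustering(G)) if k > 0 else 0.0
    out["graph_cluster.clustering_d"] = float(nx.transitivity(G))
    deg2 = [i for i in range(k) if degrees[i] >= 2]
    out["graph_cluster.clustering_e"] = (
        float(np.mean([nx.clustering(G, i) for i in deg2])) if deg2 else 0.0
    )

    comps = list(nx.connected_components(G))
    out["graph_cluster.component_count"] = float(len(comps))
    out["graph_cluster.giant_component_ratio"] = float(max(len(c) for c in comps) / k)
    out["graph_cluster.isolated_pct"] = float(100.0 * (degrees == 0).sum() / k)
    out["graph_cluster.end_node_pct"] = float(100.0 * (degrees == 1).sum() / k)
    out["graph_cluster.central_point_count"] = float(central)
    out["graph_cluster.central_point_pct"] = float(100.0 * central / k)

    lengths = np.array([e[2] for e in cg.edges], dtype=float)
    if lengths.size:
        out["graph_cluster.edge_length_mean"] = float(lengths.mean())
        out["graph_cluster.edge_length_std"] = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
        out["graph_cluster.edge_length_skewness"] = (
            float(sps.skew(lengths)) if lengths.size > 2 else 0.0
        )
        out["graph_cluster.edge_length_kurtosis"] = (
            float(sps.kurtosis(lengths)) if lengths.size > 3 else 0.0
        )
    else:
        for nm in ("mean", "std", "skewness", "kurtosis"):
            out[f"graph_cluster.edge_length_{nm}"] = 0.0

    sizes = np.array([len(c["member_ids"]) for c in cg.clusters], dtype=float)
    out["graph_cluster.cluster_size_mean"] = float(sizes.mean())
    out["graph_cluster.cluster_size_std"] = float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0
    out["graph_cluster.clusters_per_10kpx2"] = float(k / (w * h) * 1e4) if w and h else np.nan

    return {name: out[name] for name in feature_names("graph_cluster")}
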