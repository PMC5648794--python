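"""Per-nucleus shape, orientation co-occurrence, and chromatin texture features.

Shape (100 descriptors): 25 per-nucleus base descriptors — 15 geometric plus
the magnitudes of Fourier shape descriptors 1..10 of the centroid-to-boundary
radius signal — each aggregated across nuclei by mean, standard deviation,
median and min/max ratio.

Orientation (39): the long-axis direction of every nucleus (principal axis of
its boundary points, folded to [0, 180) degrees) is quantised into B bins; for
every nuclear cluster a B x B co-occurrence matrix over all unordered
within-cluster pairs is formed and 13 second-order statistics computed, then
aggregated across clusters by mean, median and std.

Texture (26): a gray-level co-occurrence matrix is accumulated inside each
nuclear mask (global-spot equal-width quantisation, symmetric offsets at
distance 1) and the same 13 statistics are summarised across nuclei by mean
and std.

All entropic quantities use log base 2 with 0*log(0) = 0.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage.color import rgb2gray
from skimage.draw import polygon as draw_polygon

from .core_io import (
    HARALICK_STATS,
    SHAPE_BASE_DESCRIPTORS,
    NucleiSet,
    NucleusBoundary,
    SpotImage,
    feature_names,
)
from .graph_features import ClusterGraph, minmax_ratio

__all__ = [
    "resample_boundary",
    "fourier_shape_descriptors",
    "shape_base_descriptors",
    "shape_features",
    "nucleus_orientation",
    "OrientationResult",
    "orientation_cooccurrence",
    "cooccurrence_stats_13",
    "orientation_entropy_features",
    "texture_features",
    "DEFAULT_OFFSETS",
]


# ---------------------------------------------------------------------------
# Boundary resampling and Fourier shape descriptors
# ---------------------------------------------------------------------------

def resample_boundary(vertices: np.ndarray, n_points: int = 128) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` equal arc-length samples.

    The traversal starts at the vertex farthest from the area centroid, which
    makes the sampling — and hence every statistic computed from it —
    independent of which vertex the stored ring happens to start at.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("boundary needs at least 3 vertices")
    centroid = Polygon(v).centroid
    c = np.array([centroid.x, centroid.y])
    r = np.linalg.norm(v - c, axis=1)
    start = int(np.argmax(r))
    v = np.roll(v, -start, axis=0)

    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        raise ValueError("degenerate zero-length boundary")
    t = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(t, arc, closed[:, 0])
    y = np.interp(t, arc, closed[:, 1])
    return np.column_stack([x, y])


def fourier_shape_descriptors(
    boundary: NucleusBoundary | np.ndarray, n_points: int = 128, n_fsd: int = 10
) -> np.ndarray:
    """FSD_k = |F_k| / |F_0| of the centroid-to-boundary radius signal.

    The boundary is resampled to ``n_points`` equal arc-length samples; the
    distance of each sample to the area centroid forms a periodic signal whose
    DFT magnitudes, normalised by the DC term, are invariant to translation,
    rotation, scaling and the stored start vertex.
    """
    verts = boundary.vertices if isinstance(boundary, NucleusBoundary) else np.asarray(boundary)
    pts = resample_boundary(verts, n_points=n_points)
    centroid = Polygon(verts).centroid
    r = np.linalg.norm(pts - np.array([centroid.x, centroid.y]), axis=1)
    spec = np.abs(np.fft.rfft(r))
    if spec[0] == 0:
        raise ValueError("degenerate boundary: zero mean radius")
    return spec[1 : n_fsd + 1] / spec[0]


# ---------------------------------------------------------------------------
# Per-nucleus geometric descriptors
# ---------------------------------------------------------------------------

def _curvature_mean_sq(pts: np.ndarray) -> float:
    """Mean squared curvature of a closed, equal-arc-length sampled boundary."""
    n = len(pts)
    ds = np.linalg.norm(pts[1] - pts[0])  # uniform spacing
    if ds == 0:
        return 0.0
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    d1 = (nxt - prev) / (2 * ds)
    d2 = (nxt - 2 * pts + prev) / (ds * ds)
    num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    kappa = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    return float(np.mean(kappa**2))


def shape_base_descriptors(
    boundary: NucleusBoundary, n_points: int = 128, n_fsd: int = 10
) -> dict[str, float]:
    """The 25 per-nucleus base shape descriptors (see module docstring)."""
    poly = Polygon(boundary.vertices)
    area = poly.area
    perim = poly.length
    if area <= 0 or perim <= 0:
        raise ValueError(f"nucleus {boundary.nucleus_id}: degenerate polygon")

    pts = resample_boundary(boundary.vertices, n_points=n_points)
    c = np.array([poly.centroid.x, poly.centroid.y])
    radii = np.linalg.norm(pts - c, axis=1)

    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.maximum(evals, 0.0)
    # boundary points of an ellipse have variance a^2/2 along the major axis
    major = 2.0 * np.sqrt(2.0 * evals[0])
    minor = 2.0 * np.sqrt(2.0 * evals[1])
    ecc = np.sqrt(max(0.0, 1.0 - (evals[1] / evals[0]))) if evals[0] > 0 else 0.0

    hull = poly.convex_hull
    minx, miny, maxx, maxy = poly.bounds
    bbox_area = (maxx - minx) * (maxy - miny)

    fsd = fourier_shape_descriptors(boundary, n_points=n_points, n_fsd=n_fsd)

    out = {
        "area": float(area),
        "perimeter": float(perim),
        "equivalent_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "min_radius": float(radii.min()),
        "max_radius": float(radii.max()),
        "mean_radius": float(radii.mean()),
        "radius_std": float(radii.std(ddof=1)),
        "major_axis": float(major),
        "minor_axis": float(minor),
        "eccentricity": float(ecc),
        "compactness": float(min(1.0, 4.0 * np.pi * area / perim**2)),
        "solidity": float(area / hull.area) if hull.area > 0 else np.nan,
        "extent": float(area / bbox_area) if bbox_area > 0 else np.nan,
        "convex_perimeter_ratio": float(hull.length / perim),
        "bending_energy": _curvature_mean_sq(pts),
    }
    for k in range(1, n_fsd + 1):
        out[f"fsd{k}"] = float(fsd[k - 1])
    assert tuple(out.keys()) == SHAPE_BASE_DESCRIPTORS
    return out


def shape_features(nuclei: NucleiSet, n_points: int = 128) -> dict[str, float]:
    """The 100 spot-level shape descriptors, in registry order.

    Per-nucleus failures skip that nucleus with a warning; fewer than 2 valid
    nuclei yield NaN for every aggregate.
    """
    names = feature_names("shape")
    per_nucleus: list[dict[str, float]] = []
    for n in nuclei.nuclei:
        try:
            per_nucleus.append(shape_base_descriptors(n, n_points=n_points))
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"skipping nucleus {n.nucleus_id}: {exc}")
    if len(per_nucleus) < 2:
        warnings.warn(f"spot {nuclei.spot_id}: <2 valid nuclei; shape features are NaN")
        return {name: np.nan for name in names}

    out: dict[str, float] = {}
    for base in SHAPE_BASE_DESCRIPTORS:
        vals = np.array([d[base] for d in per_nucleus], dtype=float)
        out[f"shape.{base}_mean"] = float(vals.mean())
        out[f"shape.{base}_std"] = float(vals.std(ddof=1))
        out[f"shape.{base}_median"] = float(np.median(vals))
        out[f"shape.{base}_minmax_ratio"] = minmax_ratio(vals)
    return {name: out[name] for name in names}


# ---------------------------------------------------------------------------
# Nuclear orientation
# ---------------------------------------------------------------------------

class OrientationResult(NamedTuple):
    angle_deg: float        # principal-axis direction in [0, 180)
    axis_ratio: float       # sqrt(lambda1 / lambda2) >= 1
    low_confidence: bool    # True when the nucleus is nearly isotropic


def nucleus_orientation(
    boundary: NucleusBoundary, n_points: int = 128, isotropy_ratio: float = 1.05
) -> OrientationResult:
    """Long-axis direction of a nucleus via PCA of its boundary points.

    The angle of the first principal axis of the (equal arc-length resampled)
    vertex cloud, folded to [0, 180) degrees.  Nuclei whose eigenvalue ratio
    falls below ``isotropy_ratio`` are flagged low-confidence: their
    orientation is numerically defined but not biologically meaningful.
    """
    pts = resample_boundary(boundary.vertices, n_points=n_points)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order: principal axis is the last column
    v = evecs[:, 1]
    lam1, lam2 = float(evals[1]), float(evals[0])
    angle = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    ratio = np.sqrt(lam1 / lam2) if lam2 > 0 else np.inf
    low_conf = (lam1 / max(lam2, 1e-300)) < isotropy_ratio
    return OrientationResult(float(angle), float(ratio), bool(low_conf))


def orientation_cooccurrence(angles_deg: Sequence[float], bins: int = 10) -> np.ndarray:
    """Symmetric, normalised B x B co-occurrence of quantised orientations.

    Orientations in [0, 180) are quantised into ``bins`` equal bins; every
    unordered pair of nuclei increments the matrix symmetrically.
    """
    a = np.asarray(angles_deg, dtype=float) % 180.0
    if len(a) < 2:
        raise ValueError("orientation co-occurrence needs at least 2 angles")
    q = np.minimum((a / 180.0 * bins).astype(int), bins - 1)
    P = np.zeros((bins, bins))
    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            P[q[i], q[j]] += 1.0
            P[q[j], q[i]] += 1.0
    return P / P.sum()


# ---------------------------------------------------------------------------
# The 13 second-order co-occurrence statistics
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def cooccurrence_stats_13(P: np.ndarray) -> dict[str, float]:
    """The 13 second-order statistics of a normalised symmetric matrix.

    Contrast statistics are moments/entropy of the |i-j| difference
    distribution; intensity statistics are moments/entropy of the i+j sum
    distribution.  Entropies are in bits; the correlation of a matrix with a
    degenerate marginal is 0 by convention.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if np.any(P < 0) or not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix must be nonnegative and sum to 1")

    B = P.shape[0]
    i = np.arange(B)[:, None]
    j = np.arange(B)[None, :]
    diff = np.abs(i - j)
    summ = i + j

    p_diff = np.zeros(B)
    np.add.at(p_diff, diff.ravel(), P.ravel())
    p_sum = np.zeros(2 * B - 1)
    np.add.at(p_sum, summ.ravel(), P.ravel())

    k_d = np.arange(B)
    k_s = np.arange(2 * B - 1)
    c_avg = float((k_d * p_diff).sum())
    i_avg = float((k_s * p_sum).sum())

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(B) * px).sum())
    mu_y = float((np.arange(B) * py).sum())
    var_x = float(((np.arange(B) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(B) - mu_y) ** 2 * py).sum())

    H = -float(_xlog2(P).sum())
    HX = -float(_xlog2(px).sum())
    HY = -float(_xlog2(py).sum())
    pxy = px[:, None] * py[None, :]
    mask = (P > 0) & (pxy > 0)
    HXY1 = -float((P[mask] * np.log2(pxy[mask])).sum())
    HXY2 = -float(_xlog2(pxy).sum())

    if var_x > 0 and var_y > 0:
        corr = (float((i * j * P).sum()) - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        corr = 0.0

    denom = max(HX, HY)
    imc1 = (H - HXY1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - H)))))

    out = {
        "contrast_energy": float(((i - j) ** 2 * P).sum()),
        "contrast_inverse_moment": float((P / (1.0 + (i - j) ** 2)).sum()),
        "contrast_average": c_avg,
        "contrast_variance": float(((k_d - c_avg) ** 2 * p_diff).sum()),
        "contrast_entropy": -float(_xlog2(p_diff).sum()),
        "intensity_average": i_avg,
        "intensity_variance": float(((k_s - i_avg) ** 2 * p_sum).sum()),
        "intensity_entropy": -float(_xlog2(p_sum).sum()),
        "entropy": H,
        "energy": float((P**2).sum()),
        "correlation": float(corr),
        "info_measure_1": float(imc1),
        "info_measure_2": imc2,
    }
    assert tuple(out.keys()) == HARALICK_STATS
    return out


# ---------------------------------------------------------------------------
# Orientation entropy features (39)
# ---------------------------------------------------------------------------

def orientation_entropy_features(
    nuclei: NucleiSet,
    cg: ClusterGraph,
    bins: int = 10,
    angles: dict[str, float] | None = None,
) -> dict[str, float]:
    """13 orientation co-occurrence statistics per cluster, aggregated by
    mean / median / std across clusters (39 values, registry order).

    Clusters with fewer than 2 member nuclei contribute nothing; if no cluster
    qualifies the features are NaN.  ``angles`` may carry precomputed
    orientations keyed by nucleus_id.
    """
    names = feature_names("orientation")
    if angles is None:
        angles = {
            n.nucleus_id: nucleus_orientation(n).angle_deg for n in nuclei.nuclei
        }

    per_cluster: list[dict[str, float]] = []
    for cluster in cg.clusters:
        member_angles = [angles[nid] for nid in cluster["member_ids"] if nid in angles]
        if len(member_angles) < 2:
            continue
        P = orientation_cooccurrence(member_angles, bins=bins)
        per_cluster.append(cooccurrence_stats_13(P))

    if not per_cluster:
        warnings.warn(f"spot {nuclei.spot_id}: no cluster with >=2 nuclei; orientation features are NaN")
        return {name: np.nan for name in names}

    out: dict[str, float] = {}
    for stat in HARALICK_STATS:
        vals = np.array([d[stat] for d in per_cluster], dtype=float)
        out[f"orientation.{stat}_mean"] = float(vals.mean())
        out[f"orientation.{stat}_median"] = float(np.median(vals))
        out[f"orientation.{stat}_std"] = (
            float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        )
    return {name: out[name] for name in names}


# ---------------------------------------------------------------------------
# Texture features (26)
# ---------------------------------------------------------------------------

#: symmetric pixel offsets (dy, dx) at distance 1
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _nucleus_glcm(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, offsets
) -> np.ndarray | None:
    """Accumulate a symmetric GLCM over the masked pixels; None if no pairs."""
    P = np.zeros((n_levels, n_levels))
    h, w = mask.shape
    for dy, dx in offsets:
        ys, xs = np.nonzero(mask)
        y2, x2 = ys + dy, xs + dx
        ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
        ok[ok] &= mask[y2[ok], x2[ok]]
        a = levels[ys[ok], xs[ok]]
        b = levels[y2[ok], x2[ok]]
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total == 0:
        return None
    return P / total


def texture_features(
    image: SpotImage,
    nuclei: NucleiSet,
    gray_levels: int = 16,
    offsets=DEFAULT_OFFSETS,
    min_mask_px: int = 16,
) -> dict[str, float]:
    """The 26 spot-level chromatin texture descriptors, in registry order.

    Luminance pixels inside each nuclear polygon are quantised to
    ``gray_levels`` by equal-width binning over the range of all nuclear
    pixels in the spot; a symmetric GLCM per nucleus over the given offsets
    yields 13 statistics, aggregated across nuclei by mean and std.
    """
    names = feature_names("texture")
    gray = rgb2gray(image.pixels) * 255.0
    h, w = gray.shape

    masks: list[tuple[str, np.ndarray, np.ndarray]] = []  # (id, rows, cols)
    all_vals = []
    for n in nuclei.nuclei:
        rr, cc = draw_polygon(n.vertices[:, 1], n.vertices[:, 0], shape=(h, w))
        if len(rr) < min_mask_px:
            warnings.warn(f"nucleus {n.nucleus_id}: mask < {min_mask_px} px, skipped")
            continue
        masks.append((n.nucleus_id, rr, cc))
        all_vals.append(gray[rr, cc])

    if len(masks) < 1:
        warnings.warn(f"spot {nuclei.spot_id}: no usable nuclear masks; texture features are NaN")
        return {name: np.nan for name in names}

    vmin = min(v.min() for v in all_vals)
    vmax = max(v.max() for v in all_vals)
    if vmax > vmin:
        levels = np.clip(
            ((gray - vmin) / (vmax - vmin) * gray_levels).astype(int), 0, gray_levels - 1
        )
    else:
        levels = np.zeros_like(gray, dtype=int)

    per_nucleus: list[dict[str, float]] = []
    for nid, rr, cc in masks:
        y0, y1 = rr.min(), rr.max() + 1
        x0, x1 = cc.min(), cc.max() + 1
        local_mask = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        local_mask[rr - y0, cc - x0] = True
        P = _nucleus_glcm(levels[y0:y1, x0:x1], local_mask, gray_levels, offsets)
        if P is None:
            warnings.warn(f"nucleus {nid}: no co-occurring pixel pairs, skipped")
            continue
        per_nucleus.append(cooccurrence_stats_13(P))

    if not per_nucleus:
        warnings.warn(f"spot {nuclei.spot_id}: no usable nuclear masks; texture features are NaN")
        return {name: np.nan for name in names}

    out: dict[str, float] = {}
    for stat in HARALICK_STATS:
        vals = np.array([d[stat] for d in per_nucleus], dtype=float)
        out[f"texture.{stat}_mean"] = float(vals.mean())
        out[f"texture.{stat}_std"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {name: out[name] for name in names}
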