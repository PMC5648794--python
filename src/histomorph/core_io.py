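"""Domain types, the canonical feature-name registry, and artifact I/O.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based with ``x`` = column and ``y`` = row, origin at
  the top-left of the image.  Polygons are stored counter-clockwise in the
  (x, y) sense (positive shoelace area).
* All distances are in pixels.  ``microns_per_pixel`` is carried as metadata
  only (default 0.5, the usual 20x scanning convention) and never enters a
  feature formula.
* The feature registry below is the single source of truth for feature names,
  their category, and their order.  Every extractor emits exactly the registry
  names of its category, in registry order, and a full feature vector always
  has 242 entries: 51 global-graph, 26 cluster-graph, 100 shape,
  39 orientation and 26 texture descriptors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "SpotImage",
    "NucleusBoundary",
    "NucleiSet",
    "FeatureVector",
    "ClinicalRecord",
    "CATEGORIES",
    "CATEGORY_COUNTS",
    "HARALICK_STATS",
    "SHAPE_BASE_DESCRIPTORS",
    "DISPLAY_NAMES",
    "feature_registry",
    "feature_names",
    "category_of",
    "read_nuclei",
    "write_nuclei",
    "read_feature_table",
    "write_feature_table",
    "read_clinical",
    "write_clinical",
    "save_model",
    "load_model",
    "CLINICAL_COLUMNS",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpotImage:
    """One RGB TMA-spot raster (8 bit per channel)."""

    pixels: np.ndarray
    spot_id: str
    microns_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SpotImage requires an (H, W, 3) RGB array")
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise ValueError("SpotImage must be at least 64x64 pixels")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return self.pixels.shape[1], self.pixels.shape[0]


def _polygon_centroid_area(vertices: np.ndarray) -> tuple[np.ndarray, float]:
    """Area centroid and signed shoelace area of a closed polygon (open ring)."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        return vertices.mean(axis=0), 0.0
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    return np.array([cx, cy]), area


@dataclass
class NucleusBoundary:
    """Closed simple polygon outlining one nucleus, plus its area centroid.

    ``vertices`` is an (n, 2) float array of (x, y) pixel coordinates, stored
    as an open ring (the closing edge is implicit), counter-clockwise.
    """

    nucleus_id: str
    vertices: np.ndarray
    centroid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError(f"nucleus {self.nucleus_id}: vertices must be (n, 2)")
        if len(self.vertices) >= 2 and np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 8:
            raise ValueError(
                f"nucleus {self.nucleus_id}: polygon needs >= 8 vertices, "
                f"got {len(self.vertices)}"
            )
        centroid, area = _polygon_centroid_area(self.vertices)
        if area < 0:  # stored clockwise -> flip to counter-clockwise
            self.vertices = self.vertices[::-1]
            centroid, area = _polygon_centroid_area(self.vertices)
        if area <= 0:
            raise ValueError(f"nucleus {self.nucleus_id}: polygon area must be positive")
        if self.centroid is None:
            self.centroid = centroid
        else:
            self.centroid = np.asarray(self.centroid, dtype=float)
            if not np.allclose(self.centroid, centroid, atol=1e-6):
                raise ValueError(
                    f"nucleus {self.nucleus_id}: centroid does not match the "
                    f"polygon area-centroid"
                )

    def validate_simple(self) -> None:
        """Raise if the polygon self-intersects (shapely validity check)."""
        if not Polygon(self.vertices).is_valid:
            raise ValueError(f"nucleus {self.nucleus_id}: polygon is self-intersecting")

    @property
    def area(self) -> float:
        return _polygon_centroid_area(self.vertices)[1]


@dataclass
class NucleiSet:
    """All segmented nuclear boundaries of one TMA spot."""

    spot_id: str
    nuclei: list[NucleusBoundary]
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        ids = [n.nucleus_id for n in self.nuclei]
        if len(set(ids)) != len(ids):
            raise ValueError(f"spot {self.spot_id}: nucleus_ids are not unique")
        w, h = self.image_size
        for n in self.nuclei:
            v = n.vertices
            if v[:, 0].min() < 0 or v[:, 0].max() >= w or v[:, 1].min() < 0 or v[:, 1].max() >= h:
                raise ValueError(
                    f"spot {self.spot_id}: nucleus {n.nucleus_id} has vertices "
                    f"outside [0,{w})x[0,{h})"
                )

    def __len__(self) -> int:
        return len(self.nuclei)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of nuclear centroids in (x, y)."""
        if not self.nuclei:
            return np.empty((0, 2))
        return np.array([n.centroid for n in self.nuclei])


@dataclass
class ClinicalRecord:
    patient_id: str
    gender: str            # "M" | "F"
    t_stage: str           # "T1" | "T2"
    n_stage: str           # "N0" | "N1"
    stage: str             # "I" | "II"
    recurrence: bool
    rfs_months: float      # time to recurrence/death or censoring
    event_observed: bool

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"{self.patient_id}: gender must be M or F")
        if self.t_stage not in ("T1", "T2"):
            raise ValueError(f"{self.patient_id}: t_stage must be T1 or T2")
        if self.n_stage not in ("N0", "N1"):
            raise ValueError(f"{self.patient_id}: n_stage must be N0 or N1")
        if self.stage not in ("I", "II"):
            raise ValueError(f"{self.patient_id}: stage must be I or II")
        if self.rfs_months < 0:
            raise ValueError(f"{self.patient_id}: rfs_months must be >= 0")


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

CATEGORIES = ("graph_global", "graph_cluster", "shape", "orientation", "texture")
CATEGORY_COUNTS = {
    "graph_global": 51,
    "graph_cluster": 26,
    "shape": 100,
    "orientation": 39,
    "texture": 26,
}

#: the 13 second-order (co-occurrence) statistics, in canonical order
HARALICK_STATS = (
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure_1",
    "info_measure_2",
)

#: the 25 per-nucleus shape descriptors aggregated into the 100 shape features
SHAPE_BASE_DESCRIPTORS = (
    "area",
    "perimeter",
    "equivalent_diameter",
    "min_radius",
    "max_radius",
    "mean_radius",
    "radius_std",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "compactness",
    "solidity",
    "extent",
    "convex_perimeter_ratio",
    "bending_energy",
) + tuple(f"fsd{k}" for k in range(1, 11))

_AGG4 = ("mean", "std", "minmax_ratio", "disorder")

_CLUSTER_FEATURES = (
    "node_count",
    "edge_count",
    "degree_mean",
    "eccentricity_mean",
    "diameter",
    "radius",
    "eccentricity_mean_core90",
    "diameter_core90",
    "radius_core90",
    "path_length_mean",
    "clustering_c",
    "clustering_d",
    "clustering_e",
    "component_count",
    "giant_component_ratio",
    "isolated_pct",
    "end_node_pct",
    "central_point_count",
    "central_point_pct",
    "edge_length_mean",
    "edge_length_std",
    "edge_length_skewness",
    "edge_length_kurtosis",
    "cluster_size_mean",
    "cluster_size_std",
    "clusters_per_10kpx2",
)

KNN_KS = (3, 5, 7)
NEIGHBOR_RADII = (10, 20, 30, 40, 50)


@lru_cache(maxsize=1)
def feature_registry() -> tuple[tuple[str, str], ...]:
    """The ordered list of all 242 (name, category) pairs.

    Deterministic and stable: downstream code indexes feature vectors by this
    order.  Category counts are 51 / 26 / 100 / 39 / 26.
    """
    reg: list[tuple[str, str]] = []

    # --- global graph (51): Voronoi 12, Delaunay 8, MST 4, density 27
    for metric in ("area", "perimeter", "chord"):
        for agg in _AGG4:
            reg.append((f"graph_global.voronoi.{metric}_{agg}", "graph_global"))
    for metric in ("side", "area"):
        for agg in _AGG4:
            reg.append((f"graph_global.delaunay.{metric}_{agg}", "graph_global"))
    for agg in _AGG4:
        reg.append((f"graph_global.mst.edge_{agg}", "graph_global"))
    for k in KNN_KS:
        for agg in ("mean", "std", "disorder"):
            reg.append((f"graph_global.density.nn{k}_dist_{agg}", "graph_global"))
    for r in NEIGHBOR_RADII:
        for agg in ("mean", "std", "disorder"):
            reg.append((f"graph_global.density.neighbors_r{r}_{agg}", "graph_global"))
    reg.append(("graph_global.density.nuclei_count", "graph_global"))
    reg.append(("graph_global.density.nuclei_per_10kpx2", "graph_global"))
    reg.append(("graph_global.density.area_fraction_r40", "graph_global"))

    # --- cluster graph (26)
    for name in _CLUSTER_FEATURES:
        reg.append((f"graph_cluster.{name}", "graph_cluster"))

    # --- shape (100): 25 base descriptors x {mean, std, median, minmax_ratio}
    for base in SHAPE_BASE_DESCRIPTORS:
        for agg in ("mean", "std", "median", "minmax_ratio"):
            reg.append((f"shape.{base}_{agg}", "shape"))

    # --- orientation (39): 13 co-occurrence stats x {mean, median, std}
    for stat in HARALICK_STATS:
        for agg in ("mean", "median", "std"):
            reg.append((f"orientation.{stat}_{agg}", "orientation"))

    # --- texture (26): 13 co-occurrence stats x {mean, std}
    for stat in HARALICK_STATS:
        for agg in ("mean", "std"):
            reg.append((f"texture.{stat}_{agg}", "texture"))

    counts = {c: sum(1 for _, cat in reg if cat == c) for c in CATEGORIES}
    assert counts == CATEGORY_COUNTS and len(reg) == 242
    return tuple(reg)


def feature_names(category: str | None = None) -> list[str]:
    """Registry names, optionally restricted to one category (registry order)."""
    if category is None:
        return [n for n, _ in feature_registry()]
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return [n for n, c in feature_registry() if c == category]


@lru_cache(maxsize=1)
def _category_lookup() -> dict[str, str]:
    return dict(feature_registry())


def category_of(name: str) -> str:
    try:
        return _category_lookup()[name]
    except KeyError:
        raise KeyError(f"unknown feature name {name!r}") from None


#: field-standard display phrasing for the descriptors most often reported
#: with these pipelines
DISPLAY_NAMES = {
    "graph_global.voronoi.area_minmax_ratio": "Voronoi: Area Ratio Minimum / Maximum",
    "graph_global.density.neighbors_r40_mean":
        "Arch: Average Nearest Neighbors in a 40 Pixel Radius",
    "shape.fsd4_mean": "Mean of Fourier Descriptor 4",
    "shape.fsd8_minmax_ratio": "Min/max ratio of Fourier Descriptor 8",
    "texture.contrast_variance_std":
        "Haralick standard deviation intensity contrast variance",
    "texture.contrast_energy_std":
        "Haralick standard deviation intensity contrast energy",
    "texture.contrast_inverse_moment_std":
        "Haralick standard deviation intensity contrast inverse moment",
}


@dataclass
class FeatureVector:
    """The 242 named histomorphometric descriptors of one spot."""

    spot_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        names = feature_names()
        if list(self.values.keys()) != names:
            missing = set(names) - set(self.values)
            extra = set(self.values) - set(names)
            if missing or extra:
                raise ValueError(
                    f"feature vector for {self.spot_id}: "
                    f"missing={sorted(missing)[:3]} extra={sorted(extra)[:3]}"
                )
            # same names, wrong order -> reorder canonically
            self.values = {n: self.values[n] for n in names}

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in feature_names()], dtype=float)

    def category_values(self, category: str) -> dict[str, float]:
        return {n: self.values[n] for n in feature_names(category)}


# ---------------------------------------------------------------------------
# Nuclei I/O
# ---------------------------------------------------------------------------

def _nuclei_from_records(
    spot_id: str, image_size: tuple[int, int], records: Iterable[tuple[str, np.ndarray]]
) -> NucleiSet:
    nuclei = []
    for nucleus_id, verts in records:
        verts = np.asarray(verts, dtype=float)
        if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 8:
            raise ValueError(
                f"nucleus {nucleus_id}: polygon needs >= 8 vertices, got {len(verts)}"
            )
        nb = NucleusBoundary(nucleus_id=nucleus_id, vertices=verts)
        try:
            nb.validate_simple()
        except ValueError as exc:
            raise ValueError(str(exc)) from None
        nuclei.append(nb)
    return NucleiSet(spot_id=spot_id, nuclei=nuclei, image_size=tuple(image_size))


def write_nuclei(nuclei: NucleiSet, path: str | Path, format: str = "csv") -> None:
    """Write a NucleiSet as CSV (long vertex table) or JSON (polygon list)."""
    path = Path(path)
    if format == "csv":
        rows = []
        for n in nuclei.nuclei:
            for i, (x, y) in enumerate(n.vertices):
                rows.append((nuclei.spot_id, n.nucleus_id, i, x, y))
        df = pd.DataFrame(rows, columns=["spot_id", "nucleus_id", "vertex_index", "x", "y"])
        with open(path, "w") as fh:
            w, h = nuclei.image_size
            fh.write(f"# image_size: {w} {h}\n")
            df.to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "spot_id": nuclei.spot_id,
            "image_size": list(nuclei.image_size),
            "nuclei": [
                {"nucleus_id": n.nucleus_id, "vertices": n.vertices.tolist()}
                for n in nuclei.nuclei
            ],
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown nuclei format {format!r}")


def read_nuclei(path: str | Path, format: str = "csv") -> NucleiSet:
    path = Path(path)
    if format == "csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# image_size:"):
                raise ValueError("nuclei CSV must start with '# image_size: W H'")
            w, h = (int(t) for t in header.split(":")[1].split())
            df = pd.read_csv(fh)
        records = []
        for nucleus_id, grp in df.groupby("nucleus_id", sort=False):
            grp = grp.sort_values("vertex_index")
            records.append((str(nucleus_id), grp[["x", "y"]].to_numpy()))
        spot_id = str(df["spot_id"].iloc[0]) if len(df) else path.stem
        return _nuclei_from_records(spot_id, (w, h), records)
    elif format == "json":
        payload = json.loads(path.read_text())
        records = [(n["nucleus_id"], np.asarray(n["vertices"])) for n in payload["nuclei"]]
        return _nuclei_from_records(payload["spot_id"], tuple(payload["image_size"]), records)
    raise ValueError(f"unknown nuclei format {format!r}")


# ---------------------------------------------------------------------------
# Feature-table and clinical I/O
# ---------------------------------------------------------------------------

def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Feature CSV: `spot_id` + the 242 registry columns, registry order."""
    names = feature_names()
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"feature table missing: {missing[0]}")
    out = df[["spot_id"] + names] if "spot_id" in df.columns else df[names]
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    names = feature_names()
    cols = [c for c in df.columns if c != "spot_id"]
    unknown = sorted(set(cols) - set(names))
    if unknown:
        raise ValueError(f"unknown feature column: {unknown[0]}")
    missing = [n for n in names if n not in cols]
    if missing:
        raise ValueError(f"missing: {missing[0]}")
    return df[["spot_id"] + names] if "spot_id" in df.columns else df[names]


CLINICAL_COLUMNS = [
    "patient_id",
    "batch",
    "gender",
    "t_stage",
    "n_stage",
    "stage",
    "recurrence",
    "rfs_months",
    "event_observed",
]


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing fields: {missing}")
    df[CLINICAL_COLUMNS].to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing fields: {missing}")
    for col in ("recurrence", "event_observed"):
        df[col] = df[col].astype(bool)
    # validate row-wise via ClinicalRecord
    for _, row in df.iterrows():
        ClinicalRecord(
            patient_id=str(row["patient_id"]),
            gender=row["gender"],
            t_stage=row["t_stage"],
            n_stage=row["n_stage"],
            stage=row["stage"],
            recurrence=bool(row["recurrence"]),
            rfs_months=float(row["rfs_months"]),
            event_observed=bool(row["event_observed"]),
        )
    return df


def save_model(bundle, path: str | Path) -> None:
    """Serialize a fitted ModelBundle to JSON (lossless round-trip)."""
    from . import modeling

    modeling.save_model(bundle, path)


def load_model(path: str | Path):
    from . import modeling

    return modeling.load_model(path)
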