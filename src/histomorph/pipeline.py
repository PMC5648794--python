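"""End-to-end orchestration: full 242-feature extraction per spot, cohort
feature tables, and the train/validate recurrence workflow."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureVector, NucleiSet, SpotImage, feature_names
from .graph_features import (
    ClusterGraphConfig,
    GlobalGraphConfig,
    build_cluster_graph,
    cluster_graph_features,
    global_graph_features,
)
from .modeling import (
    ModelBundle,
    SelectionResult,
    predict,
    qda_subset_search,
    select_candidates,
    train_classifier,
)
from .nuclear_features import (
    DEFAULT_OFFSETS,
    nucleus_orientation,
    orientation_entropy_features,
    shape_features,
    texture_features,
)

__all__ = ["FeatureConfig", "extract_features", "extract_cohort_features",
           "select_and_train", "recurrence_pipeline"]


@dataclass
class FeatureConfig:
    """Tunable knobs of the five feature families (all lengths in pixels)."""

    global_graph: GlobalGraphConfig = field(default_factory=GlobalGraphConfig)
    cluster_graph: ClusterGraphConfig = field(default_factory=ClusterGraphConfig)
    orientation_bins: int = 10
    gray_levels: int = 16
    glcm_offsets: tuple = DEFAULT_OFFSETS
    boundary_samples: int = 128


def extract_features(
    image: SpotImage | None,
    nuclei: NucleiSet,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """All 242 descriptors of one spot, in registry order.

    ``image`` may be None, in which case the 26 texture features are NaN
    (boundary-only workflows).
    """
    config = config or FeatureConfig()
    values: dict[str, float] = {}

    values.update(global_graph_features(nuclei, config.global_graph))

    cg = build_cluster_graph(nuclei, config.cluster_graph)
    values.update(cluster_graph_features(cg, nuclei.image_size))

    values.update(shape_features(nuclei, n_points=config.boundary_samples))

    angles = {
        n.nucleus_id: nucleus_orientation(n, n_points=config.boundary_samples).angle_deg
        for n in nuclei.nuclei
    }
    values.update(
        orientation_entropy_features(
            nuclei, cg, bins=config.orientation_bins, angles=angles
        )
    )

    if image is not None:
        values.update(
            texture_features(
                image, nuclei,
                gray_levels=config.gray_levels, offsets=config.glcm_offsets,
            )
        )
    else:
        values.update({name: np.nan for name in feature_names("texture")})

    return FeatureVector(spot_id=nuclei.spot_id, values=values)


def extract_cohort_features(
    images: list[SpotImage] | None,
    nuclei_sets: list[NucleiSet],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table (spot_id + 242 registry columns) for a list of spots."""
    rows = []
    for i, ns in enumerate(nuclei_sets):
        img = images[i] if images else None
        fv = extract_features(img, ns, config)
        rows.append({"spot_id": fv.spot_id, **fv.values})
    return pd.DataFrame(rows)


def select_and_train(
    features: pd.DataFrame,
    labels: np.ndarray,
    classifier_kind: str = "QDA",
    k_per_category: int = 3,
    subset_size: int = 7,
    n_iter: int = 100,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[SelectionResult, ModelBundle]:
    """mRMR top-k per category -> exhaustive QDA subset search -> final fit."""
    per_cat = select_candidates(features, labels, k=k_per_category)
    candidates = [n for cat in per_cat for n in per_cat[cat]]
    selection = qda_subset_search(
        candidates, features, labels,
        subset_size=subset_size, n_iter=n_iter, n_folds=n_folds, seed=seed,
        per_category=per_cat,
    )
    bundle = train_classifier(
        classifier_kind, features, labels, selection.selected, seed=seed
    )
    return selection, bundle


def recurrence_pipeline(
    train_features: pd.DataFrame,
    train_labels: np.ndarray,
    test_features: pd.DataFrame,
    classifier_kind: str = "QDA",
    subset_size: int = 7,
    n_iter: int = 100,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[SelectionResult, ModelBundle, np.ndarray, np.ndarray]:
    """Train on one cohort, score another: returns
    (selection, model, test scores, test calls)."""
    selection, bundle = select_and_train(
        train_features, train_labels, classifier_kind=classifier_kind,
        subset_size=subset_size, n_iter=n_iter, n_folds=n_folds, seed=seed,
    )
    scores, calls = predict(bundle, test_features)
    return selection, bundle, scores, calls
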