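"""Colour normalisation and watershed nuclear segmentation.

Normalisation is a per-channel monotone spline variant of histogram matching:
11 matched quantiles (deciles) of each RGB channel are interpolated with a
monotone piecewise-cubic (PCHIP) spline, giving a non-decreasing 256-entry
lookup table per channel.  It removes batch-to-batch stain variation while
preserving within-image ordering of intensities.

Segmentation separates a hematoxylin-like channel by fixed H&E
colour-deconvolution vectors, smooths, thresholds (Otsu), and splits touching
nuclei by marker-controlled watershed on the distance transform.  Boundaries
come out of the same contour-tracing path used for imported label masks, so
downstream feature code is agnostic to where a segmentation came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import PchipInterpolator
from skimage.color import rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours
from skimage.segmentation import watershed
from shapely.geometry import Polygon as ShPolygon

from .core_io import NucleiSet, NucleusBoundary, SpotImage

__all__ = [
    "NormalizationMap",
    "fit_normalization",
    "apply_normalization",
    "SegmentationConfig",
    "segment_watershed",
    "mask_to_boundaries",
]


# ---------------------------------------------------------------------------
# Colour normalisation
# ---------------------------------------------------------------------------

_QUANTILES = np.linspace(0.0, 1.0, 11)  # deciles incl. endpoints


@dataclass
class NormalizationMap:
    """Per-channel monotone lookup tables mapping source to template."""

    luts: np.ndarray  # (3, 256) float, each row non-decreasing
    template_id: str = ""

    def __post_init__(self):
        self.luts = np.asarray(self.luts, dtype=float)
        if self.luts.shape != (3, 256):
            raise ValueError("NormalizationMap needs (3, 256) LUTs")
        if np.any(np.diff(self.luts, axis=1) < -1e-9):
            raise ValueError("LUTs must be monotone non-decreasing")


def _channel_lut(src: np.ndarray, tmpl: np.ndarray, channel: int) -> np.ndarray:
    """Monotone PCHIP through matched deciles; identity for constant channels."""
    sq = np.quantile(src, _QUANTILES)
    tq = np.quantile(tmpl, _QUANTILES)
    # collapse duplicated source knots (flat histogram regions)
    uniq, idx = np.unique(sq, return_index=True)
    if len(uniq) < 2:
        warnings.warn(f"channel {channel}: constant source channel, identity mapping")
        return np.arange(256, dtype=float)
    ty = np.array([tq[sq == u].mean() for u in uniq])
    # PCHIP through monotone data is monotone; extrapolate linearly and clip
    spline = PchipInterpolator(uniq, ty, extrapolate=True)
    x = np.arange(256, dtype=float)
    lut = np.clip(spline(x), 0.0, 255.0)
    return np.maximum.accumulate(lut)


def fit_normalization(template: SpotImage, source: SpotImage) -> NormalizationMap:
    """Fit the per-channel quantile-matching splines from source to template."""
    luts = np.stack([
        _channel_lut(
            source.pixels[..., c].astype(float),
            template.pixels[..., c].astype(float),
            c,
        )
        for c in range(3)
    ])
    return NormalizationMap(luts=luts, template_id=template.spot_id)


def apply_normalization(norm_map: NormalizationMap, source: SpotImage) -> SpotImage:
    out = np.empty_like(source.pixels)
    for c in range(3):
        out[..., c] = np.clip(
            np.round(norm_map.luts[c][source.pixels[..., c]]), 0, 255
        ).astype(np.uint8)
    return SpotImage(
        pixels=out,
        spot_id=source.spot_id,
        microns_per_pixel=source.microns_per_pixel,
    )


# ---------------------------------------------------------------------------
# Label masks -> boundaries
# ---------------------------------------------------------------------------

def _contour_to_polygon(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray | None:
    """Convert a (row, col) find_contours ring to clipped (x, y) vertices."""
    h, w = shape
    xy = np.column_stack([contour[:, 1], contour[:, 0]])  # x=col, y=row
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    xy[:, 0] = np.clip(xy[:, 0], 0.0, w - 0.01)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, h - 0.01)
    # drop consecutive duplicates introduced by clipping
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) > 1e-9
    xy = xy[keep]
    if len(xy) >= 2 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 8:
        return None
    poly = ShPolygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        if poly.is_empty or poly.geom_type != "Polygon":
            return None
        xy = np.asarray(poly.exterior.coords)[:-1]
        if len(xy) < 8:
            return None
    if ShPolygon(xy).area <= 0:
        return None
    return xy


def mask_to_boundaries(label_mask: np.ndarray, spot_id: str = "mask") -> NucleiSet:
    """One polygon per positive label of an integer raster (0 = background).

    Each label's 0.5-level contour is traced and stored as the nuclear
    boundary; labels whose contour cannot form a valid >= 8-vertex polygon are
    dropped with a warning.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.ndim != 2 or not np.issubdtype(label_mask.dtype, np.integer):
        raise ValueError("label mask must be a 2-D integer raster")
    h, w = label_mask.shape
    nuclei = []
    for lab in np.unique(label_mask):
        if lab == 0:
            continue
        mask = np.pad(label_mask == lab, 1)
        contours = find_contours(mask.astype(float), 0.5)
        if not contours:
            warnings.warn(f"label {lab}: no contour, dropped")
            continue
        contour = max(contours, key=len) - 1.0  # undo padding offset
        xy = _contour_to_polygon(contour, (h, w))
        if xy is None:
            warnings.warn(f"label {lab}: boundary too small or degenerate, dropped")
            continue
        nuclei.append(NucleusBoundary(nucleus_id=f"n{int(lab):04d}", vertices=xy))
    return NucleiSet(spot_id=spot_id, nuclei=nuclei, image_size=(w, h))


# ---------------------------------------------------------------------------
# Watershed segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    """Defaults are matched to the synthetic-phantom scale (nuclei of roughly
    100 px^2); for full-resolution 20x material raise ``min_peak_distance``
    to ~10 px and ``min_area`` to ~80 px^2."""

    smoothing_sigma: float = 1.5    # px, Gaussian smoothing of the H channel
    min_peak_distance: int = 5      # px, marker separation for the watershed
    min_area: float = 30.0          # px^2, nuclei below are discarded
    max_area: float = 3000.0        # px^2, nuclei above are discarded
    min_channel_range: float = 0.02  # H-channel dynamic range below which the
                                     # spot is treated as empty


def segment_watershed(
    image: SpotImage, config: SegmentationConfig | None = None
) -> NucleiSet:
    """Watershed nuclear segmentation of an RGB spot.

    Pipeline: H&E colour deconvolution (fixed published stain matrix) ->
    hematoxylin channel -> Gaussian smoothing -> Otsu foreground threshold ->
    distance transform -> local-maximum markers -> watershed -> contour
    tracing, with an area gate.  An empty image yields an empty NucleiSet.
    """
    config = config or SegmentationConfig()
    hed = rgb2hed(image.pixels)
    hchan = hed[..., 0]
    w, h = image.size

    if hchan.max() - hchan.min() < config.min_channel_range:
        return NucleiSet(spot_id=image.spot_id, nuclei=[], image_size=(w, h))

    smoothed = gaussian(hchan, sigma=config.smoothing_sigma)
    fg = smoothed > threshold_otsu(smoothed)
    lab, _ = ndi.label(fg)
    counts = np.bincount(lab.ravel())
    fg &= counts[lab] >= config.min_area
    if not fg.any():
        return NucleiSet(spot_id=image.spot_id, nuclei=[], image_size=(w, h))

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=config.min_peak_distance, labels=fg, exclude_border=False
    )
    if len(peaks) == 0:
        return NucleiSet(spot_id=image.spot_id, nuclei=[], image_size=(w, h))
    markers = np.zeros_like(dist, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=fg)

    # area gate before tracing
    counts = np.bincount(labels.ravel())
    bad = np.where((counts < config.min_area) | (counts > config.max_area))[0]
    for lab in bad:
        if lab != 0:
            labels[labels == lab] = 0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny fragments are dropped silently here
        return mask_to_boundaries(labels, spot_id=image.spot_id)
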