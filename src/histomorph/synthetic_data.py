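"""Synthetic TMA-spot phantoms and cohorts.

Generates nuclei sets, H&E-like renderings and whole cohorts with
controllable spatial clustering, orientation disorder, boundary irregularity
and chromatin-texture heterogeneity, plus phenotype-linked recurrence-free
survival times.  The two default presets emulate the contrast between an
aggressive, early-recurring tumour phenotype (clustered nuclei, disordered
orientations, irregular boundaries, heterogeneous chromatin) and an indolent
one (regular spacing, aligned, smooth, homogeneous).

All randomness flows through ``numpy.random.default_rng`` (PCG64, a named and
versioned generator): identical seeds give byte-identical outputs across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .core_io import NucleiSet, NucleusBoundary, SpotImage

__all__ = [
    "ClusteringParams",
    "OrientationParams",
    "ShapeParams",
    "TextureParams",
    "PhenotypeParams",
    "SurvivalParams",
    "CohortSpec",
    "RECURRENT_PRESET",
    "NONRECURRENT_PRESET",
    "generate_nuclei",
    "render_spot",
    "sample_survival",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusteringParams:
    process: str = "hardcore"       # "hardcore" | "neyman_scott"
    parent_count: int = 6           # Neyman-Scott parent count
    offspring_sd_px: float = 25.0   # Gaussian offspring spread around parents
    min_spacing_px: float = 12.0    # hard-core centre-to-centre minimum

    def __post_init__(self):
        if self.process not in ("hardcore", "neyman_scott"):
            raise ValueError("process must be 'hardcore' or 'neyman_scott'")
        if self.parent_count <= 0 or self.offspring_sd_px <= 0 or self.min_spacing_px <= 0:
            raise ValueError("clustering parameters must be positive")


@dataclass(frozen=True)
class OrientationParams:
    mean_angle_deg: float = 45.0
    vonmises_kappa: float = 0.0     # 0 = uniform orientations

    def __post_init__(self):
        if self.vonmises_kappa < 0:
            raise ValueError("vonmises_kappa must be >= 0")


@dataclass(frozen=True)
class ShapeParams:
    mean_major_px: float = 7.0      # mean semi-major axis
    mean_minor_px: float = 4.5      # mean semi-minor axis
    fourier_perturb_amp: float = 0.1  # radial perturbation amplitude in [0, 1)
    size_jitter: float = 0.12       # lognormal sd of per-nucleus size scaling

    def __post_init__(self):
        if self.mean_major_px <= 0 or self.mean_minor_px <= 0:
            raise ValueError("axes must be positive")
        if not (0 <= self.fourier_perturb_amp < 1):
            raise ValueError("fourier_perturb_amp must be in [0, 1)")


@dataclass(frozen=True)
class TextureParams:
    base_intensity: float = 110.0   # mean nuclear stain intensity, 0-255
    heterogeneity_sd: float = 10.0  # sd of the smoothed intranuclear field
    blob_scale_px: float = 2.0      # correlation length of the field

    def __post_init__(self):
        if not (0 <= self.base_intensity <= 255):
            raise ValueError("base_intensity must be in [0, 255]")
        if self.heterogeneity_sd < 0 or self.blob_scale_px <= 0:
            raise ValueError("texture parameters must be nonnegative/positive")


@dataclass(frozen=True)
class PhenotypeParams:
    n_nuclei: int = 70
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    shape: ShapeParams = field(default_factory=ShapeParams)
    texture: TextureParams = field(default_factory=TextureParams)

    def __post_init__(self):
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")


#: aggressive phenotype: Neyman-Scott clustering, near-uniform orientations,
#: strongly perturbed boundaries, heterogeneous chromatin
RECURRENT_PRESET = PhenotypeParams(
    clustering=ClusteringParams(process="neyman_scott", parent_count=6,
                                offspring_sd_px=22.0, min_spacing_px=10.0),
    orientation=OrientationParams(mean_angle_deg=45.0, vonmises_kappa=0.5),
    shape=ShapeParams(fourier_perturb_amp=0.35),
    texture=TextureParams(base_intensity=110.0, heterogeneity_sd=25.0, blob_scale_px=2.0),
)

#: indolent phenotype: hard-core spacing, aligned, smooth, homogeneous
NONRECURRENT_PRESET = PhenotypeParams(
    clustering=ClusteringParams(process="hardcore", min_spacing_px=18.0),
    orientation=OrientationParams(mean_angle_deg=45.0, vonmises_kappa=8.0),
    shape=ShapeParams(fourier_perturb_amp=0.08),
    texture=TextureParams(base_intensity=110.0, heterogeneity_sd=8.0, blob_scale_px=2.0),
)


@dataclass(frozen=True)
class SurvivalParams:
    weibull_shape: float = 1.5
    scale_recurrent_months: float = 20.0
    scale_nonrecurrent_months: float = 80.0
    censor_uniform_max_months: float = 120.0

    def __post_init__(self):
        if self.scale_recurrent_months >= self.scale_nonrecurrent_months:
            raise ValueError("recurrent phenotype must have the shorter survival scale")
        if min(self.weibull_shape, self.scale_recurrent_months,
               self.censor_uniform_max_months) <= 0:
            raise ValueError("survival parameters must be positive")


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 120
    recurrence_fraction: float = 0.5
    params_recurrent: PhenotypeParams = RECURRENT_PRESET
    params_nonrecurrent: PhenotypeParams = NONRECURRENT_PRESET
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.recurrence_fraction < 1):
            raise ValueError("recurrence_fraction must be in (0, 1)")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


# ---------------------------------------------------------------------------
# Nuclei generation
# ---------------------------------------------------------------------------

def _sample_axial_angles(rng, n, mean_deg, kappa):
    """Axial orientations in [0, 180): von Mises on the doubled angle."""
    if kappa == 0:
        return rng.uniform(0.0, 180.0, n)
    psi = rng.vonmises(2.0 * np.radians(mean_deg), kappa, n)
    return (np.degrees(psi) / 2.0) % 180.0


def _place_centres(rng, n, image_size, margins, clustering: ClusteringParams):
    """Centre placement with per-nucleus bound margins and hard-core spacing."""
    w, h = image_size
    max_margin = margins.max()
    if w - 2 * max_margin <= 0 or h - 2 * max_margin <= 0:
        raise ValueError("image too small for the requested nucleus size")

    centres = np.empty((n, 2))
    if clustering.process == "neyman_scott":
        parents = np.column_stack([
            rng.uniform(max_margin, w - max_margin, clustering.parent_count),
            rng.uniform(max_margin, h - max_margin, clustering.parent_count),
        ])
    placed = 0
    attempts = 0
    max_attempts = 400 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} nuclei with min spacing "
                f"{clustering.min_spacing_px} px; use a larger image or fewer nuclei"
            )
        attempts += 1
        m = margins[placed]
        if clustering.process == "hardcore":
            cand = np.array([rng.uniform(m, w - m), rng.uniform(m, h - m)])
        else:
            parent = parents[rng.integers(len(parents))]
            cand = parent + rng.normal(0.0, clustering.offspring_sd_px, 2)
            cand = np.clip(cand, [m, m], [w - m, h - m])
        if placed and (np.linalg.norm(centres[:placed] - cand, axis=1).min()
                       < clustering.min_spacing_px):
            continue
        centres[placed] = cand
        placed += 1
    return centres


def _nucleus_boundary(rng, centre, major, minor, angle_deg, perturb_amp,
                      n_vertices=48):
    """Star-shaped polygon: ellipse radius times (1 + radial perturbation).

    The perturbation is a sum of cosine harmonics 2..8 with random phases,
    rescaled so its peak magnitude equals ``perturb_amp`` < 1, which keeps the
    radius positive and the polygon simple.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    theta = np.radians(angle_deg)
    phi = t - theta
    r_ell = major * minor / np.sqrt((minor * np.cos(phi)) ** 2 + (major * np.sin(phi)) ** 2)
    if perturb_amp > 0:
        harmonics = np.arange(2, 9)
        coef = rng.normal(0.0, 1.0, len(harmonics)) / harmonics
        phases = rng.uniform(0.0, 2.0 * np.pi, len(harmonics))
        g = np.sum(coef[:, None] * np.cos(harmonics[:, None] * t[None, :] + phases[:, None]), axis=0)
        peak = np.abs(g).max()
        if peak > 0:
            g = g / peak * perturb_amp
        r = r_ell * (1.0 + g)
    else:
        r = r_ell
    x = centre[0] + r * np.cos(t)
    y = centre[1] + r * np.sin(t)
    return np.column_stack([x, y])


def generate_nuclei(
    params: PhenotypeParams,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    spot_id: str = "synthetic",
) -> NucleiSet:
    """Generate exactly ``params.n_nuclei`` simple nuclear polygons.

    Centres follow the configured point process (hard-core dart throwing or
    Neyman-Scott parents + Gaussian offspring, both with a hard-core minimum
    spacing); orientations are von Mises on the doubled angle; boundaries are
    radially perturbed ellipses.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_nuclei

    sizes = np.exp(rng.normal(0.0, params.shape.size_jitter, n))
    majors = params.shape.mean_major_px * sizes
    minors = params.shape.mean_minor_px * sizes
    angles = _sample_axial_angles(
        rng, n, params.orientation.mean_angle_deg, params.orientation.vonmises_kappa
    )
    # worst-case boundary radius per nucleus, plus half a pixel of slack
    margins = majors * (1.0 + params.shape.fourier_perturb_amp) + 0.5

    centres = _place_centres(rng, n, image_size, margins, params.clustering)

    nuclei = []
    for i in range(n):
        verts = _nucleus_boundary(
            rng, centres[i], majors[i], minors[i], angles[i],
            params.shape.fourier_perturb_amp,
        )
        nuclei.append(NucleusBoundary(nucleus_id=f"n{i:04d}", vertices=verts))
    return NucleiSet(spot_id=spot_id, nuclei=nuclei, image_size=tuple(image_size))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_BACKGROUND_RGB = np.array([236, 207, 223], dtype=float)  # eosin-like pink


def _nucleus_rgb(v: np.ndarray) -> np.ndarray:
    """Map stain intensity (0-255) to a bluish-purple hematoxylin-like colour."""
    return np.stack([0.35 * v, 0.25 * v, 0.60 * v + 40.0], axis=-1)


def render_spot(
    nuclei: NucleiSet, params: PhenotypeParams, seed: int = 0
) -> SpotImage:
    """H&E-like rendering: pink background, bluish-purple textured nuclei.

    Intranuclear texture is a Gaussian random field smoothed at
    ``blob_scale_px`` and rescaled to standard deviation ``heterogeneity_sd``,
    added to ``base_intensity``.  Identical seeds give identical image bytes.
    """
    w, h = nuclei.image_size
    rng = np.random.default_rng(seed)
    img = np.tile(_BACKGROUND_RGB, (h, w, 1))

    tex = params.texture
    if tex.heterogeneity_sd > 0:
        field_ = gaussian_filter(rng.standard_normal((h, w)), tex.blob_scale_px)
        sd = field_.std()
        field_ = field_ * (tex.heterogeneity_sd / sd) if sd > 0 else field_
    else:
        field_ = np.zeros((h, w))

    for n in nuclei.nuclei:
        rr, cc = draw_polygon(n.vertices[:, 1], n.vertices[:, 0], shape=(h, w))
        v = np.clip(tex.base_intensity + field_[rr, cc], 0.0, 255.0)
        img[rr, cc] = _nucleus_rgb(v)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SpotImage(pixels=pixels, spot_id=nuclei.spot_id)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def sample_survival(
    rng: np.random.Generator, n: int, shape: float, scale: float, censor_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """(rfs_months, event_observed): Weibull event times under independent
    Uniform(0, censor_max) censoring."""
    t_event = scale * rng.weibull(shape, n)
    t_censor = rng.uniform(0.0, censor_max, n)
    observed = t_event <= t_censor
    return np.where(observed, t_event, t_censor), observed


def generate_cohort(
    spec: CohortSpec, render: bool = True, geometry: bool = True
) -> tuple[list[SpotImage], list[NucleiSet], pd.DataFrame]:
    """Generate a full synthetic cohort: one spot per patient plus a clinical
    table (CohortTable contract: the documented clinical columns; feature
    columns are joined downstream after extraction).

    round(n_patients * recurrence_fraction) patients receive the recurrent
    phenotype and the shorter Weibull survival scale.  ``render=False`` skips
    image synthesis (images list empty); ``geometry=False`` additionally
    skips nuclei generation, for survival-only experiments.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_rec = int(round(n * spec.recurrence_fraction))
    recurrent = np.zeros(n, dtype=bool)
    recurrent[:n_rec] = True  # deterministic count; order is immaterial downstream

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(2 * n) % (2**31)

    surv = spec.survival
    rfs = np.empty(n)
    observed = np.empty(n, dtype=bool)
    rfs_rec, obs_rec = sample_survival(
        rng, n_rec, surv.weibull_shape, surv.scale_recurrent_months,
        surv.censor_uniform_max_months,
    )
    rfs_non, obs_non = sample_survival(
        rng, n - n_rec, surv.weibull_shape, surv.scale_nonrecurrent_months,
        surv.censor_uniform_max_months,
    )
    rfs[recurrent], observed[recurrent] = rfs_rec, obs_rec
    rfs[~recurrent], observed[~recurrent] = rfs_non, obs_non

    gender = rng.choice(["M", "F"], n)
    t_stage = rng.choice(["T1", "T2"], n)
    n_stage = rng.choice(["N0", "N1"], n, p=[0.7, 0.3])

    images: list[SpotImage] = []
    nuclei_sets: list[NucleiSet] = []
    rows = []
    for i in range(n):
        pid = f"p{i:04d}"
        params = spec.params_recurrent if recurrent[i] else spec.params_nonrecurrent
        if geometry:
            ns = generate_nuclei(
                params, image_size=spec.image_size, seed=int(child_seeds[2 * i]), spot_id=pid
            )
            nuclei_sets.append(ns)
            if render:
                images.append(render_spot(ns, params, seed=int(child_seeds[2 * i + 1])))
        rows.append({
            "patient_id": pid,
            "spot_id": pid,
            "batch": 1,
            "gender": gender[i],
            "t_stage": t_stage[i],
            "n_stage": n_stage[i],
            "stage": "II" if (t_stage[i] == "T2" or n_stage[i] == "N1") else "I",
            "recurrence": bool(recurrent[i]),
            "rfs_months": float(rfs[i]),
            "event_observed": bool(observed[i]),
        })
    return images, nuclei_sets, pd.DataFrame(rows)
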