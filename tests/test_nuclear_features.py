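import numpy as np
import pytest

import histomorph as hm
from histomorph.core_io import HARALICK_STATS, SpotImage
from histomorph.graph_features import ClusterGraph
from histomorph.nuclear_features import (
    cooccurrence_stats_13,
    fourier_shape_descriptors,
    nucleus_orientation,
    orientation_cooccurrence,
    orientation_entropy_features,
    shape_features,
    texture_features,
)

from conftest import make_circle, make_ellipse, nuclei_from_polygons


# ---------------------------------------------------------------------------
# Fourier shape descriptors
# ---------------------------------------------------------------------------

class TestFSD:
    def test_circle_has_flat_spectrum(self):
        fsd = fourier_shape_descriptors(make_circle(100, 100, 40, n=100))
        assert np.all(fsd < 1e-3)

    def test_rigid_motion_and_scale_invariance(self):
        base = fourier_shape_descriptors(make_ellipse(100, 100, 30, 15, 0, n=72))
        moved = fourier_shape_descriptors(
            make_ellipse(411.3, 77.9, 30, 15, 37.0, n=72)
        )
        scaled = fourier_shape_descriptors(make_ellipse(100, 100, 90, 45, 0, n=72))
        np.testing.assert_allclose(moved, base, atol=1e-6)
        np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_start_vertex_invariance(self):
        v = make_ellipse(100, 100, 30, 17, 25.0, n=72)
        rolled = np.roll(v, -13, axis=0)
        np.testing.assert_allclose(
            fourier_shape_descriptors(rolled),
            fourier_shape_descriptors(v),
            atol=1e-6,
        )

    def test_ellipse_second_harmonic_dominates_vs_direct_dft(self):
        """Independent oracle: arc-length resample + DFT written out by hand."""
        v = make_ellipse(100, 100, 30, 15, 0, n=72)
        fsd = fourier_shape_descriptors(v, n_points=128)
        assert np.argmax(fsd) == 1  # FSD2: the 2-fold symmetry of an ellipse

        # oracle: own arc-length resampling (starting at max-radius vertex,
        # like the implementation documents) and literal DFT
        c = v.mean(axis=0)  # regular ellipse sampling: vertex mean = centroid
        r0 = np.linalg.norm(v - c, axis=1)
        v2 = np.roll(v, -int(np.argmax(r0)), axis=0)
        closed = np.vstack([v2, v2[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        t = np.linspace(0, arc[-1], 128, endpoint=False)
        pts = np.column_stack([
            np.interp(t, arc, closed[:, 0]), np.interp(t, arc, closed[:, 1])
        ])
        r = np.linalg.norm(pts - c, axis=1)
        F = np.abs(np.fft.rfft(r))
        np.testing.assert_allclose(fsd, F[1:11] / F[0], atol=1e-6)

    def test_degenerate_boundary_rejected(self):
        v = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fourier_shape_descriptors(v)


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

class TestShapeFeatures:
    def test_identical_circles_are_perfectly_uniform(self):
        ns = nuclei_from_polygons(
            [make_circle(60 + 80 * i, 60, 20) for i in range(10)],
            image_size=(900, 200),
        )
        feats = shape_features(ns)
        assert len(feats) == 100
        for base in hm.core_io.SHAPE_BASE_DESCRIPTORS:
            assert feats[f"shape.{base}_std"] == pytest.approx(0.0, abs=1e-6), base
            if abs(feats[f"shape.{base}_mean"]) < 1e-6:
                # descriptor is identically 0 for circles (FSDs, eccentricity):
                # a min/max ratio of float noise carries no information
                continue
            assert feats[f"shape.{base}_minmax_ratio"] == pytest.approx(1.0, abs=1e-6), base

    def test_two_circle_area_ratio(self):
        ns = nuclei_from_polygons(
            [make_circle(100, 100, 10), make_circle(300, 100, 20)],
            image_size=(400, 200),
        )
        feats = shape_features(ns)
        # pi r^2: discretised polygons with equal vertex count scale exactly
        assert feats["shape.area_minmax_ratio"] == pytest.approx(0.25, abs=1e-12)
        assert feats["shape.max_radius_minmax_ratio"] == pytest.approx(0.5, abs=1e-9)

    def test_fewer_than_two_nuclei_gives_nan(self):
        ns = nuclei_from_polygons([make_circle(100, 100, 10)])
        with pytest.warns(UserWarning, match="<2 valid nuclei"):
            feats = shape_features(ns)
        assert all(np.isnan(v) for v in feats.values())


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

class TestOrientation:
    @pytest.mark.parametrize("angle", [30.0, 150.0, 0.0, 91.0])
    def test_ellipse_axis_recovered(self, angle):
        v = make_ellipse(100, 100, 30, 10, angle)
        res = nucleus_orientation(nuclei_from_polygons([v]).nuclei[0])
        assert res.angle_deg == pytest.approx(angle % 180.0, abs=1.0)
        assert not res.low_confidence

    def test_circle_flagged_low_confidence(self):
        res = nucleus_orientation(
            nuclei_from_polygons([make_circle(100, 100, 20, n=128)]).nuclei[0]
        )
        assert res.low_confidence


# ---------------------------------------------------------------------------
# 13-statistic co-occurrence set
# ---------------------------------------------------------------------------

def stats_13_literal(P):
    """Independent termwise transcription of the 13 formulas."""
    B = P.shape[0]
    out = {}
    ce = cim = 0.0
    H = en = 0.0
    p_diff = np.zeros(B)
    p_sum = np.zeros(2 * B - 1)
    for i in range(B):
        for j in range(B):
            p = P[i, j]
            ce += (i - j) ** 2 * p
            cim += p / (1 + (i - j) ** 2)
            if p > 0:
                H -= p * np.log2(p)
            en += p * p
            p_diff[abs(i - j)] += p
            p_sum[i + j] += p
    ca = sum(k * p_diff[k] for k in range(B))
    cv = sum((k - ca) ** 2 * p_diff[k] for k in range(B))
    cent = -sum(p * np.log2(p) for p in p_diff if p > 0)
    ia = sum(k * p_sum[k] for k in range(2 * B - 1))
    iv = sum((k - ia) ** 2 * p_sum[k] for k in range(2 * B - 1))
    ient = -sum(p * np.log2(p) for p in p_sum if p > 0)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = sum(i * px[i] for i in range(B))
    my = sum(j * py[j] for j in range(B))
    vx = sum((i - mx) ** 2 * px[i] for i in range(B))
    vy = sum((j - my) ** 2 * py[j] for j in range(B))
    corr = 0.0
    if vx > 0 and vy > 0:
        corr = (sum(i * j * P[i, j] for i in range(B) for j in range(B)) - mx * my) / np.sqrt(vx * vy)
    hx = -sum(p * np.log2(p) for p in px if p > 0)
    hy = -sum(p * np.log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i, j] * np.log2(px[i] * py[j])
        for i in range(B) for j in range(B)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(B) for j in range(B)
        if px[i] * py[j] > 0
    )
    imc1 = (H - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - H))))
    return {
        "contrast_energy": ce, "contrast_inverse_moment": cim,
        "contrast_average": ca, "contrast_variance": cv, "contrast_entropy": cent,
        "intensity_average": ia, "intensity_variance": iv, "intensity_entropy": ient,
        "entropy": H, "energy": en, "correlation": corr,
        "info_measure_1": imc1, "info_measure_2": imc2,
    }


class TestCooccurrenceStats:
    def test_diagonal_matrix_has_zero_contrast(self):
        P = np.eye(8) / 8
        s = cooccurrence_stats_13(P)
        assert s["contrast_average"] == 0.0
        assert s["contrast_variance"] == 0.0

    def test_uniform_4x4_entropy_is_4_bits(self):
        s = cooccurrence_stats_13(np.full((4, 4), 1 / 16))
        assert s["entropy"] == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_matrices_match_literal_formulas(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((4, 4))
        P = A + A.T
        P /= P.sum()
        ours = cooccurrence_stats_13(P)
        oracle = stats_13_literal(P)
        for k in HARALICK_STATS:
            assert ours[k] == pytest.approx(oracle[k], abs=1e-10), k

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_stats_13(np.ones((4, 4)))


# ---------------------------------------------------------------------------
# Orientation entropy features
# ---------------------------------------------------------------------------

def _cg_single_cluster(ids):
    return ClusterGraph(
        clusters=[{"member_ids": list(ids), "centroid": (0.0, 0.0)}],
        edges=[], image_size=(512, 512),
    )


class TestOrientationEntropy:
    def test_aligned_nuclei_have_zero_entropy(self):
        polys = [make_ellipse(60 + 70 * i, 60, 25, 10, 40.0) for i in range(6)]
        ns = nuclei_from_polygons(polys, image_size=(600, 200))
        cg = ClusterGraph(
            clusters=[
                {"member_ids": [n.nucleus_id for n in ns.nuclei[:3]], "centroid": (0, 0)},
                {"member_ids": [n.nucleus_id for n in ns.nuclei[3:]], "centroid": (0, 0)},
            ],
            edges=[], image_size=(600, 200),
        )
        feats = orientation_entropy_features(ns, cg)
        assert len(feats) == 39
        assert list(feats.keys()) == hm.feature_names("orientation")
        assert feats["orientation.entropy_mean"] == pytest.approx(0.0, abs=1e-12)
        assert feats["orientation.energy_mean"] == pytest.approx(1.0, abs=1e-12)
        assert feats["orientation.entropy_std"] == pytest.approx(0.0, abs=1e-12)

    def test_disorder_raises_entropy(self):
        """Disordered clusters carry more orientation entropy than aligned
        ones (Monte-Carlo over 20 seeds, brute-force pair-histogram oracle)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            aligned = np.degrees(rng.vonmises(0.0, 50.0, 50)) / 2 % 180
            disordered = rng.uniform(0, 180, 50)
            e = {}
            for name, angles in (("a", aligned), ("d", disordered)):
                P = orientation_cooccurrence(angles, bins=10)
                # oracle: entropy of the explicit pair histogram
                q = np.minimum((angles / 18).astype(int), 9)
                counts = np.zeros((10, 10))
                for i in range(50):
                    for j in range(i + 1, 50):
                        counts[q[i], q[j]] += 1
                        counts[q[j], q[i]] += 1
                Pref = counts / counts.sum()
                np.testing.assert_allclose(P, Pref, atol=1e-12)
                p = Pref[Pref > 0]
                e[name] = -(p * np.log2(p)).sum()
            if e["d"] > e["a"]:
                wins += 1
        assert wins >= 18

    def test_no_qualifying_cluster_gives_nan(self):
        ns = nuclei_from_polygons([make_ellipse(100, 100, 25, 10, 0.0)])
        cg = _cg_single_cluster([ns.nuclei[0].nucleus_id])
        with pytest.warns(UserWarning, match="no cluster"):
            feats = orientation_entropy_features(ns, cg)
        assert all(np.isnan(v) for v in feats.values())


# ---------------------------------------------------------------------------
# Texture features
# ---------------------------------------------------------------------------

class TestTexture:
    def test_constant_nuclei_have_degenerate_glcm(self):
        ns = hm.generate_nuclei(hm.NONRECURRENT_PRESET, seed=3)
        params = hm.PhenotypeParams(
            texture=hm.synthetic_data.TextureParams(heterogeneity_sd=0.0)
        )
        img = hm.render_spot(ns, params, seed=3)
        feats = texture_features(img, ns)
        assert len(feats) == 26
        assert feats["texture.contrast_average_mean"] == pytest.approx(0.0, abs=1e-12)
        assert feats["texture.energy_mean"] == pytest.approx(1.0, abs=1e-12)
        assert feats["texture.energy_std"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_contrast_matches_pair_enumeration(self):
        """2-level checkerboard in one nucleus: every offset pair differs, so
        the contrast average equals the level separation (enumeration oracle)."""
        img_arr = np.full((64, 64, 3), 200, dtype=np.uint8)
        patch = np.indices((8, 8)).sum(axis=0) % 2
        vals = np.where(patch == 1, 180, 60).astype(np.uint8)
        img_arr[8:16, 8:16, :] = vals[..., None]
        img = SpotImage(pixels=img_arr, spot_id="cb")
        square = np.array([
            [7.9, 7.9], [11.5, 7.9], [15.1, 7.9], [15.1, 11.5],
            [15.1, 15.1], [11.5, 15.1], [7.9, 15.1], [7.9, 11.5],
        ])
        ns = nuclei_from_polygons([square], image_size=(64, 64))
        feats = texture_features(img, ns, gray_levels=16, offsets=((0, 1), (1, 0)))

        # oracle: explicit pair enumeration on the 8x8 patch
        gray = np.dot(vals[..., None].repeat(3, axis=2) / 255.0,
                      [0.2125, 0.7154, 0.0721]) * 255.0
        lv = np.clip(((gray - gray.min()) / (gray.max() - gray.min()) * 16).astype(int), 0, 15)
        pairs = []
        for y in range(8):
            for x in range(8):
                if x + 1 < 8:
                    pairs.append((lv[y, x], lv[y, x + 1]))
                if y + 1 < 8:
                    pairs.append((lv[y, x], lv[y + 1, x]))
        diffs = [abs(a - b) for a, b in pairs]
        expected_contrast_avg = np.mean(diffs)  # all pairs differ: 15
        assert expected_contrast_avg == 15.0
        assert feats["texture.contrast_average_mean"] == pytest.approx(
            expected_contrast_avg, abs=1e-12
        )

    def test_nucleus_order_invariance(self):
        ns = hm.generate_nuclei(hm.RECURRENT_PRESET, seed=5)
        img = hm.render_spot(ns, hm.RECURRENT_PRESET, seed=5)
        feats = texture_features(img, ns)
        rev = hm.NucleiSet(
            spot_id=ns.spot_id, nuclei=list(reversed(ns.nuclei)), image_size=ns.image_size
        )
        feats_rev = texture_features(img, rev)
        for k in feats:
            assert feats_rev[k] == pytest.approx(feats[k], abs=1e-12)
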