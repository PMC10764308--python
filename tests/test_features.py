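import numpy as np
import pytest

from odefgvf.errors import FeatureError
from odefgvf.features import (
    FEATURE_NAMES,
    GLCMSpec,
    color_features,
    compute_glcm,
    extract_all,
    glcm_feature_vector,
    glcm_features,
    line_profile_features,
    vessel_features,
)
from odefgvf.localization import ODLocation, VesselMap
from odefgvf.preprocess import ROIPatch
from odefgvf.retina_io import BinaryMask, FundusImage, RetinaGeometry


def brute_force_glcm_features(img, levels, offset):
    """Independent double-loop oracle for all ten GLCM statistics."""
    q = np.minimum((img * levels).astype(int), levels - 1)
    h, w = q.shape
    p = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + offset[0], c + offset[1]
            if 0 <= r2 < h and 0 <= c2 < w:
                p[q[r, c], q[r2, c2]] += 1
    p = p + p.T
    p /= p.sum()
    lev = np.arange(1, levels + 1)
    px, py = p.sum(1), p.sum(0)
    mx, my = lev @ px, lev @ py
    sx = np.sqrt(((lev - mx) ** 2) @ px)
    sy = np.sqrt(((lev - my) ** 2) @ py)
    out = dict(autoc=0.0, contr=0.0, cprom=0.0, cshad=0.0, dissi=0.0,
               energy=0.0, entro=0.0, homop=0.0)
    for a in range(levels):
        for b in range(levels):
            i, j, v = a + 1, b + 1, p[a, b]
            out["autoc"] += i * j * v
            out["contr"] += (i - j) ** 2 * v
            out["cprom"] += (i + j - mx - my) ** 4 * v
            out["cshad"] += (i + j - mx - my) ** 3 * v
            out["dissi"] += abs(i - j) * v
            out["energy"] += v * v
            if v > 0:
                out["entro"] -= v * np.log(v)
            out["homop"] += v / (1 + (i - j) ** 2)
    out["corrp"] = (out["autoc"] - mx * my) / (sx * sy)
    out["maxpr"] = p.max()
    return out


class TestGLCM:
    def test_constant_image_single_entry(self):
        G = compute_glcm(np.full((16, 16), 0.5), GLCMSpec(), (0, 1))
        assert G.p.max() == pytest.approx(1.0)
        assert (G.p > 0).sum() == 1

    def test_stripe_image_off_diagonal_halves(self):
        img = np.tile(np.array([0.0, 0.6]), (16, 8))
        G = compute_glcm(img, GLCMSpec(levels=2), (0, 1))
        assert G.p[0, 1] == pytest.approx(0.5)
        assert G.p[1, 0] == pytest.approx(0.5)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(0)
        for off in ((0, 1), (1, 0), (1, 1), (1, -1)):
            G = compute_glcm(rng.random((20, 20)), GLCMSpec(), off)
            assert G.p.sum() == pytest.approx(1.0)
            assert np.allclose(G.p, G.p.T)  # symmetric by construction

    def test_closed_form_limits(self):
        const = glcm_features(compute_glcm(np.full((16, 16), 0.5), GLCMSpec(), (0, 1)),
                              ("contr", "dissi", "entro", "energy", "homop", "maxpr"))
        assert const["contr"] == 0 and const["dissi"] == 0
        assert const["entro"] == pytest.approx(0.0)
        assert const["energy"] == 1 and const["homop"] == 1 and const["maxpr"] == 1
        stripes = glcm_features(
            compute_glcm(np.tile(np.array([0.0, 0.6]), (16, 8)), GLCMSpec(levels=2), (0, 1)))
        assert stripes["contr"] == pytest.approx(1.0)
        assert stripes["dissi"] == pytest.approx(1.0)
        assert stripes["homop"] == pytest.approx(0.5)
        assert stripes["energy"] == pytest.approx(0.5)

    def test_correlation_undefined_on_constant_image(self):
        G = compute_glcm(np.full((16, 16), 0.5), GLCMSpec(), (0, 1))
        with pytest.raises(FeatureError) as exc:
            glcm_features(G)
        assert exc.value.feature == "corrp"

    @pytest.mark.parametrize("levels", [2, 4, 8, 16])
    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (1, -1)])
    def test_oracle_equivalence(self, levels, offset):
        rng = np.random.default_rng(levels * 100 + offset[0] * 10 + offset[1])
        for _ in range(10):
            img = rng.random((16, 16))
            mine = glcm_features(compute_glcm(img, GLCMSpec(levels=levels), offset))
            ref = brute_force_glcm_features(img, levels, offset)
            for k, v in mine.items():
                assert v == pytest.approx(ref[k], abs=1e-10), k


class TestVesselFeatures:
    def _vm(self, mask):
        m = BinaryMask(mask.astype(np.uint8), "vessel")
        return VesselMap(m, BinaryMask(np.zeros_like(mask, np.uint8), "vessel"), [])

    def test_component_counting(self):
        mask = np.zeros((50, 50))
        mask[5:10, 5:13] = 1   # 40 px
        mask[20:26, 20:25] = 1  # 30 px
        mask[40:42, 40:45] = 1  # 10 px
        gray = np.where(np.indices((50, 50)).sum(0) % 2 == 0, 0.2, 0.8)
        f = vessel_features(self._vm(mask), BinaryMask(np.ones((50, 50), np.uint8),
                                                       "od_predicted"), gray)
        assert f["vdi"] == 3
        assert f["largest_vessel_area"] == 40
        assert f["mean_vessel_area"] == pytest.approx(80 / 3)
        assert f["vdip"] == 3  # od mask covers everything

    def test_two_point_distribution_moments(self):
        gray = np.where(np.indices((50, 50)).sum(0) % 2 == 0, 0.2, 0.8)
        f = vessel_features(self._vm(np.zeros((50, 50))),
                            BinaryMask(np.ones((50, 50), np.uint8), "od_predicted"), gray)
        assert f["sigma"] == pytest.approx(0.3)
        assert f["kurtosis"] == pytest.approx(1.0)
        assert f["vdi"] == 0 and f["largest_vessel_area"] == 0

    def test_gaussian_kurtosis_is_three(self):
        rng = np.random.default_rng(0)
        x = np.clip(rng.standard_normal(100_000) * 0.1 + 0.5, 0, 1)
        side = int(np.sqrt(x.size))
        gray = x[: side * side].reshape(side, side)
        f = vessel_features(self._vm(np.zeros_like(gray)),
                            BinaryMask(np.ones_like(gray, dtype=np.uint8), "od_predicted"),
                            gray)
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_constant_image_kurtosis_undefined(self):
        with pytest.raises(FeatureError) as exc:
            vessel_features(self._vm(np.zeros((20, 20))),
                            BinaryMask(np.ones((20, 20), np.uint8), "od_predicted"),
                            np.full((20, 20), 0.5))
        assert exc.value.feature == "kurtosis"


class TestColorFeatures:
    def test_constant_gray_roi(self):
        f = color_features(ROIPatch(np.full((64, 64, 3), 0.5), (0, 0), 64))
        assert f["sharpness"] == 0
        assert f["saturation"] == 0

    def test_pure_red_roi(self):
        roi = np.zeros((64, 64, 3))
        roi[:, :, 0] = 1.0
        f = color_features(ROIPatch(roi, (0, 0), 64))
        assert f["hue"] == pytest.approx(0.0)
        assert f["saturation"] == pytest.approx(1.0)

    def test_unit_slope_ramp_sharpness(self):
        ramp = np.tile(np.arange(128, dtype=float), (128, 1)) / 127.0
        f = color_features(ROIPatch(np.stack([ramp] * 3, axis=-1), (0, 0), 128))
        assert f["sharpness"] * 127 == pytest.approx(1.0, rel=0.02)


class TestLineProfile:
    def _setup(self, value=0.3, shape=(300, 500)):
        img = FundusImage(np.full((*shape, 3), value))
        geom = RetinaGeometry((shape[0] / 2, shape[1] / 2), 400.0)
        loc = ODLocation((shape[0] / 2, shape[1] / 2), "parabola")
        return img, geom, loc

    def test_constant_image(self):
        img, geom, loc = self._setup(0.3)
        f = line_profile_features(img, loc, geom)
        assert (f["profile_mean"], f["profile_min"], f["profile_max"],
                f["profile_std"]) == pytest.approx((0.3, 0.3, 0.3, 0.0))

    def test_length_is_half_diameter(self):
        img, geom, loc = self._setup()
        gray = img.pixels[150] @ np.array([0.2125, 0.7154, 0.0721])
        # alternate 0/1 on the sampled row to count samples via the mean
        img.pixels[150, ::2] = 0.0
        img.pixels[150, 1::2] = 1.0
        f = line_profile_features(img, loc, geom)
        # 200 samples centered at col 250 -> cols 150..349, 100 of each value
        assert f["profile_mean"] == pytest.approx(0.5)
        assert f["profile_min"] == pytest.approx(0.0)
        assert f["profile_max"] == pytest.approx(1.0)
        assert f["profile_std"] == pytest.approx(0.5)


class TestExtractAll:
    def test_full_pipeline_vector_finite_and_deterministic(
            self, sharp_phantom, sharp_stage):
        from odefgvf.preprocess import enhance_contrast

        enh = enhance_contrast(sharp_stage["roi"])
        args = (sharp_phantom.image, sharp_phantom.geometry, sharp_stage["loc"],
                enh, sharp_stage["od_gt"], sharp_stage["vessel_map"])
        fv1 = extract_all(*args)
        fv2 = extract_all(*args)
        arr = fv1.as_array()
        assert arr.shape == (27,)
        assert np.isfinite(arr).all()
        assert np.array_equal(arr, fv2.as_array())
        assert list(fv1.values) == list(FEATURE_NAMES)

    def test_constant_image_names_undefined_features(self):
        img = FundusImage(np.full((300, 300, 3), 0.5))
        geom = RetinaGeometry((150, 150), 280.0)
        loc = ODLocation((150.0, 150.0), "parabola")
        roi = ROIPatch(np.full((93, 93, 3), 0.5), (104, 104), 93)
        empty = BinaryMask(np.zeros((93, 93), np.uint8), "vessel")
        vm = VesselMap(empty, empty, [])
        od = BinaryMask(np.ones((93, 93), np.uint8), "od_predicted")
        with pytest.raises(FeatureError) as exc:
            extract_all(img, geom, loc, roi, od, vm)
        assert "kurtosis" in str(exc.value)
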