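import numpy as np
import pytest

from odefgvf.errors import (
    ConvergenceError,
    DegenerateRegionError,
    NumericalError,
    RoiError,
)
from odefgvf.fgvf import (
    Contour,
    FGVFParams,
    LevelSetField,
    RepresentativeFeatures,
    check_convergence,
    compute_region_weights,
    dirac,
    evolve_step,
    heaviside,
    init_level_set,
    make_feature_matrix,
    segment_od,
    update_representatives,
)

from conftest import dice


class TestMakeFeatureMatrix:
    def test_dimensions(self):
        Y = make_feature_matrix(np.random.default_rng(0).random((60, 70)))
        assert Y.values.shape == (77, 60 * 70)
        assert len(Y.band_names) == 77

    def test_constant_image_all_columns_equal(self):
        Y = make_feature_matrix(np.full((60, 60), 0.3))
        assert np.abs(Y.values - Y.values[:, :1]).max() < 1e-6

    def test_two_texture_phantom_separates_regions(self, sharp_stage):
        Y = make_feature_matrix(sharp_stage["vessel_free"])
        od = sharp_stage["od_gt"].pixels.astype(bool)
        flat = od.reshape(-1, order="F")
        # columns well inside each region (away from the histogram window mix)
        from scipy import ndimage
        core_in = ndimage.binary_erosion(od, iterations=8).reshape(-1, order="F")
        core_out = ndimage.binary_erosion(~od, iterations=8).reshape(-1, order="F")
        mu_in = Y.values[:, core_in].mean(axis=1)
        mu_out = Y.values[:, core_out].mean(axis=1)
        between = np.linalg.norm(mu_in - mu_out)
        within_in = np.linalg.norm(
            Y.values[:, core_in] - mu_in[:, None], axis=0).mean()
        assert between > 1.0 * within_in  # clear texture contrast

    def test_affine_intensity_invariance(self, sharp_stage):
        vf = sharp_stage["vessel_free"]
        Y1 = make_feature_matrix(vf)
        Y2 = make_feature_matrix(0.5 * vf + 0.25)
        assert np.allclose(Y1.values, Y2.values)

    def test_too_small_roi_rejected(self):
        with pytest.raises(RoiError):
            make_feature_matrix(np.zeros((5, 5)))


class TestInitLevelSet:
    def test_signed_distance_properties(self):
        field = init_level_set((100, 100), (50.0, 50.0))
        phi = field.phi
        assert phi[50, 50] == pytest.approx(-25.0)  # radius = width/4
        gr, gc = np.gradient(phi)
        mag = np.hypot(gr, gc)
        # central differences break down only across the SDF apex (3x3 block)
        mask = np.ones_like(mag, bool)
        mask[49:52, 49:52] = False
        assert np.abs(mag[mask] - 1).max() <= 0.05

    def test_zero_level_set_is_the_circle(self):
        field = init_level_set((100, 100), (50.0, 50.0))
        from skimage import measure
        (contour,) = measure.find_contours(field.phi, 0.0)
        radii = np.hypot(contour[:, 0] - 50, contour[:, 1] - 50)
        assert np.abs(radii - 25).max() < 1

    def test_center_outside_rejected(self):
        with pytest.raises(RoiError):
            init_level_set((50, 50), (60.0, 10.0))


class TestRegionWeights:
    def test_exact_recovery_with_orthogonal_columns(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((20, 2)))
        beta0 = rng.standard_normal((2, 30))
        from odefgvf.fgvf import TextureFeatureMatrix
        Y = TextureFeatureMatrix(values=q @ beta0, shape=(5, 6))
        w = compute_region_weights(Y, RepresentativeFeatures(values=q))
        assert np.allclose(w.beta, beta0, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            R = rng.standard_normal((15, 2))
            Yv = rng.standard_normal((15, 40))
            from odefgvf.fgvf import TextureFeatureMatrix
            Y = TextureFeatureMatrix(values=Yv, shape=(5, 8))
            w = compute_region_weights(Y, RepresentativeFeatures(values=R))
            oracle = np.linalg.pinv(R) @ Yv
            assert np.allclose(w.beta, oracle, atol=1e-6)

    def test_identical_columns_rejected(self):
        col = np.random.default_rng(2).standard_normal(10)
        from odefgvf.fgvf import TextureFeatureMatrix
        Y = TextureFeatureMatrix(values=np.zeros((10, 4)), shape=(2, 2))
        with pytest.raises(NumericalError):
            compute_region_weights(
                Y, RepresentativeFeatures(values=np.column_stack([col, col])))


class TestRepresentatives:
    def test_heaviside_at_zero_is_half(self):
        assert heaviside(np.array(0.0), 1.5) == pytest.approx(0.5)
        # dirac is the derivative of heaviside (finite-difference check)
        eps, z = 1.5, 0.7
        num = (heaviside(np.array(z + 1e-6), eps) - heaviside(np.array(z - 1e-6), eps)) / 2e-6
        assert dirac(np.array(z), eps) == pytest.approx(num, rel=1e-4)

    def test_weighted_mean_identity_and_region_mean_limit(self, sharp_stage):
        """R matches an explicit weighted-average oracle exactly, and
        approaches the plain per-region means as the Heaviside narrows
        (the arctan tails are heavy, so at eps = 1.5 each column mixes in a
        visible share of the opposite region by construction)."""
        Y = make_feature_matrix(sharp_stage["vessel_free"])
        od = sharp_stage["od_gt"].pixels.astype(bool)
        from scipy import ndimage
        phi = (ndimage.distance_transform_edt(~od)
               - ndimage.distance_transform_edt(od)).astype(float)
        field = LevelSetField(phi=phi)

        # oracle: explicit weighted average at the working eps
        R = update_representatives(Y, field, 1.5)
        w_obj = heaviside(-phi.reshape(-1, order="F"), 1.5)
        oracle_obj = (Y.values * w_obj).sum(axis=1) / w_obj.sum()
        assert np.allclose(R.values[:, 0], oracle_obj, atol=1e-12)

        # small-eps limit: weighted means converge to the plain region means
        R_sharp = update_representatives(Y, field, 0.05)
        flat = od.reshape(-1, order="F")
        direct_obj = Y.values[:, flat].mean(axis=1)
        direct_bg = Y.values[:, ~flat].mean(axis=1)
        assert (np.linalg.norm(R_sharp.values[:, 0] - direct_obj)
                < 0.02 * np.linalg.norm(direct_obj))
        assert (np.linalg.norm(R_sharp.values[:, 1] - direct_bg)
                < 0.02 * np.linalg.norm(direct_bg))

    def test_one_sided_phi_degenerate(self):
        from odefgvf.fgvf import TextureFeatureMatrix
        Y = TextureFeatureMatrix(values=np.ones((3, 100)), shape=(10, 10))
        phi = np.full((10, 10), 50.0)  # everything background
        with pytest.raises(DegenerateRegionError):
            update_representatives(Y, LevelSetField(phi=phi), 1.5)


class TestEvolveStep:
    def test_stationary_when_forces_balance(self):
        """omega_o == omega_b and |grad phi| == 1 is a fixed point."""
        from odefgvf.fgvf import RegionWeights, TextureFeatureMatrix
        h = w = 40
        field = init_level_set((h, w), (20.0, 20.0))
        Y = TextureFeatureMatrix(values=np.ones((3, h * w)), shape=(h, w))
        R = RepresentativeFeatures(values=np.column_stack([np.ones(3), 2 * np.ones(3)]))
        weights = RegionWeights(omega_o=np.full(h * w, 0.5), omega_b=np.full(h * w, 0.5))
        out = evolve_step(field, Y, R, FGVFParams(), weights=weights)
        inner = np.abs(out.phi - field.phi)[5:-5, 5:-5]
        # curvature of the circular level sets allows only a small residual
        assert np.median(inner) < 0.02


class TestCheckConvergence:
    def _circle(self, radius, center=(50.0, 50.0), offset=0.0):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([center[0] - radius * np.cos(t),
                               center[1] + radius * np.sin(t) + offset])
        return Contour(points=pts, closed=True)

    def test_identical_contours_converged(self):
        c = self._circle(20)
        assert check_convergence(c, c, 0.05)

    def test_threshold_is_five_hundredths(self):
        c = self._circle(20)
        assert check_convergence(self._circle(20, offset=0.04), c, 0.05)
        assert not check_convergence(self._circle(20, offset=0.06), c, 0.05)

    def test_empty_contour_raises(self):
        c = self._circle(20)
        with pytest.raises(ConvergenceError):
            check_convergence(Contour(points=np.empty((0, 2))), c, 0.05)


class TestSegmentOD:
    def test_sharp_phantom_dice(self, sharp_stage):
        mask, contour, diag = segment_od(sharp_stage["vessel_free"],
                                         sharp_stage["seed_in_roi"])
        assert diag["converged"]
        assert dice(mask, sharp_stage["od_gt"].pixels) >= 0.90

    def test_max_iters_one_returns_valid_nonconverged_mask(self, sharp_stage):
        params = FGVFParams(max_iters=1)
        mask, contour, diag = segment_od(sharp_stage["vessel_free"],
                                         sharp_stage["seed_in_roi"], params)
        assert not diag["converged"]
        assert diag["iterations"] == 1
        assert mask.any()

    def test_affine_rescale_changes_dice_little(self, sharp_stage):
        m1, _, _ = segment_od(sharp_stage["vessel_free"], sharp_stage["seed_in_roi"])
        m2, _, _ = segment_od(0.6 * sharp_stage["vessel_free"] + 0.2,
                              sharp_stage["seed_in_roi"])
        gt = sharp_stage["od_gt"].pixels
        assert abs(dice(m1, gt) - dice(m2, gt)) < 0.02
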