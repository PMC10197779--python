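"""Refocusing, FBP, FISTA, focus measures, depth sweeps, calibration."""

import warnings

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse.linalg import lsqr
from skimage.transform import iradon, radon

import lifttomo as lt
from lifttomo.operators import ForwardOperator
from lifttomo.recon import CalibrationError, InsufficientAnglesError


@pytest.fixture(scope="module")
def point_setup():
    """Off-center point imaged at shear s=4 and at focus (s=0)."""
    N = 48
    geom = lt.build_view_plan(5, N, image_size_N=N)
    img = np.zeros((N, N))
    img[30, 28] = 1.0
    s = 4.0
    sino_d = lt.forward_sinogram([(img, s)], geom)
    sino_0 = lt.forward_sinogram(img, geom)
    return geom, img, s, sino_d, sino_0


def _row_centroid(row, halfwidth=3):
    j = int(np.argmax(row))
    lo, hi = max(0, j - halfwidth), min(len(row), j + halfwidth + 1)
    w = row[lo:hi]
    return float(np.sum(np.arange(lo, hi) * w) / w.sum())


class TestRefocus:
    def test_zero_shear_leaves_sinogram_unchanged(self, point_setup):
        geom, _, _, sino_d, _ = point_setup
        out = lt.refocus_sinogram(sino_d, geom, 0.0)
        assert np.array_equal(out.rows, sino_d.rows)

    def test_matched_shear_aligns_with_in_focus_point(self, point_setup):
        geom, _, s, sino_d, sino_0 = point_setup
        ref = lt.refocus_sinogram(sino_d, geom, s)
        for i in range(sino_0.n_rows):
            assert abs(_row_centroid(ref.rows[i])
                       - _row_centroid(sino_0.rows[i])) < 0.5

    def test_refocus_roundtrip_is_identity_interior(self):
        # linear interpolation makes the roundtrip a mild smoothing, so the
        # identity holds to interpolation tolerance on smooth rows (and is
        # exact for integer-pixel shifts)
        N = 48
        geom = lt.build_view_plan(5, N, image_size_N=N)
        yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
        blob = np.exp(-((yy - 23.5) ** 2 + (xx - 23.5) ** 2) / 50.0)
        sino = lt.forward_sinogram(blob, geom)
        back = lt.refocus_sinogram(lt.refocus_sinogram(sino, geom, 2.5),
                                   geom, -2.5)
        interior = slice(10, -10)
        assert np.abs(back.rows[:, interior] - sino.rows[:, interior]).max() \
            < 0.02 * sino.rows.max()


class TestFBP:
    def test_centered_point_reconstructs_at_center(self, small_geom):
        N = small_geom.image_size_N
        img = np.zeros((N, N))
        c = (N - 1) // 2
        img[c, c] = 1.0
        rec = lt.fbp_reconstruct(lt.forward_sinogram(img, small_geom),
                                 small_geom)
        assert np.unravel_index(np.argmax(rec), rec.shape) == (c, c)

    def test_agrees_with_reference_fbp_within_half_db(self):
        """Shepp-Logan PSNR matches an independent FBP implementation."""
        N = 128
        ph = lt.shepp_logan(N)
        geom = lt.build_view_plan(1, N, image_size_N=N)
        sino = lt.forward_sinogram(ph, geom)
        mine = lt.fbp_reconstruct(sino, geom, window="hann")
        th = np.array([a for _, a in geom.angle_assignment])
        ref = iradon(radon(ph, theta=th), theta=th, filter_name="hann",
                     output_size=N)
        psnr_mine = lt.psnr(mine, ph)
        psnr_ref = lt.psnr(ref, ph)
        assert abs(psnr_mine - psnr_ref) < 0.5

    def test_linearity(self, small_geom, disk_image, rng):
        other = np.roll(disk_image, 2, axis=0)
        s1 = lt.forward_sinogram(disk_image, small_geom)
        s2 = lt.forward_sinogram(other, small_geom)
        both = lt.Sinogram(s1.rows + s2.rows, s1.views, s1.angles_deg)
        lhs = lt.fbp_reconstruct(both, small_geom)
        rhs = (lt.fbp_reconstruct(s1, small_geom)
               + lt.fbp_reconstruct(s2, small_geom))
        assert np.abs(lhs - rhs).max() < 1e-8 * np.abs(rhs).max()

    def test_too_few_angles_rejected(self, small_geom):
        one_row = lt.Sinogram(np.ones((1, 32)), [0], [0.0])
        with pytest.raises(InsufficientAnglesError):
            lt.fbp_reconstruct(one_row, small_geom)


class TestFista:
    def test_mu_zero_matches_cgls_on_well_posed_instance(self):
        """Unregularized FISTA agrees with a conjugate-gradient-style
        least-squares oracle within 1% on an overdetermined system."""
        N = 32
        ph = lt.shepp_logan(N)
        geom = lt.build_view_plan(4, 2 * N, image_size_N=N)
        op = ForwardOperator(geom)
        sino = lt.forward_sinogram(ph, geom, operator=op)
        cfg = lt.ReconConfig(mu=0.0, denoiser="none", max_iters=800,
                             rel_tol=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = lt.fista_reconstruct(sino, geom, cfg=cfg, operator=op)
        A = op.matrix(0.0)
        b = sino.rows.ravel()
        x_cg = lsqr(A, b, atol=1e-12, btol=1e-12, iter_lim=8000)[0]
        rel = (np.linalg.norm(res.image.ravel() - x_cg)
               / np.linalg.norm(x_cg))
        assert rel < 0.01
        resid = np.linalg.norm(A @ res.image.ravel() - b) / np.linalg.norm(b)
        assert resid < 1e-3

    def test_objective_non_increasing(self, small_geom, disk_image):
        sino = lt.forward_sinogram(disk_image, small_geom)
        cfg = lt.ReconConfig(mu=0.05, max_iters=40, rel_tol=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = lt.fista_reconstruct(sino, small_geom, cfg=cfg)
        assert np.all(np.diff(res.objective) <= 1e-9 * res.objective[0])

    def test_non_convergence_sets_flag_and_warns(self, small_geom, disk_image):
        sino = lt.forward_sinogram(disk_image, small_geom)
        cfg = lt.ReconConfig(mu=0.0, denoiser="none", max_iters=3,
                             rel_tol=1e-14)
        with pytest.warns(RuntimeWarning):
            res = lt.fista_reconstruct(sino, small_geom, cfg=cfg)
        assert not res.converged

    def test_sparse_bead_image_compressive_recovery(self):
        """At 9-fold angular compression a sparse bead image is recovered
        with SSIM >= 0.9 using TV regularization."""
        N = 90
        scene = lt.make_beads3d(N, n_beads=6, seed=1)
        img = scene.planes[0]
        geom = lt.build_view_plan(5, N // 9, image_size_N=N)  # CR = 9
        sino = lt.forward_sinogram(img, geom)
        cfg = lt.ReconConfig(mu=0.05, max_iters=120, rel_tol=1e-7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rec = lt.fista_reconstruct(sino, geom, cfg=cfg).image
        _, ssim = lt.image_metrics(rec, img)
        assert ssim >= 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            lt.ReconConfig(mu=-1.0)
        with pytest.raises(ValueError):
            lt.ReconConfig(max_iters=0)


@pytest.fixture(scope="module")
def two_bead_stack():
    """Two beads at -4 and +4 um, swept through refocus depths."""
    N = 48
    geom = lt.build_view_plan(5, N, image_size_N=N)
    cal = lt.ShearCalibration(slope=0.8, intercept=0.0,
                              valid_range=(-20, 20))
    yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    bead_a = (((yy - 14) ** 2 + (xx - 14) ** 2) <= 4).astype(float)
    bead_b = (((yy - 34) ** 2 + (xx - 32) ** 2) <= 4).astype(float)
    s_a, s_b = cal.shear_of(-4.0), cal.shear_of(4.0)
    sino = lt.forward_sinogram([(bead_a, s_a), (bead_b, s_b)], geom)
    depths = np.arange(-8.0, 8.1, 2.0)
    stack = lt.depth_sweep(sino, geom, cal, depths)
    return stack, (14, 14), (34, 32)


class TestFocusAndDepth:
    def test_constant_image_has_zero_focus(self):
        assert not np.any(lt.focus_measure(np.full((16, 16), 3.7)))

    def test_blur_strictly_reduces_focus(self, rng):
        sharp = np.indices((32, 32)).sum(axis=0) % 2 * 1.0  # checkerboard
        blurred = ndimage.gaussian_filter(sharp, 2.0)
        assert lt.focus_measure(sharp).mean() > lt.focus_measure(blurred).mean()

    def test_depth_sweep_slice_count_matches_protocol_span(self):
        """A -16..16 um sweep at 2 um steps yields 17 slices."""
        depths = np.arange(-16.0, 16.1, 2.0)
        assert len(depths) == 17
        N = 32
        geom = lt.build_view_plan(4, N, image_size_N=N)
        cal = lt.ShearCalibration(slope=0.3, intercept=0.0,
                                  valid_range=(-20, 20))
        img = np.zeros((N, N))
        img[15, 15] = 1.0
        sino = lt.forward_sinogram(img, geom)
        stack = lt.depth_sweep(sino, geom, cal, depths)
        assert len(stack.images) == 17

    def test_depth_map_reads_true_bead_depths(self, two_bead_stack):
        stack, pos_a, pos_b = two_bead_stack
        _, depth_map = lt.all_in_focus(stack)
        assert abs(depth_map[pos_a] - (-4.0)) <= 2.0
        assert abs(depth_map[pos_b] - 4.0) <= 2.0

    def test_edof_keeps_both_beads_sharp(self, two_bead_stack):
        stack, pos_a, pos_b = two_bead_stack
        edof, _ = lt.all_in_focus(stack)
        fm = lt.focus_measure(edof)
        for img, pos in ((edof, pos_a), (edof, pos_b)):
            # each bead at least as sharp in the composite as in the worst slice
            worst = min(lt.focus_measure(sl)[pos] for sl in stack.images)
            assert fm[pos] >= worst

    def test_single_plane_scene_gives_constant_depth_map(self):
        N = 32
        geom = lt.build_view_plan(4, N, image_size_N=N)
        cal = lt.ShearCalibration(slope=0.5, intercept=0.0,
                                  valid_range=(-10, 10))
        img = np.zeros((N, N))
        img[10:13, 18:21] = 1.0
        sino = lt.forward_sinogram(img, geom)  # in focus at s=0 -> depth 0
        stack = lt.depth_sweep(sino, geom, cal, [-4.0, 0.0, 4.0])
        edof, depth_map = lt.all_in_focus(stack)
        bright = stack.images[1] > 0.5 * stack.images[1].max()
        assert np.all(depth_map[bright] == 0.0)
        assert np.allclose(edof[bright], stack.images[1][bright])

    def test_empty_depth_list_rejected(self, small_geom, disk_image):
        sino = lt.forward_sinogram(disk_image, small_geom)
        cal = lt.ShearCalibration(slope=1.0, intercept=0.0)
        with pytest.raises(ValueError):
            lt.depth_sweep(sino, small_geom, cal, [])


class TestCalibrateDepth:
    def test_exact_line_recovered(self):
        d = np.array([-4.0, -2.0, 0.0, 2.0, 4.0])
        s = 0.8 * d + 0.1
        cal = lt.calibrate_depth(list(zip(s, d)))
        assert cal.slope == pytest.approx(0.8, abs=1e-12)
        assert cal.intercept == pytest.approx(0.1, abs=1e-12)

    def test_noisy_line_slope_within_three_standard_errors(self):
        """Monte Carlo over 100 seeds: fitted slope stays within 3 SE."""
        d = np.arange(-16.0, 16.1, 2.0)
        slopes = []
        for seed in range(100):
            rngl = np.random.default_rng(seed)
            s = 0.8 * d + 0.1 + rngl.normal(0, 0.01, size=d.size)
            slopes.append(lt.calibrate_depth(list(zip(s, d))).slope)
        slopes = np.asarray(slopes)
        se = 0.01 / np.sqrt(np.sum((d - d.mean()) ** 2))
        assert np.abs(slopes - 0.8).max() < 5 * se  # individual fits
        assert abs(slopes.mean() - 0.8) < 3 * se / np.sqrt(100)

    def test_single_depth_rejected(self):
        with pytest.raises(CalibrationError):
            lt.calibrate_depth([(1.0, 2.0), (1.1, 2.0)])

    def test_refocus_reconstruct_consistency(self):
        """A point simulated at depth d is sharpest at its own shear."""
        N = 48
        geom = lt.build_view_plan(5, N, image_size_N=N)
        img = np.zeros((N, N))
        img[30, 28] = 1.0
        s_true = 3.0
        sino = lt.forward_sinogram([(img, s_true)], geom)
        scores = {}
        for s in np.arange(-6.0, 6.1, 1.5):
            rec = lt.fbp_reconstruct(sino, geom, s=s)
            scores[s] = lt.focus_measure(rec)[30, 28]
        assert max(scores, key=scores.get) == pytest.approx(s_true)
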