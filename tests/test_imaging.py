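import numpy as np
import pytest

from diatrack import geometry as g
from diatrack import imaging as im
from diatrack import phantom as ph
from diatrack.exceptions import (
    BadDimsError,
    EmptyWindowError,
    LostTrackError,
    MissingEpipolarError,
    ZeroVarianceError,
)


def make_image(arr, **kw):
    return im.ProjectionImage(intensity=np.asarray(arr, dtype=float), **kw)


def small_template(arr, apex=(2.0, 2.0)):
    return im.DiaphragmTemplate(
        intensity=np.asarray(arr, dtype=float),
        gantry_angle=0.0,
        apex_offset=g.PixelCoord(*apex),
        strict_shape=False,
    )


class TestInpaintMarkers:
    def test_constant_background_restored_exactly(self):
        arr = np.full((64, 64), 100.0)
        arr[30:34, 30:34] = 0.0  # dark marker
        img = make_image(arr, known_marker_pixels=(g.PixelCoord(31.5, 31.5),))
        out = im.inpaint_markers(img)
        np.testing.assert_array_equal(out.intensity, 100.0)

    def test_gradient_background_annulus_mean_oracle(self):
        vv, uu = np.mgrid[0:64, 0:64]
        arr = 10.0 + 0.5 * uu + 0.25 * vv
        center = g.PixelCoord(30.0, 28.0)
        img = make_image(arr, known_marker_pixels=(center,))
        out = im.inpaint_markers(img)
        # explicit pixel-set oracle
        r2 = (uu - center.u) ** 2 + (vv - center.v) ** 2
        disc = r2 <= 25.0
        annulus = (r2 > 25.0) & (r2 <= 100.0)
        expected = arr[annulus].mean()
        np.testing.assert_allclose(out.intensity[disc], expected, atol=1e-12)
        np.testing.assert_array_equal(out.intensity[~disc], arr[~disc])

    def test_no_markers_bit_exact(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, (32, 32))
        out = im.inpaint_markers(make_image(arr))
        np.testing.assert_array_equal(out.intensity, arr)

    def test_marker_near_border(self):
        arr = np.full((32, 32), 50.0)
        img = make_image(arr, known_marker_pixels=(g.PixelCoord(1.0, 1.0),))
        out = im.inpaint_markers(img)
        np.testing.assert_array_equal(out.intensity, 50.0)


class TestLogInvert:
    def test_constant_maps_to_itself(self):
        out = im.log_invert(make_image(np.full((8, 8), 42.0)))
        np.testing.assert_array_equal(out.intensity, 42.0)

    def test_order_reversal(self):
        arr = np.array([[0.0, 1.0, 10.0, 100.0]])
        out = im.log_invert(make_image(arr)).intensity.ravel()
        assert np.all(np.diff(out) < 0)

    def test_hand_computed_two_values(self):
        # inputs {0, e-1}: log1p -> {0, 1}; inverted -> {1, 0}; rescaled to
        # the input range this maps 0 -> e-1 and e-1 -> 0
        e1 = np.e - 1.0
        arr = np.array([[0.0, e1], [0.0, e1]])
        out = im.log_invert(make_image(arr)).intensity
        np.testing.assert_allclose(out[:, 0], e1, atol=1e-12)
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)

    def test_preserves_dynamic_range(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(5, 900, (16, 16))
        out = im.log_invert(make_image(arr)).intensity
        assert out.min() == pytest.approx(arr.min(), abs=1e-9)
        assert out.max() == pytest.approx(arr.max(), abs=1e-9)


class TestResolutionMatch:
    def test_constant_preserved(self):
        out = im.resolution_match(make_image(np.full((1024, 768), 7.0)))
        np.testing.assert_allclose(out.intensity, 7.0, atol=1e-9)

    def test_shape_preserved(self):
        rng = np.random.default_rng(2)
        out = im.resolution_match(make_image(rng.uniform(0, 1, (1024, 768))))
        assert out.shape == (1024, 768)

    def test_checkerboard_suppressed(self):
        vv, uu = np.mgrid[0:1024, 0:768]
        arr = 100.0 + 50.0 * ((uu + vv) % 2)  # 2-px period, amplitude 25
        out = im.resolution_match(make_image(arr)).intensity
        amp_in = (arr.max() - arr.min()) / 2
        amp_out = (out.max() - out.min()) / 2
        assert amp_out < 0.1 * amp_in

    def test_bad_dims(self):
        with pytest.raises(BadDimsError):
            im.resolution_match(make_image(np.zeros((100, 100))))


class TestPreprocess:
    def test_output_dims(self):
        rng = np.random.default_rng(3)
        out = im.preprocess(make_image(rng.uniform(1, 100, (1024, 768))))
        assert out.shape == (1024, 768)

    def test_constant_with_markers_stays_constant(self):
        arr = np.full((1024, 768), 80.0)
        arr[500:504, 300:304] = 0.0
        img = make_image(arr, known_marker_pixels=(g.PixelCoord(301.5, 501.5),))
        out = im.preprocess(img)
        np.testing.assert_allclose(out.intensity, 80.0, atol=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        arr = rng.uniform(1, 100, (1024, 768))
        a = im.preprocess(make_image(arr)).intensity
        b = im.preprocess(make_image(arr)).intensity
        np.testing.assert_array_equal(a, b)


def brute_force_ncc(image, template, apex_offset):
    """Independent per-offset oracle: two-pass zero-mean NCC via explicit
    patch extraction; ties broken by smallest v then smallest u."""
    th, tw = template.shape
    best = (-np.inf, None)
    gammas = {}
    for v0 in range(image.shape[0] - th + 1):
        for u0 in range(image.shape[1] - tw + 1):
            patch = image[v0 : v0 + th, u0 : u0 + tw]
            pd = patch - patch.mean()
            td = template - template.mean()
            denom = np.sqrt((pd * pd).sum() * (td * td).sum())
            if denom == 0:
                continue
            gamma = float((pd * td).sum() / denom)
            apex = (u0 + apex_offset[0], v0 + apex_offset[1])
            gammas[apex] = gamma
            if gamma > best[0]:
                best = (gamma, apex)
    return best[1], best[0], gammas


class TestNccMatch:
    def test_exact_location_scores_one(self):
        rng = np.random.default_rng(5)
        image = rng.uniform(0, 1, (40, 40))
        tmpl_arr = image[10:15, 20:25].copy()
        tmpl = small_template(tmpl_arr)
        window = im.SearchWindow(0, 39, 0, 39)
        m = im.ncc_match(make_image(image), tmpl, window)
        assert m.gamma == pytest.approx(1.0, abs=1e-12)
        assert (m.apex.u, m.apex.v) == (22.0, 12.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        image = rng.uniform(0, 1, (30, 30))
        tmpl = small_template(3.0 * image[8:13, 9:14] + 40.0)
        m = im.ncc_match(make_image(image), tmpl, im.SearchWindow(0, 29, 0, 29))
        assert m.gamma == pytest.approx(1.0, abs=1e-12)
        assert (m.apex.u, m.apex.v) == (11.0, 10.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.uniform(0, 100, (12, 12))
        tmpl_arr = rng.uniform(0, 100, (5, 5))
        tmpl = small_template(tmpl_arr)
        m = im.ncc_match(make_image(image), tmpl, im.SearchWindow(0, 11, 0, 11))
        apex, gamma, gammas = brute_force_ncc(image, tmpl_arr, (2, 2))
        assert (m.apex.u, m.apex.v) == apex
        assert m.gamma == pytest.approx(gamma, abs=1e-12)
        # every placement's score agrees, not just the argmax
        for (u, v), gbf in gammas.items():
            sub = im.ncc_match(
                make_image(image), tmpl, im.SearchWindow(u, u, v, v)
            )
            assert sub.gamma == pytest.approx(gbf, abs=1e-12)

    def test_gamma_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            image = rng.uniform(0, 1, (15, 15))
            tmpl = small_template(rng.uniform(0, 1, (5, 5)))
            m = im.ncc_match(make_image(image), tmpl, im.SearchWindow(0, 14, 0, 14))
            assert -1.0 <= m.gamma <= 1.0

    def test_constant_template_raises(self):
        img = make_image(np.random.default_rng(8).uniform(0, 1, (12, 12)))
        with pytest.raises(ZeroVarianceError):
            im.ncc_match(img, small_template(np.ones((5, 5))), im.SearchWindow(0, 11, 0, 11))

    def test_constant_image_raises(self):
        tmpl = small_template(np.random.default_rng(9).uniform(0, 1, (5, 5)))
        with pytest.raises(ZeroVarianceError):
            im.ncc_match(make_image(np.ones((12, 12))), tmpl, im.SearchWindow(0, 11, 0, 11))

    def test_empty_window_raises(self):
        tmpl = small_template(np.random.default_rng(10).uniform(0, 1, (5, 5)))
        img = make_image(np.random.default_rng(11).uniform(0, 1, (12, 12)))
        with pytest.raises(EmptyWindowError):
            im.ncc_match(img, tmpl, im.SearchWindow(0, 1, 0, 1))  # template sticks out

    def test_tie_break_smallest_v_then_u(self):
        # two identical optimal placements: periodic image
        image = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (6, 6))
        tmpl = small_template(image[0:4, 0:4], apex=(0.0, 0.0))
        m = im.ncc_match(make_image(image), tmpl, im.SearchWindow(0, 8, 0, 8))
        assert (m.apex.u, m.apex.v) == (0.0, 0.0)


class TestBuildSearchWindow:
    def test_non_lateral_window(self):
        geom = g.ViewGeometry(gantry_angle=0.0)
        w = im.build_search_window(g.PixelCoord(400, 500), "non_lateral", None, geom)
        assert (w.u_min, w.u_max, w.v_min, w.v_max) == (390, 410, 450, 550)

    def test_lateral_window_from_epipolar_edges(self):
        geom = g.ViewGeometry(gantry_angle=90.0)
        epi = g.EpipolarSegment(
            a=0.0, b=1.0, c=-512.0,
            edge_points=(g.PixelCoord(0.0, 510.0), g.PixelCoord(767.0, 514.0)),
        )
        w = im.build_search_window(g.PixelCoord(400, 500), "lateral", epi, geom)
        assert (w.v_min, w.v_max) == (495, 529)
        assert (w.u_min, w.u_max) == (390, 410)

    def test_clipping_to_image(self):
        geom = g.ViewGeometry(gantry_angle=0.0)
        w = im.build_search_window(g.PixelCoord(3, 10), "non_lateral", None, geom)
        assert w.u_min == 0 and w.v_min == 0
        assert (w.u_max, w.v_max) == (13, 60)

    def test_lateral_requires_epipolar(self):
        geom = g.ViewGeometry(gantry_angle=90.0)
        with pytest.raises(MissingEpipolarError):
            im.build_search_window(g.PixelCoord(400, 500), "lateral", None, geom)

    def test_non_lateral_size_bound(self):
        geom = g.ViewGeometry(gantry_angle=0.0)
        rng = np.random.default_rng(12)
        for _ in range(50):
            q = g.PixelCoord(rng.uniform(0, 767), rng.uniform(0, 1023))
            w = im.build_search_window(q, "non_lateral", None, geom)
            assert w.size[0] <= 21 and w.size[1] <= 101


class TestNearestTemplate:
    def _bank(self, angles):
        return [
            im.DiaphragmTemplate(
                intensity=np.zeros((2, 2)) + i, gantry_angle=a,
                apex_offset=g.PixelCoord(0, 0), strict_shape=False,
            )
            for i, a in enumerate(angles)
        ]

    def test_nearest(self):
        bank = self._bank([330.0, 330.3, 330.6])
        assert im.nearest_template(bank, 330.4).gantry_angle == 330.3

    def test_tie_goes_to_lower_angle(self):
        bank = self._bank([330.0, 330.3])
        assert im.nearest_template(bank, 330.15).gantry_angle == 330.0

    def test_wraparound(self):
        bank = self._bank([359.7, 0.0, 0.3])
        assert im.nearest_template(bank, 359.9).gantry_angle == 0.0


class TestTrackSession:
    def test_phantom_tracking_accuracy(self, tracked_session, true_apex_projections):
        res = tracked_session
        err3d = np.linalg.norm(res.track.apex_3d - res.truth.apex, axis=1)
        assert np.median(err3d) < 1.0
        for imager in (1, 2):
            d = np.linalg.norm(
                res.track.apex_2d(imager) - true_apex_projections[imager], axis=1
            )
            assert (d <= 2.0).mean() >= 0.95

    def test_exactly_one_epipolar_constraint_on_lateral_frames(self, tracked_session):
        res = tracked_session
        for k in range(len(res.truth)):
            r1 = g.classify_region(res.truth.angle1_deg[k])
            r2 = g.classify_region(res.truth.angle2_deg[k])
            assert (r1, r2) != ("lateral", "lateral")
            m1 = res.track.matches[1][k]
            m2 = res.track.matches[2][k]
            if k > 0:  # frame 0 windows come from the seed
                assert m1.region == r1 and m2.region == r2

    def test_gamma_stays_high_on_clean_phantom(self, tracked_session):
        for imager in (1, 2):
            assert tracked_session.track.gammas(imager).min() > 0.8

    def test_identical_frames_give_identical_results(self):
        # two-frame session with frozen anatomy: frame 1 repeats frame 0
        anat = ph.AnatomyConfig()
        sig = ph.simulate_respiration(
            ph.RespiratoryConfig(amplitude_mm=0.0), 0.4, 0.2
        )
        truth = ph.simulate_anatomy(sig, anat)
        banks = ph.template_bank(anat, arc=truth.arc)
        frames = {1: [], 2: []}
        for imager in (1, 2):
            g1, g2 = g.view_pair(truth.angle1_deg[0])
            geom = g1 if imager == 1 else g2
            f = ph.render_frame(truth.apex[0], truth.markers[0], geom)
            frames[imager] = [f, f]
        seed = {
            i: g.project_point(frames[i][0].view, truth.apex[0]) for i in (1, 2)
        }
        res = im.track_session(
            frames, banks, initial_apexes=seed, times_s=np.array([0.0, 0.2])
        )
        for imager in (1, 2):
            a, b = res.matches[imager]
            assert (a.apex.u, a.apex.v) == (b.apex.u, b.apex.v)
            assert a.gamma == b.gamma

    def test_lost_track_on_structureless_frames(self):
        anat = ph.AnatomyConfig()
        banks = ph.template_bank(anat, arc=ph.ARC_CW)
        rng = np.random.default_rng(13)
        frames = {1: [], 2: []}
        for k in range(6):
            g1, g2 = g.view_pair(330.0 + 0.3 * k)
            for imager, geom in ((1, g1), (2, g2)):
                arr = rng.uniform(100.0, 101.0, (1024, 768))
                frames[imager].append(im.ProjectionImage(intensity=arr, view=geom))
        seed = {1: g.PixelCoord(400.0, 500.0), 2: g.PixelCoord(400.0, 500.0)}
        with pytest.raises(LostTrackError):
            im.track_session(
                frames, banks, initial_apexes=seed, times_s=np.arange(6) * 0.2
            )
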