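"""Side-view detection, profile extraction, apposition and positivity."""

import math

import numpy as np
import pytest
from scipy import ndimage, optimize

from stedview.profiling import (
    DetectionParams,
    SideViewROI,
    align_and_average,
    classify_positive,
    detect_sideview_candidates,
    extract_profile,
    measure_apposition,
    positive_fraction,
    smooth_profile,
)
from stedview.profiling import LineProfile
from stedview.synthetic import (
    ChannelSpec,
    SceneSpec,
    SynapseGroundTruth,
    render_scene,
)


def _measure_scene(scene, pixel_size, smooth_px=5):
    rois = detect_sideview_candidates(
        scene.channel("scaffold"), scene.channel("vesicle"), pixel_size
    )
    assert len(rois) == 1
    sm = smooth_profile(extract_profile(scene.images, rois[0], pixel_size), smooth_px)
    return measure_apposition(sm, "scaffold", "protein"), rois[0]


class TestDetection:
    def test_bar_with_cloud_detected_with_orientation(self, single_synapse_scene):
        theta = 0.6
        scene, syn = single_synapse_scene(theta=theta)
        rois = detect_sideview_candidates(
            scene.channel("scaffold"), scene.channel("vesicle"), 20.0
        )
        assert len(rois) == 1
        got = rois[0].axis_normal
        want = syn.axis_normal
        ang = math.degrees(math.acos(abs(got[0] * want[0] + got[1] * want[1])))
        assert ang < 5.0
        # signed toward the cloud
        assert got[0] * want[0] + got[1] * want[1] > 0

    def test_round_blob_rejected(self):
        channels = [
            ChannelSpec("Synaptophysin", "confocal", 250.0, 0.0, role="vesicle"),
            ChannelSpec("scaffold", "sted", 50.0, 0.0, role="scaffold"),
        ]
        # a circular scaffold blob (aspect 1) next to a normal cloud
        syn = SynapseGroundTruth(
            center=(1280, 1280), bar_length=60.0, bar_thickness_sigma=30.0,
            amplitudes={"vesicle": 800.0, "scaffold": 1000.0},
        )
        scene = render_scene(SceneSpec((129, 129), 20.0, channels, [syn], noise="none"))
        assert detect_sideview_candidates(
            scene.images["scaffold"], scene.images["Synaptophysin"], 20.0
        ) == []

    def test_bar_without_cloud_rejected(self, single_synapse_scene):
        scene, _ = single_synapse_scene()
        empty_vesicle = np.zeros_like(scene.channel("vesicle"))
        with pytest.warns(UserWarning, match="constant"):
            rois = detect_sideview_candidates(scene.channel("scaffold"), empty_vesicle, 20.0)
        assert rois == []


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self):
        images = {"c": np.full((129, 129), 3.5)}
        roi = SideViewROI(bar_center=(1280, 1280), axis_normal=(0.0, 1.0))
        p = extract_profile(images, roi, 20.0)
        assert np.allclose(p.intensities["c"], 3.5)
        assert p.positions[0] == -500.0 and p.positions[-1] == 500.0

    def test_gaussian_bar_cross_section_width_recovered(self, single_synapse_scene):
        scene, syn = single_synapse_scene(bar_thickness_sigma=60.0, sted_fwhm=1.0)
        roi = SideViewROI(bar_center=syn.center, axis_normal=syn.axis_normal)
        p = extract_profile(scene.images, roi, 20.0)

        def g(x, a, mu, sig):
            return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

        popt, _ = optimize.curve_fit(g, p.positions, p.intensities["scaffold"], p0=[1000, 0, 50])
        assert abs(abs(popt[2]) - 60.0) / 60.0 < 0.05

    def test_oblique_sampling_matches_rotation_oracle(self, single_synapse_scene):
        """Bilinear sampling along an oblique line equals resampling the whole
        image onto a rotated grid and reading axis-aligned rows."""
        theta = 1.1
        scene, syn = single_synapse_scene(theta=theta)
        img = scene.images["scaffold"]
        roi = SideViewROI(bar_center=syn.center, axis_normal=syn.axis_normal)
        prof = extract_profile(scene.images, roi, 20.0).intensities["scaffold"]
        nx, ny = roi.axis_normal
        A = np.array([[ny, -nx], [nx, ny]])  # rows of output along normal / bar
        c = (img.shape[0] - 1) // 2
        c_in = np.array([syn.center[1] / 20.0, syn.center[0] / 20.0])
        c_out = np.array([float(c), float(c)])
        rot = ndimage.affine_transform(img, A, offset=c_in - A @ c_out, order=1, mode="nearest")
        nsteps = (len(prof) - 1) // 2
        nw = int(250 / 2 / 20.0)
        oracle = rot[c - nsteps : c + nsteps + 1, c - nw : c + nw + 1].mean(axis=1)
        assert np.max(np.abs(prof - oracle)) / img.max() < 0.01

    def test_roi_outside_image_raises(self):
        images = {"c": np.zeros((64, 64))}
        roi = SideViewROI(bar_center=(100.0, 100.0), axis_normal=(0.0, 1.0))
        with pytest.raises(ValueError, match="bounds"):
            extract_profile(images, roi, 20.0)


class TestSmoothProfile:
    def test_constant_unchanged(self):
        p = LineProfile(np.arange(5.0), {"c": np.full(5, 2.0)})
        assert np.allclose(smooth_profile(p, 5).intensities["c"], 2.0)

    def test_impulse_center_value(self):
        p = LineProfile(np.arange(5.0), {"c": np.array([0.0, 0, 5, 0, 0])})
        assert smooth_profile(p, 5).intensities["c"][2] == pytest.approx(1.0)

    def test_linear_ramp_interior_preserved(self):
        p = LineProfile(np.arange(11.0), {"c": np.arange(11.0) * 3.0})
        out = smooth_profile(p, 5).intensities["c"]
        assert np.allclose(out[2:-2], (np.arange(11.0) * 3.0)[2:-2])


class TestMeasureApposition:
    def test_zero_offset_within_one_step(self, single_synapse_scene):
        scene, _ = single_synapse_scene(true_offset=0.0)
        m, _ = _measure_scene(scene, 20.0)
        assert abs(m.distance) <= 20.0

    def test_offset_40nm_recovered(self, single_synapse_scene):
        scene, _ = single_synapse_scene(true_offset=40.0)
        m, _ = _measure_scene(scene, 20.0)
        assert m.distance == pytest.approx(40.0, abs=10.0)
        assert not m.window_truncated

    def test_offset_beyond_window_truncates_at_100(self, single_synapse_scene):
        scene, _ = single_synapse_scene(true_offset=150.0)
        m, _ = _measure_scene(scene, 20.0)
        assert m.distance == pytest.approx(100.0, abs=1e-9)
        assert m.window_truncated

    def test_window_invariant(self, single_synapse_scene):
        for off in (0.0, 60.0, 150.0):
            scene, _ = single_synapse_scene(true_offset=off)
            m, _ = _measure_scene(scene, 20.0)
            if not m.window_truncated:
                assert abs(m.distance) <= 100.0

    def test_sign_convention_follows_presynapse(self, single_synapse_scene):
        """Presynaptic-side offsets read positive; flipping the band to the
        postsynaptic side flips the sign but not the magnitude, and a scene
        mirrored together with its cloud keeps the positive sign."""
        toward, _ = single_synapse_scene(true_offset=40.0, theta=0.0, cloud_side=1)
        away, _ = single_synapse_scene(true_offset=-40.0, theta=0.0, cloud_side=1)
        mirrored, _ = single_synapse_scene(true_offset=40.0, theta=0.0, cloud_side=-1)
        m_t, _ = _measure_scene(toward, 20.0)
        m_a, _ = _measure_scene(away, 20.0)
        m_m, _ = _measure_scene(mirrored, 20.0)
        assert m_t.distance == pytest.approx(40.0, abs=10.0)
        assert m_a.distance == pytest.approx(-m_t.distance, abs=1e-9)
        assert m_m.distance == pytest.approx(m_t.distance, abs=1e-9)

    def test_average_profile_asymmetric_toward_presynapse(self, single_synapse_scene):
        """A cleft-offset protein band biases the averaged profile toward
        the presynaptic side of the scaffold peak."""
        ms, ps = [], []
        for seed in range(5):
            scene, syn = single_synapse_scene(true_offset=40.0, theta=0.4 * seed, noise="poisson", seed=seed)
            rois = detect_sideview_candidates(scene.channel("scaffold"), scene.channel("vesicle"), 20.0)
            sm = smooth_profile(extract_profile(scene.images, rois[0], 20.0), 5)
            ms.append(measure_apposition(sm, "scaffold", "protein"))
            ps.append(sm)
        avg = align_and_average(ms, ps)
        prot = avg.mean["protein"]
        pre = prot[avg.positions > 0].sum()
        post = prot[avg.positions < 0].sum()
        assert pre > post


class TestAlignAndAverage:
    def _profile(self, shift=0.0):
        pos = np.arange(-10, 11) * 20.0
        scaf = np.exp(-0.5 * ((pos - shift) / 60.0) ** 2)
        return LineProfile(pos, {"scaffold": scaf, "protein": scaf * 0.5}, smoothing_window=5)

    def test_identical_profiles_mean_equals_profile_sem_zero(self):
        ps = [self._profile() for _ in range(4)]
        ms = [measure_apposition(p, "scaffold", "protein") for p in ps]
        avg = align_and_average(ms, ps)
        ref = self._profile()
        sel = np.isin(ref.positions, avg.positions)
        assert np.allclose(avg.mean["scaffold"], ref.intensities["scaffold"][sel])
        assert np.allclose(avg.sem["scaffold"], 0.0)
        assert avg.n_synapses == 4

    def test_offset_profiles_coincide_after_alignment(self):
        p1, p2 = self._profile(0.0), self._profile(20.0)
        ms = [measure_apposition(p, "scaffold", "protein") for p in (p1, p2)]
        avg = align_and_average(ms, [p1, p2])
        assert avg.positions[np.argmax(avg.mean["scaffold"])] == 0.0

    def test_single_profile_sem_missing(self):
        p = self._profile()
        m = measure_apposition(p, "scaffold", "protein")
        avg = align_and_average([m], [p])
        assert np.all(np.isnan(avg.sem["scaffold"]))

    def test_averaging_linearity(self):
        """Average of aligned identical-shape profiles equals the aligned
        profile of the average."""
        ps = [self._profile(s) for s in (-20.0, 0.0, 20.0)]
        ms = [measure_apposition(p, "scaffold", "protein") for p in ps]
        avg = align_and_average(ms, ps)
        ref = self._profile(0.0)
        sel = np.isin(ref.positions, avg.positions)
        assert np.allclose(avg.mean["scaffold"], ref.intensities["scaffold"][sel], atol=1e-12)


class TestClassifyPositive:
    def test_hand_computed_threshold(self):
        ko = {"c1": [10, 12, 14, 10, 14]}  # mean 12, sample SD 2 -> threshold 18
        calls = classify_positive([20.0, 18.0], ["c1", "c1"], ko)
        assert calls.threshold.iloc[0] == pytest.approx(18.0)
        assert bool(calls.positive.iloc[0]) is True
        assert bool(calls.positive.iloc[1]) is False  # strictly greater than

    def test_below_ko_mean_is_negative(self):
        calls = classify_positive([5.0], ["c1"], {"c1": [10, 12, 14, 10, 14]})
        assert bool(calls.positive.iloc[0]) is False

    def test_small_reference_culture_undetermined(self):
        with pytest.warns(UserWarning, match="undetermined"):
            calls = classify_positive([5.0, 7.0], ["c1", "c2"], {"c1": [10.0], "c2": [1.0, 2.0, 3.0]})
        assert calls.positive.isna().iloc[0]
        assert not calls.positive.isna().iloc[1]
        frac = positive_fraction(calls)
        assert frac["pooled"] == 1.0  # only the determined call counts

    def test_null_calibration_matches_gaussian_tail(self):
        """Peaks drawn from the reference distribution exceed the 3-SD
        threshold at the standard-normal rate P(Z>3) ~ 0.135%."""
        rng = np.random.default_rng(12345)
        ko = rng.normal(100.0, 10.0, 100_000)
        test = rng.normal(100.0, 10.0, 100_000)
        calls = classify_positive(test, ["c"] * len(test), {"c": ko})
        frac = positive_fraction(calls)["pooled"]
        assert frac == pytest.approx(0.00135, abs=0.0005)
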