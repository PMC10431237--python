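import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinophys import ihc, synth
from retinophys.ihc import (CHAT_ANCHORS, DepthProfile, align_profile,
                            average_profiles, compare_at_bands,
                            difference_profile, extract_profile,
                            find_band_peaks, hierarchical_average,
                            normalize_to_reference, project_stack,
                            reference_band_peaks)
from retinophys.synth import ProfileSimParams, simulate_depth_profile


def make_profile(centers=(0.33, 0.58), amps=(1.0, 1.0), noise=0.0, seed=0,
                 **kw):
    p = ProfileSimParams(band_centers=centers,
                         band_widths=(0.04,) * len(centers),
                         band_amplitudes=amps, noise_sd=noise, seed=seed, **kw)
    ref, _, _ = simulate_depth_profile(p)
    return ref


class TestProjection:
    def test_single_slice_identity(self):
        rng = np.random.default_rng(0)
        pix = rng.random((1, 20, 10, 2))
        stack = ihc.ImageStack(pix, ("reference", "target"), "reference")
        out = project_stack(stack, k=1, n=1)
        assert np.array_equal(out["reference"], pix[0, :, :, 0])

    def test_projection_dominates_contributing_slices(self):
        rng = np.random.default_rng(1)
        pix = rng.random((5, 30, 8, 2))
        stack = ihc.ImageStack(pix, ("reference", "target"), "reference")
        out = project_stack(stack, k=3, n=5)
        central = pix[1:4]
        for i, name in enumerate(stack.channel_names):
            assert np.all(out[name] >= central[..., i].max(axis=0) - 1e-12)
            assert np.allclose(out[name], central[..., i].max(axis=0))

    def test_k_exceeding_slices_rejected(self):
        pix = np.zeros((2, 10, 5, 1))
        stack = ihc.ImageStack(pix, ("reference",), "reference")
        with pytest.raises(ValueError):
            project_stack(stack, k=3, n=5)


class TestExtractProfile:
    def test_uniform_image_flat_profile(self):
        img = np.full((50, 20), 7.0)
        prof = extract_profile(img, roi=(0, 50, 0, 20), ipl_bounds=(5, 45))
        assert np.allclose(prof.intensity, 7.0)
        assert prof.depth[0] == 0.0 and prof.depth[-1] == 100.0

    def test_single_column_roi_equals_that_column(self):
        rng = np.random.default_rng(2)
        img = rng.random((40, 10))
        prof = extract_profile(img, roi=(0, 40, 3, 4), ipl_bounds=(0, 39))
        assert np.allclose(prof.intensity, img[:, 3])

    def test_band_image_reproduces_band_model(self):
        ref_p = ProfileSimParams(band_centers=(0.33, 0.58), noise_sd=0.0)
        tgt_p = ProfileSimParams(band_centers=(0.33, 0.58), noise_sd=0.0)
        stack = synth.profile_stack(ref_p, tgt_p)
        img = project_stack(stack, 3, 5)["reference"]
        prof = extract_profile(img, roi=(0, img.shape[0], 0, img.shape[1]),
                               ipl_bounds=(0, img.shape[0] - 1))
        ref, _, _ = simulate_depth_profile(ref_p)
        assert np.allclose(prof.intensity, ref.intensity)

    def test_degenerate_roi_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            extract_profile(img, roi=(0, 0, 0, 10), ipl_bounds=(0, 0))


class TestPeakDetection:
    def test_noiseless_two_band_centers_found(self):
        prof = make_profile(centers=(0.33, 0.58))
        peaks = find_band_peaks(prof)
        assert np.allclose(peaks, [33.0, 58.0], atol=0.5)

    def test_flat_profile_no_peaks(self):
        prof = DepthProfile(depth=np.linspace(0, 100, 101),
                            intensity=np.full(101, 3.0))
        assert find_band_peaks(prof).size == 0

    def test_single_band_single_peak(self):
        p = ProfileSimParams(band_centers=(0.5,), band_widths=(0.05,),
                             band_amplitudes=(1.0,))
        ref = ihc.DepthProfile(
            depth=np.linspace(0, 100, 201),
            intensity=0.1 + np.exp(-(np.linspace(0, 100, 201) - 50) ** 2
                                   / (2 * 5.0 ** 2)))
        peaks = find_band_peaks(ref)
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(50.0, abs=0.5)

    def test_chat_mode_selects_two_most_prominent(self):
        depth = np.linspace(0, 100, 201)
        y = (0.1 + 1.0 * np.exp(-(depth - 30) ** 2 / 50)
             + 0.9 * np.exp(-(depth - 60) ** 2 / 50)
             + 0.2 * np.exp(-(depth - 85) ** 2 / 50))
        prof = DepthProfile(depth=depth, intensity=y)
        outer, inner = reference_band_peaks(prof, mode="chat")
        assert outer == pytest.approx(30.0, abs=1.0)
        assert inner == pytest.approx(60.0, abs=1.0)

    def test_calretinin_mode_uses_outermost_and_innermost(self):
        depth = np.linspace(0, 100, 201)
        y = (0.1 + 0.8 * np.exp(-(depth - 25) ** 2 / 50)
             + 1.0 * np.exp(-(depth - 50) ** 2 / 50)
             + 0.9 * np.exp(-(depth - 75) ** 2 / 50))
        prof = DepthProfile(depth=depth, intensity=y)
        outer, inner = reference_band_peaks(prof, mode="calretinin")
        assert outer == pytest.approx(25.0, abs=1.0)
        assert inner == pytest.approx(75.0, abs=1.0)


class TestAlignment:
    def test_identity_when_already_on_anchors(self):
        prof = make_profile(centers=(0.28, 0.63))
        out = align_profile(prof, (28.0, 63.0))
        # warp is the identity; values at the anchors unchanged
        for anchor in (28.0, 63.0):
            assert out.value_at(anchor) == pytest.approx(
                prof.value_at(anchor), rel=1e-6)
        assert out.aligned and out.reference_peaks == (28.0, 63.0)

    def test_peaks_land_on_anchors(self):
        prof = make_profile(centers=(0.33, 0.58))
        peaks = reference_band_peaks(prof)
        out = align_profile(prof, peaks)
        redetected = find_band_peaks(out)
        assert np.allclose(redetected[:2], CHAT_ANCHORS, atol=0.5)

    @given(outer=st.floats(11.0, 44.0), inner=st.floats(51.0, 89.0))
    @settings(max_examples=30, deadline=None)
    def test_warp_is_strictly_monotone(self, outer, inner):
        x, y = ihc._warp_knots((outer, inner), CHAT_ANCHORS)
        grid = np.linspace(0, 100, 201)
        warped = np.interp(grid, x, y)
        assert np.all(np.diff(warped) > 0)

    def test_same_warp_applies_to_target_channel(self):
        ref_p = ProfileSimParams(band_centers=(0.33, 0.58))
        tgt_p = ProfileSimParams(band_centers=(0.40, 0.70),
                                 band_amplitudes=(1.0, 0.5))
        ref, tgt, _ = simulate_depth_profile(ref_p, tgt_p)
        peaks = reference_band_peaks(ref)
        tgt_al = align_profile(tgt, peaks)
        # target band at 40% maps through the same knots: between 28 and 63
        x, yk = ihc._warp_knots(peaks, CHAT_ANCHORS)
        expected = np.interp(40.0, x, yk)
        det = find_band_peaks(tgt_al)
        assert np.min(np.abs(det - expected)) <= 1.0

    def test_out_of_order_peaks_rejected(self):
        prof = make_profile()
        with pytest.raises(ValueError):
            align_profile(prof, (63.0, 28.0))


class TestGroupStatistics:
    def test_identical_profiles_mean_and_zero_sem(self):
        prof = align_profile(make_profile(), (33.0, 58.0))
        avg = average_profiles([prof, prof, prof])
        assert np.allclose(avg.intensity, prof.intensity)
        assert np.allclose(avg.sem, 0.0)

    def test_two_profile_mean(self):
        a = align_profile(make_profile(amps=(1.0, 1.0)), (33.0, 58.0))
        b = align_profile(make_profile(amps=(0.5, 0.5)), (33.0, 58.0))
        avg = average_profiles([a, b])
        assert np.allclose(avg.intensity, (a.intensity + b.intensity) / 2)

    def test_sem_matches_noise_scaling(self):
        profs = [align_profile(make_profile(noise=0.05, seed=s), (33.0, 58.0))
                 for s in range(6)]
        avg = average_profiles(profs)
        mat = np.stack([p.intensity for p in profs])
        assert np.allclose(avg.sem, mat.std(axis=0, ddof=1) / np.sqrt(6))

    def test_mixed_alignment_states_rejected(self):
        a = align_profile(make_profile(), (33.0, 58.0))
        b = make_profile()
        with pytest.raises(ValueError):
            average_profiles([a, b])

    def test_hierarchical_average_over_animals(self):
        profs = []
        for animal in ("a1", "a1", "a2"):
            p = make_profile(noise=0.02, seed=len(profs))
            p = align_profile(p, (33.0, 58.0))
            p.animal = animal
            profs.append(p)
        out = hierarchical_average(profs)
        # group mean = mean of the two animal means, not of 3 images
        a1 = average_profiles(profs[:2]).intensity
        a2 = profs[2].intensity
        assert np.allclose(out.intensity, (a1 + a2) / 2)


class TestNormalizationAndDifference:
    def test_self_normalization_peaks_at_one(self):
        prof = make_profile()
        out = normalize_to_reference(prof, float(prof.intensity.max()))
        assert out.intensity.max() == pytest.approx(1.0)

    def test_reduced_band_amplitude_recovered(self):
        wt = make_profile(amps=(1.0, 1.0))
        stg = make_profile(amps=(0.6, 0.6))
        peak = float(wt.intensity.max())
        stg_n = normalize_to_reference(stg, peak)
        # at the band centre: (0.6 + baseline) / (1.0 + baseline)
        expected = (0.6 + 0.1) / (1.0 + 0.1)
        assert stg_n.value_at(33.0) == pytest.approx(expected, abs=0.02)

    def test_double_normalization_rejected(self):
        prof = normalize_to_reference(make_profile(), 1.0)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_to_reference(prof, 1.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(make_profile(), 0.0)

    def test_difference_identities(self):
        a = align_profile(make_profile(amps=(1.0, 1.0)), (33.0, 58.0))
        b = align_profile(make_profile(amps=(0.6, 0.6)), (33.0, 58.0))
        assert np.allclose(difference_profile(a, a).intensity, 0.0)
        d_ab = difference_profile(a, b).intensity
        d_ba = difference_profile(b, a).intensity
        assert np.allclose(d_ab, -d_ba)

    def test_genotype_difference_peaks_at_band_depths(self):
        a = align_profile(make_profile(centers=(0.28, 0.63),
                                       amps=(1.0, 1.0)), CHAT_ANCHORS)
        b = align_profile(make_profile(centers=(0.28, 0.63),
                                       amps=(0.6, 0.6)), CHAT_ANCHORS)
        diff = difference_profile(a, b)
        peaks = find_band_peaks(diff)
        assert np.allclose(sorted(peaks)[:2], CHAT_ANCHORS, atol=1.0)


class TestBandComparison:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0]
        res = compare_at_bands(vals, vals, n_comparisons=2)
        assert not res.significant

    def test_constructed_reduction_detected(self):
        rng = np.random.default_rng(0)
        a = 1.0 + rng.normal(0, 0.03, 6)
        b = 0.6 + rng.normal(0, 0.03, 6)
        res = compare_at_bands(a, b, n_comparisons=2)
        assert res.significant
        assert res.mean_difference == pytest.approx(0.4, abs=0.05)
        assert res.ci95[0] < res.mean_difference < res.ci95[1]

    def test_single_comparison_is_plain_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0, 1, 6)
        res = compare_at_bands(a, b, n_comparisons=1)
        assert res.alpha_adjusted == pytest.approx(0.05)

    def test_zero_variance_flagged_degenerate(self):
        res = compare_at_bands([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate


class TestFullChainInvariant:
    @pytest.mark.parametrize("centers", [(0.12, 0.55), (0.33, 0.58),
                                         (0.40, 0.52), (0.20, 0.88)])
    def test_alignment_places_peaks_on_anchors(self, centers):
        prof = make_profile(centers=centers)
        peaks = reference_band_peaks(prof)
        out = align_profile(prof, peaks)
        redet = find_band_peaks(out)
        assert abs(redet[0] - 28.0) <= 0.5
        assert abs(redet[-1] - 63.0) <= 0.5
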