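"""Frame integration, cerebellar-median scaling, FOV QC, regional readouts
and the sample-based template."""

import dataclasses

import numpy as np
import pytest

from pibquant.quantify import (
    build_template,
    cerebellar_median,
    check_fov,
    integrate_frames,
    neocortical_composite,
    quantify_subject,
    ratio_image,
    regional_means,
)
from pibquant.synthcohort import (
    FrameSeries,
    default_centre_profiles,
    render_phantom,
    truth_value_map,
)


def series_from(volumes, schedule, fov=None):
    return FrameSeries(data=np.stack(volumes), schedule=tuple(schedule),
                       voxel_mm=3.0, fov_z_range=fov)


class TestFrameIntegration:
    def test_constant_frames_sum(self):
        vol = np.full((3, 3, 3), 2.5)
        fs = series_from([vol] * 4, [(40, 45), (45, 50), (50, 55), (55, 60)])
        np.testing.assert_allclose(integrate_frames(fs), 10.0)

    def test_centre_a_schedule_uses_exactly_four_frames(self):
        """Six 5-min frames 40-70 min: only the four inside 40-60 count."""
        centre_a = default_centre_profiles()[0]
        assert centre_a.frame_schedule == tuple(
            (40 + 5 * i, 45 + 5 * i) for i in range(6))
        vols = [np.full((2, 2, 2), float(i + 1)) for i in range(6)]
        fs = series_from(vols, centre_a.frame_schedule)
        np.testing.assert_allclose(integrate_frames(fs), 1 + 2 + 3 + 4)

    def test_straddling_frame_excluded(self):
        fs = series_from([np.ones((2, 2, 2))] * 2, [(50, 55), (58, 63)])
        np.testing.assert_allclose(integrate_frames(fs), 1.0)

    def test_no_eligible_frames_raises(self):
        fs = series_from([np.ones((2, 2, 2))], [(0, 40)])
        with pytest.raises(ValueError):
            integrate_frames(fs)


class TestCerebellarMedian:
    def test_constant_volume(self):
        vol = np.full((3, 3, 3), 4.2)
        mask = np.ones((3, 3, 3), dtype=bool)
        assert cerebellar_median(vol, mask) == pytest.approx(4.2)

    @pytest.mark.parametrize("values, expected", [
        ([1.0, 1.0, 1.0, 100.0], 1.0),      # outlier insensitivity
        ([1.0, 2.0, 3.0, 4.0], 2.5),        # even-count convention
        ([3.0, 1.0, 2.0], 2.0),
    ])
    def test_order_statistic_oracle(self, values, expected):
        vol = np.array(values).reshape(-1, 1, 1)
        mask = np.ones(vol.shape, dtype=bool)
        assert cerebellar_median(vol, mask) == pytest.approx(expected)
        # independent sort-based oracle
        s = sorted(values)
        n = len(s)
        oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        assert cerebellar_median(vol, mask) == pytest.approx(oracle)

    def test_median_robust_to_minority_contamination(self, rng):
        """Replacing <50 % of reference voxels with huge values leaves the
        median of a constant majority unchanged."""
        vol = np.full((10, 10, 1), 2.0)
        mask = np.ones(vol.shape, dtype=bool)
        contaminated = vol.copy().ravel()
        contaminated[:49] = rng.uniform(1e3, 1e6, 49)
        assert cerebellar_median(contaminated.reshape(vol.shape), mask) == 2.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cerebellar_median(np.ones((2, 2, 2)),
                              np.zeros((2, 2, 2), dtype=bool))


class TestFovRule:
    def make_mask(self):
        mask = np.zeros((2, 2, 8), dtype=bool)
        mask[:, :, 2:6] = True      # 16 voxels over slices 2..5
        return mask

    def test_full_fov(self):
        assert check_fov(self.make_mask(), None) == (0.0, False)
        frac, excl = check_fov(self.make_mask(), (0, 8))
        assert frac == 0.0 and not excl

    def test_thirty_percent_outside_excludes(self):
        mask = np.zeros((1, 1, 10), dtype=bool)
        mask[0, 0, :10] = True
        frac, excl = check_fov(mask, (3, 10))
        assert frac == pytest.approx(0.30)
        assert excl

    def test_exactly_quarter_outside_is_kept(self):
        """25 % is not 'more than 25 %': strict inequality."""
        frac, excl = check_fov(self.make_mask(), (3, 8))  # slice 2 cut: 4/16
        assert frac == pytest.approx(0.25)
        assert not excl


class TestRatioAndRegions:
    def test_constant_volume_gives_unit_image(self):
        vol = np.full((3, 3, 3), 7.0)
        np.testing.assert_allclose(ratio_image(vol, 7.0), 1.0)

    def test_nonpositive_median_raises(self):
        with pytest.raises(ValueError):
            ratio_image(np.ones((2, 2, 2)), 0.0)

    def test_all_ones_ratio_image(self, full_rois):
        values, missing = regional_means(np.ones(full_rois.gm_mask.shape),
                                         full_rois)
        assert missing == ()
        assert all(v == pytest.approx(1.0) for v in values.values())

    @pytest.mark.parametrize("vals, expected", [
        ({"frontal": 1.2, "parietal": 1.5, "temporal_lateral_basal": 1.8}, 1.5),
        ({"frontal": 2.0, "parietal": 2.0, "temporal_lateral_basal": 2.0}, 2.0),
    ])
    def test_composite_mean(self, vals, expected):
        assert neocortical_composite(vals) == pytest.approx(expected)

    def test_composite_missing_constituent_raises(self):
        with pytest.raises(ValueError):
            neocortical_composite({"frontal": 1.2, "parietal": 1.5})


class TestEndToEnd:
    def test_noiseless_recovery_exact(self, full_atlas, full_rois,
                                      default_cohort, identity_centre):
        """PSF 0, noise 0: regional values equal the subject truth to 1e-10
        and the scaled cerebellar median is exactly 1."""
        for subject in default_cohort[::40]:
            frames = render_phantom(subject, identity_centre, full_atlas)
            rr = quantify_subject(subject.subject_id, "i", frames, full_rois)
            assert not rr.qc_excluded and rr.missing_rois == ()
            for name, value in rr.regional.items():
                assert value == pytest.approx(subject.true_regional[name],
                                              abs=1e-10)
            assert rr.composite == pytest.approx(subject.true_composite,
                                                 abs=1e-10)
            integral = integrate_frames(frames)
            scaled = ratio_image(integral, rr.cereb_median)
            assert cerebellar_median(scaled, full_rois.cerebellum) == 1.0

    def test_global_scale_invariance(self, full_atlas, full_rois,
                                     default_cohort, identity_centre):
        """Multiplying all frames by k > 0 leaves every ratio unchanged."""
        subject = default_cohort[100]
        frames = render_phantom(subject, identity_centre, full_atlas)
        scaled = dataclasses.replace(frames, data=3.7 * frames.data)
        a = quantify_subject("s", "c", frames, full_rois)
        b = quantify_subject("s", "c", scaled, full_rois)
        for name in a.regional:
            assert a.regional[name] == pytest.approx(b.regional[name],
                                                     rel=1e-12)

    def test_fov_truncation_triggers_qc_exclusion(self, full_atlas, full_rois,
                                                  default_cohort,
                                                  identity_centre):
        """A FOV cutting >25 % of the cerebellar reference excludes the
        subject; a milder cut keeps it."""
        cereb_z = np.where(full_rois.cerebellum.any(axis=(0, 1)))[0]
        counts = full_rois.cerebellum.sum(axis=(0, 1))[cereb_z]
        cum = np.cumsum(counts) / counts.sum()
        z_30 = cereb_z[np.searchsorted(cum, 0.30)] + 1
        nz = full_atlas.shape[2]
        bad = dataclasses.replace(identity_centre, fov_z_range=(int(z_30), nz))
        frames = render_phantom(default_cohort[0], bad, full_atlas)
        rr = quantify_subject("s", "c", frames, full_rois)
        assert rr.qc_excluded and rr.qc_reason.startswith("fov")

    def test_blur_matches_convolution_oracle(self, full_atlas, full_rois,
                                             default_cohort, identity_centre):
        """Blurred regional values equal an independent explicit-kernel FFT
        convolution of the truth map; deviation from truth grows with FWHM."""
        from scipy.signal import fftconvolve
        subject = default_cohort[-1]   # AD subject, high contrast
        truth = truth_value_map(subject, full_atlas)
        deviations = []
        for fwhm in (3.0, 6.0, 12.0):
            centre = dataclasses.replace(identity_centre, psf_fwhm=fwhm)
            frames = render_phantom(subject, centre, full_atlas)
            rr = quantify_subject("s", "c", frames, full_rois)

            sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / full_atlas.voxel_mm
            half = int(np.ceil(4 * sigma))
            ax = np.arange(-half, half + 1)
            k1 = np.exp(-0.5 * (ax / sigma) ** 2)
            k1 /= k1.sum()
            kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
            blurred = fftconvolve(truth, kernel, mode="same")
            med = np.median(blurred[full_rois.cerebellum])
            oracle = (blurred / med)[full_rois.rois["frontal"]].mean()

            assert rr.regional["frontal"] == pytest.approx(oracle, abs=2e-3)
            deviations.append(abs(rr.regional["frontal"]
                                  - subject.true_regional["frontal"]))
        assert deviations[0] < deviations[1] < deviations[2]


class TestTemplate:
    def test_single_volume_identity(self, rng):
        vol = rng.random((4, 4, 4))
        np.testing.assert_array_equal(build_template([vol]), vol)

    def test_symmetric_pair_averages_to_one(self, rng):
        v = rng.random((4, 4, 4))
        np.testing.assert_allclose(build_template([v, 2.0 - v]), 1.0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_template([np.ones((2, 2, 2)), np.ones((3, 3, 3))])

    def test_template_of_unit_median_ratios(self, full_atlas, full_rois,
                                            default_cohort, identity_centre):
        """Averaging noiseless unit-median ratio images keeps the cerebellar
        median at 1 (linearity)."""
        ratios = []
        for subject in default_cohort[:6]:
            frames = render_phantom(subject, identity_centre, full_atlas)
            integral = integrate_frames(frames)
            med = cerebellar_median(integral, full_rois.cerebellum)
            ratios.append(ratio_image(integral, med))
        template = build_template(ratios)
        assert cerebellar_median(template, full_rois.cerebellum) == \
            pytest.approx(1.0, abs=1e-12)
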