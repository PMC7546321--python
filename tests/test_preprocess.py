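import numpy as np
import pytest

from gfcpipe.niio import TimeSeriesMatrix, Volume4D
from gfcpipe.preprocess import (
    FDTrace,
    MotionParams,
    bandpass_filter,
    build_nuisance_design,
    compute_fd,
    drop_initial_volumes,
    friston24,
    gaussian_smooth,
    linear_detrend,
    nuisance_regress,
    qc_motion_exclude,
    scrub,
)


def _ts(values, tr=2.0):
    values = np.asarray(values, dtype=float)
    vi = np.column_stack(
        np.unravel_index(np.arange(values.shape[1]), (values.shape[1], 1, 1),
                         order="F")
    )
    return TimeSeriesMatrix(values=values, voxel_index=vi, tr=tr)


class TestDropAndQC:
    def test_drop_removes_frames_from_image_and_motion_in_lockstep(self, rng):
        vol = Volume4D(data=rng.normal(size=(4, 4, 4, 250)),
                       affine=np.eye(4), tr=2.0)
        motion = MotionParams(values=rng.normal(size=(250, 6)) * 0.01)
        v2, m2 = drop_initial_volumes(vol, motion, 10)
        assert v2.n_frames == 240 and m2.n_frames == 240
        np.testing.assert_array_equal(v2.data, vol.data[..., 10:])
        np.testing.assert_array_equal(m2.values, motion.values[10:])

    def test_drop_zero_is_identity_and_full_drop_errors(self, rng):
        vol = Volume4D(data=rng.normal(size=(4, 4, 4, 20)),
                       affine=np.eye(4), tr=2.0)
        motion = MotionParams(values=np.zeros((20, 6)))
        v2, _ = drop_initial_volumes(vol, motion, 0)
        assert v2 is vol
        with pytest.raises(ValueError):
            drop_initial_volumes(vol, motion, 20)

    def test_qc_passes_still_subject_and_flags_large_translation(self):
        quiet = MotionParams(values=np.zeros((50, 6)))
        assert qc_motion_exclude(quiet) == (True, None)
        values = np.zeros((50, 6))
        values[17, 0] = 2.5  # 2.5 mm x-translation
        ok, frame = qc_motion_exclude(MotionParams(values=values))
        assert not ok and frame == 17

    def test_qc_flags_rotation_just_over_two_degrees(self):
        # 0.04 rad = 2.29 deg > 2 deg
        values = np.zeros((10, 6))
        values[4, 5] = 0.04
        ok, frame = qc_motion_exclude(MotionParams(values=values))
        assert not ok and frame == 4
        values[4, 5] = 0.03  # 1.72 deg: inside the limit
        assert qc_motion_exclude(MotionParams(values=values))[0]


class TestSmoothing:
    def test_constant_volume_unchanged(self):
        vol = Volume4D(data=np.full((8, 8, 8, 3), 5.0),
                       affine=np.diag([3.0, 3, 3, 1]), tr=2.0)
        out = gaussian_smooth(vol, 4.0)
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-10)

    def test_interior_delta_mass_preserved(self):
        data = np.zeros((16, 16, 16, 2))
        data[8, 8, 8, 0] = 1.0
        vol = Volume4D(data=data, affine=np.diag([3.0, 3, 3, 1]), tr=2.0)
        out = gaussian_smooth(vol, 4.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-3)
        # sigma = 4 / (2.3548 * 3) ~ 0.566 voxels: nearest neighbour gets
        # the Gaussian ratio exp(-1/(2 sigma^2)) of the peak
        sigma = 4.0 / (2.0 * np.sqrt(2 * np.log(2))) / 3.0
        assert sigma == pytest.approx(0.566, abs=1e-3)
        ratio = out.data[9, 8, 8, 0] / out.data[8, 8, 8, 0]
        assert ratio == pytest.approx(np.exp(-1 / (2 * sigma**2)), rel=1e-2)

    def test_zero_fwhm_is_identity_negative_rejected(self, small_volume):
        assert gaussian_smooth(small_volume, 0.0) is small_volume
        with pytest.raises(ValueError):
            gaussian_smooth(small_volume, -1.0)


class TestTemporalFilters:
    def test_detrend_removes_linear_ramp_exactly(self):
        t = np.arange(30, dtype=float)
        ts = _ts(np.column_stack([3 + 2 * t, -1 + 0.5 * t]))
        out = linear_detrend(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_detrend_output_orthogonal_to_ramp_and_zero_mean(self, random_ts):
        out = linear_detrend(random_ts)
        t = np.arange(random_ts.n_frames, dtype=float)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.T @ t).max() < 1e-8

    def test_detrend_keeps_inband_sinusoid(self):
        # 0.04 Hz over 250 frames at TR 2 s = 20 full cycles.  A finite
        # window of a sinusoid is not orthogonal to a ramp: the fitted
        # slope distorts the wave by ~ amplitude/(pi * cycles) ~ 4.8%,
        # which is the analytically expected ceiling here.
        t = np.arange(250) * 2.0
        sig = np.sin(2 * np.pi * 0.04 * t)
        out = linear_detrend(_ts(sig[:, None]))
        dev = np.abs(out.values[:, 0] - (sig - sig.mean())).max()
        assert dev < 0.05
        assert np.corrcoef(out.values[:, 0], sig)[0, 1] > 0.998

    def test_bandpass_retains_inband_and_kills_outband(self):
        t = np.arange(250) * 2.0
        inband = np.sin(2 * np.pi * 0.04 * t)
        outband = np.sin(2 * np.pi * 0.2 * t)
        const = np.ones(250)
        out = bandpass_filter(_ts(np.column_stack([inband, outband, const])))
        assert np.abs(out.values[:, 0]).max() == pytest.approx(1.0, rel=0.02)
        rms_out = np.sqrt((out.values[:, 1] ** 2).mean())
        rms_in = np.sqrt((outband**2).mean())
        assert rms_out < 0.01 * rms_in
        np.testing.assert_allclose(out.values[:, 2], 0.0, atol=1e-12)

    def test_bandpass_rejects_cut_at_nyquist(self, random_ts):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(random_ts, 0.01, 0.25)


class TestMotionRegressors:
    def test_friston24_toy_trace_matches_hand_computation(self):
        motion = np.zeros((3, 6))
        motion[:, 0] = [1.0, 2.0, 3.0]
        block = friston24(MotionParams(values=motion))
        assert block.shape == (3, 24)
        np.testing.assert_array_equal(block[:, 0], [1, 2, 3])      # p
        np.testing.assert_array_equal(block[:, 6], [0, 1, 2])      # lag
        np.testing.assert_array_equal(block[:, 12], [1, 4, 9])     # p^2
        np.testing.assert_array_equal(block[:, 18], [0, 1, 4])     # lag^2
        assert (block[:, [1, 7, 13, 19]] == 0).all()  # untouched params

    def test_zero_motion_gives_zero_block(self):
        block = friston24(MotionParams(values=np.zeros((10, 6))))
        assert block.shape == (10, 24)
        assert (block == 0).all()

    def test_fd_translation_and_rotation_conventions(self):
        values = np.zeros((5, 6))
        values[2:, 0] = 0.3           # 0.3 mm x step at frame 2
        values[4:, 3] += 0.01         # 0.01 rad rotation step at frame 4
        fd = compute_fd(MotionParams(values=values))
        assert fd.fd[0] == 0.0
        assert fd.fd[2] == pytest.approx(0.3)
        assert fd.fd[4] == pytest.approx(0.5)  # 50 mm * 0.01 rad
        assert fd.fd[1] == fd.fd[3] == 0.0
        zero = compute_fd(MotionParams(values=np.zeros((5, 6))))
        assert zero.mean_fd == 0.0


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_design(self, rng, random_ts):
        motion = MotionParams(values=rng.normal(size=(40, 6)) * 0.01)
        design, labels = build_nuisance_design(
            motion, rng.normal(size=40), rng.normal(size=40)
        )
        assert design.shape == (40, 27) and len(labels) == 27
        out = nuisance_regress(random_ts, design, labels)
        assert np.abs(design.T @ out.values).max() < 1e-8

    def test_design_column_reproduced_gives_zero_residual(self, rng):
        motion = MotionParams(values=rng.normal(size=(40, 6)) * 0.01)
        design, labels = build_nuisance_design(
            motion, rng.normal(size=40), rng.normal(size=40)
        )
        ts = _ts(design[:, [3, 25]])
        out = nuisance_regress(ts, design, labels)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_intercept_only_regression_is_mean_centering(self, random_ts):
        design = np.ones((random_ts.n_frames, 1))
        out = nuisance_regress(random_ts, design, ["intercept"])
        np.testing.assert_allclose(
            out.values, random_ts.values - random_ts.values.mean(axis=0),
            atol=1e-12,
        )

    def test_rank_deficient_design_drops_columns_with_warning(self, random_ts):
        base = np.column_stack([
            np.ones(random_ts.n_frames),
            np.arange(random_ts.n_frames, dtype=float),
        ])
        design = np.column_stack([base, base[:, 1] * 2.0])
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = nuisance_regress(random_ts, design, ["i", "t", "t2x"])
        assert np.abs(base.T @ out.values).max() < 1e-8


class TestScrubbing:
    def test_quiet_series_untouched(self, random_ts):
        fd = FDTrace(fd=np.full(random_ts.n_frames, 0.1), threshold=0.2)
        out = scrub(random_ts, fd, min_frames=5)
        assert out.n_frames == random_ts.n_frames
        assert out.scrubbed_frames.size == 0

    def test_flagged_frames_removed_and_recorded(self, random_ts):
        fd_values = np.full(random_ts.n_frames, 0.05)
        fd_values[[3, 17, 25]] = 0.31
        fd = FDTrace(fd=fd_values, threshold=0.2)
        out = scrub(random_ts, fd, min_frames=5)
        assert out.n_frames == random_ts.n_frames - 3
        np.testing.assert_array_equal(out.scrubbed_frames, [3, 17, 25])
        np.testing.assert_array_equal(out.values[3], random_ts.values[4])

    def test_threshold_is_strict(self, random_ts):
        fd = FDTrace(fd=np.full(random_ts.n_frames, 0.2), threshold=0.2)
        out = scrub(random_ts, fd, min_frames=5)
        assert out.n_frames == random_ts.n_frames

    def test_floor_violation_errors(self, random_ts):
        fd = FDTrace(fd=np.full(random_ts.n_frames, 0.5), threshold=0.2)
        with pytest.raises(ValueError, match="frames"):
            scrub(random_ts, fd, min_frames=30)


def test_full_chain_preserves_latent_correlation_structure(rng):
    """The cleaning chain applied to in-band latent signal + nuisance
    components recovers the latent pairwise correlation structure."""
    from gfcpipe.niio import GrayMatterMask, to_matrix
    from gfcpipe.preprocess import preprocess_subject

    n_frames = 250
    t = np.arange(n_frames) * 2.0
    shape = (10, 10, 10)
    # two latent in-band signals with known mixing
    lat1 = sum(np.sin(2 * np.pi * f * t + p) for f, p in
               [(0.02, 0.3), (0.05, 1.1), (0.07, 2.0)])
    lat2 = sum(np.sin(2 * np.pi * f * t + p) for f, p in
               [(0.015, 2.2), (0.04, 0.7), (0.06, 1.9)])
    lat1, lat2 = lat1 / lat1.std(), lat2 / lat2.std()
    drift = 0.02 * t
    data = 0.05 * rng.normal(size=shape + (n_frames,))
    weights = np.zeros(shape + (2,))
    weights[:5, :, :, 0] = 1.0
    weights[5:, :, :, 1] = 1.0
    weights[0, 0, 0] = weights[9, 9, 9] = 0.0  # nuisance voxels: noise only
    data += weights[..., 0:1] * lat1 + weights[..., 1:2] * lat2 + drift
    vol = Volume4D(data=data, affine=np.diag([3.0, 3, 3, 1]), tr=2.0)
    # quiet subject: rotations scaled down so the 50 mm FD lever does
    # not push frames over the scrubbing threshold
    motion_scale = np.r_[[2e-3] * 3, [5e-5] * 3]
    motion = MotionParams(values=rng.normal(size=(n_frames, 6)) * motion_scale)
    mask_data = np.ones(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool); wm[0, 0, 0] = True
    csf = np.zeros(shape, dtype=bool); csf[9, 9, 9] = True
    mask = GrayMatterMask(data=mask_data, affine=vol.affine)
    ts, report = preprocess_subject(
        vol, motion, mask, wm, csf, fwhm_mm=0.0, erode_wm=False,
    )
    assert report["qc_passed"]
    cols = mask.voxel_coords()
    same = (cols[:, 0] < 5)
    j1 = np.flatnonzero(same)[1:3]  # skip the signal-free WM voxel (0,0,0)
    j2 = np.flatnonzero(~same)[:2]
    r_same = np.corrcoef(ts.values[:, j1[0]], ts.values[:, j1[1]])[0, 1]
    r_cross = np.corrcoef(ts.values[:, j1[0]], ts.values[:, j2[0]])[0, 1]
    true_cross = np.corrcoef(lat1, lat2)[0, 1]
    assert abs(r_same - 1.0) < 0.05
    assert abs(r_cross - true_cross) < 0.05


class TestFilterVariantsAndUnits:
    def test_butterworth_variant_passes_band_and_rejects_outband(self):
        t = np.arange(250) * 2.0
        values = np.column_stack([
            np.sin(2 * np.pi * 0.04 * t), np.sin(2 * np.pi * 0.2 * t)
        ])
        out = bandpass_filter(_ts(values), method="butterworth")
        keep = np.sqrt((out.values[50:-50, 0] ** 2).mean()) / np.sqrt(0.5)
        kill = np.sqrt((out.values[50:-50, 1] ** 2).mean()) / np.sqrt(0.5)
        assert keep > 0.8
        assert kill < 0.05

    def test_unknown_filter_method_rejected(self, random_ts):
        with pytest.raises(ValueError, match="method"):
            bandpass_filter(random_ts, method="chebyshev")

    def test_motion_file_rotation_unit_conversion(self, tmp_path):
        values = np.zeros((4, 6))
        values[:, 4] = [0.0, 90.0, -90.0, 45.0]  # degrees
        path = tmp_path / "motion.txt"
        np.savetxt(path, values)
        rad = MotionParams.from_file(path, rotation_unit="degrees")
        np.testing.assert_allclose(
            rad.values[:, 4], [0.0, np.pi / 2, -np.pi / 2, np.pi / 4]
        )
        as_is = MotionParams.from_file(path, rotation_unit="radians")
        np.testing.assert_allclose(as_is.values, values)
        with pytest.raises(ValueError):
            MotionParams.from_file(path, rotation_unit="turns")
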