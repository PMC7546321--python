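import json

import numpy as np
import pytest
from scipy import ndimage

from gfcpipe.gfc import gfc_fast
from gfcpipe.niio import build_gm_mask, to_matrix
from gfcpipe.preprocess import compute_fd, MotionParams
from gfcpipe.simulate import (
    CohortSpec,
    generate_cohort,
    generate_gm_prob_map,
    generate_motion,
    generate_subject_timeseries,
    generate_tissue_masks,
    write_cohort,
)


class TestGmProbMap:
    def test_threshold_yields_single_connected_component(self):
        prob = generate_gm_prob_map((24, 24, 24), 3.0)
        mask = prob.data > 0.2
        _, n = ndimage.label(mask)
        assert n == 1

    def test_values_bounded_interior_high_boundary_low(self):
        prob = generate_gm_prob_map((24, 24, 24), 3.0)
        assert prob.data.min() >= 0 and prob.data.max() <= 1
        assert prob.data[:, :, 0].max() < 0.05
        assert prob.data[:, 0, :].max() < 0.05
        spec = CohortSpec()
        for region in spec.effect_regions:
            assert prob.data[region.center_vox] >= 0.5

    def test_gm_fraction_in_sane_range(self):
        prob = generate_gm_prob_map((24, 24, 24), 3.0)
        frac = (prob.data > 0.2).mean()
        assert 0.05 < frac < 0.80

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_gm_prob_map((0, 0, 0))
        with pytest.raises(ValueError):
            generate_gm_prob_map((24, 24, 6))


class TestMotion:
    def test_zero_target_gives_identically_zero_trace(self):
        motion = generate_motion(100, 0.0, spike_rate=0.1, seed=3)
        assert (motion.values == 0).all()
        assert compute_fd(motion).mean_fd == 0.0

    def test_same_seed_reproduces_trace(self):
        a = generate_motion(240, 0.35, seed=11)
        b = generate_motion(240, 0.35, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_realized_mean_fd_near_target(self):
        motion = generate_motion(240, 0.35, seed=1)
        fd = compute_fd(motion)
        assert 0.28 <= fd.mean_fd <= 0.42

    def test_spikes_guarantee_scrubbale_frames(self):
        for seed in range(5):
            motion = generate_motion(240, 0.3, spike_rate=0.05, seed=seed)
            assert (compute_fd(motion).fd > 0.2).any()

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            generate_motion(100, -0.1)


class TestSubjectTimeseries:
    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            generate_subject_timeseries(CohortSpec(), "sibling", 1)

    def test_noise_free_uniform_coupling_gives_perfect_correlation(self):
        spec = CohortSpec(
            grid_shape=(12, 12, 12), n_volumes=40, noise_sd=0.0,
            regional_coupling=0.0, effect_regions=[],
        )
        vol = generate_subject_timeseries(spec, "control", 5)
        prob = generate_gm_prob_map((12, 12, 12), 3.0)
        deep = prob.data >= 0.5  # full-coupling voxels share one latent
        ts = vol.data[deep]
        r = np.corrcoef(ts)
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_truth_maps_differ_only_inside_effect_regions(self):
        from gfcpipe.simulate import _coupling_map

        spec = CohortSpec(grid_shape=(16, 16, 16))
        bp = _coupling_map(spec, "patient", 0.0)
        bc = _coupling_map(spec, "control", 0.0)
        effect = np.zeros(spec.grid_shape, dtype=bool)
        from gfcpipe.simulate import _region_mask

        for region in spec.effect_regions:
            effect |= _region_mask(spec.grid_shape, region, spec.voxel_size)
        assert (bp[~effect] == bc[~effect]).all()
        assert (bp[effect] < bc[effect]).all()

    def test_latent_power_concentrated_in_band(self):
        spec = CohortSpec(grid_shape=(12, 12, 12), n_volumes=240,
                          noise_sd=0.0, regional_coupling=0.0,
                          effect_regions=[])
        vol = generate_subject_timeseries(spec, "control", 9)
        prob = generate_gm_prob_map((12, 12, 12), 3.0)
        deep = (4, 6, 6)  # interior gray matter, outside the CSF pocket
        assert prob.data[deep] > 0.5
        sig = vol.data[deep]
        freqs = np.fft.rfftfreq(sig.size, d=2.0)
        power = np.abs(np.fft.rfft(sig - sig.mean())) ** 2
        inband = power[(freqs >= 0.01) & (freqs <= 0.08)].sum()
        assert inband / power.sum() >= 0.90


class TestCohort:
    def test_counts_and_duration_presence(self, tiny_cohort):
        patients = [s for s in tiny_cohort.subjects if s.group == "patient"]
        controls = [s for s in tiny_cohort.subjects if s.group == "control"]
        assert len(patients) == 4 and len(controls) == 4
        assert all(s.duration_months is not None for s in patients)
        assert all(s.duration_months is None for s in controls)
        assert all(18 <= s.age <= 65 for s in tiny_cohort.subjects)

    def test_determinism_bit_identical(self):
        spec = CohortSpec(n_patients=3, n_controls=3, grid_shape=(12, 12, 12),
                          n_volumes=30, seed=21)
        a = generate_cohort(spec)
        b = generate_cohort(CohortSpec(
            n_patients=3, n_controls=3, grid_shape=(12, 12, 12),
            n_volumes=30, seed=21,
        ))
        assert [s.__dict__ for s in a.subjects] == [s.__dict__ for s in b.subjects]
        ia = a.subject_image(a.subjects[0]).data
        ib = b.subject_image(b.subjects[0]).data
        np.testing.assert_array_equal(ia, ib)
        np.testing.assert_array_equal(
            a.subject_motion(a.subjects[0]).values,
            b.subject_motion(b.subjects[0]).values,
        )

    def test_truth_mask_inside_gray_matter(self, tiny_cohort):
        gm = tiny_cohort.gm_prob.data > 0.2
        for voxels in tiny_cohort.truth["effect_regions"].values():
            assert len(voxels) > 0
            for x, y, z in voxels:
                assert gm[x, y, z]

    def test_zero_slope_decouples_duration_from_severity(self):
        spec = CohortSpec(n_patients=40, n_controls=3,
                          grid_shape=(12, 12, 12), n_volumes=30,
                          duration_slope=0.0, seed=2)
        cohort = generate_cohort(spec)
        z = np.array([s.coupling_z for s in cohort.subjects
                      if s.group == "patient"])
        d = np.array([s.duration_months for s in cohort.subjects
                      if s.group == "patient"], dtype=float)
        assert abs(np.corrcoef(z, d)[0, 1]) < 0.35  # ~0 up to noise

    def test_positive_slope_couples_duration_to_severity(self):
        spec = CohortSpec(n_patients=20, n_controls=3,
                          grid_shape=(12, 12, 12), n_volumes=30, seed=4)
        cohort = generate_cohort(spec)
        z = np.array([s.coupling_z for s in cohort.subjects
                      if s.group == "patient"])
        d = np.array([s.duration_months for s in cohort.subjects
                      if s.group == "patient"], dtype=float)
        assert np.corrcoef(z, d)[0, 1] > 0.4

    def test_tissue_masks_disjoint_from_effect_and_gm(self):
        spec = CohortSpec(grid_shape=(16, 16, 16))
        wm, csf = generate_tissue_masks(spec)
        assert wm.any() and csf.any() and not (wm & csf).any()
        prob = generate_gm_prob_map((16, 16, 16), 3.0)
        assert not (prob.data[wm] > 0.2).any()
        assert not (prob.data[csf] > 0.2).any()


class TestEffectDirection:
    def test_patient_effect_blob_has_lower_gfc_than_controls(self):
        """Mean GFC over the implanted blob, computed by the gfc module,
        is strictly lower for patients than controls."""
        spec = CohortSpec(grid_shape=(14, 14, 14), n_volumes=120, seed=31)
        mask = build_gm_mask(generate_gm_prob_map((14, 14, 14), 3.0))
        colmap = {tuple(c): j for j, c in enumerate(mask.voxel_coords())}
        cohort = generate_cohort(spec)
        blob = [colmap[tuple(v)]
                for v in cohort.truth["effect_regions"]["region_0"]
                if tuple(v) in colmap]
        means = {"patient": [], "control": []}
        for group in means:
            for seed in range(10):
                vol = generate_subject_timeseries(spec, group, 1000 + seed)
                gmap = gfc_fast(to_matrix(vol, mask), mode="mean_z")
                means[group].append(gmap.values[blob].mean())
        assert np.mean(means["patient"]) < np.mean(means["control"])


def test_write_cohort_layout(tmp_path):
    spec = CohortSpec(n_patients=2, n_controls=2, grid_shape=(12, 12, 12),
                      n_volumes=20, seed=5)
    out = write_cohort(generate_cohort(spec), tmp_path / "cohort")
    for name in ("gm_prob.nii.gz", "wm_mask.nii.gz", "csf_mask.nii.gz",
                 "participants.tsv", "truth.json", "cohort_spec.json"):
        assert (out / name).exists()
    for i in range(1, 5):
        assert (out / f"sub-{i:03d}_bold.nii.gz").exists()
        motion = np.loadtxt(out / f"sub-{i:03d}_motion.txt")
        assert motion.shape == (20, 6)
    lines = (out / "participants.tsv").read_text().strip().split("\n")
    assert lines[0] == "id\tgroup\tage\tsex\teducation_years\tduration_months"
    assert len(lines) == 5
    truth = json.loads((out / "truth.json").read_text())
    assert set(truth["effect_regions"]) == {"region_0", "region_1"}
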