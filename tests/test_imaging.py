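"""3D segmentation, shells, N/C ratios, cap, tracking, counting."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from histocomp.imaging import (
    CapSegmentation,
    Track,
    count_cells,
    cytoplasm_shell,
    filter_interphase,
    nc_ratio,
    nuclei_mask,
    segment_cap,
    segment_nuclei,
    track_nuclei,
    volume_fraction,
)
from histocomp.synthetic import SyntheticStackSpec, generate_embryo_stack, generate_timelapse

ISO = (1.0, 1.0, 1.0)


def segments_label_image(segments, shape):
    out = np.zeros(shape, dtype=int)
    for seg in segments:
        out[seg.slices][seg.mask] = seg.label
    return out


class TestSegmentNuclei:
    def test_all_zero_stack(self):
        assert segment_nuclei(np.zeros((10, 10, 10)), ISO) == []

    def test_noisefree_roundtrip_exact(self, noisefree_stack, small_spec):
        """On a noise-free stack the segment masks equal the planted labels
        voxel for voxel (up to label permutation)."""
        stack, truth = noisefree_stack
        segments = segment_nuclei(stack, small_spec.voxel_size)
        assert len(segments) == len(truth.nuclei)
        got = segments_label_image(segments, stack.shape) > 0
        assert np.array_equal(got, truth.label_volume > 0)
        # each segment covers exactly one planted label
        for seg in segments:
            planted = truth.label_volume[seg.slices][seg.mask]
            assert planted.min() == planted.max() != 0

    def test_binary_contrast_roundtrip_exact(self, small_spec):
        """Nuclei against a flat field (cytoplasm = outside level) still
        round-trip exactly through the degenerate second threshold."""
        spec = SyntheticStackSpec(
            **{**small_spec.__dict__, "background_intensity": small_spec.cytoplasm_intensity}
        )
        stack, truth = generate_embryo_stack(spec)
        segments = segment_nuclei(stack, spec.voxel_size)
        got = segments_label_image(segments, stack.shape) > 0
        assert np.array_equal(got, truth.label_volume > 0)

    def test_sphere_volumes_within_ten_percent_of_analytic(self, noisefree_stack, small_spec):
        _, truth = noisefree_stack
        segments = segment_nuclei(
            generate_embryo_stack(small_spec)[0], small_spec.voxel_size
        )
        analytic = 4.0 / 3.0 * np.pi * small_spec.nucleus_radius[0] ** 3
        for seg in segments:
            assert seg.volume == pytest.approx(analytic, rel=0.10)

    def test_idempotent_on_converged_result(self, noisefree_stack, small_spec):
        stack, _ = noisefree_stack
        first = segment_nuclei(stack, small_spec.voxel_size)
        second = segment_nuclei(stack, small_spec.voxel_size)
        img1 = segments_label_image(first, stack.shape)
        img2 = segments_label_image(second, stack.shape)
        assert np.array_equal(img1 > 0, img2 > 0)

    def test_local_refinement_splits_intensity_doublet(self):
        """Two touching nuclei with a 2x intensity difference merge at the
        global seed threshold but are split by per-component refinement."""
        stack = np.zeros((44, 44, 60))
        embryo = np.zeros_like(stack, dtype=bool)
        embryo[5:39, 5:39, 5:55] = True
        stack[embryo] = 10.0  # cytoplasm
        stack[14:30, 14:30, 16:32] = 100.0  # bright nucleus, 16^3
        stack[15:29, 15:29, 32:46] = 50.0  # dim nucleus, 14^3, touching
        seeds = segment_nuclei(stack, ISO, cap_mask=embryo, refine=False)
        assert len(seeds) == 1  # merged at the global seed threshold
        segments = segment_nuclei(stack, ISO, cap_mask=embryo, pad_um=1.0)
        assert len(segments) == 2
        vols = sorted(s.volume for s in segments)
        assert vols == [14.0**3, 16.0**3]


class TestCytoplasmShell:
    def test_annulus_matches_bruteforce_distance_oracle(self):
        """Shell voxels are exactly those with step < d <= 2*step from the
        nucleus surface, with anisotropic physical distances."""
        voxel = (2.0, 1.0, 1.0)
        shape = (16, 24, 24)
        mask = np.zeros(shape, dtype=bool)
        mask[6:9, 10:15, 10:15] = True
        seg = _segment_from_mask(mask, voxel)
        step = 2.5
        shell = cytoplasm_shell(seg, mask, voxel, step=step)
        # brute force: physical distance from every voxel to nearest mask voxel
        coords = np.argwhere(np.ones(shape)).astype(float) * np.array(voxel)
        mask_coords = np.argwhere(mask).astype(float) * np.array(voxel)
        d = cdist(coords, mask_coords).min(axis=1).reshape(shape)
        expected = (d > step) & (d <= 2 * step) & ~mask
        assert np.array_equal(shell, expected)

    def test_disjoint_from_all_nuclei(self, noisefree_stack, small_spec):
        stack, _ = noisefree_stack
        segments = segment_nuclei(stack, small_spec.voxel_size)
        allmask = nuclei_mask(segments, stack.shape)
        for seg in segments:
            shell = cytoplasm_shell(seg, allmask, small_spec.voxel_size)
            assert not (shell & allmask).any()

    def test_fully_surrounded_nucleus_has_empty_shell(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[4:8, 4:8, 4:8] = True
        seg = _segment_from_mask(mask, ISO)
        everything = np.ones((12, 12, 12), dtype=bool)
        shell = cytoplasm_shell(seg, everything, ISO, step=1.0)
        assert not shell.any()

    def test_one_voxel_step(self):
        mask = np.zeros((15, 15, 15), dtype=bool)
        mask[7, 7, 7] = True
        shell = cytoplasm_shell(_segment_from_mask(mask, ISO), mask, ISO, step=1.0)
        # 6-neighbours are at distance 1 (inner shell); next shell reaches 2
        assert not shell[6, 7, 7] and not shell[8, 7, 7]
        assert shell[5, 7, 7] and shell[7, 7, 9]

    def test_nonpositive_step_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError):
            cytoplasm_shell(_segment_from_mask(mask, ISO), mask, ISO, step=0.0)


class TestNcRatio:
    def test_uniform_image_gives_unity(self):
        stack = np.full((10, 10, 10), 7.0)
        mask = np.zeros_like(stack, dtype=bool)
        mask[4:6, 4:6, 4:6] = True
        seg = _segment_from_mask(mask, ISO)
        shell = cytoplasm_shell(seg, mask, ISO, step=1.0)
        seg = nc_ratio(stack, seg, shell, background=0.0)
        assert seg.nc_ratio == pytest.approx(1.0)

    def test_background_equal_to_shell_flags_invalid(self):
        stack = np.full((10, 10, 10), 5.0)
        stack[4:6, 4:6, 4:6] = 20.0
        mask = stack == 20.0
        seg = _segment_from_mask(mask, ISO)
        shell = cytoplasm_shell(seg, mask, ISO, step=1.0)
        seg = nc_ratio(stack, seg, shell, background=5.0)
        assert not seg.valid_ratio
        assert np.isnan(seg.nc_ratio)

    def test_offset_invariance_with_matched_background(self):
        """Adding a constant to all intensities and to the background
        measurement leaves the corrected ratio exactly unchanged."""
        rng = np.random.default_rng(0)
        stack = rng.uniform(10, 30, size=(12, 12, 12))
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[5:8, 5:8, 5:8] = True
        seg = _segment_from_mask(mask, ISO)
        shell = cytoplasm_shell(seg, mask, ISO, step=1.5)
        r0 = nc_ratio(stack, seg, shell, background=2.0).nc_ratio
        seg2 = _segment_from_mask(mask, ISO)
        r1 = nc_ratio(stack + 100.0, seg2, shell, background=102.0).nc_ratio
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_planted_ratio_recovered_on_synthetic_stack(self, noisy_stack):
        spec, stack, truth = noisy_stack
        segments = segment_nuclei(stack, spec.voxel_size)
        allmask = nuclei_mask(segments, stack.shape)
        cap = segment_cap(stack, spec.voxel_size, smooth_sigma_um=1.0)
        ratios = []
        for seg in segments:
            shell = cytoplasm_shell(seg, allmask, spec.voxel_size, within=cap.mask)
            seg = nc_ratio(stack, seg, shell, background=0.0)
            if seg.valid_ratio:
                ratios.append(seg.nc_ratio)
        assert np.median(ratios) == pytest.approx(truth.planted_r, rel=0.05)


class TestFilterInterphase:
    def test_strict_threshold(self):
        segs = [_dummy_segment(r) for r in (1.5, 2.0, 2.01, 2.5, 7.0)]
        kept = filter_interphase(segs)
        assert sorted(s.nc_ratio for s in kept) == [2.01, 2.5, 7.0]

    def test_invalid_ratios_excluded(self):
        seg = _dummy_segment(5.0)
        seg.valid_ratio = False
        assert filter_interphase([seg]) == []


class TestSegmentCap:
    def test_two_level_noiseless_exact(self):
        stack = np.zeros((20, 30, 30))
        stack[2:12, 5:25, 5:25] = 100.0
        cap = segment_cap(stack, ISO)
        assert 0 < cap.threshold < 100
        assert np.array_equal(cap.mask, stack == 100.0)
        assert cap.cap_volume == float((stack == 100.0).sum())

    def test_hemisphere_volume_recovered(self, noisy_stack):
        spec, stack, truth = noisy_stack
        cap = segment_cap(stack, spec.voxel_size, smooth_sigma_um=1.0)
        assert cap.cap_volume == pytest.approx(truth.planted_cap_volume, rel=0.10)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            segment_cap(np.full((8, 8, 8), 3.0), ISO)

    def test_2d_mode_extrudes_projection(self):
        stack = np.zeros((6, 10, 10))
        stack[2, 3:7, 3:7] = 50.0
        cap = segment_cap(stack, ISO, mode="2d")
        assert cap.mask[:, 4, 4].all()  # full column included


class TestTracking:
    def test_static_nuclei_identity_matching(self, noisefree_stack, small_spec):
        stack, _ = noisefree_stack
        segs = segment_nuclei(stack, small_spec.voxel_size)
        tracks = track_nuclei([segs, segs])
        assert len(tracks) == len(segs)  # zero track births
        assert all(len(t.items) == 2 for t in tracks)

    def test_small_displacement_links_match_ground_truth(self, small_spec):
        stacks, truths, parents = generate_timelapse(small_spec, 3, displacement=0.5)
        frame_segs = [segment_nuclei(s, small_spec.voxel_size) for s in stacks]
        tracks = track_nuclei(frame_segs)
        assert len(tracks) == small_spec.n_nuclei
        # verify each track's centroids stay near one planted trajectory
        for t in tracks:
            assert len(t.items) == 3

    def test_division_creates_one_new_track_per_division(self, small_spec):
        # seed chosen so daughters of neighbouring parents stay resolvable
        spec = SyntheticStackSpec(**{**small_spec.__dict__, "n_nuclei": 4, "seed": 3})
        stacks, truths, _ = generate_timelapse(spec, 3, 0.5, division_frame=2)
        frame_segs = [segment_nuclei(s, spec.voxel_size) for s in stacks]
        assert [len(s) for s in frame_segs] == [4, 4, 8]
        tracks = track_nuclei(frame_segs)
        # each division continues one daughter and births one new track
        assert len(tracks) == 8

    def test_strictly_increasing_frames_enforced(self):
        t = Track(1)
        t.add(0, 1, 10.0)
        with pytest.raises(ValueError):
            t.add(0, 2, 10.0)


class TestVolumeFraction:
    def test_single_static_nucleus(self):
        t = Track(1)
        t.add(0, 1, 5.0)
        cap = CapSegmentation(mask=np.ones((1, 1, 1), bool), cap_volume=500.0, threshold=1.0)
        assert volume_fraction([t], cap) == pytest.approx(0.01)

    def test_max_extension_not_mean(self):
        t = Track(1)
        for f, v in enumerate((1.0, 2.0, 3.0)):
            t.add(f, 1, v)
        cap = CapSegmentation(np.ones((1, 1, 1), bool), 100.0, 1.0)
        assert volume_fraction([t], cap) == pytest.approx(0.03)

    def test_nuclei_exceeding_cap_rejected(self):
        t = Track(1)
        t.add(0, 1, 200.0)
        cap = CapSegmentation(np.ones((1, 1, 1), bool), 100.0, 1.0)
        with pytest.raises(ValueError):
            volume_fraction([t], cap)


class TestCountCells:
    def test_empty_stack(self):
        assert count_cells(np.zeros((8, 8, 8)), ISO) == 0

    def test_exact_count_on_separated_nuclei(self, noisy_stack):
        spec, stack, truth = noisy_stack
        assert count_cells(stack, spec.voxel_size) == len(truth.nuclei)


# -- helpers ---------------------------------------------------------------

def _segment_from_mask(mask, voxel_size):
    from scipy import ndimage

    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    from histocomp.imaging import _component_segment

    return _component_segment(mask.astype(np.int8), 1, sl, voxel_size, frame=0)


def _dummy_segment(r):
    from histocomp.imaging import NucleusSegment

    return NucleusSegment(
        label=1,
        slices=(slice(0, 1), slice(0, 1), slice(0, 1)),
        mask=np.ones((1, 1, 1), bool),
        centroid=(0.0, 0.0, 0.0),
        volume=1.0,
        voxel_count=1,
        nc_ratio=r,
    )
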