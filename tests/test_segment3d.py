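import numpy as np
import pytest

from microsol.segment3d import (
    LabelVolume,
    SeedSet,
    SegmentationParams,
    detect_bright_centers,
    detect_objects,
    filter_by_shape,
    filter_by_size,
    flag_border_cells,
    split_cells,
)

from conftest import make_mask, make_stack


def label_volume(arr, spacing=None):
    from microsol.imaging_io import VoxelSpacing

    return LabelVolume(labels=np.asarray(arr, dtype=np.int32),
                       spacing=spacing or VoxelSpacing(1.0, 1.0, 1.0))


class TestDetectObjects:
    def test_two_disjoint_cubes(self):
        vox = np.zeros((10, 10, 10), bool)
        vox[1:4, 1:4, 1:4] = True
        vox[6:9, 6:9, 6:9] = True
        lab = detect_objects(make_mask(vox))
        assert lab.n_labels == 2
        counts = np.bincount(lab.labels.ravel())[1:]
        assert list(counts) == [27, 27]

    def test_corner_touching_cubes_join_under_26_connectivity(self):
        vox = np.zeros((8, 8, 8), bool)
        vox[1:4, 1:4, 1:4] = True
        vox[4:7, 4:7, 4:7] = True  # touches only at the (3,3,3)/(4,4,4) diagonal
        lab = detect_objects(make_mask(vox))
        assert lab.n_labels == 1

    def test_empty_mask(self):
        lab = detect_objects(make_mask(np.zeros((3, 3, 3), bool)))
        assert lab.n_labels == 0


class TestFilterBySize:
    def _volume_with_sizes(self):
        vox = np.zeros((50, 60, 60), bool)
        vox[1, 1, 1:6] = True                     # 5 voxels
        vox[5:10, 5:15, 5:15] = True              # 500 voxels
        vox[15:35, 10:60, 10:60] = True           # 50000 voxels
        return detect_objects(make_mask(vox))

    def test_gates_keep_only_mid_sized_object(self):
        lab = self._volume_with_sizes()
        out = filter_by_size(lab, SegmentationParams(min_object_voxels=100, max_object_voxels=10_000))
        assert out.n_labels == 1
        assert (out.labels > 0).sum() == 500

    def test_all_inside_gates_is_identity_up_to_relabeling(self):
        lab = self._volume_with_sizes()
        out = filter_by_size(lab, SegmentationParams(min_object_voxels=1, max_object_voxels=10**6))
        assert out.n_labels == lab.n_labels
        np.testing.assert_array_equal(out.labels > 0, lab.labels > 0)

    def test_trivial_gates_remove_nothing(self):
        lab = self._volume_with_sizes()
        out = filter_by_size(lab, SegmentationParams(min_object_voxels=1, max_object_voxels=10**9))
        assert out.n_labels == lab.n_labels


def _gaussian_bump(shape, center, sigma, amplitude):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (yy - center[1]) ** 2 + (xx - center[2]) ** 2 + ((zz - center[0]) * 2) ** 2
    return amplitude * np.exp(-d2 / (2 * sigma**2))


class TestDetectBrightCenters:
    def test_single_soma_gives_one_seed_at_center(self):
        shape = (9, 40, 40)
        img = _gaussian_bump(shape, (4, 20, 20), 4.0, 100.0)
        mask = img > 5
        labels = detect_objects(make_mask(mask))
        seeds = detect_bright_centers(make_stack(img), labels, SegmentationParams())
        assert len(seeds.points) == 1
        z, y, x = seeds.points[0]
        assert abs(y - 20) <= 2 and abs(x - 20) <= 2

    def test_two_somata_in_one_object_give_two_seeds(self):
        shape = (7, 30, 50)
        img = _gaussian_bump(shape, (3, 15, 15), 4.0, 100.0) + _gaussian_bump(shape, (3, 15, 35), 4.0, 90.0)
        mask = img > 2  # single connected object containing both bumps
        labels = detect_objects(make_mask(mask))
        assert labels.n_labels == 1
        seeds = detect_bright_centers(
            make_stack(img), labels, SegmentationParams(seed_min_distance_px=8)
        )
        assert len(seeds.points) == 2

    def test_uniform_object_gets_exactly_one_deterministic_seed(self):
        img = np.zeros((5, 30, 30), dtype=np.float32)
        img[1:4, 5:25, 5:25] = 50.0
        labels = detect_objects(make_mask(img > 0))
        seeds = detect_bright_centers(make_stack(img), labels, SegmentationParams())
        assert len(seeds.points) == 1
        again = detect_bright_centers(make_stack(img), labels, SegmentationParams())
        assert seeds.points == again.points


class TestSplitCells:
    def test_single_seed_object_passes_through(self):
        vox = np.zeros((5, 10, 10), bool)
        vox[1:4, 2:8, 2:8] = True
        labels = detect_objects(make_mask(vox))
        img = make_stack(vox.astype(np.float32) * 10)
        seeds = SeedSet(points=[(2, 5, 5)])
        out = split_cells(labels, seeds, img)
        assert out.n_labels == 1
        np.testing.assert_array_equal(out.labels > 0, vox)

    def test_dumbbell_splits_into_balanced_halves(self):
        """Two blobs joined by a thin bridge split near the bridge midline."""
        shape = (9, 24, 60)
        img = _gaussian_bump(shape, (4, 12, 15), 5.0, 100.0) + _gaussian_bump(shape, (4, 12, 45), 5.0, 100.0)
        vox = img > 10
        bridge = np.zeros(shape, bool)
        bridge[4, 11:13, 15:46] = True
        vox |= bridge
        labels = detect_objects(make_mask(vox))
        assert labels.n_labels == 1
        seeds = SeedSet(points=[(4, 12, 15), (4, 12, 45)])
        out = split_cells(labels, seeds, make_stack(img))
        assert out.n_labels == 2
        counts = np.bincount(out.labels.ravel())[1:]
        assert abs(counts[0] - counts[1]) <= 0.1 * counts.mean()

    def test_splitting_is_a_partition(self):
        shape = (9, 24, 60)
        img = _gaussian_bump(shape, (4, 12, 15), 5.0, 100.0) + _gaussian_bump(shape, (4, 12, 45), 5.0, 100.0)
        vox = img > 10
        labels = detect_objects(make_mask(vox))
        seeds = detect_bright_centers(make_stack(img), labels, SegmentationParams())
        out = split_cells(labels, seeds, make_stack(img))
        np.testing.assert_array_equal(out.labels > 0, labels.labels > 0)
        assert out.n_labels == len(seeds.points)

    def test_seed_outside_foreground_rejected(self):
        vox = np.zeros((3, 5, 5), bool)
        vox[1, 2, 2] = True
        labels = detect_objects(make_mask(vox))
        with pytest.raises(ValueError):
            split_cells(labels, SeedSet(points=[(0, 0, 0)]), make_stack(vox.astype(float)))


class TestFilterByShape:
    def test_thin_fiber_removed_by_elongation(self):
        vox = np.zeros((5, 5, 50), bool)
        vox[2, 2, 5:45] = True
        lab = detect_objects(make_mask(vox))
        params = SegmentationParams(min_cell_voxels=1, max_cell_voxels=10**6,
                                    max_elongation=10, min_extent=0.001)
        assert filter_by_shape(lab, params).n_labels == 0

    def test_compact_cube_retained_under_defaults(self):
        vox = np.zeros((13, 13, 13), bool)
        vox[2:11, 2:11, 2:11] = True
        lab = detect_objects(make_mask(vox))
        assert filter_by_shape(lab, SegmentationParams()).n_labels == 1

    def test_decisions_match_independent_recomputation(self):
        """Keep/drop decisions equal a per-object recomputation of all criteria."""
        rng = np.random.default_rng(5)
        vox = np.zeros((20, 60, 60), bool)
        blocks = [
            (slice(2, 5), slice(2, 8), slice(2, 8)),        # small compact
            (slice(2, 12), slice(20, 30), slice(20, 30)),   # big compact
            (slice(9, 10), slice(40, 41), slice(2, 58)),    # fiber
            (slice(14, 18), slice(2, 14), slice(2, 14)),    # medium compact
        ]
        for b in blocks:
            vox[b] = True
        vox[2:4, 40:56, 40:42] = True                       # small slab
        lab = detect_objects(make_mask(vox))
        params = SegmentationParams(min_cell_voxels=80, max_cell_voxels=900,
                                    max_elongation=12, min_extent=0.02)
        out = filter_by_shape(lab, params)
        kept_masks = [out.labels == i for i in range(1, out.n_labels + 1)]

        spacing_zyx = np.array(lab.spacing.as_zyx())
        expected_keep = []
        for obj in range(1, lab.n_labels + 1):
            pts = np.argwhere(lab.labels == obj)
            n = len(pts)
            phys = pts * spacing_zyx
            cov = np.cov(phys.T) + np.diag(spacing_zyx**2) / 12.0
            ev = np.linalg.eigvalsh(cov)
            span = pts.max(axis=0) - pts.min(axis=0) + 1
            ok = (
                params.min_cell_voxels <= n <= params.max_cell_voxels
                and ev[-1] / ev[0] <= params.max_elongation
                and n / span.prod() >= params.min_extent
            )
            if ok:
                expected_keep.append(lab.labels == obj)
        assert len(kept_masks) == len(expected_keep)
        for got, want in zip(kept_masks, expected_keep):
            np.testing.assert_array_equal(got, want)


class TestLabelDebugDump:
    def test_label_volume_round_trips_as_uint16_tiff(self, tmp_path):
        import tifffile

        from microsol.segment3d import write_label_tiff

        vox = np.zeros((4, 6, 6), bool)
        vox[1:3, 1:3, 1:3] = True
        vox[1:3, 4:6, 4:6] = True
        lab = detect_objects(make_mask(vox))
        write_label_tiff(lab, tmp_path / "lab.tif")
        back = tifffile.imread(tmp_path / "lab.tif")
        assert back.dtype == np.uint16
        np.testing.assert_array_equal(back, lab.labels)


class TestBorderFlags:
    def test_corner_cell_flagged(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[0:2, 0:2, 0:2] = True
        flags = flag_border_cells(detect_objects(make_mask(vox)))
        assert flags == [(1, True)]

    def test_interior_cell_not_flagged(self):
        vox = np.zeros((7, 7, 7), bool)
        vox[2:5, 2:5, 2:5] = True
        flags = flag_border_cells(detect_objects(make_mask(vox)))
        assert flags == [(1, False)]

    def test_empty_volume_gives_empty_list(self):
        assert flag_border_cells(detect_objects(make_mask(np.zeros((3, 3, 3), bool)))) == []


class TestChainProperties:
    def _scene(self):
        from microsol.preprocess import PreprocessParams
        from microsol.pipeline import quantify_stack
        from microsol.synthdata import CellPhenotypeParams, SceneParams, generate_scene

        pheno = CellPhenotypeParams(soma_radius_um=7, n_branches=4, branch_length_um=10,
                                    branch_width_um=6, branch_tortuosity=0.3)
        scene = SceneParams(field_size_um=260, depth_um=30, dx=780 / 512, dy=780 / 512,
                            n_cells=3, min_centroid_separation_um=80, rng_seed=3)
        stack, truth = generate_scene(scene, [pheno] * 3)
        return stack, truth

    def test_pipeline_monotone_and_deterministic(self):
        from microsol.preprocess import PreprocessParams
        from microsol.pipeline import quantify_stack

        stack, _ = self._scene()
        pre = PreprocessParams(opening_radius_px=12)
        r1 = quantify_stack(stack, pre)
        r2 = quantify_stack(stack, pre)
        np.testing.assert_array_equal(r1.labels.labels, r2.labels.labels)
        # every voxel labeled after shape filtering was foreground in the mask
        assert not np.any((r1.labels.labels > 0) & ~r1.mask.voxels)
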