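"""Overlap resolution, surface extraction, STL format, mold generation."""

import numpy as np
import pytest
from scipy import ndimage

from neuroprint import LabelMap, StructureDescriptor, StructureMesh, crop_skull_base, extract_surface, generate_mold, read_stl, resolve_overlaps, write_stl
from neuroprint.errors import ConfigurationError, EmptyStructureError, ParameterError


def digital_ball(radius, grid=None, center=None):
    n = grid or (2 * radius + 5)
    c = center or ((n - 1) / 2,) * 3
    g = np.mgrid[0:n, 0:n, 0:n]
    return ((g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2) <= radius ** 2


class TestResolveOverlaps:
    def test_disjoint_masks_unchanged(self):
        a = np.zeros((6, 6, 6), bool); a[:2] = True
        b = np.zeros((6, 6, 6), bool); b[4:] = True
        out = resolve_overlaps({"a": a, "b": b}, {"a": 1, "b": 2})
        assert np.array_equal(out["a"], a) and np.array_equal(out["b"], b)

    def test_priority_subtraction_counts(self):
        tumor = np.zeros((6, 6, 6), bool); tumor.flat[:10] = True
        parenchyma = np.zeros((6, 6, 6), bool); parenchyma.flat[5:25] = True
        out = resolve_overlaps({"tumor": tumor, "parenchyma": parenchyma},
                               {"tumor": 1, "parenchyma": 2})
        assert out["tumor"].sum() == 10
        assert out["parenchyma"].sum() == 15

    def test_three_way_overlap_goes_to_rank_one(self):
        m = np.zeros((4, 4, 4), bool); m[1, 1, 1] = True
        out = resolve_overlaps({"a": m.copy(), "b": m.copy(), "c": m.copy()},
                               {"a": 2, "b": 1, "c": 3})
        assert out["b"][1, 1, 1] and not out["a"].any() and not out["c"].any()

    def test_pairwise_disjoint_after_resolution(self, phantom_case):
        _, truth = phantom_case
        # dilate the truth masks so they genuinely overlap
        masks = {d.name: ndimage.binary_dilation(truth.mask(sid))
                 for sid, d in truth.structures.items()}
        pri = {d.name: d.priority for d in truth.structures.values()}
        out = resolve_overlaps(masks, pri)
        names = list(out)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not (out[names[i]] & out[names[j]]).any()

    def test_duplicate_ranks_rejected(self):
        m = np.zeros((4, 4, 4), bool); m[0, 0, 0] = True
        with pytest.raises(ConfigurationError):
            resolve_overlaps({"a": m, "b": m}, {"a": 1, "b": 1})


class TestCropSkullBase:
    def test_saturating_margin_keeps_mask(self):
        mask = np.ones((12, 12, 12), bool)
        tumor = np.zeros((12, 12, 12), bool); tumor[5:7, 5:7, 5:7] = True
        assert np.array_equal(crop_skull_base(mask, tumor, margin_mm=100.0), mask)

    def test_zero_margin_is_tight_bounding_box(self):
        mask = np.ones((12, 12, 12), bool)
        tumor = np.zeros((12, 12, 12), bool); tumor[3:6, 4:7, 5:8] = True
        out = crop_skull_base(mask, tumor, margin_mm=0.0)
        want = np.zeros_like(mask); want[3:6, 4:7, 5:8] = True
        assert np.array_equal(out, want)

    def test_margin_grows_box_by_spacing(self):
        mask = np.ones((30, 30, 30), bool)
        tumor = np.zeros((30, 30, 30), bool); tumor[10:20, 10:20, 10:20] = True
        out = crop_skull_base(mask, tumor, margin_mm=5.0, spacing=(1.0, 1.0, 1.0))
        assert out.sum() == 20 ** 3

    def test_empty_tumor_rejected(self):
        mask = np.ones((6, 6, 6), bool)
        with pytest.raises(EmptyStructureError):
            crop_skull_base(mask, np.zeros_like(mask), margin_mm=1.0)


class TestExtractSurface:
    def _labelmap(self, mask):
        return LabelMap(labels=mask.astype(np.int32),
                        structures={1: StructureDescriptor(name="blob")})

    def test_empty_label_rejected(self):
        lm = self._labelmap(np.zeros((8, 8, 8), bool))
        lm.labels[0, 0, 0] = 0
        with pytest.raises(EmptyStructureError):
            extract_surface(lm, 1)

    def test_ball_volume_within_two_percent(self):
        ball = digital_ball(10)
        mesh = extract_surface(self._labelmap(ball), 1, smoothing_iterations=0)
        assert mesh.volume_mm3 == pytest.approx(ball.sum(), rel=0.02)

    def test_smoothing_keeps_volume_within_five_percent(self):
        ball = digital_ball(10)
        mesh = extract_surface(self._labelmap(ball), 1, smoothing_iterations=10)
        assert mesh.is_watertight()
        assert mesh.volume_mm3 == pytest.approx(ball.sum(), rel=0.05)

    def test_error_decreases_with_radius(self):
        errs = []
        for r in (5, 10, 20):
            ball = digital_ball(r)
            mesh = extract_surface(self._labelmap(ball), 1, smoothing_iterations=0)
            errs.append(abs(mesh.volume_mm3 - ball.sum()) / ball.sum())
        assert errs[0] > errs[1] > errs[2]

    def test_every_structure_meshed_watertight(self, phantom_case):
        _, truth = phantom_case
        for sid in truth.structures:
            mesh = extract_surface(truth, sid, smoothing_iterations=0)
            mesh.validate()
            assert mesh.volume_mm3 > 0


class TestStl:
    def _triangle(self):
        return StructureMesh(descriptor=StructureDescriptor(name="tri"),
                             vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                             triangles=np.array([[0, 1, 2]]))

    def test_single_triangle_binary_is_134_bytes(self, tmp_path):
        path = tmp_path / "tri.stl"
        write_stl(self._triangle(), path, format="binary")
        assert path.stat().st_size == 134

    def test_triangle_count_field(self, tmp_path):
        ball = digital_ball(5)
        lm = LabelMap(labels=ball.astype(np.int32),
                      structures={1: StructureDescriptor(name="ball")})
        mesh = extract_surface(lm, 1, smoothing_iterations=0)
        path = tmp_path / "ball.stl"
        write_stl(mesh, path, format="binary")
        count = int.from_bytes(path.read_bytes()[80:84], "little")
        assert count == len(mesh.triangles)
        assert path.stat().st_size == 84 + 50 * count

    def test_round_trip_preserves_triangles(self, tmp_path):
        ball = digital_ball(5)
        lm = LabelMap(labels=ball.astype(np.int32),
                      structures={1: StructureDescriptor(name="ball")})
        mesh = extract_surface(lm, 1, smoothing_iterations=0)
        path = tmp_path / "ball.stl"
        write_stl(mesh, path, format="binary")
        back = read_stl(path)
        tri_set = lambda m: {tuple(sorted(map(tuple, np.round(m.vertices[t], 6)))) for t in m.triangles}
        assert tri_set(back) == tri_set(mesh)


class TestMold:
    def test_voxel_count_conservation_exact(self):
        rng = np.random.default_rng(4)
        blob = digital_ball(8, grid=30)
        p1, p2 = generate_mold(blob, wall_thickness_mm=3.0, split_axis="y")
        dist = ndimage.distance_transform_edt(~blob)
        dilated = blob | (dist <= 3.0)
        shell = dilated & ~blob
        # reconstruct part voxel counts from the split plane used
        centroid = np.mean(np.nonzero(blob)[1])
        sel = np.arange(30)[None, :, None] <= centroid
        n1 = int((shell & np.broadcast_to(sel, shell.shape)).sum())
        n2 = int(shell.sum()) - n1
        assert dilated.sum() == blob.sum() + n1 + n2

    def test_cube_mold_voxels_match_euclidean_oracle(self):
        cube = np.zeros((30, 30, 30), bool)
        cube[10:20, 10:20, 10:20] = True
        # brute-force oracle: voxels within 2 mm of the cube, outside it
        pts = np.argwhere(~cube)
        cube_pts = np.argwhere(cube)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(cube_pts).query(pts)
        n_oracle = int((d <= 2.0).sum())
        assert n_oracle == 1328  # frozen: Euclidean dilation rounds the corners
        dist = ndimage.distance_transform_edt(~cube)
        assert int(((dist <= 2.0) & ~cube).sum()) == n_oracle

    def test_both_parts_watertight(self):
        blob = digital_ball(8, grid=30)
        p1, p2 = generate_mold(blob, wall_thickness_mm=2.0, split_axis="z")
        p1.validate()
        p2.validate()

    def test_thin_wall_rejected(self):
        blob = digital_ball(5)
        with pytest.raises(ParameterError):
            generate_mold(blob, wall_thickness_mm=0.5)
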