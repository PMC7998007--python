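"""Graph construction, min-cut optimality, and the fallback segmenters."""

import itertools

import numpy as np
import pytest

from neuroprint import GraphCutParams, ImageVolume, SeedSet, build_energy_graph, cut_energy, region_grow, threshold_segment
from neuroprint.errors import IncompleteSeedError, ParameterError
from neuroprint.graphcut import binary_cut, draw_cut

pytestmark = pytest.mark.filterwarnings("ignore::DeprecationWarning")


def two_voxel_weight(i0, i1, sigma, spacing):
    """Weight of the single n-link of a 2x2x2 toy volume read off the graph."""
    data = np.zeros((2, 2, 2))
    data[0, 0, 0], data[1, 0, 0] = i0, i1
    vol = ImageVolume(data=data, spacing=spacing)
    seeds = SeedSet(fg={1: {(0, 0, 0)}}, bg={1: {(1, 1, 1)}})
    g = build_energy_graph(vol, seeds, 1, GraphCutParams(sigma=sigma))
    flat = np.ravel_multi_index(([0, 1], [0, 0], [0, 0]), (2, 2, 2))
    sel = (g.edges_u == flat[0]) & (g.edges_v == flat[1])
    sel |= (g.edges_u == flat[1]) & (g.edges_v == flat[0])
    (w,) = g.edge_weight[sel]
    return w


class TestBoundaryWeights:
    def test_equal_intensities_give_unit_weight(self):
        assert two_voxel_weight(5.0, 5.0, sigma=10.0, spacing=(1, 1, 1)) == pytest.approx(1.0)

    def test_large_step_explicit_value(self):
        w = two_voxel_weight(0.0, 100.0, sigma=10.0, spacing=(1, 1, 1))
        assert w == pytest.approx(np.exp(-50.0))

    def test_spacing_aware_halves_weight_at_2mm(self):
        w1 = two_voxel_weight(0.0, 10.0, sigma=10.0, spacing=(1, 1, 1))
        w2 = two_voxel_weight(0.0, 10.0, sigma=10.0, spacing=(2, 1, 1))
        assert w2 == pytest.approx(w1 / 2.0)

    def test_seed_links_exceed_any_cut(self):
        vol = ImageVolume(data=np.zeros((3, 3, 3)))
        seeds = SeedSet(fg={1: {(0, 0, 0)}}, bg={1: {(2, 2, 2)}})
        g = build_energy_graph(vol, seeds, 1)
        incident = np.zeros(27)
        np.add.at(incident, g.edges_u, g.edge_weight)
        np.add.at(incident, g.edges_v, g.edge_weight)
        assert g.hard_capacity == pytest.approx(1.0 + incident.max())

    def test_missing_seeds_rejected(self):
        vol = ImageVolume(data=np.zeros((3, 3, 3)))
        with pytest.raises(IncompleteSeedError):
            build_energy_graph(vol, SeedSet(fg={1: {(0, 0, 0)}}, bg={}), 1)


def brute_force_minimum(vol, seeds, sid, params):
    """Exhaustive enumeration over all labelings consistent with the seeds."""
    g = build_energy_graph(vol, seeds, sid, params)
    fg = seeds.fg_voxels(sid)
    bg = seeds.bg_voxels(sid)
    free = [v for v in np.ndindex(vol.shape) if v not in fg and v not in bg]
    assert len(free) <= 12
    best = np.inf
    base = np.zeros(vol.shape, dtype=bool)
    for v in fg:
        base[v] = True
    for bits in itertools.product([False, True], repeat=len(free)):
        lab = base.copy()
        for v, b in zip(free, bits):
            lab[v] = b
        best = min(best, cut_energy(g, lab))
    return best


class TestDrawCut:
    def test_step_profile_cuts_at_the_weak_edge(self):
        """Intensity step along z: the cut severs the near-zero-weight edge."""
        data = np.tile(np.array([0.0, 0.0, 100.0, 100.0]), (2, 2, 1))
        vol = ImageVolume(data=data)
        seeds = SeedSet(fg={1: {(0, 0, 3)}}, bg={1: {(0, 0, 0)}})
        mask = binary_cut(vol, seeds, 1, GraphCutParams(sigma=10.0))
        expected = np.tile(np.array([False, False, True, True]), (2, 2, 1))
        assert np.array_equal(mask, expected)

    def test_uniform_volume_cut_is_globally_minimal(self):
        vol = ImageVolume(data=np.zeros((2, 2, 3)))
        seeds = SeedSet(fg={1: {(0, 0, 0)}}, bg={1: {(1, 1, 2)}})
        params = GraphCutParams(sigma=10.0)
        g = build_energy_graph(vol, seeds, 1, params)
        mask = binary_cut(vol, seeds, 1, params)
        assert cut_energy(g, mask) == pytest.approx(
            brute_force_minimum(vol, seeds, 1, params), abs=1e-4)

    def test_fully_seeded_problem_reproduces_seeds(self):
        rng = np.random.default_rng(3)
        vol = ImageVolume(data=rng.random((2, 2, 2)) * 100)
        fg = {(0, 0, 0), (0, 1, 1), (1, 0, 1)}
        bg = set(np.ndindex((2, 2, 2))) - fg
        mask = binary_cut(vol, SeedSet(fg={1: fg}, bg={1: bg}), 1)
        assert {tuple(v) for v in np.argwhere(mask)} == fg

    def test_energy_matches_exhaustive_minimum_on_random_grids(self):
        """Min-cut optimality against the enumeration oracle, 20 trials."""
        params = GraphCutParams(sigma=25.0)
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            shape = (2, 2, 4) if trial % 2 else (2, 2, 3)
            vol = ImageVolume(data=rng.random(shape) * 100)
            voxels = list(np.ndindex(shape))
            rng.shuffle(voxels)
            n_seeds = int(np.prod(shape)) - 10
            fg = {voxels[0]}
            bg = {voxels[1]}
            for v in voxels[2:n_seeds]:
                (fg if rng.random() < 0.5 else bg).add(v)
            seeds = SeedSet(fg={1: fg}, bg={1: bg})
            g = build_energy_graph(vol, seeds, 1, params)
            mask = binary_cut(vol, seeds, 1, params)
            assert np.all(mask[tuple(np.array(sorted(fg)).T)])
            assert not np.any(mask[tuple(np.array(sorted(bg)).T)])
            assert cut_energy(g, mask) == pytest.approx(
                brute_force_minimum(vol, seeds, 1, params), abs=1e-4)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.random((3, 3, 3)) * 50
        seeds = SeedSet(fg={1: {(0, 0, 0)}}, bg={1: {(2, 2, 2)}})
        m1 = binary_cut(ImageVolume(data=data), seeds, 1, GraphCutParams(sigma=20.0))
        m2 = binary_cut(ImageVolume(data=data * 4.0), seeds, 1, GraphCutParams(sigma=80.0))
        assert np.array_equal(m1, m2)

    def test_draw_cut_labels_every_structure(self):
        data = np.tile(np.array([0.0, 0.0, 100.0, 100.0]), (2, 2, 1))
        vol = ImageVolume(data=data)
        seeds = SeedSet(fg={1: {(0, 0, 3)}, 2: {(0, 0, 0)}},
                        bg={1: {(0, 0, 0)}, 2: {(0, 0, 3)}})
        lm = draw_cut(vol, seeds, GraphCutParams(sigma=10.0))
        assert set(np.unique(lm.labels)) == {1, 2}
        assert set(lm.structures) == {1, 2}

    def test_regional_terms_fill_unseeded_gap(self):
        """With regional t-links, an unseeded bright blob is still claimed."""
        data = np.zeros((3, 3, 7))
        data[:, :, 4:] = 100.0
        vol = ImageVolume(data=data)
        seeds = SeedSet(fg={1: {(1, 1, 6)}}, bg={1: {(1, 1, 0)}})
        params = GraphCutParams(sigma=10.0, lambda_regional=0.5)
        mask = binary_cut(vol, seeds, 1, params)
        assert np.array_equal(mask, data >= 50.0)


class TestRegionGrow:
    def test_uniform_volume_floods_everything(self):
        vol = ImageVolume(data=np.zeros((3, 4, 5)))
        assert region_grow(vol, {(0, 0, 0)}, tolerance=0.0).all()

    def test_step_profile_stops_at_barrier(self):
        data = np.tile(np.array([0.0, 0.0, 100.0, 100.0]), (2, 2, 1))
        vol = ImageVolume(data=data)
        mask = region_grow(vol, {(0, 0, 0)}, tolerance=10.0)
        assert np.array_equal(mask, data < 50.0)

    def test_zero_tolerance_equal_intensity_component(self):
        data = np.zeros((4, 4, 4))
        data[:2] = 7.0
        vol = ImageVolume(data=data)
        mask = region_grow(vol, {(0, 0, 0)}, tolerance=0.0)
        assert np.array_equal(mask, data == 7.0)


class TestThreshold:
    def test_otsu_separates_two_classes(self):
        data = np.zeros((5, 2, 2))
        data[3:, 0, 0] = 100.0
        vol = ImageVolume(data=data)
        # 2 of the 20 voxels are bright
        assert threshold_segment(vol, "otsu").sum() == 2

    def test_fixed_level_boundaries(self):
        vol = ImageVolume(data=np.arange(8.0).reshape(2, 2, 2))
        assert threshold_segment(vol, "fixed", level=0.0).all()
        assert not threshold_segment(vol, "fixed", level=8.0).any()

    def test_constant_volume_has_no_otsu_threshold(self):
        with pytest.raises(ParameterError):
            threshold_segment(ImageVolume(data=np.ones((3, 3, 3))), "otsu")
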