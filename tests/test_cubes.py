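import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphnet.cubes import (
    Cube,
    CubeSet,
    apply_rotation,
    cube_similarity,
    resize_to_atlas,
    rotation_set,
    tile_cubes,
)
from morphnet.volumes import AtlasVolume

from oracles import brute_rotation_similarity, pearson_from_sums


class TestRotationSet:
    def test_cardinality_24(self):
        # independent count: signed axis permutations with det +1
        from itertools import permutations, product

        count = 0
        for axes in permutations(range(3)):
            for signs in product((1, -1), repeat=3):
                m = np.eye(3)[list(axes)] * np.array(signs)[:, None]
                if round(np.linalg.det(m)) == 1:
                    count += 1
        assert count == 24
        assert rotation_set().shape == (24, 27)

    def test_contains_identity(self):
        perms = rotation_set()
        assert any(np.array_equal(p, np.arange(27)) for p in perms)

    def test_all_distinct(self):
        perms = rotation_set()
        assert len({tuple(p) for p in perms}) == 24

    def test_closed_under_composition(self):
        perms = rotation_set()
        keys = {tuple(p) for p in perms}
        for p1 in perms:
            for p2 in perms:
                assert tuple(p1[p2]) in keys

    def test_closed_under_inverse(self):
        perms = rotation_set()
        keys = {tuple(p) for p in perms}
        for p in perms:
            assert tuple(np.argsort(p)) in keys


class TestCubeSimilarity:
    def test_identical_cubes(self, rng):
        v = rng.normal(size=27)
        assert cube_similarity(v, v) == pytest.approx(1.0)

    def test_rotated_copy_recovers_one(self, rng):
        v = rng.normal(size=27)
        for perm in rotation_set():
            assert cube_similarity(v, apply_rotation(v, perm)) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=27)
            b = rng.normal(size=27)
            assert cube_similarity(a, b) == pytest.approx(
                brute_rotation_similarity(a, b), abs=1e-12
            )

    def test_fixed_patterns_against_oracle(self):
        # deterministic fixture pair
        a = np.arange(27, dtype=float)
        b = np.cos(np.arange(27, dtype=float))
        assert cube_similarity(a, b) == pytest.approx(brute_rotation_similarity(a, b), abs=1e-12)

    def test_zero_variance_convention(self, rng):
        flat = np.full(27, 0.7)
        assert cube_similarity(flat, rng.normal(size=27)) == 0.0
        assert cube_similarity(flat, flat) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(2, 27))
            assert cube_similarity(a, b) == pytest.approx(cube_similarity(b, a), abs=1e-12)

    def test_rotation_invariance(self, rng):
        a, b = rng.normal(size=(2, 27))
        base = cube_similarity(a, b)
        perms = rotation_set()
        for perm in perms[::5]:
            assert cube_similarity(apply_rotation(a, perm), b) == pytest.approx(base, abs=1e-12)
            assert cube_similarity(a, apply_rotation(b, perm)) == pytest.approx(base, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_max_property(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=(2, 27))
        assert cube_similarity(a, b) >= pearson_from_sums(a, b) - 1e-12

    def test_bounds(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(2, 27))
            assert -1.0 <= cube_similarity(a, b) <= 1.0


class TestTileCubes:
    def _atlas(self, shape, label=1):
        return AtlasVolume(np.full(shape, label, dtype=np.int32))

    def test_full_6cube_volume(self, rng):
        gm = rng.uniform(0.1, 1.0, size=(6, 6, 6))
        cs = tile_cubes(gm, self._atlas((6, 6, 6)))
        assert len(cs) == 8

    def test_partial_cubes_discarded(self, rng):
        gm = rng.uniform(0.1, 1.0, size=(5, 5, 5))
        cs = tile_cubes(gm, self._atlas((5, 5, 5)))
        assert len(cs) == 1

    def test_empty_volume(self):
        cs = tile_cubes(np.zeros((6, 6, 6)), self._atlas((6, 6, 6)))
        assert len(cs) == 0

    def test_anchor_at_nonzero_bounding_box(self, rng):
        gm = np.zeros((9, 9, 9))
        gm[2:8, 2:8, 2:8] = rng.uniform(0.1, 1.0, size=(6, 6, 6))
        cs = tile_cubes(gm, self._atlas((9, 9, 9)))
        assert cs.anchor == (2, 2, 2)
        assert len(cs) == 8
        assert all(np.all((np.array(c.origin) - 2) % 3 == 0) for c in cs.cubes)

    def test_all_zero_cube_discarded(self, rng):
        gm = rng.uniform(0.1, 1.0, size=(6, 6, 6))
        gm[0:3, 0:3, 0:3] = 0.0
        cs = tile_cubes(gm, self._atlas((6, 6, 6)))
        assert len(cs) == 7

    def test_majority_label_and_tie_break(self):
        gm = np.ones((3, 3, 3))
        atlas = np.ones((3, 3, 3), dtype=np.int32)
        atlas.ravel()[:13] = 2  # 13 voxels label 2, 14 label 1 -> majority 1
        cs = tile_cubes(gm, AtlasVolume(atlas))
        assert cs.cubes[0].roi_label == 1
        atlas.ravel()[:14] = 2  # 14 vs 13 -> majority 2
        cs = tile_cubes(gm, AtlasVolume(atlas))
        assert cs.cubes[0].roi_label == 2

    def test_background_majority_discarded(self):
        gm = np.ones((3, 3, 3))
        atlas = np.zeros((3, 3, 3), dtype=np.int32)
        atlas.ravel()[:13] = 1  # 14 background voxels win
        assert len(tile_cubes(gm, AtlasVolume(atlas))) == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            tile_cubes(np.ones((6, 6, 6)), self._atlas((9, 9, 9)))

    def test_values_raster_order(self):
        gm = np.arange(27, dtype=float).reshape(3, 3, 3) + 1.0
        cs = tile_cubes(gm, self._atlas((3, 3, 3)))
        np.testing.assert_array_equal(cs.cubes[0].values, np.arange(27) + 1.0)


def _cube(values, roi, origin=(0, 0, 0)):
    return Cube(origin=origin, values=np.asarray(values, dtype=float), roi_label=roi)


class TestResizeToAtlas:
    def test_single_pair_equals_similarity(self, rng):
        a = _cube(rng.normal(size=27), 1)
        b = _cube(rng.normal(size=27), 2, origin=(3, 0, 0))
        m = resize_to_atlas(CubeSet([a, b]))
        assert m.values[0, 1] == pytest.approx(cube_similarity(a, b), abs=1e-12)
        assert m.n_cube_pairs[0, 1] == 1

    def test_mean_of_constant_similarities(self, rng):
        cubes = [
            _cube(rng.normal(size=27), 1),
            _cube(rng.normal(size=27), 1, origin=(3, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(6, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(9, 0, 0)),
        ]
        sims = {(0, 2): 0.5, (0, 3): 0.5, (1, 2): 0.5, (1, 3): 0.5}
        m = resize_to_atlas(CubeSet(cubes), similarities=sims)
        assert m.values[0, 1] == pytest.approx(0.5)

    def test_mean_of_mixed_similarities(self, rng):
        cubes = [
            _cube(rng.normal(size=27), 1),
            _cube(rng.normal(size=27), 1, origin=(3, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(6, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(9, 0, 0)),
        ]
        sims = {(0, 2): 0.2, (0, 3): 0.4, (1, 2): 0.6, (1, 3): 0.8}
        m = resize_to_atlas(CubeSet(cubes), similarities=sims)
        assert m.values[0, 1] == pytest.approx(0.5)  # direct average
        assert m.n_cube_pairs[0, 1] == 4

    def test_vectorized_path_matches_scalar_path(self, rng):
        cubes = [
            _cube(rng.normal(size=27), roi, origin=(3 * i, 0, 0))
            for i, roi in enumerate([1, 1, 2, 2, 3])
        ]
        cs = CubeSet(cubes)
        fast = resize_to_atlas(cs)
        slow = resize_to_atlas(cs, similarities=cube_similarity)
        np.testing.assert_allclose(fast.values, slow.values, atol=1e-12)

    def test_symmetric_zero_diagonal_bounded(self, small_cohort):
        from morphnet.cubes import tile_cubes

        cs = tile_cubes(small_cohort.volumes[0], small_cohort.atlas)
        m = resize_to_atlas(cs)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)
        assert np.all(np.abs(m.values) <= 1.0)
        assert m.scale == "r"

    def test_diagnostics_within_roi(self, rng):
        cubes = [
            _cube(rng.normal(size=27), 1),
            _cube(rng.normal(size=27), 1, origin=(3, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(6, 0, 0)),
            _cube(rng.normal(size=27), 2, origin=(9, 0, 0)),
        ]
        m = resize_to_atlas(CubeSet(cubes), with_diagnostics=True)
        within = m.diagnostics["within_roi_mean"]
        assert within[1] == pytest.approx(cube_similarity(cubes[0], cubes[1]), abs=1e-12)
        # never placed on the diagonal
        assert m.values[0, 0] == 0.0
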