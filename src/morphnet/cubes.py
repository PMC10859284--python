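"""Single-subject morphological similarity extraction.

A gray-matter volume is tiled into non-overlapping 3x3x3-voxel cubes anchored
at the bounding box of nonzero voxels.  Pairwise cube similarity is the
maximum Pearson correlation over the 24 proper rotations of one cube relative
to the other.  Cube-level similarities are then averaged within region pairs
to produce a symmetric ROI x ROI matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Callable, Mapping

import numpy as np

CUBE_EDGE = 3
CUBE_SIZE = CUBE_EDGE**3  # 27 voxels

__all__ = [
    "Cube",
    "CubeSet",
    "ROIMatrix",
    "tile_cubes",
    "rotation_set",
    "apply_rotation",
    "cube_similarity",
    "resize_to_atlas",
]


@dataclass(frozen=True)
class Cube:
    """A 3x3x3 block of gray-matter densities.

    ``values`` are stored in fixed (x, y, z) raster order, i.e. flat index
    ``x * 9 + y * 3 + z`` for in-cube coordinates (x, y, z) in {0, 1, 2}.
    """

    origin: tuple[int, int, int]
    values: np.ndarray
    roi_label: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (CUBE_SIZE,):
            raise ValueError(f"cube must hold exactly {CUBE_SIZE} values, got {v.shape}")
        object.__setattr__(self, "values", v)


@dataclass
class CubeSet:
    """Non-overlapping cubes from one volume, ordered lexicographically by origin."""

    cubes: list[Cube]
    source: str = ""
    anchor: tuple[int, int, int] = (0, 0, 0)

    def __len__(self) -> int:
        return len(self.cubes)

    @property
    def roi_labels(self) -> np.ndarray:
        return np.array([c.roi_label for c in self.cubes], dtype=int)

    def value_matrix(self) -> np.ndarray:
        """(n_cubes, 27) array of cube contents."""
        if not self.cubes:
            return np.empty((0, CUBE_SIZE))
        return np.stack([c.values for c in self.cubes])


@dataclass
class ROIMatrix:
    """Symmetric ROI x ROI similarity matrix with zero diagonal."""

    values: np.ndarray
    scale: str  # "r" or "z"
    roi_ids: np.ndarray
    n_cube_pairs: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_roi, k=1)
        return self.values[iu]


def _rotation_matrices() -> list[np.ndarray]:
    """The 24 signed axis permutations with determinant +1."""
    mats = []
    for axes in permutations(range(3)):
        base = np.eye(3, dtype=int)[list(axes)]
        for signs in product((1, -1), repeat=3):
            r = base * np.array(signs, dtype=int)[:, None]
            if round(float(np.linalg.det(r))) == 1:
                mats.append(r)
    return mats


def rotation_set() -> np.ndarray:
    """The 24 proper rotations of the cube as index permutations.

    Returns a (24, 27) integer array ``P``; applying rotation ``g`` to a value
    vector ``v`` is ``v[P[g]]``.  The set contains the identity and is closed
    under composition (it is the rotation group of the cube acting on the 27
    voxel positions).  Reflections are deliberately excluded: relative
    re-orientation of rigid anatomy cannot mirror it.
    """
    coords = np.array(list(product(range(CUBE_EDGE), repeat=3)), dtype=int)
    offsets = coords - 1  # centre the cube at the origin
    perms = []
    for r in _rotation_matrices():
        moved = offsets @ r.T + 1
        scatter = moved[:, 0] * 9 + moved[:, 1] * 3 + moved[:, 2]
        # gather form: rotated[j] = v[perm[j]]
        perms.append(np.argsort(scatter))
    return np.array(perms, dtype=int)


_ROTATIONS: np.ndarray | None = None


def _rotations() -> np.ndarray:
    global _ROTATIONS
    if _ROTATIONS is None:
        _ROTATIONS = rotation_set()
    return _ROTATIONS


def apply_rotation(values: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply one rotation permutation to a 27-value vector."""
    return np.asarray(values)[np.asarray(perm)]


def _as_values(cube) -> np.ndarray:
    if isinstance(cube, Cube):
        return cube.values
    v = np.asarray(cube, dtype=float)
    if v.shape != (CUBE_SIZE,):
        raise ValueError(f"expected {CUBE_SIZE} values, got shape {v.shape}")
    return v


def _standardize(v: np.ndarray) -> np.ndarray | None:
    """Zero-mean unit-variance copy, or None for constant input."""
    if np.ptp(v) == 0:  # exact constancy; std() of a constant can round to ~1e-17
        return None
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (v - v.mean()) / sd


def cube_similarity(a, b) -> float:
    """Maximum Pearson correlation between two cubes over the 24 rotations.

    A cube with zero variance correlates 0 with everything by convention
    (undefined correlation made neutral rather than dropping the cube).
    """
    va = _as_values(a)
    vb = _as_values(b)
    za = _standardize(va)
    zb = _standardize(vb)
    if za is None or zb is None:
        return 0.0
    best = -np.inf
    for perm in _rotations():
        r = float(za @ zb[perm]) / CUBE_SIZE
        if r > best:
            best = r
    return min(best, 1.0)


def tile_cubes(gm, atlas, source: str = "") -> CubeSet:
    """Tile a gray-matter volume into 3x3x3 cubes aligned with the atlas grid.

    The tiling grid is anchored at the low corner of the bounding box of
    nonzero GM voxels; only complete cubes are kept.  Cubes whose GM content
    is entirely zero are discarded.  Each cube takes the majority atlas label
    among its 27 voxels (ties broken toward the smallest label); cubes whose
    majority label is 0 (background) are discarded.
    """
    gm_data = np.asarray(getattr(gm, "data", gm), dtype=float)
    atlas_data = np.asarray(getattr(atlas, "data", atlas))
    if gm_data.shape != atlas_data.shape:
        raise ValueError(
            f"GM shape {gm_data.shape} does not match atlas shape {atlas_data.shape}"
        )
    if gm_data.ndim != 3:
        raise ValueError(f"expected 3D volumes, got {gm_data.ndim}D")

    nz = np.argwhere(gm_data != 0)
    if nz.size == 0:
        return CubeSet([], source=source)
    lo = nz.min(axis=0)
    shape = np.array(gm_data.shape)
    n_blocks = (shape - lo) // CUBE_EDGE

    cubes: list[Cube] = []
    for bx in range(n_blocks[0]):
        for by in range(n_blocks[1]):
            for bz in range(n_blocks[2]):
                x0 = int(lo[0] + bx * CUBE_EDGE)
                y0 = int(lo[1] + by * CUBE_EDGE)
                z0 = int(lo[2] + bz * CUBE_EDGE)
                block = gm_data[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3]
                if not np.any(block != 0):
                    continue
                labels = atlas_data[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3]
                counts = np.bincount(labels.ravel().astype(int))
                maj = int(np.argmax(counts))  # argmax ties -> smallest label
                if maj == 0:
                    continue
                cubes.append(
                    Cube(origin=(x0, y0, z0), values=block.ravel(order="C"), roi_label=maj)
                )
    return CubeSet(cubes, source=source, anchor=tuple(int(v) for v in lo))


def _standardized_matrix(values: np.ndarray) -> np.ndarray:
    """Row-standardize cube values; constant rows become zero rows (r = 0)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    ok = (sd[:, 0] > 0) & np.isfinite(sd[:, 0]) & (np.ptp(values, axis=1) > 0)
    out[ok] = (values[ok] - mu[ok]) / sd[ok]
    return out


def _block_max_correlation(zi: np.ndarray, zj: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Max over rotations of Pearson r between all rows of zi and zj."""
    best = np.full((zi.shape[0], zj.shape[0]), -np.inf)
    for perm in rotations:
        np.maximum(best, (zi @ zj[:, perm].T) / CUBE_SIZE, out=best)
    # rows that were all-zero (constant cubes) correlate 0 by convention
    zero_i = ~zi.any(axis=1)
    zero_j = ~zj.any(axis=1)
    best[zero_i, :] = 0.0
    best[:, zero_j] = 0.0
    return np.clip(best, -1.0, 1.0)


def resize_to_atlas(
    cube_set: CubeSet,
    similarities: Mapping[tuple[int, int], float] | Callable[[Cube, Cube], float] | None = None,
    with_diagnostics: bool = False,
) -> ROIMatrix:
    """Average cube-pair similarities within ROI pairs into an ROI x ROI matrix.

    Entry (I, J) with I < J is the arithmetic mean of cube similarity over all
    cross pairs (one cube in I, one in J); the lower triangle mirrors the
    upper and the diagonal is zero.  ROI pairs with no contributing cube pairs
    get 0 and ``n_cube_pairs`` 0.

    Parameters
    ----------
    similarities:
        Optional precomputed similarities: a mapping from cube-index pairs
        ``(ci, cj)`` (indices into ``cube_set.cubes``, either order) to r
        values, or a callable ``f(cube_a, cube_b) -> r``.  When omitted the
        rotation-maximized correlation is computed in vectorized ROI-block
        form, so peak memory is one ROI-pair block rather than the full
        cube-pair matrix.
    with_diagnostics:
        Also record mean within-ROI similarity per ROI (never placed on the
        matrix diagonal).
    """
    labels = cube_set.roi_labels
    if labels.size and labels.min() < 1:
        raise ValueError("all cubes must carry an ROI label >= 1")
    roi_ids = np.unique(labels)
    n_roi = len(roi_ids)
    values = np.zeros((n_roi, n_roi))
    n_pairs = np.zeros((n_roi, n_roi), dtype=int)
    diagnostics: dict = {}

    idx_by_roi = {rid: np.flatnonzero(labels == rid) for rid in roi_ids}

    def pair_mean_from_lookup(ai: np.ndarray, bi: np.ndarray) -> float:
        total = 0.0
        for ci in ai:
            for cj in bi:
                if callable(similarities):
                    total += similarities(cube_set.cubes[ci], cube_set.cubes[cj])
                else:
                    key = (ci, cj) if (ci, cj) in similarities else (cj, ci)
                    total += similarities[key]
        return total / (len(ai) * len(bi))

    if similarities is None:
        vm = cube_set.value_matrix()
        z = _standardized_matrix(vm)
        rotations = _rotations()
        for i in range(n_roi):
            zi = z[idx_by_roi[roi_ids[i]]]
            if with_diagnostics and len(zi) > 1:
                block = _block_max_correlation(zi, zi, rotations)
                iu = np.triu_indices(len(zi), k=1)
                diagnostics.setdefault("within_roi_mean", {})[int(roi_ids[i])] = float(
                    block[iu].mean()
                )
            for j in range(i + 1, n_roi):
                zj = z[idx_by_roi[roi_ids[j]]]
                block = _block_max_correlation(zi, zj, rotations)
                values[i, j] = values[j, i] = float(block.mean())
                n_pairs[i, j] = n_pairs[j, i] = block.size
    else:
        for i in range(n_roi):
            ai = idx_by_roi[roi_ids[i]]
            for j in range(i + 1, n_roi):
                bi = idx_by_roi[roi_ids[j]]
                values[i, j] = values[j, i] = pair_mean_from_lookup(ai, bi)
                n_pairs[i, j] = n_pairs[j, i] = len(ai) * len(bi)

    np.fill_diagonal(values, 0.0)
    return ROIMatrix(
        values=values,
        scale="r",
        roi_ids=roi_ids,
        n_cube_pairs=n_pairs,
        diagnostics=diagnostics,
    )
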