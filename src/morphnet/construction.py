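"""Fisher z-transform, proportional sparsity thresholding, binarization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubes import ROIMatrix

__all__ = ["BinaryNetwork", "fisher_z", "threshold_sparsity", "sparsity_grid"]

#: clip |r| to 1 - _R_CLIP before arctanh so z stays finite
_R_CLIP = 1e-7


@dataclass
class BinaryNetwork:
    """Unweighted undirected network at one proportional sparsity level."""

    adjacency: np.ndarray  # symmetric boolean, zero diagonal
    sparsity: float
    n_edges: int
    source: str = ""

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of upper-triangle node index pairs."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return np.column_stack([iu[0][mask], iu[1][mask]])


def fisher_z(m: ROIMatrix) -> ROIMatrix:
    """Elementwise r-to-z (arctanh) transform of a correlation-scale matrix.

    |r| is clipped to ``1 - 1e-7`` first so perfect correlations map to a
    large finite z.  Symmetry and the zero diagonal are preserved.
    """
    if m.scale != "r":
        raise ValueError(f"fisher_z expects an r-scale matrix, got scale={m.scale!r}")
    r = np.asarray(m.values, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("r-scale matrix has entries outside [-1, 1]")
    z = np.arctanh(np.clip(r, -1 + _R_CLIP, 1 - _R_CLIP))
    np.fill_diagonal(z, 0.0)
    return ROIMatrix(
        values=z,
        scale="z",
        roi_ids=m.roi_ids,
        n_cube_pairs=m.n_cube_pairs,
        diagnostics=dict(m.diagnostics),
    )


def n_edges_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """Edge count retained at a proportional threshold: round(s * n(n-1)/2).

    Python's round (half-to-even) is the recorded convention for the
    half-way case, which never arises at the seven standard levels.
    """
    m_possible = n_nodes * (n_nodes - 1) // 2
    return int(round(sparsity * m_possible))


def threshold_sparsity(m: ROIMatrix, sparsity: float, source: str = "") -> BinaryNetwork:
    """Keep the top fraction of edges by value and binarize.

    The K = round(s * n(n-1)/2) largest upper-triangle entries become edges.
    Ties at the cut are resolved deterministically by descending value, then
    ascending (row, column), which also makes edge sets nested across
    increasing sparsity levels.
    """
    if not 0 < sparsity < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    n = m.values.shape[0]
    k = n_edges_at_sparsity(n, sparsity)
    if k < 1:
        raise ValueError(
            f"sparsity {sparsity} retains zero edges on {n} nodes (degenerate network)"
        )
    iu, ju = np.triu_indices(n, k=1)
    vals = m.values[iu, ju]
    # lexsort: last key is primary -> (-value, i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity), n_edges=k, source=source)


def sparsity_grid() -> tuple[float, ...]:
    """The seven standard proportional-threshold levels, 0.05 to 0.35 step 0.05."""
    return (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
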