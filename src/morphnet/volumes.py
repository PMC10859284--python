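"""In-memory 3D volume types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GMVolume", "AtlasVolume"]


@dataclass
class GMVolume:
    """Gray-matter density grid in register with the atlas."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"GM volume must be 3D, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation grid; 0 is background."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"atlas volume must be 3D, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=0):
                raise ValueError("atlas volume must hold integer labels")
            arr = rounded.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        self.data = arr.astype(np.int32)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]
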