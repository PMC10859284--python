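"""Synthetic registered GM volumes, toy atlases and cohort tables.

Every downstream stage is testable without any imaging download.  Volumes are
built from per-ROI 27-value cube "motifs": cubes of the same ROI repeat the
ROI motif plus voxel noise, ROIs in ``shared_motif_pairs`` carry identical
motifs (high-similarity edges), and ``effect_edges`` mix the second ROI's
motif toward the first with a per-subject latent blend weight whose mean is
shifted by ``effect_size`` standard deviations in the High group.  The blend
weight is the standardized latent driver of edge similarity, so the planted
group difference is a Cohen's-d-style shift on that driver; with
``effect_size = 0`` the two groups' generating distributions are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stress
from .volumes import AtlasVolume, GMVolume

__all__ = ["SyntheticDesign", "Cohort", "make_atlas", "make_subject_volume", "make_cohort", "write_cohort"]

# latent blend-weight model at effect edges
_LAMBDA_BASE = 0.30
_LAMBDA_SD = 0.12

# substreams off (seed, subject index)
_STREAM_VOLUME = 0
_STREAM_QUESTIONNAIRE = 1
_STREAM_MOTIFS = 0xA71A5


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic cohort.  ROI indices are 1-based labels."""

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_roi: int = 10
    shared_motif_pairs: list = field(default_factory=list)
    effect_edges: list = field(default_factory=list)
    effect_size: float = 0.0
    noise_sd: float = 0.05
    n_low: int = 10
    n_high: int = 10
    seed: int = 0
    #: weight of the first ROI's motif in a shared pair: 1.0 copies it verbatim
    #: (similarity ~1); values < 1 blend it with the second ROI's own motif,
    #: giving correlated-but-distinct textures (lets a single ROI correlate
    #: with many others without making those others mutually near-identical)
    motif_share_weight: float = 1.0
    roi_motifs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s % 3 != 0 or s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive and divisible by 3, got {self.grid_shape}")
        if self.n_roi < 2:
            raise ValueError("n_roi must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for pair in list(self.shared_motif_pairs) + list(self.effect_edges):
            i, j = pair
            if not (1 <= i <= self.n_roi and 1 <= j <= self.n_roi) or i == j:
                raise ValueError(f"ROI pair {pair} out of range for n_roi={self.n_roi}")
        if not 0 < self.motif_share_weight <= 1:
            raise ValueError("motif_share_weight must be in (0, 1]")
        if self.roi_motifs is None:
            rng = np.random.default_rng([self.seed, _STREAM_MOTIFS])
            self.roi_motifs = rng.uniform(0.2, 0.8, size=(self.n_roi, 27))
            # shared pairs blend the first ROI's motif into the second
            w = self.motif_share_weight
            base = self.roi_motifs.copy()
            for i, j in self.shared_motif_pairs:
                self.roi_motifs[j - 1] = w * base[i - 1] + (1 - w) * base[j - 1]
        else:
            # explicit motifs are final: sharing is assumed already applied
            self.roi_motifs = np.asarray(self.roi_motifs, dtype=float)
            if self.roi_motifs.shape != (self.n_roi, 27):
                raise ValueError("roi_motifs must have shape (n_roi, 27)")

    @property
    def n_cubes(self) -> int:
        return int(np.prod([s // 3 for s in self.grid_shape]))

    def to_json(self) -> str:
        d = {
            "grid_shape": list(self.grid_shape),
            "n_roi": self.n_roi,
            "shared_motif_pairs": [list(p) for p in self.shared_motif_pairs],
            "effect_edges": [list(p) for p in self.effect_edges],
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "seed": self.seed,
            "motif_share_weight": self.motif_share_weight,
            "roi_motifs": self.roi_motifs.tolist(),
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticDesign":
        d = json.loads(text)
        motifs = np.array(d.pop("roi_motifs"))
        d["grid_shape"] = tuple(d["grid_shape"])
        d["shared_motif_pairs"] = [tuple(p) for p in d["shared_motif_pairs"]]
        d["effect_edges"] = [tuple(p) for p in d["effect_edges"]]
        return cls(roi_motifs=motifs, **d)


def _cube_blocks(grid_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Low corners of all 3x3x3 blocks, lexicographic."""
    nb = [s // 3 for s in grid_shape]
    return [
        (3 * bx, 3 * by, 3 * bz)
        for bx in range(nb[0])
        for by in range(nb[1])
        for bz in range(nb[2])
    ]


def make_atlas(design: SyntheticDesign) -> AtlasVolume:
    """Partition the grid into n_roi parcels made of whole 3x3x3 cube blocks.

    Blocks in lexicographic order are split into contiguous runs of
    near-equal size; every ROI gets at least two cubes or a sizing error is
    raised.  Every voxel is labeled (no background inside the grid).
    """
    blocks = _cube_blocks(design.grid_shape)
    n_cubes = len(blocks)
    if n_cubes < 2 * design.n_roi:
        raise ValueError(
            f"grid {design.grid_shape} holds {n_cubes} cubes; "
            f"{design.n_roi} ROIs need at least {2 * design.n_roi}"
        )
    sizes = np.full(design.n_roi, n_cubes // design.n_roi, dtype=int)
    sizes[: n_cubes % design.n_roi] += 1
    data = np.zeros(design.grid_shape, dtype=np.int32)
    pos = 0
    for label, size in enumerate(sizes, start=1):
        for x0, y0, z0 in blocks[pos : pos + size]:
            data[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3] = label
        pos += size
    return AtlasVolume(data=data)


def _subject_motifs(design: SyntheticDesign, group: str, rng: np.random.Generator) -> np.ndarray:
    motifs = design.roi_motifs.copy()
    is_high = 1.0 if group == stress.HIGH else 0.0
    for i, j in design.effect_edges:
        lam = _LAMBDA_BASE + _LAMBDA_SD * (rng.standard_normal() + design.effect_size * is_high)
        lam = float(np.clip(lam, 0.0, 0.95))
        motifs[j - 1] = (1.0 - lam) * design.roi_motifs[j - 1] + lam * design.roi_motifs[i - 1]
    return motifs


def make_subject_volume(
    atlas: AtlasVolume, design: SyntheticDesign, group: str, subject_seed: int
) -> GMVolume:
    """One registered GM volume: per-ROI motifs plus voxel noise, clipped to [0, 1]."""
    if group not in (stress.LOW, stress.HIGH):
        raise ValueError(f"unknown group label {group!r}; expected {stress.LOW!r} or {stress.HIGH!r}")
    rng = np.random.default_rng([design.seed, int(subject_seed), _STREAM_VOLUME])
    motifs = _subject_motifs(design, group, rng)
    data = np.zeros(design.grid_shape)
    for x0, y0, z0 in _cube_blocks(design.grid_shape):
        label = int(atlas.data[x0, y0, z0])
        cube = motifs[label - 1].copy()
        if design.noise_sd > 0:
            cube = cube + rng.normal(0.0, design.noise_sd, size=27)
        data[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3] = cube.reshape(3, 3, 3)
    np.clip(data, 0.0, 1.0, out=data)
    return GMVolume(data=data, subject_id=f"sub-{subject_seed:03d}")


def _leq_items(group: str, rng: np.random.Generator) -> list:
    """39 item ratings realizing the intended stress group by construction."""
    if group == stress.LOW:
        n = int(rng.integers(1, 6))  # 1..5 negative events
        lo, hi = max(-5, -2 * n), -n
    else:
        n = int(rng.integers(6, 11))  # 6..10 negative events
        lo, hi = max(-20, -2 * n), -11
    total = int(rng.integers(lo, hi + 1))
    items: list = [None] * stress.N_ITEMS
    neg_idx = rng.choice(stress.N_ITEMS, size=n, replace=False)
    for k in neg_idx:
        items[k] = -1
    n_minus2 = -total - n  # items upgraded to -2
    for k in rng.choice(neg_idx, size=n_minus2, replace=False):
        items[k] = -2
    other = [k for k in range(stress.N_ITEMS) if items[k] is None]
    draws = rng.choice([-9, 0, 1, 2], size=len(other), p=[0.4, 0.2, 0.2, 0.2])
    for k, d in zip(other, draws):
        items[k] = None if d == -9 else int(d)
    return items


@dataclass
class Cohort:
    design: SyntheticDesign
    table: pd.DataFrame
    atlas: AtlasVolume
    volumes: list  # GMVolume per row of table


def make_cohort(design: SyntheticDesign) -> Cohort:
    """Cohort table plus per-subject volumes with planted group structure.

    Subjects 0..n_low-1 are Low, the rest High.  Each subject consumes RNG
    substreams derived from (design seed, subject index) only, so cohorts
    are extensible without reshuffling existing subjects.  Covariates: age ~
    U[14, 15], sex ~ Bernoulli(0.5), site ~ two levels, PDS ~ N(16, 2.7),
    SES ~ N(7, 3).
    """
    if design.n_low < 1 or design.n_high < 1:
        raise ValueError("n_low and n_high must both be >= 1")
    atlas = make_atlas(design)
    rows = []
    volumes = []
    groups = [stress.LOW] * design.n_low + [stress.HIGH] * design.n_high
    for idx, group in enumerate(groups):
        rng = np.random.default_rng([design.seed, idx, _STREAM_QUESTIONNAIRE])
        items = _leq_items(group, rng)
        row = {
            "subject_id": f"sub-{idx:03d}",
            "intended_group": group,
            "age": float(rng.uniform(14, 15)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "site": "site1" if rng.random() < 0.5 else "site2",
            "PDS": float(rng.normal(16, 2.7)),
            "SES": float(rng.normal(7, 3)),
        }
        for col, v in zip(stress.leq_columns(), items):
            row[col] = v
        rows.append(row)
        volumes.append(make_subject_volume(atlas, design, group, subject_seed=idx))
    table = pd.DataFrame(rows)
    # nullable integers keep the item dtype stable whether or not any item
    # is not-experienced, and serialize as empty cells
    cols = stress.leq_columns()
    table[cols] = table[cols].astype("Int64")
    return Cohort(design=design, table=table, atlas=atlas, volumes=volumes)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write cohort CSV, atlas and GM NIfTI volumes, lookup TSV and design JSON."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = cohort.table.copy()
    table["volume_file"] = [f"gm_{sid}.nii" for sid in table["subject_id"]]
    csv_path = out / "cohort.csv"
    table.to_csv(csv_path, index=False, float_format="%.6f")
    mio.write_volume(cohort.atlas, out / "atlas.nii")
    for vol, fname in zip(cohort.volumes, table["volume_file"]):
        mio.write_volume(vol, out / fname)
    lookup = pd.DataFrame(
        {
            "label": np.arange(1, cohort.design.n_roi + 1),
            "name": [f"roi_{i:03d}" for i in range(1, cohort.design.n_roi + 1)],
            "hemisphere": ["L" if i % 2 else "R" for i in range(1, cohort.design.n_roi + 1)],
            "network": [f"net_{(i - 1) % 4 + 1}" for i in range(1, cohort.design.n_roi + 1)],
        }
    )
    lookup_path = out / "roi_lookup.tsv"
    lookup.to_csv(lookup_path, sep="\t", index=False)
    (out / "design.json").write_text(cohort.design.to_json())
    return {
        "cohort_csv": str(csv_path),
        "atlas": str(out / "atlas.nii"),
        "lookup": str(lookup_path),
        "design": str(out / "design.json"),
        "volumes": [str(out / f) for f in table["volume_file"]],
    }
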