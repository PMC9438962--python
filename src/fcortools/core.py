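"""Shared data model: voxel grids, BOLD series, network templates, clinical tables.

All voxel-wise fields are stored as flat vectors over the in-mask voxels of a
:class:`VolumeGrid`; the grid owns the mapping back to 3-D volumes and to world
(scanner/MNI-like) millimetre coordinates through its affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with an affine into world mm and a brain mask.

    Voxel indices are 0-based (i, j, k); world coordinates are obtained by the
    NIfTI convention ``world = affine @ [i, j, k, 1]``.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ParameterError(f"dims must be 3 positive integers, got {dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ShapeError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ParameterError("affine is not invertible")
        object.__setattr__(self, "affine", aff)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != dims:
            raise ShapeError(f"mask shape {mask.shape} != dims {dims}")
        if not mask.any():
            raise ParameterError("mask has no in-mask voxel")
        object.__setattr__(self, "mask", mask)

    # -- derived geometry -------------------------------------------------
    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def mask_coords(self) -> np.ndarray:
        """(V, 3) integer voxel coordinates of in-mask voxels, C-order."""
        return np.argwhere(self.mask)

    def flat_index(self) -> np.ndarray:
        """3-D int field mapping each in-mask voxel to its flat position, -1 outside."""
        idx = np.full(self.dims, -1, dtype=np.int64)
        idx[self.mask] = np.arange(self.n_voxels)
        return idx

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T) + inv[:3, 3]

    # -- field packing -----------------------------------------------------
    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask vector (V,) or stack (V, k) into full 3-D/4-D arrays."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ShapeError(
                f"expected leading dimension {self.n_voxels}, got {values.shape[0]}"
            )
        out_shape = self.dims + values.shape[1:]
        out = np.full(out_shape, fill, dtype=values.dtype if values.dtype.kind == "f" else float)
        out[self.mask] = values
        return out

    def mask_field(self, volume: np.ndarray) -> np.ndarray:
        """Gather a full 3-D (or 4-D) array into an in-mask vector (or matrix)."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.dims:
            raise ShapeError(f"volume shape {volume.shape[:3]} != dims {self.dims}")
        return volume[self.mask]

    def sphere_roi(self, center_world_mm: Sequence[float], radius_mm: float) -> np.ndarray:
        """In-mask flat indices of voxels whose centres lie within ``radius_mm``.

        Membership uses centre-to-centre Euclidean distance in world mm
        (boundary inclusive), so on a 3 mm isotropic grid a 3 mm sphere holds
        between 1 and 7 voxels depending on where the centre falls.
        """
        coords = self.mask_coords
        world = self.voxel_to_world(coords)
        d = np.linalg.norm(world - np.asarray(center_world_mm, dtype=float), axis=1)
        idx = np.nonzero(d <= radius_mm + 1e-9)[0]
        return idx


@dataclass
class BoldSeries:
    """One subject's in-mask voxel x time matrix plus acquisition metadata."""

    data: np.ndarray
    tr_s: float
    motion: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ShapeError("data must be 2-D (voxels x frames)")
        if self.n_frames < 2:
            raise ParameterError("a BOLD series needs at least 2 frames")
        if self.tr_s <= 0:
            raise ParameterError("tr_s must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_frames, 6):
                raise ShapeError(
                    f"motion must be (frames, 6) = ({self.n_frames}, 6), "
                    f"got {self.motion.shape}"
                )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data=data, tr_s=self.tr_s, motion=self.motion,
                          subject_id=self.subject_id)


class RSNTemplateSet:
    """Named, binary resting-state network templates on a shared grid.

    Templates are stored as an in-mask boolean indicator matrix of shape
    (V, k) with one column per network.
    """

    def __init__(self, grid: VolumeGrid, names: Sequence[str], masks: np.ndarray):
        names = list(names)
        if len(set(names)) != len(names):
            raise ParameterError("template names must be unique")
        masks = np.asarray(masks, dtype=bool)
        if masks.ndim != 2 or masks.shape != (grid.n_voxels, len(names)):
            raise ShapeError(
                f"masks must be (n_voxels, n_templates) = "
                f"({grid.n_voxels}, {len(names)}), got {masks.shape}"
            )
        sizes = masks.sum(axis=0)
        empty = [n for n, s in zip(names, sizes) if s == 0]
        if empty:
            raise ParameterError(f"templates with no in-mask voxel: {empty}")
        self.grid = grid
        self.names = names
        self.masks = masks

    @property
    def n_templates(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> np.ndarray:
        return self.masks.sum(axis=0)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[:, self.names.index(name)]

    def __iter__(self) -> Iterable[str]:
        return iter(self.names)

    def reordered(self, names: Sequence[str]) -> "RSNTemplateSet":
        order = [self.names.index(n) for n in names]
        return RSNTemplateSet(self.grid, list(names), self.masks[:, order])


#: MDS-UPDRS sub-items entering the tremor-dominant composite score.
TREMOR_ITEMS = ("2.10", "3.15", "3.16", "3.17", "3.18")
#: MDS-UPDRS sub-items entering the postural instability / gait difficulty score.
PIGD_ITEMS = ("2.12", "2.13", "3.10", "3.11", "3.12")

UPDRS_PREFIX = "updrs_"


@dataclass
class ClinicalTable:
    """Per-subject clinical covariates and scores.

    The underlying frame has one row per subject with columns
    ``subject_id, group, age, sex, mean_fd, ledd, ace_r`` plus any number of
    ``updrs_<item>`` columns (e.g. ``updrs_3.15``). ``group`` is
    ``patient``/``control``; ``sex`` is ``male``/``female``. Missing values
    are NaN and are preserved (controls have no LEDD or UPDRS entries).
    """

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ParameterError(f"clinical table lacks columns: {missing}")
        bad = set(self.frame["group"]) - {"patient", "control"}
        if bad:
            raise ParameterError(f"unknown group labels: {sorted(bad)}")
        items = self.frame[self.updrs_columns()]
        if (items.to_numpy(dtype=float) < 0).any():
            raise ParameterError("UPDRS item scores must be non-negative")

    def updrs_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(UPDRS_PREFIX)]

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    def subset(self, group: str) -> "ClinicalTable":
        return ClinicalTable(self.frame[self.frame["group"] == group].reset_index(drop=True))

    def require_group_sizes(self, minimum: int = 2) -> None:
        counts = self.frame["group"].value_counts()
        for g in ("patient", "control"):
            if counts.get(g, 0) < minimum:
                raise ParameterError(
                    f"group '{g}' has {counts.get(g, 0)} subjects; needs >= {minimum}"
                )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t"))
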