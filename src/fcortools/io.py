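"""NIfTI and TSV input/output.

Volumes are exchanged as ``.nii``/``.nii.gz`` through nibabel; motion traces
and tabular results as TSV. All voxel-wise payloads returned to callers are
in-mask vectors tied to a :class:`~fcortools.core.VolumeGrid`.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, RSNTemplateSet, VolumeGrid
from .errors import FormatError, ParameterError, ShapeError

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _load(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    return img


def read_volume(path, expect: str = "any"):
    """Read a NIfTI file and return ``(grid, data)``.

    ``grid`` carries the file's affine with an all-true mask; ``data`` is the
    raw 3-D (or 4-D, for ``expect='4d'``/'any') array. Use
    :func:`read_mask` / :func:`read_bold` for the typed entry points.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if expect == "3d" and data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if expect == "4d" and data.ndim != 4:
        raise ShapeError(f"{path}: expected a 4-D series, got {data.ndim}-D")
    if data.ndim not in (3, 4):
        raise ShapeError(f"{path}: expected 3-D or 4-D data, got {data.ndim}-D")
    dims = data.shape[:3]
    grid = VolumeGrid(dims=dims, affine=img.affine, mask=np.ones(dims, dtype=bool))
    return grid, data


def write_volume(grid: VolumeGrid, values: np.ndarray, path, *, masked: bool = True) -> None:
    """Write an in-mask vector/stack (``masked=True``) or a full array as NIfTI."""
    data = grid.unmask(np.asarray(values)) if masked else np.asarray(values)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def write_mask(grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> VolumeGrid:
    """Read a binary brain mask into a :class:`VolumeGrid`."""
    grid, data = read_volume(path, expect="3d")
    return VolumeGrid(dims=grid.dims, affine=grid.affine, mask=data > 0)


def read_bold(path, grid: VolumeGrid, *, tr_s: float | None = None,
              motion_path=None, subject_id: str | None = None) -> BoldSeries:
    """Read a 4-D series, mask it with ``grid`` and attach motion traces."""
    vgrid, data = read_volume(path, expect="4d")
    if vgrid.dims != grid.dims:
        raise ShapeError(f"{path}: dims {vgrid.dims} do not match grid {grid.dims}")
    if tr_s is None:
        tr_s = float(_load(path).header.get_zooms()[3]) or 1.0
    motion = read_motion(motion_path) if motion_path is not None else None
    sid = subject_id if subject_id is not None else Path(str(path)).name.split(".")[0]
    return BoldSeries(data=grid.mask_field(data), tr_s=tr_s, motion=motion,
                      subject_id=sid)


def write_bold(bold: BoldSeries, grid: VolumeGrid, path) -> None:
    vol = grid.unmask(np.asarray(bold.data, dtype=np.float32))
    img = nib.Nifti1Image(vol, grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size_mm) + (bold.tr_s,))
    nib.save(img, str(path))


def read_motion(path) -> np.ndarray:
    """Read a 6-column motion-parameter TSV (mm translations, rad rotations)."""
    table = pd.read_csv(path, sep="\t")
    cols = [c for c in MOTION_COLUMNS if c in table.columns]
    if len(cols) == 6:
        table = table[cols]
    elif table.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns")
    return table.to_numpy(dtype=float)


def write_motion(motion: np.ndarray, path) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ShapeError("motion must be (frames, 6)")
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_templates(paths: dict, grid: VolumeGrid) -> RSNTemplateSet:
    """Read one binary NIfTI per network name into an :class:`RSNTemplateSet`."""
    if not paths:
        raise ParameterError("no template files given")
    names, cols = [], []
    for name, p in paths.items():
        tgrid, data = read_volume(p, expect="3d")
        if tgrid.dims != grid.dims:
            raise ShapeError(f"template {name}: dims {tgrid.dims} != grid {grid.dims}")
        names.append(name)
        cols.append(grid.mask_field(data > 0))
    return RSNTemplateSet(grid, names, np.column_stack(cols))


def write_templates(templates: RSNTemplateSet, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, name in enumerate(templates.names):
        p = outdir / f"template_{name}.nii.gz"
        write_volume(templates.grid, templates.masks[:, i].astype(np.float32), p)
        paths[name] = str(p)
    return paths
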