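"""NIfTI volume I/O with acquisition-parameter sidecars.

Volumes travel as NIfTI-1 files whose affine is diagonal in the voxel size
(world coordinates in mm, origin at the corner voxel); acquisition constants
travel in a JSON sidecar next to the volumes.  Data is written float32 —
susceptibility in ppb and fields in ppm are comfortably inside float32
range — except label volumes, which stay integer.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VoxelGrid
from .acquisition import AcquisitionParams

SIDECAR_NAME = "acquisition.json"


def write_volume(path: str | Path, values: np.ndarray, grid: VoxelGrid) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), float32 unless integer."""
    path = Path(path)
    arr = np.asarray(values)
    grid.check_volume(arr, path.name)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32)
    affine = np.diag(list(grid.voxel_size) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(grid.voxel_size)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path,
                b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
                ) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI volume; the grid is rebuilt from shape and zooms."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VoxelGrid(arr.shape, zooms, b0_direction)
    return np.asarray(arr), grid


def write_sidecar(directory: str | Path, params: AcquisitionParams) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / SIDECAR_NAME
    path.write_text(params.to_json())
    return path


def read_sidecar(directory: str | Path) -> AcquisitionParams:
    path = Path(directory) / SIDECAR_NAME
    if not path.exists():
        raise FileNotFoundError(f"missing acquisition sidecar: {path}")
    return AcquisitionParams.from_json(path.read_text())


def save_dataset(dataset, directory: str | Path) -> Path:
    """Write a STAGE dataset (echo volumes, masks, truth) plus sidecar."""
    from .acquisition import StageDataset  # noqa: F401 (type only)
    directory = Path(directory)
    for name in dataset.ECHO_NAMES:
        echo = dataset.echo(name)
        write_volume(directory / f"mag_{name}.nii.gz", echo.magnitude,
                     dataset.grid)
        write_volume(directory / f"phase_{name}.nii.gz", echo.phase,
                     dataset.grid)
    write_volume(directory / "brain_mask.nii.gz",
                 dataset.brain_mask.astype(np.int16), dataset.grid)
    write_volume(directory / "structural.nii.gz", dataset.structural,
                 dataset.grid)
    if dataset.chi_truth is not None:
        write_volume(directory / "chi_gt.nii.gz", dataset.chi_truth.values,
                     dataset.grid)
    if dataset.labels is not None:
        write_volume(directory / "labels.nii.gz",
                     dataset.labels.astype(np.int16), dataset.grid)
    write_sidecar(directory, dataset.params)
    return directory


def load_dataset(directory: str | Path):
    """Read a dataset written by :func:`save_dataset`."""
    from .acquisition import StageDataset, EchoImage
    from .grids import SusceptibilityVolume
    directory = Path(directory)
    params = read_sidecar(directory)
    echoes = []
    grid = None
    tes = {"fal_te1": params.echo_times_s[0][0],
           "fal_te2": params.echo_times_s[0][1],
           "fah_te1": params.echo_times_s[1][0],
           "fah_te2": params.echo_times_s[1][1]}
    fas = {"fal_te1": params.flip_angles_deg[0],
           "fal_te2": params.flip_angles_deg[0],
           "fah_te1": params.flip_angles_deg[1],
           "fah_te2": params.flip_angles_deg[1]}
    for name in StageDataset.ECHO_NAMES:
        mag, grid = read_volume(directory / f"mag_{name}.nii.gz",
                                params.b0_direction)
        phase, _ = read_volume(directory / f"phase_{name}.nii.gz",
                               params.b0_direction)
        echoes.append(EchoImage(mag, phase, tes[name], fas[name], grid))
    mask, _ = read_volume(directory / "brain_mask.nii.gz", params.b0_direction)
    structural, _ = read_volume(directory / "structural.nii.gz",
                                params.b0_direction)
    chi_truth = labels = None
    if (directory / "chi_gt.nii.gz").exists():
        vals, _ = read_volume(directory / "chi_gt.nii.gz", params.b0_direction)
        chi_truth = SusceptibilityVolume(np.asarray(vals, dtype=float), grid)
    if (directory / "labels.nii.gz").exists():
        labels, _ = read_volume(directory / "labels.nii.gz", params.b0_direction)
        labels = np.asarray(labels)
    return StageDataset(echoes=echoes, params=params, grid=grid,
                        brain_mask=mask.astype(bool), structural=structural,
                        chi_truth=chi_truth, labels=labels)
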