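"""Voxel-grid conventions, the k-space dipole kernel, and the shared linear operators.

Every inversion in this package works on the same discrete model: a tissue
susceptibility distribution chi (in ppb) living on a regular Cartesian voxel
grid perturbs the main field B0 through a convolution with the unit magnetic
dipole response.  In k-space the convolution is a pointwise multiplication
with

    D(k) = 1/3 - (k . b_hat)^2 / |k|^2,

where b_hat is the direction of B0.  D vanishes on the magic-angle cone
(k . b_hat)^2 = |k|^2 / 3, which is what makes the inverse problem ill-posed
and motivates everything else in this package.

Conventions
-----------
* The DC term D(k=0) is set to 0, so every forward field (and every
  reconstruction) is mean-free over the volume.  Evaluation re-references
  explicitly (e.g. to CSF) where an absolute zero matters.
* The frequency lattice uses FFT sample frequencies scaled per axis by the
  voxel size, so anisotropic voxels are handled without resampling.
* Susceptibility is carried in ppb, field maps in ppm; `forward_field`
  performs the 1/1000 conversion.
* Spatial gradients are forward finite differences with a replicate
  (zero-gradient) boundary; `divergence` is their negative adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA = 2.675e8

_PPM = 1e-6
_PPB_PER_PPM = 1000.0

_AXES = {"x": 0, "y": 1, "z": 2}


class GridError(ValueError):
    """Raised for degenerate grids or mismatched volume/grid shapes."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).  Each component must be >= 8; a
        smaller slab cannot hold a meaningful dipole kernel.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    b0_direction : tuple of float
        Unit vector of the main field.  COSMOS orientations are expressed by
        rotating this vector, never by resampling the volume.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vox = tuple(float(v) for v in self.voxel_size)
        b0 = np.asarray(self.b0_direction, dtype=float)
        if len(shape) != 3 or any(n < 8 for n in shape):
            raise GridError(f"grid shape must be 3 components >= 8, got {shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise GridError(f"voxel size must be positive, got {vox}")
        if b0.shape != (3,) or abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            raise GridError("b0_direction must be a unit 3-vector")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vox)
        object.__setattr__(self, "b0_direction", tuple(float(c) for c in b0))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def frequency_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """FFT sample frequencies (cycles/mm) per axis, DC first."""
        return tuple(
            sfft.fftfreq(n, d=v) for n, v in zip(self.shape, self.voxel_size)
        )

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers, origin at the volume center."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def check_volume(self, values: np.ndarray, name: str = "volume") -> np.ndarray:
        arr = np.asarray(values)
        if arr.shape != self.shape:
            raise GridError(
                f"{name} shape {arr.shape} does not match grid shape {self.shape}"
            )
        return arr


def _finite_volume(grid: VoxelGrid, values: np.ndarray, name: str) -> np.ndarray:
    arr = grid.check_volume(np.asarray(values, dtype=float), name)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SusceptibilityVolume:
    """A 3D susceptibility map in ppb on a :class:`VoxelGrid`."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = _finite_volume(self.grid, self.values, "susceptibility")


@dataclass
class FieldMap:
    """A relative field-shift map deltaB in ppm (dimensionless x 1e-6)."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = _finite_volume(self.grid, self.values, "field map")


@dataclass
class DipoleKernel:
    """The k-space dipole response D(k) on the grid's FFT frequency lattice.

    Values lie in [-2/3, 1/3]; the DC sample is zero by convention.  The array
    is stored DC-first (unshifted), matching ``scipy.fft.fftn`` layout.
    """

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = self.grid.check_volume(np.asarray(self.values, dtype=float),
                                             "dipole kernel")

    def rfft_values(self) -> np.ndarray:
        """The kernel restricted to the ``rfftn`` half-spectrum (real input FFTs)."""
        n3 = self.grid.shape[2]
        return np.ascontiguousarray(self.values[..., : n3 // 2 + 1])


def make_dipole_kernel(grid: VoxelGrid) -> DipoleKernel:
    """Build D(k) = 1/3 - (k.b_hat)^2/|k|^2 on the grid's frequency lattice.

    The DC value is defined as 0 (mean-free convention).  Works for any unit
    ``b0_direction``; kz is the projection of k onto that axis.
    """
    fx, fy, fz = grid.frequency_axes()
    kx, ky, kz = np.meshgrid(fx, fy, fz, indexing="ij")
    b = np.asarray(grid.b0_direction)
    k_par = kx * b[0] + ky * b[1] + kz * b[2]
    k2 = kx * kx + ky * ky + kz * kz
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (k_par * k_par) / k2
    d[0, 0, 0] = 0.0
    # Enforce D(-k) = D(k) on the discrete lattice.  On Nyquist planes the
    # aliased frequency has a fixed sign, which for an oblique b0 breaks the
    # Hermitian symmetry of the cross terms in (k.b)^2; averaging with the
    # index-negated kernel restores a real, even convolution kernel so that
    # full-spectrum and half-spectrum FFT paths agree.
    d_neg = np.roll(d[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
    d = 0.5 * (d + d_neg)
    return DipoleKernel(values=d, grid=grid)


def forward_field(chi: SusceptibilityVolume, kernel: DipoleKernel) -> FieldMap:
    """Apply the dipole convolution: deltaB[ppm] = F^-1{ D F{chi} } / 1000.

    Linear in chi.  A spatially constant chi maps to an identically zero field
    because all of its spectral energy sits at DC where D := 0.
    """
    if chi.grid.shape != kernel.grid.shape:
        raise GridError("susceptibility and kernel grids differ")
    spec = sfft.rfftn(chi.values)
    field_ppb = sfft.irfftn(spec * kernel.rfft_values(), s=chi.grid.shape)
    return FieldMap(values=field_ppb / _PPB_PER_PPM, grid=kernel.grid)


def apply_dipole(values: np.ndarray, kernel: DipoleKernel) -> np.ndarray:
    """Raw dipole convolution on an array (no unit conversion).

    The operator is self-adjoint: D(k) is real and even, so the same call
    serves as forward and adjoint in the normal equations.
    """
    spec = sfft.rfftn(values)
    return sfft.irfftn(spec * kernel.rfft_values(), s=values.shape)


def field_to_phase(field: FieldMap, te_s: float, b0_T: float) -> np.ndarray:
    """Convert a ppm field shift into GRE phase (radians): phi = gamma B0 TE dB."""
    if te_s <= 0 or b0_T <= 0:
        raise ValueError("te_s and b0_T must be positive")
    return GAMMA * b0_T * te_s * (field.values * _PPM)


def phase_to_field(phase: np.ndarray, grid: VoxelGrid, te_s: float,
                   b0_T: float) -> FieldMap:
    """Inverse of :func:`field_to_phase`: deltaB[ppm] = phi / (gamma B0 TE)."""
    if te_s <= 0 or b0_T <= 0:
        raise ValueError("te_s and b0_T must be positive")
    values = np.asarray(phase, dtype=float) / (GAMMA * b0_T * te_s * _PPM)
    return FieldMap(values=values, grid=grid)


def gradient(values: np.ndarray, grid: VoxelGrid, axis: int | str) -> np.ndarray:
    """Forward finite difference along an axis, scaled by 1/voxel_size (1/mm).

    Replicate boundary: the last slice along the axis has zero gradient.
    """
    ax = _AXES.get(axis, axis) if isinstance(axis, str) else int(axis)
    arr = np.asarray(values, dtype=float)
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    src[ax] = slice(1, None)
    dst[ax] = slice(None, -1)
    out[tuple(dst)] = arr[tuple(src)] - arr[tuple(dst)]
    return out / grid.voxel_size[ax]


def divergence(values: np.ndarray, grid: VoxelGrid, axis: int | str) -> np.ndarray:
    """Negative adjoint of :func:`gradient` along one axis.

    Satisfies <G x, y> = <x, G^T y> with G^T = -divergence, to round-off.
    """
    ax = _AXES.get(axis, axis) if isinstance(axis, str) else int(axis)
    arr = np.asarray(values, dtype=float)
    # backward difference y_j - y_{j-1} (y_{-1} = 0), except the last slice,
    # which only receives -y_{N-2}: the forward difference there was zeroed
    # by the replicate boundary, so its adjoint carries no y_{N-1} term.
    shifted = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    src[ax] = slice(None, -1)
    dst[ax] = slice(1, None)
    shifted[tuple(dst)] = arr[tuple(src)]
    out = arr - shifted
    last = [slice(None)] * 3
    last[ax] = slice(-1, None)
    prev = [slice(None)] * 3
    prev[ax] = slice(-2, -1)
    out[tuple(last)] = -arr[tuple(prev)]
    return out / grid.voxel_size[ax]


def gradient_adjoint(values: np.ndarray, grid: VoxelGrid, axis: int | str) -> np.ndarray:
    """G^T y, i.e. minus the matched divergence."""
    return -divergence(values, grid, axis)
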