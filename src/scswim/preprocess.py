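"""From wrapped multi-echo phase to a local field map.

Three stages: phase unwrapping (spectral Laplacian method with a congruence
restoration step), SHARP harmonic background-field removal (spherical-mean-
value filtering with truncated-SVD deconvolution), and the magnitude-derived
data-fidelity weight W.

The Laplacian unwrapper estimates the true phase from

    phi = Lap^-1( cos(phi_w) Lap sin(phi_w) - sin(phi_w) Lap cos(phi_w) ),

with the Laplacian and its inverse evaluated spectrally under a cosine
(mirror) boundary, then snaps the estimate back onto the measured phase by
adding the nearest integer multiple of 2 pi voxelwise.  The congruence step
makes the output exactly equal to the input modulo 2 pi wherever the estimate
is within pi of the truth, which removes the smooth bias the pure spectral
estimate carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

from .grids import VoxelGrid, FieldMap


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing knobs.

    sharp_kernel_radius_vox : SMV sphere radius in voxels (default 6).
    sharp_tsvd_threshold : truncation level for the SMV deconvolution,
        relative to the filter's maximum of 1.  Default 0.05.
    unwrap_method : "laplacian" (built-in) or "none" (phase already unwrapped).
    """

    sharp_kernel_radius_vox: int = 6
    sharp_tsvd_threshold: float = 0.05
    unwrap_method: str = "laplacian"
    pad_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.sharp_kernel_radius_vox < 1:
            raise ValueError("SHARP kernel radius must be >= 1 voxel")
        if not (0 < self.sharp_tsvd_threshold < 0.5):
            raise ValueError("TSVD threshold must be in (0, 0.5)")


def zero_pad(values: np.ndarray, grid: VoxelGrid,
             pad_shape: tuple[int, int, int]) -> tuple[np.ndarray, VoxelGrid]:
    """Symmetrically zero-pad a volume to ``pad_shape`` (per-axis >= input).

    Padding before the k-space inversion suppresses circular-convolution
    wrap-around of the dipole field.  Returns the padded volume and its
    grid; :func:`crop_to` inverts the operation.
    """
    arr = grid.check_volume(np.asarray(values), "volume")
    pads = []
    for n, m in zip(grid.shape, pad_shape):
        if m < n:
            raise ValueError(f"pad shape {pad_shape} smaller than {grid.shape}")
        before = (m - n) // 2
        pads.append((before, m - n - before))
    padded = np.pad(arr, pads)
    return padded, VoxelGrid(tuple(pad_shape), grid.voxel_size,
                             grid.b0_direction)


def crop_to(values: np.ndarray, padded_grid: VoxelGrid,
            orig_shape: tuple[int, int, int]) -> np.ndarray:
    """Undo :func:`zero_pad`: extract the centered original region."""
    arr = padded_grid.check_volume(np.asarray(values), "volume")
    slices = []
    for m, n in zip(padded_grid.shape, orig_shape):
        before = (m - n) // 2
        slices.append(slice(before, before + n))
    return arr[tuple(slices)]


def _dct_laplace_eigs(grid: VoxelGrid) -> np.ndarray:
    """Eigenvalues -|k|^2 of the continuum Laplacian under the DCT-II basis."""
    eig = np.zeros(grid.shape)
    for ax, (n, h) in enumerate(zip(grid.shape, grid.voxel_size)):
        k = np.pi * np.arange(n) / (n * h)
        shape = [1, 1, 1]
        shape[ax] = n
        eig = eig - (k ** 2).reshape(shape)
    return eig


def _dct_laplacian(vol: np.ndarray, eig: np.ndarray) -> np.ndarray:
    return sfft.idctn(eig * sfft.dctn(vol, type=2, norm="ortho"),
                      type=2, norm="ortho")


def _dct_inv_laplacian(vol: np.ndarray, eig: np.ndarray) -> np.ndarray:
    spec = sfft.dctn(vol, type=2, norm="ortho")
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = spec / eig
    spec.flat[0] = 0.0  # the constant mode is unobservable
    return sfft.idctn(spec, type=2, norm="ortho")


def unwrap_phase(wrapped: np.ndarray, grid: VoxelGrid,
                 mask: np.ndarray | None = None,
                 method: str = "laplacian") -> np.ndarray:
    """Unwrap a 3D phase volume (radians).

    The output is congruent with the input modulo 2 pi voxelwise.  ``mask``
    restricts the congruence anchoring (phase outside it is irrelevant noise
    in air); with ``method="none"`` the input is returned untouched for
    pipelines that bring their own unwrapper.
    """
    phase = np.asarray(wrapped, dtype=float)
    grid.check_volume(phase, "phase")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
    if method == "none":
        return phase.copy()
    if method != "laplacian":
        raise ValueError(f"unknown unwrap method: {method!r}")

    phase = np.angle(np.exp(1j * phase))  # enforce (-pi, pi]
    eig = _dct_laplace_eigs(grid)
    s, c = np.sin(phase), np.cos(phase)
    rhs = c * _dct_laplacian(s, eig) - s * _dct_laplacian(c, eig)
    estimate = _dct_inv_laplacian(rhs, eig)
    # The estimate's constant mode is arbitrary; anchor it with the circular
    # mean of the residual so the subsequent 2 pi snapping is stable.
    anchor = mask if mask is not None else slice(None)
    offset = np.angle(np.mean(np.exp(1j * (phase[anchor] - estimate[anchor]))))
    estimate = estimate + offset
    # congruence restoration: snap to the measured phase mod 2 pi
    n = np.round((estimate - phase) / (2.0 * np.pi))
    return phase + 2.0 * np.pi * n


def _smv_kernel_fft(grid: VoxelGrid, radius_vox: int) -> np.ndarray:
    """k-space SMV filter 1 - S(k), S = normalized sphere of given radius."""
    idx = [np.minimum(np.arange(n), n - np.arange(n)) for n in grid.shape]
    ix, iy, iz = np.meshgrid(*idx, indexing="ij")
    sphere = (ix ** 2 + iy ** 2 + iz ** 2) <= radius_vox ** 2
    s = sphere.astype(float)
    s /= s.sum()
    return 1.0 - sfft.fftn(s).real


def _ball(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 + zz ** 2) <= r ** 2


def sharp_remove_background(field: FieldMap, brain_mask: np.ndarray,
                            cfg: PreprocConfig | None = None
                            ) -> tuple[FieldMap, np.ndarray]:
    """SHARP: remove harmonic (background) field inside the brain.

    Applies the spherical-mean-value filter (delta - sphere) in k-space,
    masks, and deconvolves by truncated division.  Harmonic components —
    fields sourced outside the mask, including any constant offset — are
    annihilated.  Returns the local field and the mask eroded by the kernel
    radius, outside of which the SMV kernel overlaps non-brain and the result
    is invalid.
    """
    cfg = cfg or PreprocConfig()
    grid = field.grid
    mask = np.asarray(brain_mask, dtype=bool)
    grid.check_volume(mask, "brain mask")
    if not mask.any():
        raise ValueError("empty brain mask")
    eroded = ndimage.binary_erosion(mask, structure=_ball(cfg.sharp_kernel_radius_vox))
    if not eroded.any():
        raise ValueError("SHARP kernel too large: eroded mask is empty")

    smv = _smv_kernel_fft(grid, cfg.sharp_kernel_radius_vox)
    filtered = sfft.ifftn(smv * sfft.fftn(field.values * mask)).real
    filtered *= eroded
    spec = sfft.fftn(filtered)
    inv = np.where(np.abs(smv) > cfg.sharp_tsvd_threshold, smv, np.inf)
    local = sfft.ifftn(spec / inv).real * eroded
    return FieldMap(local, grid), eroded


def bootstrap_unwrap_long_echo(wrapped_long: np.ndarray,
                               unwrapped_short: np.ndarray,
                               te_long_s: float, te_short_s: float,
                               grid: VoxelGrid) -> np.ndarray:
    """Temporally unwrap a long echo from the short echo of the same scan.

    The field is TE-independent, so the short echo's unwrapped phase scaled
    by TE_long/TE_short predicts the long echo's phase; each voxel of the
    wrapped long echo is snapped to the nearest 2 pi multiple of that
    prediction.  Because the anchoring is per-voxel, this recovers phase
    even where the long echo's spatial gradient exceeds pi per voxel (next
    to microbleeds and calcifications), which no spatial unwrapper can do.
    The prediction error is the short echo's phase noise scaled by the TE
    ratio; it only needs to stay below pi for the snap to be exact.
    """
    phase = grid.check_volume(np.asarray(wrapped_long, dtype=float), "phase")
    if te_long_s <= 0 or te_short_s <= 0:
        raise ValueError("echo times must be positive")
    predicted = np.asarray(unwrapped_short, dtype=float) * (te_long_s / te_short_s)
    phase = np.angle(np.exp(1j * phase))
    n = np.round((predicted - phase) / (2.0 * np.pi))
    return phase + 2.0 * np.pi * n


def phase_reliability_mask(wrapped_phase: np.ndarray, brain_mask: np.ndarray,
                           grid: VoxelGrid,
                           gradient_threshold_rad: float = 2.0) -> np.ndarray:
    """Flag voxels whose phase is spatially aliased (True = unreliable).

    Where the inter-voxel phase step exceeds pi the sampling theorem for
    phase is violated and no unwrapper can recover the true value — this
    happens right next to very strong susceptibility sources (microbleeds,
    calcifications) and inside signal voids where phase is pure noise.  A
    face between two in-brain voxels whose wrapped phase difference exceeds
    ``gradient_threshold_rad`` marks both voxels unreliable; the solver
    removes them from the data term (W = 0) and lets the surrounding field
    and the other echoes determine those voxels.
    """
    phase = grid.check_volume(np.asarray(wrapped_phase, dtype=float), "phase")
    mask = np.asarray(brain_mask, dtype=bool)
    bad = np.zeros(grid.shape, dtype=bool)
    for ax in range(3):
        step = np.angle(np.exp(1j * np.diff(phase, axis=ax)))
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        in_brain_face = mask[tuple(lo)] & mask[tuple(hi)]
        big = (np.abs(step) > gradient_threshold_rad) & in_brain_face
        bad[tuple(lo)] |= big
        bad[tuple(hi)] |= big
    # A step that wraps past 2 pi aliases back below the threshold and is
    # invisible to the face test, but such faces always adjoin detected ones
    # (the step grows continuously toward the source); one dilation covers
    # that blind zone.
    bad = ndimage.binary_dilation(bad) & mask
    return bad


def build_fidelity_weight(magnitude: np.ndarray, brain_mask: np.ndarray,
                          grid: VoxelGrid) -> np.ndarray:
    """W proportional to the image magnitude, mean 1 over the mask, 0 outside."""
    mag = np.asarray(magnitude, dtype=float)
    grid.check_volume(mag, "magnitude")
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    mask = np.asarray(brain_mask, dtype=bool)
    mean = mag[mask].mean() if mask.any() else 0.0
    if mean <= 0:
        raise ValueError("magnitude is zero over the mask")
    return np.where(mask, mag / mean, 0.0)
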