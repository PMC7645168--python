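"""Reference dipole inversions: TKD, iSWIM and COSMOS.

TKD (thresholded k-space division) divides the field by the dipole kernel
wherever the kernel is safely away from its zero cone and substitutes a
sign-preserving threshold value elsewhere.  It is fast but underestimates
susceptibility and streaks.

iSWIM (iterative susceptibility-weighted imaging and mapping) starts from
TKD and iteratively refills the ill-conditioned cone region of k-space with
the spectrum of a constrained map containing only the high-susceptibility
voxels (veins, nuclei, bleeds), identified by thresholding a homodyne
high-pass filtered map.  Measured k-space samples in the well-conditioned
region are never touched.

COSMOS combines fields acquired at several B0 orientations by voxelwise (in
k-space) weighted least squares; with three or more well-separated
orientations the zero cones do not intersect and the inversion is essentially
exact.  It serves as the reference standard.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from .grids import SusceptibilityVolume, FieldMap, DipoleKernel, GridError

_PPB_PER_PPM = 1000.0

#: Default size of the k-space Hanning window of the homodyne low-pass.
HOMODYNE_KERNEL_SIZE = 32
#: Default threshold (ppb) on the high-pass map marking high-|chi| voxels.
CHI_CLIP_THRESHOLD_PPB = 250.0


def homodyne_highpass(values: np.ndarray, kernel_size: int = HOMODYNE_KERNEL_SIZE
                      ) -> np.ndarray:
    """High-pass filter a volume by subtracting its Hanning low-pass.

    The low-pass is a centered ``kernel_size``^3 Hanning window in k-space —
    the same construction homodyne processing applies to magnitude images,
    used here on susceptibility maps to isolate small high-|chi| structures
    from slowly varying anatomy.
    """
    arr = np.asarray(values, dtype=float)
    spec = sfft.fftshift(sfft.fftn(arr))
    win = np.ones(1)
    full = np.zeros(arr.shape)
    slices = []
    wins = []
    for n in arr.shape:
        m = min(kernel_size, n)
        w = np.hanning(m + 2)[1:-1]
        start = n // 2 - m // 2
        slices.append(slice(start, start + m))
        wins.append(w)
    block = wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
    full[tuple(slices)] = block
    low = sfft.ifftn(sfft.ifftshift(spec * full)).real
    return arr - low


def tkd_inversion(field: FieldMap, kernel: DipoleKernel,
                  threshold: float = 0.1) -> SusceptibilityVolume:
    """Thresholded k-space division.

    chi_k = dB_k / D where |D| >= t; elsewhere chi_k = dB_k / (t sign D),
    with sign(0) taken as +1.  Input field in ppm, output chi in ppb.
    """
    if not (0 < threshold <= 1.0 / 3.0):
        raise ValueError("TKD threshold must be in (0, 1/3]")
    if field.grid.shape != kernel.grid.shape:
        raise GridError("field and kernel grids differ")
    d = kernel.values
    sign = np.where(d >= 0, 1.0, -1.0)
    d_safe = np.where(np.abs(d) >= threshold, d, threshold * sign)
    spec = sfft.fftn(field.values * _PPB_PER_PPM)
    chi = sfft.ifftn(spec / d_safe).real
    return SusceptibilityVolume(chi, field.grid)


def iswim_inversion(field: FieldMap, kernel: DipoleKernel,
                    threshold: float = 0.1, n_iter: int = 4,
                    chi_clip_threshold: float = CHI_CLIP_THRESHOLD_PPB,
                    homodyne_kernel_size: int = HOMODYNE_KERNEL_SIZE
                    ) -> SusceptibilityVolume:
    """Iterative SWIM: TKD followed by constrained k-space cone refilling.

    Each iteration thresholds the homodyne high-pass of the current map at
    ``chi_clip_threshold`` (ppb, on |chi|) to find high-susceptibility
    voxels, zeroes everything else, and substitutes that constrained map's
    spectrum into the ill-conditioned region {|D| < threshold}.  The measured
    division values on {|D| >= threshold} are kept exactly, so n_iter = 0
    reduces to TKD.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    chi = tkd_inversion(field, kernel, threshold).values
    if n_iter == 0:
        return SusceptibilityVolume(chi, field.grid)
    well = np.abs(kernel.values) >= threshold
    spec_meas = sfft.fftn(field.values * _PPB_PER_PPM)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_k_well = np.where(well, spec_meas / np.where(well, kernel.values, 1.0), 0)
    for _ in range(n_iter):
        hp = homodyne_highpass(chi, homodyne_kernel_size)
        constrained = np.where(np.abs(hp) >= chi_clip_threshold, chi, 0.0)
        chi_k = np.where(well, chi_k_well, sfft.fftn(constrained))
        chi = sfft.ifftn(chi_k).real
    return SusceptibilityVolume(chi, field.grid)


def cosmos_inversion(fields: list[FieldMap], kernels: list[DipoleKernel],
                     weights: list[float] | None = None,
                     eps: float = 1e-3) -> SusceptibilityVolume:
    """Multi-orientation weighted least squares in k-space.

    chi_k = sum_i w_i D_i dB_i,k / sum_i w_i D_i^2, with the denominator
    floored at ``eps`` where all orientations are simultaneously
    ill-conditioned.  Requires >= 3 orientations (with two the zero cones
    still intersect on curves and the inversion is unstable).
    """
    if len(fields) < 3:
        raise ValueError("COSMOS needs at least 3 orientations")
    if len(fields) != len(kernels):
        raise ValueError("one kernel per field is required")
    grid = fields[0].grid
    for f, k in zip(fields, kernels):
        if f.grid.shape != grid.shape or k.grid.shape != grid.shape:
            raise GridError("all orientations must share one grid shape")
    if weights is None:
        weights = [1.0] * len(fields)
    num = np.zeros(grid.shape, dtype=complex)
    den = np.zeros(grid.shape)
    for f, k, w in zip(fields, kernels, weights):
        spec = sfft.fftn(f.values * _PPB_PER_PPM)
        num += w * k.values * spec
        den += w * k.values ** 2
    chi = sfft.ifftn(num / np.maximum(den, eps)).real
    return SusceptibilityVolume(chi, grid)
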