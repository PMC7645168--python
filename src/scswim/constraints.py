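"""Structural priors for the constrained inversion: the P and R masks.

P (one binary volume per axis) gates the l1 gradient penalty: P_i = 0 on
voxels where either the structural image rho (a T1-weighted-enhanced
contrast) or the initial susceptibility estimate chi_hat has a significant
derivative along axis i, so true anatomical edges are exempt from gradient
sparsity and are not smoothed away.  "Significant" means exceeding
``noise_mult`` (default 2.5) times the noise level of that derivative
volume.

R (a real volume in [0, 1]) weights the l2 amplitude penalty: it is the
max-normalized structural image, forced to zero over deep-gray-matter labels
and over voxels whose homodyne high-pass filtered chi_hat exceeds a clip
threshold (veins, bleeds, calcifications), so high-susceptibility structures
are protected from shrinkage while smooth tissue is regularized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid, gradient
from .baselines import (homodyne_highpass, CHI_CLIP_THRESHOLD_PPB,
                        HOMODYNE_KERNEL_SIZE)


@dataclass
class MaskSet:
    """The solver's weighting volumes on one grid.

    P_x/P_y/P_z are binary edge-exclusion masks, R the protection weight in
    [0, 1], W the magnitude-derived fidelity weight (>= 0, mean 1 over the
    brain), and brain_mask the support of the reconstruction.
    """

    P: tuple[np.ndarray, np.ndarray, np.ndarray]
    R: np.ndarray
    W: np.ndarray
    brain_mask: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        for i, p in enumerate(self.P):
            arr = self.grid.check_volume(np.asarray(p), f"P[{i}]")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("P masks must be binary")
        self.P = tuple(np.asarray(p, dtype=float) for p in self.P)
        self.R = self.grid.check_volume(np.asarray(self.R, dtype=float), "R")
        if self.R.min() < 0 or self.R.max() > 1:
            raise ValueError("R must lie in [0, 1]")
        self.W = self.grid.check_volume(np.asarray(self.W, dtype=float), "W")
        if self.W.min() < 0:
            raise ValueError("W must be non-negative")
        self.brain_mask = self.grid.check_volume(
            np.asarray(self.brain_mask, dtype=bool), "brain mask")

    def with_weight(self, W: np.ndarray) -> "MaskSet":
        return MaskSet(self.P, self.R, W, self.brain_mask, self.grid)


def derivative_noise_level(deriv: np.ndarray, brain_mask: np.ndarray) -> float:
    """Robust sigma of a derivative volume: 1.4826 x MAD within the mask.

    On noiseless piecewise-constant inputs the MAD is zero; a tiny floor
    relative to the largest gradient keeps the edge threshold meaningful
    (any strictly nonzero derivative then counts as an edge).
    """
    vals = deriv[brain_mask]
    sigma = 1.4826 * np.median(np.abs(vals - np.median(vals)))
    if sigma == 0.0:
        peak = np.abs(vals).max()
        sigma = 1e-6 * peak if peak > 0 else np.inf
    return float(sigma)


def edge_mask(structural: np.ndarray, chi_init: np.ndarray, grid: VoxelGrid,
              brain_mask: np.ndarray | None = None, noise_mult: float = 2.5
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis binary edge-exclusion masks P_x, P_y, P_z.

    P_i = [|G_i rho| < mu1] * [|G_i chi_hat| < mu2] with mu = noise_mult
    times the robust noise level of the respective derivative volume.
    Constant inputs give P = 1 everywhere (no edges), and the masks are
    invariant to global rescaling of either input.
    """
    rho = grid.check_volume(np.asarray(structural, dtype=float), "structural")
    chi = grid.check_volume(np.asarray(chi_init, dtype=float), "chi_init")
    if brain_mask is None:
        brain_mask = np.ones(grid.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)

    masks = []
    for ax in range(3):
        g_rho = gradient(rho, grid, ax)
        g_chi = gradient(chi, grid, ax)
        mu1 = noise_mult * derivative_noise_level(g_rho, brain_mask)
        mu2 = noise_mult * derivative_noise_level(g_chi, brain_mask)
        p = (np.abs(g_rho) < mu1) & (np.abs(g_chi) < mu2)
        masks.append(p.astype(float))
    return tuple(masks)


def structural_R_mask(structural: np.ndarray, chi_init: np.ndarray,
                      grid: VoxelGrid, brain_mask: np.ndarray,
                      dgm_labels: np.ndarray | None = None,
                      chi_clip_threshold: float = CHI_CLIP_THRESHOLD_PPB,
                      homodyne_kernel_size: int = HOMODYNE_KERNEL_SIZE,
                      binary: bool = False) -> np.ndarray:
    """Protection weight R in [0, 1].

    R is the structural image normalized by its in-brain maximum (or a flat
    1 with ``binary=True``), zeroed on deep-gray labels, on voxels where the
    homodyne high-pass of chi_hat (ppb) exceeds ``chi_clip_threshold`` in
    magnitude, and outside the brain.  ``dgm_labels`` is any integer volume
    whose nonzero voxels are to be protected; it may be omitted, in which
    case only the chi_hat gate applies.
    """
    rho = grid.check_volume(np.asarray(structural, dtype=float), "structural")
    chi = grid.check_volume(np.asarray(chi_init, dtype=float), "chi_init")
    mask = np.asarray(brain_mask, dtype=bool)
    if np.any(rho < 0):
        raise ValueError("structural image must be non-negative")

    peak = rho[mask].max() if mask.any() else 0.0
    if binary or peak <= 0:
        r = np.ones(grid.shape)
    else:
        r = rho / peak
    r = np.where(mask, r, 0.0)

    hp = homodyne_highpass(chi, homodyne_kernel_size)
    r[np.abs(hp) >= chi_clip_threshold] = 0.0
    if dgm_labels is not None:
        r[np.asarray(dgm_labels) != 0] = 0.0
    return np.clip(r, 0.0, 1.0)


def ideal_masks(chi_truth: np.ndarray, structural: np.ndarray,
                labels: np.ndarray, grid: VoxelGrid,
                brain_mask: np.ndarray, W: np.ndarray | None = None,
                protect_codes: tuple[int, ...] | None = None) -> MaskSet:
    """Masks built from phantom ground truth (the P_ideal / R_ideal setting).

    Edges come from the true susceptibility and the noiseless structural
    image; the protection mask zeroes every deep-gray, vein and insert label.
    """
    from .phantom import DGM_CODES, SPHERE_CODES, VEIN_CODES
    if protect_codes is None:
        protect_codes = DGM_CODES + SPHERE_CODES + VEIN_CODES
    protect = np.isin(labels, protect_codes).astype(np.int16)
    P = edge_mask(structural, chi_truth, grid, brain_mask)
    R = structural_R_mask(structural, chi_truth, grid, brain_mask,
                          dgm_labels=protect)
    if W is None:
        W = np.where(np.asarray(brain_mask, dtype=bool), 1.0, 0.0)
    return MaskSet(P=P, R=R, W=W, brain_mask=brain_mask, grid=grid)
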