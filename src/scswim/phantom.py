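"""Simulated STAGE brain phantom.

Builds a labeled 3D susceptibility model of the human brain — cortical gray
matter, white matter, the deep-gray nuclei (CN, GP, PT, THA, RN, SN, crus
cerebri), ventricles/CSF and the major veins — plus spherical inserts that
mimic cerebral microbleeds (CMB, paramagnetic), calcium deposits (CaD,
diamagnetic) and the pineal gland (PG).  From the susceptibility model it
forward-simulates the four STAGE echoes: phase through the dipole convolution
at 3 T, magnitude through the Ernst steady-state GRE signal equation with an
R2* map derived from susceptibility (R2* = 20/s + 0.125 chi, with 40/s inside
the CMB/CaD/PG inserts), and complex Gaussian noise at a 10:1 SNR.

The geometry is a deterministic parametric atlas: the brain is an ellipsoid,
deep-gray structures are paired ellipsoids at anatomically plausible
fractional offsets, ventricles are medial ellipsoids and the straight-sinus /
internal-cerebral veins are capsule primitives.  Structure positions are
expressed as fractions of the brain semi-axes so the same anatomy scales onto
smaller grids; insert radii and susceptibilities are absolute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import (VoxelGrid, SusceptibilityVolume, make_dipole_kernel,
                    forward_field, field_to_phase)
from .acquisition import AcquisitionParams, EchoImage, StageDataset


class SphereOverlapError(ValueError):
    """Two sphere inserts intersect."""


@dataclass(frozen=True)
class TissueProperties:
    """Per-label susceptibility (ppb), T1 (ms) and relative proton density."""

    name: str
    chi_ppb: float
    t1_ms: float
    rho0: float

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise ValueError(f"{self.name}: T1 must be positive")
        if not (0 < self.rho0 <= 1):
            raise ValueError(f"{self.name}: rho0 must be in (0, 1]")


#: Tissue table of the simulated brain model: chi (ppb), T1 (ms), rho0.
TISSUE_TABLE: dict[str, TissueProperties] = {
    t.name: t for t in [
        TissueProperties("WM", 0.0, 837.0, 0.73),
        TissueProperties("GM", 20.0, 1607.0, 0.80),
        TissueProperties("GP", 180.0, 888.0, 0.72),
        TissueProperties("PT", 90.0, 1140.0, 0.82),
        TissueProperties("THA", 10.0, 1218.0, 0.79),
        TissueProperties("CN", 60.0, 1226.0, 0.82),
        TissueProperties("SN", 160.0, 1147.0, 0.79),
        TissueProperties("RN", 130.0, 833.0, 0.80),
        TissueProperties("CC", -30.0, 780.0, 0.79),
        TissueProperties("V", 450.0, 1932.0, 0.85),
        TissueProperties("CSF", -14.0, 4163.0, 1.00),
    ]
}

#: Integer label codes.  Bilateral structures carry separate L/R codes that
#: share one tissue-table entry (base name before the "-").
LABEL_CODES: dict[str, int] = {
    "WM": 1, "GM": 2, "CSF": 3, "V": 4,
    "CN-L": 10, "CN-R": 11, "GP-L": 12, "GP-R": 13,
    "PT-L": 14, "PT-R": 15, "THA-L": 16, "THA-R": 17,
    "RN-L": 18, "RN-R": 19, "SN-L": 20, "SN-R": 21,
    "CC-L": 22, "CC-R": 23,
    "CMB1": 30, "CMB2": 31, "CaD1": 32, "CaD2": 33, "PG": 34,
}
CODE_NAMES = {v: k for k, v in LABEL_CODES.items()}

#: Codes of deep-gray-matter structures (used to build the protection mask R).
DGM_NAMES = ("CN", "GP", "PT", "THA", "RN", "SN", "CC")
DGM_CODES = tuple(LABEL_CODES[f"{n}-{s}"] for n in DGM_NAMES for s in "LR")
SPHERE_NAMES = ("CMB1", "CMB2", "CaD1", "CaD2", "PG")
SPHERE_CODES = tuple(LABEL_CODES[n] for n in SPHERE_NAMES)
VEIN_CODES = (LABEL_CODES["V"],)


def tissue_of_label(name: str) -> TissueProperties:
    base = name.split("-")[0]
    return TISSUE_TABLE[base]


@dataclass(frozen=True)
class SphereInsert:
    """A spherical high-|chi| insert: center/radius in mm, chi in ppb."""

    name: str
    center_frac: tuple[float, float, float]
    radius_mm: float
    chi_ppb: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")

    def center_mm(self, semi_axes: tuple[float, float, float]) -> np.ndarray:
        return np.asarray(self.center_frac) * np.asarray(semi_axes)


@dataclass(frozen=True)
class _Ellipsoid:
    name: str
    center_frac: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass(frozen=True)
class _Capsule:
    name: str
    a_frac: tuple[float, float, float]
    b_frac: tuple[float, float, float]
    radius_mm: float


# Paired deep-gray structures; mirrored in x for the right side.
_STRUCTURES_LEFT = [
    _Ellipsoid("THA", (-0.138, -0.267, 0.073), (8.0, 11.0, 7.0)),
    _Ellipsoid("CN", (-0.185, 0.200, 0.182), (5.0, 10.0, 6.0)),
    _Ellipsoid("PT", (-0.370, 0.053, 0.073), (7.0, 11.0, 6.5)),
    _Ellipsoid("GP", (-0.200, 0.000, 0.000), (4.5, 7.0, 4.5)),
    _Ellipsoid("SN", (-0.138, -0.373, -0.255), (4.0, 6.0, 3.0)),
    _Ellipsoid("RN", (-0.077, -0.347, -0.182), (3.0, 3.5, 3.0)),
    _Ellipsoid("CC", (-0.200, -0.400, -0.291), (4.0, 8.0, 4.0)),
]

_VENTRICLES = [
    _Ellipsoid("CSF", (-0.108, 0.080, 0.255), (6.0, 22.0, 7.0)),
    _Ellipsoid("CSF", (0.108, 0.080, 0.255), (6.0, 22.0, 7.0)),
]

_VEINS = [
    _Capsule("V", (0.0, -0.600, -0.364), (0.0, -0.827, -0.091), 2.0),   # SSV
    _Capsule("V", (0.0, -0.027, 0.255), (0.0, -0.333, 0.182), 1.5),     # ICV
]

DEFAULT_SPHERES = (
    SphereInsert("CMB1", (0.230, 0.600, 0.182), 3.0, 3000.0),
    SphereInsert("CMB2", (-0.230, 0.600, 0.182), 5.0, 1000.0),
    SphereInsert("CaD1", (-0.230, -0.600, 0.182), 5.0, -1000.0),
    SphereInsert("CaD2", (0.230, -0.600, 0.182), 3.0, -3000.0),
    SphereInsert("PG", (0.0, -0.467, 0.000), 3.0, -3000.0),
)


@dataclass
class PhantomSpec:
    """Everything needed to build the phantom deterministically.

    ``brain_semi_axes_mm`` sets the outer (GM) ellipsoid; white matter is the
    interior scaled by ``wm_scale``.  All structure centers are fractions of
    the brain semi-axes.
    """

    grid: VoxelGrid
    brain_semi_axes_mm: tuple[float, float, float] = (65.0, 75.0, 55.0)
    wm_scale: float = 0.88
    spheres: tuple[SphereInsert, ...] = DEFAULT_SPHERES
    tissue_table: dict[str, TissueProperties] = field(
        default_factory=lambda: dict(TISSUE_TABLE))
    seed: int = 0

    @classmethod
    def default(cls, **kw) -> "PhantomSpec":
        """Desk-scale default: 160 x 160 x 96 voxels at 1 x 1 x 1.5 mm."""
        grid = kw.pop("grid", None) or VoxelGrid((160, 160, 96), (1.0, 1.0, 1.5))
        return cls(grid=grid, **kw)

    @classmethod
    def compact(cls, **kw) -> "PhantomSpec":
        """Smaller grid for quick runs: 128 x 128 x 80 at 1 x 1 x 1.5 mm."""
        grid = kw.pop("grid", None) or VoxelGrid((128, 128, 80), (1.0, 1.0, 1.5))
        axes = kw.pop("brain_semi_axes_mm", (52.0, 60.0, 46.0))
        return cls(grid=grid, brain_semi_axes_mm=axes, **kw)

    @classmethod
    def tiny(cls, **kw) -> "PhantomSpec":
        """Smoke-test scale (64 x 64 x 40): anatomy is cramped and ROI
        accuracy degrades; use only to exercise the pipeline quickly."""
        grid = kw.pop("grid", None) or VoxelGrid((64, 64, 40), (1.0, 1.0, 1.5))
        axes = kw.pop("brain_semi_axes_mm", (30.0, 34.0, 26.0))
        return cls(grid=grid, brain_semi_axes_mm=axes, **kw)

    def validate(self) -> None:
        a = np.asarray(self.brain_semi_axes_mm)
        for s1 in self.spheres:
            c1 = s1.center_mm(self.brain_semi_axes_mm)
            if np.sum((c1 / a) ** 2) >= 1.0:
                raise ValueError(f"sphere {s1.name} outside the brain")
        for i, s1 in enumerate(self.spheres):
            for s2 in self.spheres[i + 1:]:
                d = np.linalg.norm(s1.center_mm(self.brain_semi_axes_mm)
                                   - s2.center_mm(self.brain_semi_axes_mm))
                if d < s1.radius_mm + s2.radius_mm:
                    raise SphereOverlapError(
                        f"spheres {s1.name} and {s2.name} overlap")


def _inside_ellipsoid(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def _inside_capsule(coords, a, b, radius) -> np.ndarray:
    x, y, z = coords
    p = np.stack([x, y, z], axis=-1)
    a = np.asarray(a)
    d = np.asarray(b) - a
    t = np.clip(np.tensordot(p - a, d, axes=1) / np.dot(d, d), 0.0, 1.0)
    closest = a + t[..., None] * d
    return np.linalg.norm(p - closest, axis=-1) <= radius


def build_phantom(spec: PhantomSpec) -> tuple[SusceptibilityVolume, np.ndarray]:
    """Rasterize the phantom: returns (chi_ideal in ppb, integer label volume).

    Painting order is GM shell -> WM -> ventricles -> deep gray -> veins ->
    spheres, so nuclei stay intact where they abut the ventricles and the
    inserts always win.  Deterministic given the spec.
    """
    spec.validate()
    coords = spec.grid.coordinates_mm()
    semi = np.asarray(spec.brain_semi_axes_mm)
    labels = np.zeros(spec.grid.shape, dtype=np.int16)

    brain = _inside_ellipsoid(coords, (0, 0, 0), semi)
    wm = _inside_ellipsoid(coords, (0, 0, 0), semi * spec.wm_scale)
    labels[brain] = LABEL_CODES["GM"]
    labels[wm] = LABEL_CODES["WM"]

    for e in _VENTRICLES:
        m = _inside_ellipsoid(coords, np.asarray(e.center_frac) * semi,
                              e.semi_axes_mm)
        labels[m & brain] = LABEL_CODES[e.name]

    for e in _STRUCTURES_LEFT:
        for side, sign in (("L", 1.0), ("R", -1.0)):
            center = np.asarray(e.center_frac) * semi
            center[0] *= sign
            m = _inside_ellipsoid(coords, center, e.semi_axes_mm)
            labels[m & brain] = LABEL_CODES[f"{e.name}-{side}"]

    for c in _VEINS:
        m = _inside_capsule(coords, np.asarray(c.a_frac) * semi,
                            np.asarray(c.b_frac) * semi, c.radius_mm)
        labels[m & brain] = LABEL_CODES[c.name]

    for s in spec.spheres:
        m = _inside_ellipsoid(coords, s.center_mm(spec.brain_semi_axes_mm),
                              (s.radius_mm,) * 3)
        labels[m] = LABEL_CODES[s.name]

    chi = np.zeros(spec.grid.shape)
    for name, code in LABEL_CODES.items():
        sel = labels == code
        if not np.any(sel):
            continue
        sphere = next((s for s in spec.spheres if s.name == name), None)
        chi[sel] = sphere.chi_ppb if sphere else tissue_of_label(name).chi_ppb
    return SusceptibilityVolume(chi, spec.grid), labels


def chi_to_r2star(chi: SusceptibilityVolume, labels: np.ndarray) -> np.ndarray:
    """R2* (1/s) from susceptibility: 20 + 0.125*chi, 40 inside the inserts.

    The linear iron-like relation does not hold for microbleeds, calcium or
    the pineal gland, which are assigned a flat 40/s; the result is clamped
    at zero.
    """
    r2s = 20.0 + 0.125 * chi.values
    inserts = np.isin(labels, SPHERE_CODES)
    r2s[inserts] = 40.0
    return np.clip(r2s, 0.0, None)


def ernst_magnitude(rho0: np.ndarray, t1_ms: np.ndarray, r2star: np.ndarray,
                    params: AcquisitionParams, flip_deg: float,
                    te_s: float) -> np.ndarray:
    """Steady-state spoiled-GRE signal with T2* decay.

    S = rho0 sin(a) (1 - E1) / (1 - cos(a) E1) * exp(-TE R2*),  E1 = e^(-TR/T1)
    """
    if not (0 < flip_deg < 180):
        raise ValueError("flip angle must be in (0, 180) degrees")
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive everywhere")
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-params.tr_s / (t1 * 1e-3))
    steady = np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    return np.asarray(rho0, dtype=float) * steady * np.exp(-te_s * np.asarray(r2star))


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.angle(np.exp(1j * phase))


def tissue_maps(spec: PhantomSpec, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """(rho0, T1[ms]) volumes from the label map.

    The CMB/CaD/PG inserts have zero proton density (they contribute no
    signal); their T1 is set to an arbitrary positive value since it never
    enters with rho0 = 0.  Outside the brain rho0 = 0.
    """
    rho0 = np.zeros(spec.grid.shape)
    t1 = np.full(spec.grid.shape, 1000.0)
    for name, code in LABEL_CODES.items():
        sel = labels == code
        if not np.any(sel):
            continue
        if name in SPHERE_NAMES:
            rho0[sel] = 0.0
            continue
        tp = tissue_of_label(name)
        rho0[sel] = tp.rho0
        t1[sel] = tp.t1_ms
    return rho0, t1


def simulate_stage(spec: PhantomSpec,
                   params: AcquisitionParams | None = None,
                   snr: float = 10.0,
                   seed: int | None = None) -> StageDataset:
    """Forward-simulate the four STAGE echoes from the phantom.

    Per echo: the noiseless phase is the wrapped dipole-convolution phase at
    that TE and the magnitude comes from the Ernst equation; complex Gaussian
    noise with per-channel sigma = (mean noise-free brain magnitude)/snr is
    added to the complex signal and magnitude/phase are recomputed.  The
    structural reference is the noise-free high-flip short-TE magnitude,
    standing in for the T1-weighted-enhanced image.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    params = params or AcquisitionParams()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    grid = VoxelGrid(spec.grid.shape, spec.grid.voxel_size,
                     b0_direction=params.b0_direction)
    chi, labels = build_phantom(replace(spec, grid=grid))
    r2star = chi_to_r2star(chi, labels)
    rho0, t1 = tissue_maps(spec, labels)
    brain = labels > 0

    kernel = make_dipole_kernel(grid)
    field = forward_field(chi, kernel)

    echoes = []
    fa_lo, fa_hi = params.flip_angles_deg
    for fa_idx, fa in enumerate((fa_lo, fa_lo, fa_hi, fa_hi)):
        te = params.echo_times_s[0 if fa == fa_lo else 1][0 if fa_idx % 2 == 0 else 1]
        phase_clean = _wrap(field_to_phase(field, te_s=te, b0_T=params.b0_T))
        mag_clean = ernst_magnitude(rho0, t1, r2star, params, fa, te)
        sigma = float(np.mean(mag_clean[brain & (mag_clean > 0)])) / snr
        signal = mag_clean * np.exp(1j * phase_clean)
        if np.isfinite(snr):
            signal = signal + sigma * (rng.standard_normal(grid.shape)
                                       + 1j * rng.standard_normal(grid.shape))
        echoes.append(EchoImage(np.abs(signal), np.angle(signal), te, fa, grid))

    # dataset order: FA_L TE1, FA_L TE2, FA_H TE1, FA_H TE2
    structural = ernst_magnitude(
        rho0, t1, r2star, params, fa_hi, params.echo_times_s[1][0])
    return StageDataset(echoes=echoes, params=params, grid=grid,
                        brain_mask=brain, structural=structural,
                        chi_truth=chi, labels=labels)
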