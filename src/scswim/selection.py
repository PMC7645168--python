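"""L-curve selection of the regularization weight lambda2.

With the ratio lambda1 = 0.005 lambda2 fixed, a single scalar remains to be
chosen.  The L-curve method runs the solver over a log-spaced grid of
lambda2 values, plots log data-fidelity residual against log regularization
norm, and picks the point of maximum curvature (the "corner" where the
trade-off between fitting the data and regularizing turns).

Curvature is evaluated by three-point finite differences on the log-log
curve after monotone (PCHIP) interpolation onto a dense log-lambda grid;
the returned lambda2 is always an element of the scanned grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import SusceptibilityVolume, FieldMap, DipoleKernel, apply_dipole, gradient
from .constraints import MaskSet
from .solver import ScswimParams, scswim_solve

_CHI_SCALE = 1e-9
_FIELD_SCALE = 1e-6


@dataclass
class LcurveScan:
    """Result table of an L-curve scan (one row per lambda2)."""

    lambda2: np.ndarray
    residual: np.ndarray       # ||W (A chi - dB)||_2, ppm
    reg_norm: np.ndarray       # combined penalty at ratio weighting, see below
    curvature: np.ndarray
    selected: float

    def as_rows(self) -> list[dict]:
        return [
            {"lambda2": float(l), "residual": float(r), "reg_norm": float(g),
             "curvature": float(c), "selected": bool(l == self.selected)}
            for l, r, g, c in zip(self.lambda2, self.residual,
                                  self.reg_norm, self.curvature)
        ]


def default_lambda2_grid(lo: float = 1e-5, hi: float = 1e-1,
                         per_decade: int = 8) -> np.ndarray:
    """Log-spaced lambda2 grid, 8 points per decade over [1e-5, 1e-1]."""
    n = int(np.round(per_decade * np.log10(hi / lo))) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _penalty_norm(chi: SusceptibilityVolume, masks: MaskSet,
                  lambda1_ratio: float) -> float:
    """The lambda2-factored penalty: ratio * ||P G chi||_1 + 1/2 ||R chi||_2^2.

    Multiplying by lambda2 recovers the full regularization value, so this is
    the natural "regularization norm" axis of the L-curve under the fixed
    lambda1/lambda2 ratio.
    """
    x = chi.values * _CHI_SCALE
    grid = chi.grid
    val = 0.5 * float(np.sum((masks.R * x) ** 2))
    for ax in range(3):
        val += lambda1_ratio * float(np.sum(np.abs(masks.P[ax] * gradient(x, grid, ax))))
    return val


def select_corner(lambdas: np.ndarray, residuals: np.ndarray,
                  reg_norms: np.ndarray, n_dense: int = 400
                  ) -> tuple[float, np.ndarray]:
    """Maximum-curvature point of the log-log L-curve.

    Interpolates (log residual, log reg-norm) against log lambda with PCHIP
    (shape-preserving, no overshoot), computes the signed curvature

        kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)

    on the dense grid, and returns (selected lambda, curvature at the input
    grid points).  The selected lambda is the input grid point closest to the
    dense-grid curvature maximum.
    """
    lam = np.asarray(lambdas, dtype=float)
    if len(lam) < 5:
        raise ValueError("need at least 5 lambda values")
    order = np.argsort(lam)
    lam = lam[order]
    rho = np.log(np.asarray(residuals, dtype=float)[order])
    eta = np.log(np.asarray(reg_norms, dtype=float)[order])
    t = np.log(lam)

    fx = PchipInterpolator(t, rho)
    fy = PchipInterpolator(t, eta)
    td = np.linspace(t[0], t[-1], n_dense)
    dt = td[1] - td[0]
    x, y = fx(td), fy(td)
    x1, y1 = np.gradient(x, dt), np.gradient(y, dt)
    x2, y2 = np.gradient(x1, dt), np.gradient(y1, dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (x1 * y2 - y1 * x2) / np.power(x1 ** 2 + y1 ** 2, 1.5)
    kappa[~np.isfinite(kappa)] = -np.inf
    # ignore the 2 edge samples, where one-sided differences are unreliable
    interior = slice(2, -2)
    t_star = td[interior][np.argmax(kappa[interior])]
    selected = lam[np.argmin(np.abs(t - t_star))]

    kappa_grid = np.interp(t, td, np.where(np.isfinite(kappa), kappa, 0.0))
    return float(selected), kappa_grid[np.argsort(np.argsort(lambdas))]


def lcurve_scan(field: FieldMap, kernel: DipoleKernel, masks: MaskSet,
                lambda2_grid: np.ndarray | None = None,
                chi_init: SusceptibilityVolume | None = None,
                params: ScswimParams | None = None) -> LcurveScan:
    """Run the solver across a lambda2 grid and locate the L-curve corner.

    Each lambda2 runs a full (warm-started) solve; the scan records the
    weighted data residual and the ratio-weighted penalty norm.  A
    non-monotone residual over the grid (possible at loose solver
    tolerances) triggers a warning but still returns the curvature argmax.
    """
    params = params or ScswimParams()
    lam_grid = np.asarray(lambda2_grid if lambda2_grid is not None
                          else default_lambda2_grid(), dtype=float)
    if len(lam_grid) < 5:
        raise ValueError("lambda2 grid must have at least 5 points")
    if chi_init is None:
        chi_init = SusceptibilityVolume(np.zeros(field.grid.shape), field.grid)

    residuals, regs = [], []
    chi_warm = chi_init
    for lam2 in np.sort(lam_grid):
        from dataclasses import replace
        chi, _ = scswim_solve(field, kernel, masks,
                              replace(params, lambda2=float(lam2)), chi_warm)
        chi_warm = chi
        x = chi.values * _CHI_SCALE
        resid = masks.W * (apply_dipole(x, kernel) - field.values * _FIELD_SCALE)
        residuals.append(float(np.linalg.norm(resid)))
        regs.append(_penalty_norm(chi, masks, params.lambda1_ratio))

    lam_sorted = np.sort(lam_grid)
    residuals = np.asarray(residuals)
    regs = np.asarray(regs)
    if np.any(np.diff(residuals) < -1e-12 * residuals.max()):
        warnings.warn("data residual is not monotone over the lambda2 grid; "
                      "solver tolerance may be loose", RuntimeWarning)
    selected, kappa = select_corner(lam_sorted, residuals, regs)
    return LcurveScan(lambda2=lam_sorted, residual=residuals, reg_norm=regs,
                      curvature=kappa, selected=selected)
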