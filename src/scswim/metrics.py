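"""Quantitative evaluation of reconstructions.

RMSE and 3D SSIM against a reference map over a mask, per-structure ROI
statistics over full 3D labels, and the CSF-zero-referenced regression of
measured against reference susceptibilities (the accuracy summary: a slope
of 1 with r ~ 1 means the method recovers deep-gray susceptibility without
scale bias).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .grids import SusceptibilityVolume


def _aligned(chi: SusceptibilityVolume, ref: SusceptibilityVolume):
    if chi.grid.shape != ref.grid.shape:
        raise ValueError("volumes must share one grid")
    return chi.values, ref.values


def rmse(chi: SusceptibilityVolume, chi_ref: SusceptibilityVolume,
         mask: np.ndarray) -> float:
    """Root-mean-square difference (ppb) within the mask."""
    a, b = _aligned(chi, chi_ref)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return float(np.sqrt(np.mean((a[m] - b[m]) ** 2)))


def ssim_index(chi: SusceptibilityVolume, chi_ref: SusceptibilityVolume,
               mask: np.ndarray) -> float:
    """Mean local 3D SSIM over the mask.

    Standard stabilizers K1 = 0.01, K2 = 0.03 with a Gaussian window
    (sigma = 1.5); the data range is taken from the reference within the
    mask.  Both volumes are zeroed outside the mask so air does not
    contribute structure.
    """
    a, b = _aligned(chi, chi_ref)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    ref_vals = b[m]
    data_range = float(ref_vals.max() - ref_vals.min())
    if data_range == 0:
        data_range = 1.0
    _, smap = structural_similarity(
        np.where(m, b, 0.0), np.where(m, a, 0.0),
        data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, full=True)
    return float(smap[m].mean())


def roi_stats(chi: SusceptibilityVolume, labels: np.ndarray,
              names: dict[int, str] | None = None) -> pd.DataFrame:
    """Mean / sd / voxel count of chi over each nonzero label's full 3D extent.

    Works identically for atlas labels and manually traced ROIs.  Returns a
    DataFrame indexed by label name (or code when no name table is given).
    """
    lab = chi.grid.check_volume(np.asarray(labels), "labels")
    rows = []
    for code in np.unique(lab):
        if code == 0:
            continue
        sel = lab == code
        vals = chi.values[sel]
        rows.append({
            "label": names.get(int(code), str(int(code))) if names else str(int(code)),
            "code": int(code),
            "mean_ppb": float(vals.mean()),
            "sd_ppb": float(vals.std(ddof=0)),
            "n_voxels": int(sel.sum()),
        })
    if not rows:
        raise ValueError("label volume has no nonzero labels")
    return pd.DataFrame(rows).set_index("label")


def bilateral_means(report: pd.DataFrame) -> pd.Series:
    """Average left/right pairs ("X-L"/"X-R" -> "X"); other labels pass through."""
    grouped: dict[str, list[float]] = {}
    for name, value in report["mean_ppb"].items():
        base = name[:-2] if name.endswith(("-L", "-R")) else name
        grouped.setdefault(base, []).append(float(value))
    return pd.Series({k: float(np.mean(v)) for k, v in grouped.items()})


def reference_regression(report: pd.DataFrame,
                         reference: dict[str, float],
                         csf_label: str = "CSF") -> tuple[float, float, float]:
    """CSF-zero-referenced OLS of measured vs reference ROI means.

    Bilateral structures are averaged, each side's CSF mean is subtracted
    (zero-referencing removes the arbitrary constant of mean-free
    reconstructions), and ordinary least squares of measured on reference is
    fit over the structures present in both.  Returns (slope, intercept, r).
    """
    measured = bilateral_means(report)
    if csf_label not in measured or csf_label not in reference:
        raise ValueError("CSF must be present in both measured and reference")
    common = [k for k in measured.index
              if k in reference and k != csf_label]
    if len(common) < 3:
        raise ValueError("need at least 3 common structures besides CSF")
    x = np.array([reference[k] - reference[csf_label] for k in common])
    y = np.array([measured[k] - measured[csf_label] for k in common])
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
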