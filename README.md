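# scswim

Structurally constrained susceptibility mapping for multi-echo,
multi-flip-angle gradient-echo (STAGE) brain MRI.

## The problem

Tissue magnetic susceptibility chi perturbs the main field B0; the
perturbation appears in the gradient-echo phase as

    phi(r) = gamma * B0 * TE * F^-1{ D(k) F{chi(r)} },
    D(k)   = 1/3 - (k . b_hat)^2 / |k|^2,

so mapping chi (in ppb) means deconvolving the dipole kernel D, which
vanishes on the magic-angle cone — an ill-posed inversion that turns noise
into streak artifacts. Quantitative susceptibility mapping (QSM) matters
clinically because chi tracks iron (deep gray matter, microbleeds),
deoxyhemoglobin (veins) and calcium (diamagnetic deposits).

This package implements a structurally constrained inversion (scSWIM) that
solves

    min_chi 1/2 ||W (F^-1 D F chi - dB)||^2
            + lambda1 ||P G chi||_1 + lambda2/2 ||R chi||^2

where the binary edge masks P (from a high-contrast structural image and an
initial susceptibility estimate) exempt true anatomical edges from gradient
sparsity, and the protection weight R (zero over deep gray matter, veins
and high-|chi| inserts) exempts those structures from amplitude shrinkage.
With lambda1 = 0.005 * lambda2 fixed, lambda2 per echo is chosen by an
L-curve. The four STAGE echoes (flip angles 6/24 deg, two echoes each) are
solved in a chain — each echo initialized from the previous solution — and
fused with R2*-derived weights w_i = TE_i exp(-TE_i R2*).

Also included: the TKD, iSWIM and COSMOS reference inversions, Laplacian +
multi-echo bootstrap phase unwrapping with aliasing-aware reliability
masking, SHARP background-field removal, a fully synthetic multi-echo STAGE
brain phantom (tissue susceptibility/T1/proton-density table, Ernst-equation
magnitudes, microbleed/calcification/pineal sphere inserts, complex noise at
SNR 10), and the evaluation harness (RMSE, 3D SSIM, ROI statistics,
CSF-zero-referenced regression). Audience: MRI methods researchers working
on QSM reconstruction and anyone needing a reproducible, fully synthetic
QSM benchmark.

## Worked example

```python
import numpy as np
from scswim import (PhantomSpec, simulate_stage, ideal_masks,
                    run_stage_pipeline, rmse, LABEL_CODES)

ds = simulate_stage(PhantomSpec.compact(), snr=10.0, seed=1)
masks = ideal_masks(ds.chi_truth.values, ds.structural, ds.labels,
                    ds.grid, ds.brain_mask)
result = run_stage_pipeline(ds, masks=masks)   # ~10 min, one CPU

chi = result.fused
for name in ("GP-L", "WM", "V", "CMB2", "CaD2"):
    sel = ds.labels == LABEL_CODES[name]
    print(f"{name:5s} {chi.values[sel].mean():9.2f} "
          f"+- {chi.values[sel].std():5.2f} ppb")
print("RMSE", round(rmse(chi, ds.chi_truth, ds.brain_mask), 2), "ppb")
```

prints

```
GP-L     177.70 +-  0.08 ppb
WM        -3.22 +-  0.00 ppb
V        447.45 +-  2.43 ppb
CMB2     995.51 +-  1.11 ppb
CaD2   -3002.06 +-  0.09 ppb
RMSE 3.38 ppb
```

The globus pallidus (truth 180 ppb) and the +1000 ppb microbleed and
-3000 ppb calcification inserts are recovered to within a few ppb with
sub-ppb spread — the edge-gated l1 term smooths noise in flat tissue while
the protection mask keeps high-susceptibility structures from being
shrunk. White matter sits ~3 ppb below its true zero because
reconstructions are mean-free (the dipole kernel is zero at DC); the ROI
regression therefore zero-references against CSF.

## Command line

```bash
scswim simulate   --config phantom.yaml --out data/
scswim reconstruct --data data/ --out recon/
scswim invert     --method tkd --field field.nii.gz --out chi.nii.gz
scswim lcurve     --data data/ --echo fah_te1 --out scan.tsv
scswim evaluate   --chi recon/chi_scswim.nii.gz --ref data/chi_gt.nii.gz \
                  --labels data/labels.nii.gz --out report.tsv
scswim demo       --seed 1 --preset compact --out demo/
```

All volumes are NIfTI-1 with a JSON sidecar for acquisition constants; one
YAML schema configures every subcommand and rejects unknown keys.

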