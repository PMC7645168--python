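"""Shared fixtures.

The expensive full-phantom reconstruction is session-scoped and reused by
every accuracy test; everything else builds tiny volumes on the fly.
"""

from __future__ import annotations

import numpy as np
import pytest

from scswim import (VoxelGrid, make_dipole_kernel, PhantomSpec,
                    simulate_stage, ideal_masks, run_stage_pipeline,
                    tkd_inversion, fuse_echoes, stage_fields, stage_r2star)


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid((16, 12, 10), (1.0, 1.3, 2.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def compact_dataset():
    """SNR-10 simulated STAGE acquisition of the compact phantom."""
    return simulate_stage(PhantomSpec.compact(), snr=10.0, seed=0)


@pytest.fixture(scope="session")
def compact_run(compact_dataset):
    """Full multi-echo scSWIM reconstruction with ideal P/R masks.

    This is the package's desk-scale evaluation condition: compact
    128 x 128 x 80 phantom, SNR 10, published per-echo lambda2 preset.
    """
    ds = compact_dataset
    masks = ideal_masks(ds.chi_truth.values, ds.structural, ds.labels,
                        ds.grid, ds.brain_mask)
    return ds, run_stage_pipeline(ds, masks=masks)


@pytest.fixture(scope="session")
def compact_tkd_fused(compact_dataset):
    """R2*-weighted fusion of per-echo TKD maps on the same dataset."""
    ds = compact_dataset
    fields, _ = stage_fields(ds)
    kernel = make_dipole_kernel(ds.grid)
    chis = []
    for name in ds.ECHO_NAMES:
        chi = tkd_inversion(fields[name], kernel)
        chi.values *= ds.brain_mask
        chis.append(chi)
    tes = [ds.echo(n).te_s for n in ds.ECHO_NAMES]
    return fuse_echoes(chis, tes, stage_r2star(ds))
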