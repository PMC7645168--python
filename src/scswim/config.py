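"""Shared YAML configuration schema for the command-line tools.

One schema serves every subcommand; unknown keys anywhere in the tree are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .acquisition import AcquisitionParams
from .grids import VoxelGrid
from .phantom import PhantomSpec
from .solver import ScswimParams, SIMULATED_LAMBDA2, IN_VIVO_LAMBDA2

_SCHEMA: dict[str, set[str]] = {
    "phantom": {"preset", "shape", "voxel_size_mm", "brain_semi_axes_mm",
                "wm_scale", "snr", "seed"},
    "acquisition": {"b0_T", "tr_s", "flip_angles_deg", "echo_times_s",
                    "b0_direction"},
    "solver": {"lambda2_per_echo", "lambda2_preset", "lambda1_ratio",
               "outer_max_iter", "outer_tol", "cg_max_iter", "cg_tol",
               "irls_epsilon"},
    "masks": {"source", "chi_clip_threshold_ppb", "noise_mult", "binary_r"},
    "preprocess": {"sharp_kernel_radius_vox", "sharp_tsvd_threshold",
                   "unwrap_method", "apply_sharp"},
}


class ConfigError(ValueError):
    """Unknown or malformed configuration content."""


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML config; None or a missing file means all defaults."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section: {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ConfigError(
                f"unknown keys in section {section!r}: {sorted(unknown)}")
    return raw


def phantom_spec_from_config(cfg: dict) -> tuple[PhantomSpec, float, int]:
    """Build (PhantomSpec, snr, seed) from the ``phantom`` section."""
    p = dict(cfg.get("phantom") or {})
    preset = p.pop("preset", "default")
    snr = float(p.pop("snr", 10.0))
    seed = int(p.pop("seed", 0))
    kwargs = {}
    if "shape" in p or "voxel_size_mm" in p:
        shape = tuple(p.pop("shape", (160, 160, 96)))
        voxel = tuple(p.pop("voxel_size_mm", (1.0, 1.0, 1.5)))
        kwargs["grid"] = VoxelGrid(shape, voxel)
    if "brain_semi_axes_mm" in p:
        kwargs["brain_semi_axes_mm"] = tuple(p.pop("brain_semi_axes_mm"))
    if "wm_scale" in p:
        kwargs["wm_scale"] = float(p.pop("wm_scale"))
    factory = {"default": PhantomSpec.default, "compact": PhantomSpec.compact,
               "tiny": PhantomSpec.tiny}.get(preset)
    if factory is None:
        raise ConfigError(f"unknown phantom preset: {preset!r}")
    return factory(seed=seed, **kwargs), snr, seed


def acquisition_from_config(cfg: dict) -> AcquisitionParams:
    a = dict(cfg.get("acquisition") or {})
    if "flip_angles_deg" in a:
        a["flip_angles_deg"] = tuple(a["flip_angles_deg"])
    if "echo_times_s" in a:
        a["echo_times_s"] = tuple(tuple(t) for t in a["echo_times_s"])
    if "b0_direction" in a:
        a["b0_direction"] = tuple(a["b0_direction"])
    return AcquisitionParams(**a)


def solver_from_config(cfg: dict) -> tuple[ScswimParams, tuple[float, ...]]:
    """Build (ScswimParams, per-echo lambda2 tuple) from the ``solver`` section."""
    s = dict(cfg.get("solver") or {})
    preset = s.pop("lambda2_preset", "simulated")
    lam2 = s.pop("lambda2_per_echo", None)
    if lam2 is None:
        lam2 = {"simulated": SIMULATED_LAMBDA2,
                "in_vivo": IN_VIVO_LAMBDA2}.get(preset)
        if lam2 is None:
            raise ConfigError(f"unknown lambda2 preset: {preset!r}")
    lam2 = tuple(float(v) for v in lam2)
    params = ScswimParams(lambda2=lam2[0], **s)
    return params, lam2
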