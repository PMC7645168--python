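"""Acquisition parameters and in-memory containers for multi-echo GRE data.

The STAGE protocol acquires two double-echo gradient-echo scans at a low and
a high flip angle relative to the white-matter Ernst angle.  Each scan yields
a magnitude and a wrapped phase volume per echo, so a full dataset is four
:class:`EchoImage` objects sharing one grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .grids import VoxelGrid, SusceptibilityVolume


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner and sequence constants shared by simulation and reconstruction.

    Defaults are the STAGE protocol used throughout this package:
    FA 6/24 deg, TE1 = 7.5/8.75 ms and TE2 = 17.5/18.75 ms (low/high flip
    angle scans have slightly different echo times), TR 25 ms at 3 T.
    """

    b0_T: float = 3.0
    tr_s: float = 0.025
    flip_angles_deg: tuple[float, float] = (6.0, 24.0)
    #: echo times in seconds, indexed [flip_angle][echo]
    echo_times_s: tuple[tuple[float, float], tuple[float, float]] = (
        (7.5e-3, 17.5e-3),
        (8.75e-3, 18.75e-3),
    )
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.b0_T <= 0 or self.tr_s <= 0:
            raise ValueError("b0_T and tr_s must be positive")
        for tes in self.echo_times_s:
            if any(te <= 0 for te in tes):
                raise ValueError("echo times must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionParams":
        raw = json.loads(text)
        required = {"b0_T", "tr_s", "flip_angles_deg", "echo_times_s"}
        missing = required - raw.keys()
        if missing:
            raise KeyError(f"acquisition sidecar missing keys: {sorted(missing)}")
        raw["flip_angles_deg"] = tuple(raw["flip_angles_deg"])
        raw["echo_times_s"] = tuple(tuple(t) for t in raw["echo_times_s"])
        raw["b0_direction"] = tuple(raw.get("b0_direction", (0.0, 0.0, 1.0)))
        return cls(**raw)


@dataclass
class EchoImage:
    """One echo's magnitude (arbitrary units >= 0) and wrapped phase (rad)."""

    magnitude: np.ndarray
    phase: np.ndarray
    te_s: float
    flip_angle_deg: float
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.magnitude = self.grid.check_volume(
            np.asarray(self.magnitude, dtype=float), "magnitude")
        self.phase = self.grid.check_volume(
            np.asarray(self.phase, dtype=float), "phase")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.te_s <= 0:
            raise ValueError("te_s must be positive")


@dataclass
class StageDataset:
    """A full simulated (or loaded) STAGE acquisition on one grid.

    ``echoes`` is ordered (FA_L TE1, FA_L TE2, FA_H TE1, FA_H TE2).  Ground
    truth (chi, labels) is present for simulated data and ``None`` otherwise.
    """

    echoes: list[EchoImage]
    params: AcquisitionParams
    grid: VoxelGrid
    brain_mask: np.ndarray
    structural: np.ndarray
    chi_truth: SusceptibilityVolume | None = None
    labels: np.ndarray | None = None

    ECHO_NAMES = ("fal_te1", "fal_te2", "fah_te1", "fah_te2")

    def __post_init__(self) -> None:
        if len(self.echoes) != 4:
            raise ValueError("a STAGE dataset has exactly 4 echoes")
        for e in self.echoes:
            if e.grid.shape != self.grid.shape:
                raise ValueError("all echoes must share the dataset grid")
        self.brain_mask = self.grid.check_volume(
            np.asarray(self.brain_mask, dtype=bool), "brain mask")
        self.structural = self.grid.check_volume(
            np.asarray(self.structural, dtype=float), "structural")

    def echo(self, name: str) -> EchoImage:
        return self.echoes[self.ECHO_NAMES.index(name)]

    @property
    def chain_order(self) -> list[int]:
        """Echo indices in the reconstruction chain order.

        The solver chain runs short echoes before long ones:
        FA_L TE1 -> FA_H TE1 -> FA_L TE2 -> FA_H TE2.
        """
        return [self.ECHO_NAMES.index(n)
                for n in ("fal_te1", "fah_te1", "fal_te2", "fah_te2")]
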