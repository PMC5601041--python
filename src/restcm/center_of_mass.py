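"""Positive center of mass of scalp topographies, its trajectory and speed.

The positive CM of a topography is the average of the electrode coordinates
weighted by the strictly positive channel voltages — a single point
summarizing where positive potential sits on the scalp.  Tracking it sample
by sample gives a trajectory; scaling the normalized head to a physical
radius (10 cm by default) turns frame-to-frame displacements into a traveling
speed in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ElectrodeMontage
from .referencing import ScalpRecording
from .transforms import PositiveCM

__all__ = [
    "CMTrajectory",
    "VelocityCurve",
    "positive_cm",
    "cm_trajectory",
    "traveling_velocity",
    "cm_error",
    "UndefinedCMError",
]


class UndefinedCMError(ValueError):
    """Raised when a CM error is requested against a zero-norm standard CM."""


@dataclass(frozen=True)
class CMTrajectory:
    times: np.ndarray          # (n,), seconds
    coords: np.ndarray         # (n, dim), normalized head units
    defined_mask: np.ndarray   # (n,), False where no channel was positive

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = ["X", "Y", "Z"][: self.dim]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "time", self.times)
        df["defined"] = self.defined_mask
        return df


@dataclass(frozen=True)
class VelocityCurve:
    times: np.ndarray        # (n-1,), time of the later sample of each step
    speed: np.ndarray        # m/s; NaN across undefined CMs
    scale_radius: float
    dt: float

    def __len__(self) -> int:
        return len(self.times)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.speed)


def positive_cm(values, montage: ElectrodeMontage, dim: int = 3):
    """CM of one topography; returns None when no channel is positive."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError("voltage count must equal montage size")
    cm = PositiveCM(coords=montage.positions, dim=dim).fit().transform(values[None, :])[0]
    return None if np.any(np.isnan(cm)) else cm


def cm_trajectory(
    rec: ScalpRecording,
    montage: ElectrodeMontage,
    window: tuple[float, float] | None = None,
    dim: int = 2,
) -> CMTrajectory:
    """One CM per sample over the half-open time window [start, end).

    The recording is restricted to the montage channels (EOG and mastoids are
    expected to have been excluded from the montage already).
    """
    sub = rec.pick(montage.labels)
    times = sub.times
    if window is not None:
        lo, hi = window
        keep = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if not np.any(keep):
            raise ValueError("window does not overlap the recording")
    else:
        keep = np.ones(len(times), dtype=bool)
    X = sub.data.T[keep]
    cm = PositiveCM(coords=montage.positions, dim=dim).fit().transform(X)
    defined = ~np.any(np.isnan(cm), axis=1)
    return CMTrajectory(times=times[keep], coords=cm, defined_mask=defined)


def traveling_velocity(traj: CMTrajectory, scale_radius: float = 0.10) -> VelocityCurve:
    """Speed of the CM between consecutive samples, in m/s.

    speed(t) = scale_radius * ||CM(t) - CM(t-1)|| / dt; steps touching an
    undefined CM are NaN.
    """
    if len(traj) < 2:
        raise ValueError("trajectory must have at least 2 samples")
    dt = float(np.median(np.diff(traj.times)))
    if dt <= 0:
        raise ValueError("non-positive sample interval")
    step = np.linalg.norm(np.diff(traj.coords, axis=0), axis=1)
    speed = scale_radius * step / dt
    bad = ~(traj.defined_mask[1:] & traj.defined_mask[:-1])
    speed[bad] = np.nan
    return VelocityCurve(times=traj.times[1:], speed=speed,
                         scale_radius=scale_radius, dt=dt)


def cm_error(cm_ref, cm_ir) -> float:
    """Relative CM error ||CM_ref - CM_ir|| / ||CM_ir||."""
    cm_ref = np.asarray(cm_ref, dtype=float)
    cm_ir = np.asarray(cm_ir, dtype=float)
    if cm_ref.shape != cm_ir.shape:
        raise ValueError("CM dimensionality mismatch")
    denom = np.linalg.norm(cm_ir)
    if denom == 0:
        raise UndefinedCMError("standard CM has zero norm; error undefined")
    return float(np.linalg.norm(cm_ref - cm_ir) / denom)
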