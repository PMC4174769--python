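"""Pen-trajectory data model, CSV interchange, and completeness screening.

A drawing is an ordered sequence of timestamped pen positions captured by a
digitizing tablet, nominally at 60 Hz.  Coordinates are centimetres in the
template frame (origin at the spiral center).  The reader drops rows with
non-finite values and logs what it dropped; irregular sampling is flagged,
not rejected, because the downstream measures are defined on whatever
samples exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyTrajectoryError, TrajectoryFormatError
from .template import SpiralTemplate

__all__ = [
    "PenTrajectory",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "screen_completeness",
]

logger = logging.getLogger(__name__)

_COLUMNS = ("t_s", "x_cm", "y_cm")


@dataclass
class PenTrajectory:
    """Timestamped 2-D pen samples for one drawing.

    ``t`` is seconds since drawing start and must be strictly increasing;
    ``x`` and ``y`` are centimetres in the template frame.  A median
    inter-sample interval more than 20% away from ``1/nominal_rate`` marks
    the trajectory as irregularly sampled (``sampling_regular`` False) but
    does not invalidate it.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float = 60.0
    subject_id: str = ""
    sampling_regular: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise TrajectoryFormatError("t, x, y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise EmptyTrajectoryError(
                f"trajectory needs >= 2 samples, got {self.t.size}"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)) or not np.all(
            np.isfinite(self.y)
        ):
            raise TrajectoryFormatError("non-finite values in trajectory arrays")
        if np.any(self.t < 0.0):
            raise TrajectoryFormatError("timestamps must be non-negative")
        dt = np.diff(self.t)
        if np.any(dt <= 0.0):
            raise TrajectoryFormatError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0.0:
            raise TrajectoryFormatError("nominal_rate must be positive")
        expected = 1.0 / self.nominal_rate
        med = float(np.median(dt))
        self.sampling_regular = abs(med - expected) <= 0.2 * expected
        if not self.sampling_regular:
            logger.warning(
                "trajectory %s: median interval %.4fs deviates >20%% from nominal %.4fs",
                self.subject_id or "<unnamed>",
                med,
                expected,
            )
        n_gaps = int(np.sum(dt > 3.0 * expected))
        if n_gaps:
            logger.warning(
                "trajectory %s: %d inter-sample gaps exceed 3 nominal intervals "
                "(possible pen lift); samples used as-is",
                self.subject_id or "<unnamed>",
                n_gaps,
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y})


def read_trajectory_csv(path, nominal_rate: float = 60.0, subject_id: str = "") -> PenTrajectory:
    """Parse a trajectory CSV with mandatory header ``t_s,x_cm,y_cm``.

    Rows containing NaN or infinite values are dropped (count logged).
    Raises ``TrajectoryFormatError`` on missing columns and
    ``EmptyTrajectoryError`` if fewer than two valid rows remain.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required columns {missing}")
    df = df.loc[:, list(_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(df.to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values", path, n_dropped)
    df = df.loc[ok]
    if len(df) < 2:
        raise EmptyTrajectoryError(f"{path}: fewer than 2 valid samples")
    return PenTrajectory(
        t=df["t_s"].to_numpy(),
        x=df["x_cm"].to_numpy(),
        y=df["y_cm"].to_numpy(),
        nominal_rate=nominal_rate,
        subject_id=subject_id,
    )


def write_trajectory_csv(traj: PenTrajectory, path) -> None:
    """Write a trajectory as CSV at full float precision (round-trippable)."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def screen_completeness(
    traj: PenTrajectory, template: SpiralTemplate, threshold: float = 0.95
) -> str:
    """Classify a drawing as ``"complete"`` or ``"incomplete"``.

    A drawing counts as complete when its final unwrapped angle reaches at
    least ``threshold`` (default 95%) of the template's angular extent.
    Trajectories that cannot be unwrapped (degenerate, badly aligned) are
    incomplete by definition.
    """
    from .kinematics import unwrap_polar  # local import to avoid cycle

    try:
        polar = unwrap_polar(traj, template)
    except Exception as exc:  # degenerate or misaligned traces
        logger.info(
            "trajectory %s marked incomplete: %s", traj.subject_id or "<unnamed>", exc
        )
        return "incomplete"
    if polar.theta.size == 0:
        return "incomplete"
    return "complete" if polar.theta[-1] >= threshold * template.theta_max else "incomplete"
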