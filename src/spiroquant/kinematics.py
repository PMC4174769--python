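"""Quantitative spiral-drawing measures.

Six measures summarise one traced spiral against its Archimedean template:

* **length of drawing** (cm) — summed Euclidean inter-sample distances;
* **movement time** (s) — time from first to last sample;
* **average speed** (cm/s) — length / movement time;
* **speed variability** (cm/s) — sample SD of the instantaneous speed
  (per-interval distance over per-interval time, no smoothing);
* **deviation from template** (cm^2) — unsigned polar area enclosed
  between the drawn trace and the template curve;
* **crossings** — number of times the trace passes from inside the
  template curve to outside or vice versa.

Correspondence between trace and template is by angle: the trace is
unwrapped to a continuous angle series and compared with the template
radius at the same angle.  Samples closer than ``r_min`` to the center are
excluded from the polar trace because the angle is ill-defined there.

A rule-based surrogate of the clinical spiral score (ICARS item, 0 split
into 0A/0B) maps deviation area and crossings to {0A, 0B, 1, 2}.  It is a
deterministic stand-in for human visual rating, monotone in both inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, IncompleteDrawingError
from .template import SpiralTemplate
from .trajectory import PenTrajectory, screen_completeness

__all__ = [
    "PolarTrace",
    "DrawingMeasures",
    "unwrap_polar",
    "drawing_length",
    "movement_time",
    "average_speed",
    "speed_variability",
    "deviation_area",
    "count_crossings",
    "surrogate_clinical_score",
    "quantify",
    "quantify_cohort",
    "measures_to_frame",
]

logger = logging.getLogger(__name__)

R_MIN_DEFAULT = 0.2  # cm; atan2 is unstable nearer the center
DEADBAND_DEFAULT = 0.02  # cm; hysteresis band for the crossing counter
CLINICAL_SCORES = ("0A", "0B", "1", "2")


@dataclass
class PolarTrace:
    """Trajectory unwrapped against the template.

    ``theta``: continuous unwrapped angle per retained sample (radians);
    ``delta_r``: drawn radius minus template radius at the same angle (cm);
    ``r``: drawn radius (cm); ``t``: seconds per retained sample.
    """

    theta: np.ndarray
    delta_r: np.ndarray
    r: np.ndarray
    t: np.ndarray


def unwrap_polar(
    traj: PenTrajectory,
    template: SpiralTemplate,
    r_min: float = R_MIN_DEFAULT,
) -> PolarTrace:
    """Unwrap a trajectory to a continuous angle + radial-deviation series.

    The drawing must start near the template center (within 2 cm; the
    protocol asks the pen to be placed in the middle).  Angles follow the
    template handedness, so theta increases along a correctly-traced
    spiral regardless of drawing direction convention.
    """
    r_all = np.hypot(traj.x, traj.y)
    if r_all[0] > 2.0:
        raise AlignmentError(
            f"trajectory starts {r_all[0]:.2f} cm from the template center (limit 2 cm)"
        )
    if r_all[0] > 0.5:
        logger.warning(
            "trajectory %s starts %.2f cm from center (protocol expects < 0.5 cm)",
            traj.subject_id or "<unnamed>",
            r_all[0],
        )
    keep = r_all >= r_min
    if int(keep.sum()) < 2:
        raise AlignmentError("fewer than 2 samples outside the near-center exclusion zone")
    sign = 1.0 if template.handedness == "counterclockwise" else -1.0
    raw = np.arctan2(sign * traj.y[keep], traj.x[keep])
    theta = np.unwrap(raw)
    # Fix the 2*pi branch: the first retained sample sits at radius ~r_min,
    # so its true angle is close to r/b for an on-template trace.
    r = r_all[keep]
    k = np.round((r[0] / template.pitch_b - theta[0]) / (2.0 * np.pi))
    theta = theta + 2.0 * np.pi * k
    delta_r = r - template.pitch_b * theta
    return PolarTrace(theta=theta, delta_r=delta_r, r=r, t=traj.t[keep])


def drawing_length(traj: PenTrajectory) -> float:
    """Length of the drawn curve: sum of inter-sample Euclidean distances (cm)."""
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


def movement_time(traj: PenTrajectory) -> float:
    """Time taken to trace the spiral: last minus first timestamp (s)."""
    return traj.duration


def average_speed(length_cm: float, movement_time_s: float) -> float:
    """Average drawing speed: length over time (cm/s)."""
    if movement_time_s <= 0.0:
        raise DegenerateInputError("movement time must be positive")
    return length_cm / movement_time_s


def speed_variability(traj: PenTrajectory) -> float:
    """Sample SD (n-1 denominator) of the instantaneous speed series (cm/s).

    Instantaneous speed is the per-interval distance divided by the
    per-interval time; no smoothing is applied.
    """
    if len(traj) < 3:
        raise DegenerateInputError("speed variability needs >= 3 samples")
    ds = np.hypot(np.diff(traj.x), np.diff(traj.y))
    dt = np.diff(traj.t)
    return float(np.std(ds / dt, ddof=1))


def deviation_area(polar: PolarTrace, template: SpiralTemplate) -> float:
    """Unsigned polar area between the drawn trace and the template (cm^2).

    Integrates 0.5 * |r_drawn^2 - r_template^2| over the unwrapped angle by
    the trapezoid rule, splitting each interval at sign changes of the
    radial deviation (linear interpolation of the crossing angle) so that
    regions inside and outside the template never cancel.  Angle increments
    enter as |dtheta|, so locally retraced sections still contribute
    positive area.
    """
    th, dr, r = polar.theta, polar.delta_r, polar.r
    if th.size < 2:
        raise DegenerateInputError("polar trace must span a positive angular extent")
    r_t = template.pitch_b * th
    g = 0.5 * (r * r - r_t * r_t)  # signed integrand; sign(g) == sign(delta_r)
    g0, g1 = g[:-1], g[1:]
    d0, d1 = dr[:-1], dr[1:]
    dth = np.abs(np.diff(th))
    crossing = (d0 * d1) < 0.0
    frac = np.where(crossing, d0 / np.where(crossing, d0 - d1, 1.0), 0.5)
    plain = 0.5 * (np.abs(g0) + np.abs(g1)) * dth
    # split segment: two triangles with a zero at the interpolated crossing
    split = 0.5 * (np.abs(g0) * frac + np.abs(g1) * (1.0 - frac)) * dth
    return float(np.sum(np.where(crossing, split, plain)))


def count_crossings(polar: PolarTrace, deadband: float = DEADBAND_DEFAULT) -> int:
    """Count template crossings with a hysteresis deadband.

    A crossing is registered only when the radial deviation, having last
    been beyond one edge of the band [-deadband, +deadband], reaches beyond
    the opposite edge; excursions that stay inside the band (sensor jitter)
    are ignored.  With ``deadband=0`` this reduces to a plain signed
    zero-crossing count.
    """
    if deadband < 0.0:
        raise DegenerateInputError("deadband must be >= 0")
    dr = polar.delta_r
    if deadband == 0.0:
        side = np.sign(dr)
        side = side[side != 0.0]
    else:
        out = np.abs(dr) >= deadband
        side = np.sign(dr[out])
    if side.size < 2:
        return 0
    return int(np.sum(side[1:] != side[:-1]))


def surrogate_clinical_score(deviation_area_cm2: float, crossings: int) -> str:
    """Rule-based surrogate of the visual clinical spiral score.

    Thresholds (invented, fixed): 0A for deviation < 4 cm^2 with at most 2
    crossings; 0B for deviation < 8 cm^2 with at most 6 crossings; 1 for
    deviation < 16 cm^2; otherwise 2.  Monotone non-decreasing in both
    deviation area and crossings.
    """
    if deviation_area_cm2 < 4.0 and crossings <= 2:
        return "0A"
    if deviation_area_cm2 < 8.0 and crossings <= 6:
        return "0B"
    if deviation_area_cm2 < 16.0:
        return "1"
    return "2"


@dataclass
class DrawingMeasures:
    """The six quantitative outcomes plus surrogate clinical score."""

    length_cm: float
    movement_time_s: float
    avg_speed: float
    speed_variability: float
    deviation_area: float
    crossings: int
    clinical_score: str

    def __post_init__(self) -> None:
        for name in (
            "length_cm",
            "movement_time_s",
            "avg_speed",
            "speed_variability",
            "deviation_area",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise DegenerateInputError(f"{name} must be finite and >= 0, got {v}")
        if self.crossings < 0 or int(self.crossings) != self.crossings:
            raise DegenerateInputError("crossings must be a non-negative integer")
        if self.clinical_score not in CLINICAL_SCORES:
            raise DegenerateInputError(f"unknown clinical score {self.clinical_score!r}")


def quantify(
    traj: PenTrajectory,
    template: SpiralTemplate,
    *,
    deadband: float = DEADBAND_DEFAULT,
    r_min: float = R_MIN_DEFAULT,
    completeness_threshold: float = 0.95,
) -> DrawingMeasures:
    """Compute all measures for one drawing.

    Refuses incomplete drawings (final unwrapped angle short of 95% of the
    template extent), mirroring the screening step that removes them before
    quantitative analysis.  ``avg_speed * movement_time == length`` holds
    exactly by construction.
    """
    if screen_completeness(traj, template, threshold=completeness_threshold) != "complete":
        raise IncompleteDrawingError(
            f"drawing {traj.subject_id or '<unnamed>'} does not cover "
            f">= {completeness_threshold:.0%} of the template"
        )
    polar = unwrap_polar(traj, template, r_min=r_min)
    length = drawing_length(traj)
    mt = movement_time(traj)
    area = deviation_area(polar, template)
    ncross = count_crossings(polar, deadband=deadband)
    return DrawingMeasures(
        length_cm=length,
        movement_time_s=mt,
        avg_speed=average_speed(length, mt),
        speed_variability=speed_variability(traj),
        deviation_area=area,
        crossings=ncross,
        clinical_score=surrogate_clinical_score(area, ncross),
    )


def quantify_cohort(
    trajectories: dict[str, PenTrajectory],
    template: SpiralTemplate,
    **kwargs,
) -> pd.DataFrame:
    """Quantify a set of drawings into a tidy measures table.

    Returns one row per drawing with columns subject_id, length_cm,
    movement_time_s, avg_speed, speed_variability, deviation_area,
    crossings, clinical_score.  Drawings that fail quantification are
    skipped with a logged reason.
    """
    rows = []
    for sid, traj in trajectories.items():
        try:
            m = quantify(traj, template, **kwargs)
        except Exception as exc:
            logger.warning("drawing %s not quantified: %s", sid, exc)
            continue
        rows.append({"subject_id": sid, **m.__dict__})
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "length_cm",
            "movement_time_s",
            "avg_speed",
            "speed_variability",
            "deviation_area",
            "crossings",
            "clinical_score",
        ],
    )


def measures_to_frame(measures: dict[str, DrawingMeasures]) -> pd.DataFrame:
    """Convert a mapping subject_id -> DrawingMeasures to a tidy table."""
    rows = [{"subject_id": sid, **m.__dict__} for sid, m in measures.items()]
    return pd.DataFrame(rows)
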