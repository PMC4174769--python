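"""Archimedes spiral template geometry.

The tracing target is an Archimedean spiral, r(theta) = b * theta, drawn
outward from the center over a fixed number of turns.  The template used for
the motor test is characterised entirely by its pitch ``b`` (radial growth
per radian, cm/rad) and angular extent ``theta_max``; the printed constraint
on the physical template is its total curve length (about 56 cm), so the
pitch is solved from a requested arc length.

Arc length of ``r = b*theta`` from 0 to ``theta`` has the closed form

    L(theta) = (b / 2) * [ theta * sqrt(1 + theta^2) + asinh(theta) ]

which is linear in ``b``; inverting for ``b`` at fixed ``theta_max`` is
therefore exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, InvalidParameterError

__all__ = [
    "SpiralTemplate",
    "build_template",
    "template_radius",
    "arc_length",
    "render_polyline",
    "polyline_length",
    "save_template",
    "load_template",
]

_HANDEDNESS = ("counterclockwise", "clockwise")


def _unit_arc_length(theta: np.ndarray | float) -> np.ndarray | float:
    """Arc length of the unit-pitch spiral r = theta, from 0 to theta."""
    th = np.asarray(theta, dtype=float)
    return 0.5 * (th * np.sqrt(1.0 + th * th) + np.arcsinh(th))


@dataclass(frozen=True)
class SpiralTemplate:
    """Parametric Archimedes spiral r(theta) = pitch_b * theta.

    Parameters
    ----------
    pitch_b
        Radial growth rate in cm per radian; must be positive.
    theta_max
        Total angular extent in radians; must be positive.
    handedness
        ``"counterclockwise"`` (angle increases counterclockwise from +x)
        or ``"clockwise"``.
    n_points
        Default polyline sampling resolution.
    """

    pitch_b: float
    theta_max: float
    handedness: str = "counterclockwise"
    n_points: int = 2000

    def __post_init__(self) -> None:
        if not (self.pitch_b > 0.0) or not np.isfinite(self.pitch_b):
            raise InvalidParameterError(f"pitch_b must be > 0, got {self.pitch_b}")
        if not (self.theta_max > 0.0) or not np.isfinite(self.theta_max):
            raise InvalidParameterError(f"theta_max must be > 0, got {self.theta_max}")
        if self.n_points < 2:
            raise InvalidParameterError(f"n_points must be >= 2, got {self.n_points}")
        if self.handedness not in _HANDEDNESS:
            raise InvalidParameterError(
                f"handedness must be one of {_HANDEDNESS}, got {self.handedness!r}"
            )

    @property
    def outer_radius(self) -> float:
        """Radius at the end of the spiral, cm."""
        return self.pitch_b * self.theta_max

    @property
    def total_arc_length(self) -> float:
        """Analytic length of the full template curve, cm."""
        return arc_length(self, self.theta_max)

    def radius(self, theta):
        return template_radius(self, theta)


def build_template(
    n_turns: int,
    target_length: float,
    *,
    handedness: str = "counterclockwise",
    n_points: int = 2000,
) -> SpiralTemplate:
    """Construct a spiral template with a prescribed total curve length.

    The angular extent is fixed at ``2*pi*n_turns`` and the pitch is solved
    in closed form (arc length is linear in the pitch) so that the analytic
    arc length equals ``target_length`` exactly to floating-point precision.
    """
    if n_turns < 1:
        raise InvalidParameterError(f"n_turns must be >= 1, got {n_turns}")
    if not (target_length > 0.0):
        raise InvalidParameterError(f"target_length must be > 0, got {target_length}")
    theta_max = 2.0 * np.pi * n_turns
    pitch_b = target_length / float(_unit_arc_length(theta_max))
    return SpiralTemplate(
        pitch_b=pitch_b, theta_max=theta_max, handedness=handedness, n_points=n_points
    )


def _check_theta(template: SpiralTemplate, theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0.0) or np.any(th > template.theta_max * (1.0 + 1e-12)):
        raise DomainError(
            f"theta must lie in [0, {template.theta_max}], got range "
            f"[{th.min()}, {th.max()}]"
        )
    return th


def template_radius(template: SpiralTemplate, theta):
    """Template radius r = b * theta at the given angle(s), cm."""
    th = _check_theta(template, theta)
    return template.pitch_b * th


def arc_length(template: SpiralTemplate, theta):
    """Analytic arc length of the template from its center to angle theta."""
    th = _check_theta(template, theta)
    return template.pitch_b * _unit_arc_length(th)


def render_polyline(template: SpiralTemplate, n_points: int | None = None) -> np.ndarray:
    """Sample the template at uniform angular spacing.

    Returns an (n_points, 2) array of (x, y) in cm, starting at the origin.
    Clockwise templates are rendered with decreasing polar angle.
    """
    n = template.n_points if n_points is None else int(n_points)
    if n < 2:
        raise InvalidParameterError(f"n_points must be >= 2, got {n}")
    theta = np.linspace(0.0, template.theta_max, n)
    r = template.pitch_b * theta
    sign = 1.0 if template.handedness == "counterclockwise" else -1.0
    return np.column_stack([r * np.cos(theta), sign * r * np.sin(theta)])


def polyline_length(points: np.ndarray) -> float:
    """Total length of an ordered polyline given as an (n, 2) array."""
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))


def save_template(template: SpiralTemplate, csv_path, json_path=None) -> None:
    """Export the template as a polyline CSV plus a JSON parameter sidecar.

    The CSV has columns ``theta_rad,x_cm,y_cm``; the sidecar records the
    parametric description so the template can be reconstructed exactly.
    """
    csv_path = Path(csv_path)
    pts = render_polyline(template)
    theta = np.linspace(0.0, template.theta_max, template.n_points)
    arr = np.column_stack([theta, pts])
    header = "theta_rad,x_cm,y_cm"
    np.savetxt(csv_path, arr, delimiter=",", header=header, comments="", fmt="%.12g")
    sidecar = Path(json_path) if json_path is not None else csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pitch_b": template.pitch_b,
                "theta_max": template.theta_max,
                "handedness": template.handedness,
                "n_points": template.n_points,
            },
            indent=2,
        )
        + "\n"
    )


def load_template(json_path) -> SpiralTemplate:
    """Reconstruct a template from its JSON sidecar."""
    params = json.loads(Path(json_path).read_text())
    return SpiralTemplate(
        pitch_b=params["pitch_b"],
        theta_max=params["theta_max"],
        handedness=params.get("handedness", "counterclockwise"),
        n_points=params.get("n_points", 2000),
    )
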