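import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spiroquant import GeneratorConfig, build_template, generate_cohort, quantify_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the generator logs every off-center start; keep test output readable
logging.getLogger("spiroquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def template():
    """The standard 4-turn, 56 cm Archimedes template."""
    return build_template(n_turns=4, target_length=56.0)


@pytest.fixture(scope="session")
def full_cohort(template):
    """Default-configuration synthetic cohort at the full study size.

    Generated once per session (seed fixed) and shared by the calibration
    and trend tests; returns (covariate table merged with measures).
    """
    config = GeneratorConfig(seed=1888)
    cohort, trajectories = generate_cohort(config, template)
    measures = quantify_cohort(trajectories, template)
    return measures.merge(cohort, on="subject_id")


def polar_area_polygon_oracle(theta, r_drawn, pitch_b):
    """Independent shoelace oracle for the between-curves polar area.

    Splits the trace at sign changes of the radial deviation, closes each
    segment into a polygon (out along the drawn curve, back along the
    template curve; the radial connecting edges contribute nothing to the
    polar area), and sums absolute shoelace areas.
    """

    def shoelace(x, y):
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    delta = r_drawn - pitch_b * theta
    sign_change = np.nonzero(delta[:-1] * delta[1:] < 0)[0]
    # insert interpolated crossing points so polygons close on the template
    th = list(theta)
    rd = list(r_drawn)
    cut_points = []
    for offset, i in enumerate(sign_change):
        f = delta[i] / (delta[i] - delta[i + 1])
        tc = theta[i] + f * (theta[i + 1] - theta[i])
        th.insert(i + 1 + offset, tc)
        rd.insert(i + 1 + offset, pitch_b * tc)
        cut_points.append(i + 1 + offset)
    th = np.asarray(th)
    rd = np.asarray(rd)
    total = 0.0
    bounds = [0, *cut_points, len(th) - 1]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_th = th[a : b + 1]
        seg_rd = rd[a : b + 1]
        x = np.concatenate([seg_rd * np.cos(seg_th), (pitch_b * seg_th * np.cos(seg_th))[::-1]])
        y = np.concatenate([seg_rd * np.sin(seg_th), (pitch_b * seg_th * np.sin(seg_th))[::-1]])
        total += abs(shoelace(x, y))
    return total
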