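"""Synthetic cohort generator.

Emulates a population-based elderly cohort performing the spiral-drawing
test: demographics (age, sex, education), brain volumes, a small action-
tremor stratum, and one simulated pen trajectory per participant, sampled
at 60 Hz.

The generator is a calibration device, not a physiological model.  Its
distributional choices are fixed so that the *quantified* drawings of the
default cohort reproduce the marginal statistics of the reference
population: non-tremor medians of roughly 3.5 cm/s average speed, 16 s
movement time, 1.7 cm/s speed variability, 5.8 cm^2 deviation area, a mean
of about 5.3 template crossings, and drawn length near 58 cm against a
56 cm template.

Structure of one simulated drawing:

* the template path is traversed at a per-subject base speed (log-normal
  across subjects) with i.i.d. multiplicative per-interval speed noise;
* the radial error around the template is a smooth Gaussian-process drift
  in angle (squared-exponential covariance; its scale sets deviation area,
  its correlation length sets the crossing rate) plus white sensor jitter;
* tremor adds radial and along-path sinusoids (4-10 Hz) and inflates
  the drift scale; the along-path component reverses the pen direction
  within cycles, lengthening the drawing without extra crossings;
* the log drift scale carries the injected covariate structure: a linear
  age slope, an extra quadratic term above a knot age (75 y), a negative
  loading on cerebral gray matter volume (z), and a positive loading on
  log white-matter-lesion volume (z) — the effects the downstream
  regression models are meant to recover.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .errors import InvalidParameterError
from .template import SpiralTemplate, build_template
from .trajectory import PenTrajectory, write_trajectory_csv

__all__ = [
    "ParticipantRecord",
    "GeneratorConfig",
    "sample_demographics",
    "sample_brain_volumes",
    "simulate_drawing",
    "generate_cohort",
    "cohort_to_frame",
]


@dataclass
class ParticipantRecord:
    """Demographics, tremor status, and brain volumes for one participant."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    primary_education_only: bool
    tremor: bool
    icv_ml: float = math.nan
    cerebral_gm_ml: float = math.nan
    cerebral_wm_ml: float = math.nan
    cerebellar_gm_ml: float = math.nan
    cerebellar_wm_ml: float = math.nan
    wml_ml: float = math.nan


@dataclass
class GeneratorConfig:
    """Defaults define the reference study conditions; see module docstring.

    All rates are per year unless noted; lengths in cm, volumes in mL.
    """

    n_no_tremor: int = 1888
    n_tremor: int = 24
    seed: int | None = None

    # demographics (per-stratum probabilities: no-tremor, tremor)
    age_mean: float = 77.4
    age_sd: float = 6.8
    age_min: float = 48.7
    age_max: float = 96.3
    female_p_no_tremor: float = 0.606
    female_p_tremor: float = 0.333
    primary_edu_p_no_tremor: float = 0.207
    primary_edu_p_tremor: float = 0.292

    # pen capture
    sampling_rate: float = 60.0

    # speed model (log-normal base speed across subjects)
    base_speed_median: float = 3.13  # cm/s at the mean age, non-tremor
    tremor_speed_median: float = 4.40  # cm/s at the mean age, tremor stratum
    speed_subject_log_sd: float = 0.47
    speed_age_slope: float = -0.010  # on log base speed
    speed_noise_log_sd: float = 0.44  # i.i.d. per-interval multiplicative noise
    speed_noise_age_slope: float = 0.015  # on log of the noise scale

    # radial drift model (smooth GP in angle + white jitter)
    drift_scale_median: float = 0.127  # cm at the mean age
    drift_subject_log_sd: float = 0.33
    drift_theta_corr: float = 1.31  # rad; SE-kernel correlation length
    drift_corr_age_slope: float = -0.008  # on log correlation length
    drift_age_slope: float = 0.020  # on log drift scale
    drift_quad_coeff: float = 0.0015  # per year^2 above the knot age
    quad_knot_age: float = 75.0
    gm_loading: float = 0.09  # log drift decrease per cerebral-GM z-SD
    wml_loading: float = 0.03  # log drift increase per log-WML z-SD
    sv_gm_loading: float = 0.06  # log speed-noise decrease per GM z-SD
    jitter_sd: float = 0.008  # cm, white sensor noise per axis

    # tremor stratum
    tremor_amplitude: float = 0.04  # cm radial sinusoid
    tremor_tangential_amplitude: float = 0.18  # cm along-path sinusoid
    tremor_freq: float = 5.0  # Hz
    tremor_speed_mod: float = 0.0  # fractional sinusoidal speed modulation
    tremor_drift_mult: float = 2.0

    # brain volumes (marginal mean/SD; wml log-normal)
    icv_mean: float = 1462.5
    icv_sd: float = 162.7
    cerebral_gm_mean: float = 454.8
    cerebral_gm_sd: float = 41.8
    cerebral_wm_mean: float = 392.7
    cerebral_wm_sd: float = 52.8
    cerebellar_gm_mean: float = 97.8
    cerebellar_gm_sd: float = 10.6
    cerebellar_wm_mean: float = 22.0
    cerebellar_wm_sd: float = 2.9
    wml_log_median: float = math.log(6.9)
    wml_log_sd: float = 1.054
    icv_corr: float = 0.6  # tissue-volume correlation with ICV
    cerebral_gm_age_slope: float = -1.6  # mL per year
    cerebral_wm_age_slope: float = -1.4
    cerebellar_gm_age_slope: float = -0.25
    cerebellar_wm_age_slope: float = -0.05
    wml_age_slope: float = 0.06  # on log volume

    def __post_init__(self) -> None:
        if self.n_no_tremor < 0 or self.n_tremor < 0:
            raise InvalidParameterError("cohort sizes must be >= 0")
        if not (4.0 <= self.tremor_freq <= 10.0):
            raise InvalidParameterError("tremor_freq must lie in [4, 10] Hz")
        for name in ("speed_noise_log_sd", "jitter_sd", "drift_scale_median"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.sampling_rate <= 0.0:
            raise InvalidParameterError("sampling_rate must be > 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _as_rng(rng_or_seed) -> Generator:
    if isinstance(rng_or_seed, Generator):
        return rng_or_seed
    return default_rng(rng_or_seed)


def sample_demographics(config: GeneratorConfig, rng=None) -> list[ParticipantRecord]:
    """Draw demographics for the full cohort (no-tremor stratum first).

    Age is truncated-normal within the observed range; sex and
    primary-education flags are Bernoulli with per-stratum probabilities.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    records: list[ParticipantRecord] = []
    strata = [
        (config.n_no_tremor, False, config.female_p_no_tremor, config.primary_edu_p_no_tremor),
        (config.n_tremor, True, config.female_p_tremor, config.primary_edu_p_tremor),
    ]
    idx = 0
    for n, tremor, p_female, p_edu in strata:
        if n == 0:
            continue
        ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
        female = rng.random(n) < p_female
        edu = rng.random(n) < p_edu
        for i in range(n):
            idx += 1
            records.append(
                ParticipantRecord(
                    subject_id=f"S{idx:05d}",
                    age=float(ages[i]),
                    sex="female" if female[i] else "male",
                    primary_education_only=bool(edu[i]),
                    tremor=tremor,
                )
            )
    return records


def sample_brain_volumes(
    record: ParticipantRecord, config: GeneratorConfig, rng=None
) -> ParticipantRecord:
    """Fill in brain volumes for one participant (returns the same record).

    Tissue volumes are normal with the configured marginal mean/SD, share a
    common scale with intracranial volume (correlation ``icv_corr``), and
    decline linearly with age; white-matter-lesion volume is log-normal
    with a positive age slope on the log scale.  All volumes are kept
    strictly positive.
    """
    rng = _as_rng(rng)
    age_c = record.age - config.age_mean
    icv = config.icv_mean + config.icv_sd * rng.standard_normal()
    icv_z = (icv - config.icv_mean) / config.icv_sd
    rho = config.icv_corr
    resid = math.sqrt(max(0.0, 1.0 - rho * rho))

    def tissue(mean: float, sd: float, slope: float) -> float:
        v = mean + slope * age_c + sd * (rho * icv_z + resid * rng.standard_normal())
        return max(v, 1e-3)

    record.icv_ml = max(icv, 1e-3)
    record.cerebral_gm_ml = tissue(
        config.cerebral_gm_mean, config.cerebral_gm_sd, config.cerebral_gm_age_slope
    )
    record.cerebral_wm_ml = tissue(
        config.cerebral_wm_mean, config.cerebral_wm_sd, config.cerebral_wm_age_slope
    )
    record.cerebellar_gm_ml = tissue(
        config.cerebellar_gm_mean, config.cerebellar_gm_sd, config.cerebellar_gm_age_slope
    )
    record.cerebellar_wm_ml = tissue(
        config.cerebellar_wm_mean, config.cerebellar_wm_sd, config.cerebellar_wm_age_slope
    )
    log_resid = math.sqrt(
        max(0.0, config.wml_log_sd**2 - (config.wml_age_slope * config.age_sd) ** 2)
    )
    record.wml_ml = math.exp(
        config.wml_log_median + config.wml_age_slope * age_c + log_resid * rng.standard_normal()
    )
    return record


# cached arc-length inversion grid per template parameters
_ARC_GRID_CACHE: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}


def _arc_grid(template: SpiralTemplate) -> tuple[np.ndarray, np.ndarray]:
    key = (template.pitch_b, template.theta_max)
    if key not in _ARC_GRID_CACHE:
        theta = np.linspace(0.0, template.theta_max, 4096)
        s = template.pitch_b * 0.5 * (theta * np.sqrt(1 + theta**2) + np.arcsinh(theta))
        _ARC_GRID_CACHE[key] = (s, theta)
    return _ARC_GRID_CACHE[key]


def _gp_drift(theta_max: float, corr_len: float, rng: Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance smooth Gaussian process on a uniform angle grid.

    Gaussian-smoothing white noise with kernel width ``corr_len/sqrt(2)``
    yields a squared-exponential covariance with correlation length
    ``corr_len``; the output is rescaled by the theoretical filter gain so
    the process has unit marginal variance (realized amplitude still
    fluctuates along the trace, as it should).
    """
    m = 2048
    grid = np.linspace(0.0, theta_max, m)
    dg = grid[1] - grid[0]
    sigma_g = corr_len / math.sqrt(2.0) / dg  # in grid samples
    white = rng.standard_normal(m)
    smooth = gaussian_filter1d(white, sigma=sigma_g, mode="reflect")
    gain = math.sqrt(1.0 / (2.0 * math.sqrt(math.pi) * sigma_g))
    return grid, smooth / gain


def _covariate_z(record: ParticipantRecord, config: GeneratorConfig) -> tuple[float, float]:
    """Cerebral-GM and log-WML z-scores against the configured population."""
    if math.isnan(record.cerebral_gm_ml):
        return 0.0, 0.0
    gm_z = (record.cerebral_gm_ml - config.cerebral_gm_mean) / config.cerebral_gm_sd
    wml_z = (math.log(record.wml_ml) - config.wml_log_median) / config.wml_log_sd
    return gm_z, wml_z


def simulate_drawing(
    record: ParticipantRecord,
    template: SpiralTemplate,
    config: GeneratorConfig,
    rng=None,
) -> PenTrajectory:
    """Simulate one 60 Hz pen trajectory tracing the template."""
    rng = _as_rng(rng)
    dt = 1.0 / config.sampling_rate
    age_c = record.age - config.age_mean
    knot = max(0.0, record.age - config.quad_knot_age)
    gm_z, wml_z = _covariate_z(record, config)

    base_median = config.tremor_speed_median if record.tremor else config.base_speed_median
    v_subj = base_median * math.exp(
        config.speed_age_slope * age_c + config.speed_subject_log_sd * rng.standard_normal()
    )
    sigma_s = config.speed_noise_log_sd * math.exp(
        config.speed_noise_age_slope * age_c - config.sv_gm_loading * gm_z
    )
    sigma_d = config.drift_scale_median * math.exp(
        config.drift_age_slope * age_c
        + config.drift_quad_coeff * knot * knot
        - config.gm_loading * gm_z
        + config.wml_loading * wml_z
        + config.drift_subject_log_sd * rng.standard_normal()
    )
    if record.tremor:
        sigma_d *= config.tremor_drift_mult
    corr_len = config.drift_theta_corr * math.exp(config.drift_corr_age_slope * age_c)

    total_len = template.total_arc_length
    # draw enough per-tick speeds to certainly finish the template
    n_max = int(math.ceil(total_len / (v_subj * dt) * 4.0)) + 64
    t_ticks = np.arange(n_max) * dt
    v = v_subj * np.exp(sigma_s * rng.standard_normal(n_max))
    phase_v = rng.uniform(0.0, 2.0 * np.pi)
    if record.tremor and config.tremor_speed_mod > 0.0:
        v = v * np.clip(
            1.0 + config.tremor_speed_mod * np.sin(2.0 * np.pi * config.tremor_freq * t_ticks + phase_v),
            0.05,
            None,
        )
    s = np.concatenate([[0.0], np.cumsum(v[:-1] * dt)])
    stop = int(np.searchsorted(s, total_len))
    s = np.minimum(s[: stop + 1], total_len)
    t = t_ticks[: s.size]
    if record.tremor and config.tremor_tangential_amplitude > 0.0:
        # along-path tremor: oscillates the pen back and forth along the
        # curve, lengthening the drawing without crossing the template
        phase_t = rng.uniform(0.0, 2.0 * np.pi)
        osc = config.tremor_tangential_amplitude * np.sin(
            2.0 * np.pi * config.tremor_freq * t + phase_t
        )
        s = np.clip(s + osc * np.minimum(s / 3.7, 1.0), 0.0, total_len)

    s_grid, th_grid = _arc_grid(template)
    theta = np.interp(s, s_grid, th_grid)

    delta = np.zeros_like(theta)
    if sigma_d > 0.0:
        grid, gp = _gp_drift(template.theta_max, corr_len, rng)
        delta = delta + sigma_d * np.interp(theta, grid, gp)
    if record.tremor and config.tremor_amplitude > 0.0:
        phase_r = rng.uniform(0.0, 2.0 * np.pi)
        delta = delta + config.tremor_amplitude * np.sin(
            2.0 * np.pi * config.tremor_freq * t + phase_r
        )
    # the pen starts on the template center, so the radial error ramps in
    # over the first turn instead of offsetting the start point
    delta = delta * np.minimum(theta / (2.0 * np.pi), 1.0)

    r = np.maximum(template.pitch_b * theta + delta, 0.0)
    sign = 1.0 if template.handedness == "counterclockwise" else -1.0
    x = r * np.cos(theta)
    y = sign * r * np.sin(theta)
    if config.jitter_sd > 0.0:
        x = x + config.jitter_sd * rng.standard_normal(x.size)
        y = y + config.jitter_sd * rng.standard_normal(y.size)
    return PenTrajectory(
        t=t, x=x, y=y, nominal_rate=config.sampling_rate, subject_id=record.subject_id
    )


def cohort_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Tidy covariate table, one row per participant."""
    return pd.DataFrame([asdict(r) for r in records])


def generate_cohort(
    config: GeneratorConfig,
    template: SpiralTemplate | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, dict[str, PenTrajectory]]:
    """Generate the full synthetic cohort: covariates plus one drawing each.

    Fully deterministic under ``config.seed``.  If ``out_dir`` is given,
    writes ``cohort.csv`` and one trajectory CSV per participant under
    ``out_dir/trajectories/``.
    """
    if config.seed is None:
        raise InvalidParameterError("GeneratorConfig.seed must be set explicitly")
    if template is None:
        template = build_template(4, 56.0)
    n_total = config.n_no_tremor + config.n_tremor
    children = SeedSequence(config.seed).spawn(n_total + 2)
    demo_rng = default_rng(children[0])
    vol_rng = default_rng(children[1])
    records = sample_demographics(config, rng=demo_rng)
    trajectories: dict[str, PenTrajectory] = {}
    for i, rec in enumerate(records):
        sample_brain_volumes(rec, config, rng=vol_rng)
        trajectories[rec.subject_id] = simulate_drawing(
            rec, template, config, rng=default_rng(children[2 + i])
        )
    frame = cohort_to_frame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        traj_dir = out_dir / "trajectories"
        traj_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "cohort.csv", index=False)
        for sid, traj in trajectories.items():
            write_trajectory_csv(traj, traj_dir / f"{sid}.csv")
    return frame, trajectories
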