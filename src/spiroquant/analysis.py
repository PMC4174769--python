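"""Cohort-level statistical pipeline for spiral-drawing measures.

Implements the analysis chain applied to the quantified drawings:

* natural-log transform of the right-skewed measures (movement time,
  speed variability, deviation area) followed by z-scoring of all six
  measures against the analysis cohort;
* tremor-group contrast by analysis of covariance — realized as an
  ordinary least-squares model with the group indicator plus age, sex and
  education as covariates (an equivalent formulation);
* age trends: sex-adjusted means per 5-year age bin for display, and
  linear / added-quadratic regression tests on continuous age (age
  centered before squaring);
* pairwise partial correlations between measures given age and sex
  (double residualization, Pearson on residuals);
* brain-volume associations: per-z-SD regression coefficients adjusting
  for age, sex, education and intracranial volume, with cerebral volumes
  additionally adjusted for total cerebellar volume and vice versa;
  white-matter-lesion volume enters as the z-score of its natural log;
* the exclusion filter that turns the assessed population into the
  analysis population, with an accounting ledger.

Confidence intervals are classical t-based 95% intervals throughout; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, DegenerateInputError

__all__ = [
    "MEASURE_COLUMNS",
    "LOG_MEASURES",
    "StandardizedMeasures",
    "ModelResult",
    "AgeTrendResult",
    "transform_and_zscore",
    "ancova_group_compare",
    "age_trend",
    "correlate_measures",
    "brainvol_association",
    "exclusion_filter",
    "tremor_prevalence",
    "score_to_numeric",
    "AGE_BIN_EDGES",
    "AGE_BIN_LABELS",
]

MEASURE_COLUMNS = (
    "length_cm",
    "movement_time_s",
    "avg_speed",
    "speed_variability",
    "deviation_area",
    "crossings",
)
#: right-skewed measures natural-log transformed before z-scoring
LOG_MEASURES = ("movement_time_s", "speed_variability", "deviation_area")

AGE_BIN_EDGES = (-np.inf, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0, np.inf)
AGE_BIN_LABELS = ("<65", "65-69", "70-74", "75-79", "80-84", "85-89", "90+")

_SCORE_RANKS = {"0A": 0, "0B": 1, "1": 2, "2": 3}

_MAX_CONDITION = 1e10


def score_to_numeric(scores: pd.Series) -> pd.Series:
    """Ordinal rank encoding of the clinical score (0A=0, 0B=1, 1=2, 2=3)."""
    return scores.map(_SCORE_RANKS).astype(float)


@dataclass
class StandardizedMeasures:
    """Z-scored measures table plus the record of applied log transforms."""

    frame: pd.DataFrame
    log_transformed: tuple[str, ...]


@dataclass
class ModelResult:
    """Tidy OLS summary: one row per term with estimate, 95% CI, p-value."""

    terms: pd.DataFrame
    n: int
    covariates: tuple[str, ...]

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in model (have {list(self.terms['term'])})")
        return row.iloc[0]


@dataclass
class AgeTrendResult:
    """Sex-adjusted binned means plus linear and quadratic trend models."""

    binned_means: pd.DataFrame
    linear: ModelResult
    quadratic: ModelResult


def _encode_sex(s: pd.Series) -> pd.Series:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return (s == "female").astype(float)
    return s.astype(float)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, n_report: int | None = None) -> ModelResult:
    """OLS with t-based 95% CIs; raises CollinearityError on singular designs."""
    Xm = sm.add_constant(X.astype(float), has_constant="add")
    arr = Xm.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1] or np.linalg.cond(arr) > _MAX_CONDITION:
        raise CollinearityError(
            f"design matrix with columns {list(Xm.columns)} is singular or ill-conditioned"
        )
    fit = sm.OLS(np.asarray(y, dtype=float), Xm).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "term": Xm.columns,
            "estimate": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return ModelResult(
        terms=terms,
        n=int(fit.nobs) if n_report is None else n_report,
        covariates=tuple(c for c in Xm.columns if c != "const"),
    )


def transform_and_zscore(
    measures: pd.DataFrame,
    log_measures: tuple[str, ...] = LOG_MEASURES,
    columns: tuple[str, ...] = MEASURE_COLUMNS,
) -> StandardizedMeasures:
    """Log-transform the skewed measures and z-score all six.

    With the default arguments, exactly movement time, speed variability
    and deviation area are natural-log transformed before z-scoring.
    Standardization alone (``log_measures=()``) is idempotent.  Raises
    ``DegenerateInputError`` if a log-transformed measure contains a
    non-positive value (the offending rows are named) or if any measure has
    zero variance across the cohort.
    """
    out = measures.copy()
    for col in log_measures:
        bad = out.index[out[col] <= 0.0].tolist()
        if bad:
            raise DegenerateInputError(
                f"{col} must be positive for the log transform; offending rows: {bad[:10]}"
            )
        out[col] = np.log(out[col].astype(float))
    for col in columns:
        v = out[col].astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(v.mean())):
            raise DegenerateInputError(f"{col} has zero variance; z-score undefined")
        out[col] = (v - v.mean()) / sd
    return StandardizedMeasures(frame=out, log_transformed=tuple(log_measures))


def ancova_group_compare(
    df: pd.DataFrame,
    outcome: str,
    group: str = "tremor",
    covariates: tuple[str, ...] = ("age", "sex", "primary_education_only"),
    alpha: float = 0.01,
) -> ModelResult:
    """Covariate-adjusted group contrast (ANCOVA as a linear model).

    Fits ``outcome ~ group + covariates`` by least squares and returns the
    adjusted group difference with 95% CI and p-value; the returned table
    carries a ``significant`` flag for the group term at ``alpha``
    (default 0.01).  Both groups must be non-empty.
    """
    g = df[group].astype(bool)
    if g.all() or (~g).all():
        raise DegenerateInputError(f"both levels of {group!r} must be present")
    X = pd.DataFrame({group: g.astype(float)})
    for c in covariates:
        X[c] = _encode_sex(df[c]) if c == "sex" else df[c].astype(float)
    res = _fit_ols(df[outcome].to_numpy(), X)
    res.terms["significant"] = (res.terms["term"] == group) & (res.terms["p"] < alpha)
    return res


def age_trend(
    df: pd.DataFrame,
    outcome: str,
    age_col: str = "age",
    sex_col: str = "sex",
) -> AgeTrendResult:
    """Age-trend analysis: binned sex-adjusted means plus trend tests.

    (a) sex-adjusted mean of the outcome per 5-year age bin (<65 through
    90+), estimated from a bin-dummy model with sex centered so bin
    coefficients are means at the cohort sex mix; empty bins are reported
    with a missing mean.  (b) linear trend: outcome on continuous age plus
    sex.  (c) quadratic trend: adds centered age squared to the linear
    model; its p-value tests the added curvature.
    """
    age = df[age_col].astype(float)
    if age.max() - age.min() < 5.0:
        raise DegenerateInputError("age range must span at least two 5-year bins")
    female = _encode_sex(df[sex_col])
    y = df[outcome].to_numpy(dtype=float)

    bins = pd.cut(age, bins=list(AGE_BIN_EDGES), labels=list(AGE_BIN_LABELS), right=False)
    dummies = pd.get_dummies(bins).astype(float)
    female_c = female - female.mean()
    rows = []
    present = [lab for lab in AGE_BIN_LABELS if dummies[lab].sum() > 0]
    Xb = pd.concat([dummies[present], female_c.rename("female_c")], axis=1)
    fitb = sm.OLS(y, Xb.to_numpy()).fit()
    coef = dict(zip(Xb.columns, fitb.params))
    se = dict(zip(Xb.columns, fitb.bse))
    for lab in AGE_BIN_LABELS:
        n_bin = int(dummies[lab].sum())
        rows.append(
            {
                "age_bin": lab,
                "n": n_bin,
                "adjusted_mean": coef.get(lab, np.nan) if n_bin else np.nan,
                "se": se.get(lab, np.nan) if n_bin else np.nan,
            }
        )
    binned = pd.DataFrame(rows)

    linear = _fit_ols(y, pd.DataFrame({"age": age, "female": female}))
    age_c = age - age.mean()
    quadratic = _fit_ols(
        y,
        pd.DataFrame({"age_c": age_c, "age_c_sq": age_c**2, "female": female}),
    )
    return AgeTrendResult(binned_means=binned, linear=linear, quadratic=quadratic)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return y - Xc @ beta


def correlate_measures(
    standardized: StandardizedMeasures | pd.DataFrame,
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = MEASURE_COLUMNS,
) -> pd.DataFrame:
    """Pairwise partial correlations between measures given age and sex.

    Each measure is residualized on age and sex, then Pearson correlations
    are taken between residuals.  ``covariates`` must carry ``age`` and
    ``sex`` aligned with the measures table.
    """
    frame = standardized.frame if isinstance(standardized, StandardizedMeasures) else standardized
    if len(frame) < 3:
        raise DegenerateInputError("partial correlation needs >= 3 rows")
    Z = np.column_stack(
        [
            covariates["age"].to_numpy(dtype=float),
            _encode_sex(covariates["sex"]).to_numpy(),
        ]
    )
    resid = np.column_stack(
        [_residualize(frame[c].to_numpy(dtype=float), Z) for c in columns]
    )
    corr = np.corrcoef(resid, rowvar=False)
    return pd.DataFrame(corr, index=list(columns), columns=list(columns))


_VOLUME_COLUMNS = (
    "cerebral_gm_ml",
    "cerebral_wm_ml",
    "cerebellar_gm_ml",
    "cerebellar_wm_ml",
    "wml_ml",
)


def brainvol_association(
    df: pd.DataFrame,
    outcome: str,
    volume: str,
    covariates: tuple[str, ...] = ("age", "sex", "primary_education_only"),
    extra_covariates: tuple[str, ...] = (),
) -> ModelResult:
    """Per-z-SD association between a brain volume and a drawing measure.

    The volume of interest enters as its cohort z-score (natural log first
    for white-matter-lesion volume); the model adjusts for age, sex,
    education and intracranial-volume z.  Cerebral volumes are additionally
    adjusted for total cerebellar volume and vice versa; lesion volume gets
    neither extra adjustment.  The coefficient on ``volume_z`` is the
    Table-2-style per-SD effect.
    """
    if volume not in _VOLUME_COLUMNS:
        raise DegenerateInputError(f"volume must be one of {_VOLUME_COLUMNS}, got {volume!r}")

    def z(v: pd.Series) -> pd.Series:
        v = v.astype(float)
        return (v - v.mean()) / v.std(ddof=1)

    vol = np.log(df[volume].astype(float)) if volume == "wml_ml" else df[volume].astype(float)
    X = pd.DataFrame({"volume_z": z(vol)})
    for c in covariates:
        X[c] = _encode_sex(df[c]) if c == "sex" else df[c].astype(float)
    X["icv_z"] = z(df["icv_ml"])
    if volume.startswith("cerebral"):
        X["cerebellar_total_z"] = z(df["cerebellar_gm_ml"] + df["cerebellar_wm_ml"])
    elif volume.startswith("cerebellar"):
        X["cerebral_total_z"] = z(df["cerebral_gm_ml"] + df["cerebral_wm_ml"])
    for c in extra_covariates:
        X[c] = df[c].astype(float)
    return _fit_ols(df[outcome].to_numpy(), X)


def exclusion_filter(
    df: pd.DataFrame,
    joint_policy: str = "covariate",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Turn the assessed population into the analysis population.

    Removes participants flagged ``parkinson`` (self-reported Parkinson
    disease) or ``unusable`` (drawing unsuited for post-processing).
    Participants with self-reported joint problems of the dominant hand are
    either retained with ``joint_problems`` kept as an extra covariate
    (``joint_policy="covariate"``, the default) or removed
    (``joint_policy="exclude"``).  Returns the filtered table and an
    accounting ledger of every decision.
    """
    if joint_policy not in ("covariate", "exclude"):
        raise DegenerateInputError("joint_policy must be 'covariate' or 'exclude'")
    for col in ("parkinson", "joint_problems", "unusable"):
        if col not in df.columns:
            raise DegenerateInputError(f"flag column {col!r} missing from cohort table")
    pd_mask = df["parkinson"].astype(bool)
    unusable_mask = df["unusable"].astype(bool) & ~pd_mask
    drop = pd_mask | unusable_mask
    joint_mask = df["joint_problems"].astype(bool) & ~drop
    if joint_policy == "exclude":
        drop = drop | joint_mask
    out = df.loc[~drop].copy()
    accounting = {
        "n_input": int(len(df)),
        "n_parkinson_excluded": int(pd_mask.sum()),
        "n_unusable_excluded": int(unusable_mask.sum()),
        "n_joint_problem": int(joint_mask.sum()),
        "n_joint_excluded": int(joint_mask.sum()) if joint_policy == "exclude" else 0,
        "n_retained": int(len(out)),
    }
    return out, accounting


def tremor_prevalence(
    n_no_tremor: int = 1888,
    n_tremor: int = 24,
    female_frac_no_tremor: float = 0.606,
    female_frac_tremor: float = 0.333,
) -> dict[str, float]:
    """Tremor prevalence overall and by sex, in percent.

    Sex-specific counts are reconstructed from the stratum sizes and the
    female fractions within each stratum.
    """
    total = n_no_tremor + n_tremor
    if total == 0:
        raise DegenerateInputError("empty cohort")
    women_t = n_tremor * female_frac_tremor
    men_t = n_tremor - women_t
    women_nt = n_no_tremor * female_frac_no_tremor
    men_nt = n_no_tremor - women_nt
    return {
        "overall_pct": 100.0 * n_tremor / total,
        "men_pct": 100.0 * men_t / (men_t + men_nt),
        "women_pct": 100.0 * women_t / (women_t + women_nt),
    }
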