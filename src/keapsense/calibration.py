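"""Calibration-curve estimation of residual KEAP1 activity.

A graded-dosage series of mouse genotypes (relative KEAP1 protein level as a
percent of wild type, paired with fold-induction of an NRF2 target gene such as
*Nqo1*) defines a monotone calibration curve.  The curve is modelled as a power
law — linear in log-log coordinates — because repression strength behaves
multiplicatively and a two-parameter monotone form is analytically invertible.
Inverting the fitted curve at an observed mRNA fold-change yields the residual
KEAP1 activity of a stressed condition; uncertainty comes from a nonparametric
bootstrap over both the calibration points and the observed replicates.

Conventions: levels and activities are percent of wild type at the curve
interface (the units the calibration series is expressed in); the
:class:`ActivityEstimate` carries fractions in [0, 1] for downstream model
arithmetic.  Fold-changes are relative to the wild-type baseline, whose
geometric mean defines 1.0 (noise is multiplicative).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "ActivityEstimate",
    "InsufficientDataError",
    "NonInverseRelationshipError",
    "fit_calibration",
    "predict_mrna",
    "invert_activity",
    "estimate_activity_ci",
]

_BASELINE_LEVEL = 100.0  # percent of wild type; anchors fold-change 1.0
_MAX_RESAMPLE_ROUNDS = 100


class InsufficientDataError(ValueError):
    """Fewer distinct calibration levels than a two-parameter fit requires."""


class NonInverseRelationshipError(ValueError):
    """Fitted slope is non-negative: mRNA does not decrease with KEAP1 level."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One replicate measurement on the graded-KEAP1 series."""

    keap1_level: float  # percent of wild type, > 0
    mrna_rel: float  # fold-change vs wild type, > 0
    replicate_id: str = ""
    gene: str = "Nqo1"

    def __post_init__(self) -> None:
        if not self.keap1_level > 0:
            raise ValueError(f"keap1_level must be > 0, got {self.keap1_level!r}")
        if not self.mrna_rel > 0:
            raise ValueError(f"mrna_rel must be > 0, got {self.mrna_rel!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Power-law fit log(mrna) = intercept + slope * (log(level) - log(100)).

    ``slope`` is the log-log slope (negative: repression), ``intercept`` the
    log fold-change at the 100% baseline, ``residual_sd`` the log-scale
    standard deviation of fit residuals.
    """

    slope: float
    intercept: float
    residual_sd: float
    n_points: int
    gene: str = "Nqo1"


@dataclass(frozen=True)
class ActivityEstimate:
    """Inferred residual KEAP1 activity for one condition, as fractions."""

    activity_point: float
    ci_low: float
    ci_high: float
    n_boot: int = 0
    seed: int = 0
    gene: str = "Nqo1"
    condition_label: str = ""

    def __post_init__(self) -> None:
        for name in ("activity_point", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


def _fit_loglog(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x with residual SD; x is log(level/100), y is log(mrna)."""
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.intercept + res.slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return float(res.slope), float(res.intercept), residual_sd


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationCurve:
    """Fit the log-log calibration line through replicate measurements.

    Requires at least three distinct KEAP1 levels (two would determine the
    power law without any residual information).  A non-negative slope is
    rejected: the model presumes KEAP1 represses the target gene.
    """
    levels = np.array([p.keap1_level for p in points], dtype=float)
    mrna = np.array([p.mrna_rel for p in points], dtype=float)
    if np.unique(levels).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct keap1_level values, got {np.unique(levels).size}"
        )
    x = np.log(levels / _BASELINE_LEVEL)
    y = np.log(mrna)
    slope, intercept, residual_sd = _fit_loglog(x, y)
    if slope >= 0:
        raise NonInverseRelationshipError(
            f"fitted slope {slope:.4g} >= 0; calibration data must show mRNA "
            "decreasing as KEAP1 level increases"
        )
    genes = {p.gene for p in points}
    gene = points[0].gene if len(genes) == 1 else ",".join(sorted(genes))
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        n_points=len(points),
        gene=gene,
    )


def predict_mrna(curve: CalibrationCurve, keap1_level: float) -> float:
    """Fold-change the fitted curve predicts at a given KEAP1 level (percent)."""
    if not keap1_level > 0:
        raise ValueError(f"keap1_level must be > 0, got {keap1_level!r}")
    return math.exp(
        curve.intercept + curve.slope * (math.log(keap1_level) - math.log(_BASELINE_LEVEL))
    )


def invert_activity(curve: CalibrationCurve, mrna_observed: float) -> float:
    """KEAP1 activity level (percent) whose predicted mRNA equals the observation.

    The power law is strictly monotone, so the solution is unique:
    level = 100 * exp((log(mrna) - intercept) / slope).  Solutions above 100%
    (observations below the fitted baseline) are clipped to 100% with a
    warning, since activity is expressed as a fraction of the WT pool.
    """
    if not mrna_observed > 0:
        raise ValueError(f"mrna_observed must be > 0, got {mrna_observed!r}")
    level = _BASELINE_LEVEL * math.exp(
        (math.log(mrna_observed) - curve.intercept) / curve.slope
    )
    if level > _BASELINE_LEVEL:
        warnings.warn(
            f"inverted activity {level:.1f}% exceeds the 100% baseline; clipping",
            stacklevel=2,
        )
        level = _BASELINE_LEVEL
    return level


def _stratified_indices(
    rng: np.random.Generator, level_groups: list[np.ndarray], n_boot: int
) -> np.ndarray:
    """Bootstrap indices resampled within each calibration level (B, n)."""
    cols = [
        grp[rng.integers(0, grp.size, size=(n_boot, grp.size))]
        for grp in level_groups
    ]
    return np.concatenate(cols, axis=1)


def _vectorised_ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slopes and intercepts for (B, n) design/response arrays."""
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    slope = sxy / sxx
    intercept = ym[:, 0] - slope * xm[:, 0]
    return slope, intercept


def estimate_activity_ci(
    points: list[CalibrationPoint],
    observed_replicates: list[float],
    n_boot: int = 2000,
    seed: int = 1,
    gene: str = "Nqo1",
    condition_label: str = "",
) -> ActivityEstimate:
    """Residual activity with a percentile-bootstrap 95% confidence interval.

    Each bootstrap resample redraws the calibration points (stratified by
    KEAP1 level, so every level stays represented) and the observed replicates,
    refits the curve, and inverts the resampled geometric-mean observation.
    Resamples whose refitted slope is non-negative cannot be inverted and are
    redrawn; if every resample keeps failing the data do not support the
    repression model and an error is raised.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if len(observed_replicates) < 2:
        raise ValueError("need >= 2 observed replicates for a bootstrap CI")
    obs = np.asarray(observed_replicates, dtype=float)
    if not np.all(obs > 0):
        raise ValueError("observed fold-changes must be > 0")

    curve = fit_calibration(points)
    point_mrna = float(np.exp(np.mean(np.log(obs))))  # geometric mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        activity_point = invert_activity(curve, point_mrna) / 100.0

    levels = np.array([p.keap1_level for p in points], dtype=float)
    x_all = np.log(levels / _BASELINE_LEVEL)
    y_all = np.log([p.mrna_rel for p in points])
    level_groups = [np.flatnonzero(levels == lv) for lv in np.unique(levels)]

    rng = np.random.default_rng(seed)
    boot_activity = np.empty(n_boot)
    pending = np.arange(n_boot)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        b = pending.size
        idx = _stratified_indices(rng, level_groups, b)
        slope, intercept = _vectorised_ols(x_all[idx], y_all[idx])
        obs_idx = rng.integers(0, obs.size, size=(b, obs.size))
        log_obs = np.mean(np.log(obs[obs_idx]), axis=1)
        valid = slope < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            act = _BASELINE_LEVEL * np.exp((log_obs - intercept) / slope)
        boot_activity[pending[valid]] = np.minimum(act[valid], _BASELINE_LEVEL)
        pending = pending[~valid]
        if pending.size == 0:
            break
    else:
        raise RuntimeError(
            "bootstrap resampling kept producing non-repressive refits; "
            "calibration data are inconsistent with the power-law model"
        )

    ci_low, ci_high = np.percentile(boot_activity, [2.5, 97.5]) / 100.0
    # Percentile intervals can narrowly exclude the full-data point estimate;
    # widen to keep the invariant ci_low <= point <= ci_high.
    ci_low = min(float(ci_low), activity_point)
    ci_high = max(float(ci_high), activity_point)
    return ActivityEstimate(
        activity_point=activity_point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        gene=gene,
        condition_label=condition_label,
    )
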