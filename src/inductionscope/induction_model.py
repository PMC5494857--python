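"""Standardized characteristic features, regime rules and the EP model.

A non-induced reference well converts the two device- and
condition-dependent fit features into dimensionless characteristic
parameters:

    c_std     = c / c_ref
    slope_std = SL_fit'(c) / SL_fit'(c)_ref

Rule-based regime classification (fixed precedence):

    1. c_std > 2                                  → too strong induction
    2. slope_std < 0.25 and 1.1 < c_std < 1.9     → optimal induction
    3. slope_std > 0.25 and c_std < 1.1           → insufficient induction
    4. otherwise                                  → indeterminate

Non-induced cultures are behaviourally a special case of insufficient
induction and are folded into that class at the pipeline level. The
standardized expression performance (EP, min–max scaled product
measurement within one dataset, 0 = weakest, 1 = best) is predicted by
the empirical response surface

    EP = β0 + β1·c_std + β2·c_std² + β3·slope_std + β4·c_std·slope_std

with default coefficients (0.76, 0.37, −0.14, −1.14, 0.27); the same
five-term structure can be refit to new data by ordinary least squares
(the slope_std² term is deliberately absent — it does not improve the
model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from inductionscope.errors import (
    CollinearityError,
    DegenerateCurveError,
    DegenerateReferenceError,
    InsufficientDataError,
    MissingReferenceError,
)
from inductionscope.sigmoid_fit import SigmoidFit

LABEL_INSUFFICIENT = "insufficient"
LABEL_OPTIMAL = "optimal"
LABEL_TOO_STRONG = "too_strong"
LABEL_INDETERMINATE = "indeterminate"


@dataclass
class ReferenceFeatures:
    """Inflection time and slope of the non-induced reference culture(s)."""

    c_ref: float
    slope_ref: float
    n_reference_cultures: int
    aggregation: str  # "single" | "median"

    def __post_init__(self) -> None:
        if not (self.c_ref > 0 and self.slope_ref > 0):
            raise DegenerateReferenceError(
                f"reference features must be > 0, got c_ref={self.c_ref}, "
                f"slope_ref={self.slope_ref}"
            )


@dataclass
class StandardizedFeatures:
    """Dimensionless (c_std, slope_std) of one culture."""

    c_std: float
    slope_std: float
    source_well: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_std) and math.isfinite(self.slope_std)):
            raise ValueError("standardized features must be finite")
        if self.c_std <= 0 or self.slope_std <= 0:
            raise ValueError(
                f"standardized features must be > 0, got ({self.c_std}, {self.slope_std})"
            )


@dataclass
class ClassificationThresholds:
    """Decision boundaries of the regime rules (dimensionless)."""

    too_strong_c: float = 2.0
    optimal_slope_max: float = 0.25
    optimal_c_low: float = 1.1
    optimal_c_high: float = 1.9


@dataclass
class InductionClass:
    """Regime label plus the clause of the rule set that assigned it."""

    label: str
    rule_fired: str


@dataclass
class EPModel:
    """Five-coefficient empirical model over (1, c, c², s, c·s)."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    fitted_r_squared: float | None = None
    n_train: int | None = None

    @classmethod
    def default(cls) -> "EPModel":
        """The published default coefficients."""
        return cls(beta0=0.76, beta1=0.37, beta2=-0.14, beta3=-1.14, beta4=0.27)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3, self.beta4])


@dataclass
class EPPrediction:
    """Predicted EP, both the raw model value and its [0, 1] clip."""

    raw: float
    clipped: float


@dataclass
class ExpressionMeasurement:
    """Measured endpoint expression with its min–max standardized value."""

    well: str
    raw_value: float
    ep_standardized: float


def compute_reference(fits: Sequence[SigmoidFit]) -> ReferenceFeatures:
    """Aggregate reference features from kept fits of non-induced wells.

    A single fit yields its (c, slope) directly; several replicate
    reference wells are aggregated component-wise by the median, which
    tolerates one failed well.
    """
    fits = list(fits)
    if not fits:
        raise MissingReferenceError("no kept reference fit available")
    if len(fits) == 1:
        fit = fits[0]
        return ReferenceFeatures(
            c_ref=fit.params.c,
            slope_ref=fit.slope_at_inflection,
            n_reference_cultures=1,
            aggregation="single",
        )
    return ReferenceFeatures(
        c_ref=float(np.median([f.params.c for f in fits])),
        slope_ref=float(np.median([f.slope_at_inflection for f in fits])),
        n_reference_cultures=len(fits),
        aggregation="median",
    )


def standardize(fit: SigmoidFit, reference: ReferenceFeatures) -> StandardizedFeatures:
    """Dimensionless features of one fit relative to the reference."""
    if fit.params.c <= 0:
        raise ValueError(
            f"{fit.well_id}: inflection time c={fit.params.c} h is not positive; "
            "refusing to standardize"
        )
    return StandardizedFeatures(
        c_std=fit.params.c / reference.c_ref,
        slope_std=fit.slope_at_inflection / reference.slope_ref,
        source_well=fit.well_id or "",
    )


def classify_induction(
    f: StandardizedFeatures, thresholds: ClassificationThresholds | None = None
) -> InductionClass:
    """Apply the regime rules in fixed precedence order.

    The rule regions leave gaps (e.g. c_std between the optimal upper edge
    and the too-strong edge); such cultures are labelled indeterminate
    rather than silently assigned.
    """
    th = thresholds or ClassificationThresholds()
    if f.c_std > th.too_strong_c:
        return InductionClass(LABEL_TOO_STRONG, f"c_std > {th.too_strong_c}")
    if f.slope_std < th.optimal_slope_max and th.optimal_c_low < f.c_std < th.optimal_c_high:
        return InductionClass(
            LABEL_OPTIMAL,
            f"slope_std < {th.optimal_slope_max} and "
            f"{th.optimal_c_low} < c_std < {th.optimal_c_high}",
        )
    if f.slope_std > th.optimal_slope_max and f.c_std < th.optimal_c_low:
        return InductionClass(
            LABEL_INSUFFICIENT,
            f"slope_std > {th.optimal_slope_max} and c_std < {th.optimal_c_low}",
        )
    return InductionClass(LABEL_INDETERMINATE, "no rule region matched")


def evaluate_ep(c_std: float, slope_std: float, model: EPModel | None = None) -> float:
    """Raw EP response-surface value at arbitrary (c_std, slope_std)."""
    m = model or EPModel.default()
    c, s = c_std, slope_std
    return m.beta0 + m.beta1 * c + m.beta2 * c * c + m.beta3 * s + m.beta4 * c * s


def predict_ep(f: StandardizedFeatures, model: EPModel | None = None) -> EPPrediction:
    """Evaluate the empirical EP response surface at (c_std, slope_std).

    Returns both the raw polynomial value and its clip to [0, 1] (measured
    EP is min–max scaled, so values outside [0, 1] are extrapolations).
    """
    raw = evaluate_ep(f.c_std, f.slope_std, model)
    return EPPrediction(raw=raw, clipped=float(np.clip(raw, 0.0, 1.0)))


def standardize_expression(
    values: Sequence[float], wells: Sequence[str] | None = None
) -> list[ExpressionMeasurement]:
    """Min–max standardize measured expression within one dataset.

    The weakest measurement maps to 0 and the best to 1. Datasets with
    different products or temperatures are not comparable on the raw
    scale, so this must be applied per dataset grouping.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("min-max standardization needs >= 2 values")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateCurveError("all expression values equal; min-max scaling undefined")
    wells = list(wells) if wells is not None else [""] * vals.size
    if len(wells) != vals.size:
        raise ValueError("wells and values must have equal length")
    return [
        ExpressionMeasurement(well=w, raw_value=float(v), ep_standardized=(float(v) - lo) / (hi - lo))
        for w, v in zip(wells, vals)
    ]


def _design_matrix(features: Sequence[StandardizedFeatures]) -> np.ndarray:
    c = np.array([f.c_std for f in features])
    s = np.array([f.slope_std for f in features])
    return np.column_stack([np.ones_like(c), c, c * c, s, c * s])


def refit_ep_model(
    features: Sequence[StandardizedFeatures], ep: Sequence[float]
) -> EPModel:
    """Ordinary least squares refit of the five-term EP structure.

    The term set (1, c, c², s, c·s) is fixed; only the coefficients are
    re-estimated. Requires at least 10 observations and a full-rank
    design.
    """
    features = list(features)
    y = np.asarray(list(ep), dtype=float)
    if len(features) != y.size:
        raise ValueError("features and ep must have equal length")
    if y.size < 10:
        raise InsufficientDataError(f"EP refit needs >= 10 observations, got {y.size}")
    X = _design_matrix(features)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("EP design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return EPModel(*[float(b) for b in beta], fitted_r_squared=r2, n_train=int(y.size))
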