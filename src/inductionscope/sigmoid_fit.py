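"""The extended sigmoid growth-proxy model and its least-squares fitting.

Model of a scattered-light trajectory SL(t):

    SL_fit(t) = a + b / (1 + exp(−(t − c)/d)) + e·t

with a the baseline intensity [a.u.], b the hub (min-to-max rise of the
sigmoidal fraction) [a.u.], c the inflection time [h], d the inverse-slope
shape parameter [h] and e a linear slope [a.u./h]. Its derivative

    SL_fit'(t) = b / (2·d·cosh((t − c)/d) + 2·d) + e

evaluated at the inflection point t = c (cosh(0) = 1) gives the closed
form SL_fit'(c) = b/(4·d) + e — one of the two characteristic parameters
of a culture; the other is c itself. Depending on its parameters the model
spans the whole range from a step function (small d) to a nearly linear
rise (large d), covering the phenomenology of insufficient, optimal and
too strong induction.

Fitting is bounded trust-region nonlinear least squares with a heuristic
start plus four deterministic perturbations; fits are kept only when the
coefficient of determination on the raw signal exceeds a quality
threshold (default 0.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from inductionscope.errors import DegenerateCurveError, InsufficientDataError
from inductionscope.plate_io import CultureRecord

DEFAULT_R2_THRESHOLD = 0.96

EXCLUDED_NOT_CONVERGED = "not_converged"
EXCLUDED_LOW_R2 = "r_squared_below_threshold"


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters (a, b, c, d, e) of the extended sigmoid; d > 0, b >= 0."""

    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"shape parameter d must be > 0, got {self.d}")
        if self.b < 0:
            raise ValueError(f"hub b must be >= 0, got {self.b}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e])


def extended_sigmoid(t, params: SigmoidParams):
    """Evaluate SL_fit(t); overflow-safe via the logistic function."""
    t = np.asarray(t, dtype=float)
    out = params.a + params.b * expit((t - params.c) / params.d) + params.e * t
    return float(out) if out.ndim == 0 else out


def extended_sigmoid_derivative(t, params: SigmoidParams):
    """Evaluate SL_fit'(t).

    Uses the identity 1/(2·cosh(x) + 2) = σ(x)·σ(−x) with the logistic σ,
    which stays finite for arbitrarily large |x| where cosh overflows.
    """
    t = np.asarray(t, dtype=float)
    x = (t - params.c) / params.d
    out = (params.b / params.d) * expit(x) * expit(-x) + params.e
    return float(out) if out.ndim == 0 else out


def slope_at_inflection(params: SigmoidParams) -> float:
    """Closed-form slope at the inflection point: b/(4·d) + e."""
    return params.b / (4.0 * params.d) + params.e


@dataclass
class SigmoidFit:
    """Result of fitting one culture; the inflection slope is derived.

    ``r_squared`` is −inf for a failed fit (sentinel, never an exception
    from the fitter itself). ``slope_at_inflection`` is recomputed from the
    parameters on access so it can never disagree with them.
    """

    params: SigmoidParams
    r_squared: float
    converged: bool
    n_points: int
    residual_sum_squares: float
    well_id: str | None = None
    is_reference: bool = False
    induced: bool = False

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    @property
    def slope_at_inflection(self) -> float:
        return slope_at_inflection(self.params)


@dataclass
class FitOptions:
    """Fitting controls: multistart perturbations, tolerances, budget."""

    max_nfev: int = 2000
    ftol: float = 1e-10
    xtol: float = 1e-12
    #: deterministic multiplicative perturbations applied to (c0, d0)
    perturbations: tuple = ((1.25, 1.25), (1.25, 0.75), (0.75, 1.25), (0.75, 0.75))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    span = t[-1] - t[0]
    a0 = float(np.min(y))
    b0 = float(np.ptp(y))
    slopes = np.gradient(y, t)
    c0 = float(t[int(np.argmax(slopes))])
    d0 = span / 10.0
    k = max(2, int(np.ceil(0.2 * t.size)))
    e0 = max(0.0, float(np.polyfit(t[-k:], y[-k:], 1)[0]))
    return np.array([a0, b0, c0, d0, e0])


def fit_curve(curve: CultureRecord, options: FitOptions | None = None) -> SigmoidFit:
    """Fit the extended sigmoid to one scattered-light trajectory.

    Bounded trust-region least squares from five deterministic starts
    (heuristic start plus ±25% perturbations of the inflection-time and
    shape guesses); the lowest residual sum of squares wins, ties broken
    by the smaller d. The result is fully deterministic for identical
    inputs and options. A fit in which no start converges is returned as a
    failure result (``converged=False``, ``r_squared=-inf``), never raised.
    """
    options = options or FitOptions()
    t = curve.times
    y = curve.scattered_light
    if t.size < 10:
        raise InsufficientDataError(f"{curve.well}: fitting needs >= 10 points, got {t.size}")
    span = float(t[-1] - t[0])
    hub = float(np.ptp(y))
    failure_params = SigmoidParams(a=float(np.mean(y)), b=0.0, c=float(t[0]), d=1.0, e=0.0)
    if hub == 0.0:
        return SigmoidFit(
            params=failure_params,
            r_squared=float("-inf"),
            converged=False,
            n_points=t.size,
            residual_sum_squares=float("inf"),
            well_id=curve.well,
            is_reference=curve.metadata.is_reference,
            induced=curve.metadata.induced,
        )

    lower = np.array([-np.inf, 0.0, t[0] - span, 1e-3, -np.inf])
    upper = np.array([np.inf, 10.0 * hub, t[-1] + span, span, np.inf])

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] + p[1] * expit((t - p[2]) / p[3]) + p[4] * t - y

    x0 = _initial_guess(t, y)
    starts = [x0]
    for fc, fd in options.perturbations:
        starts.append(np.array([x0[0], x0[1], x0[2] * fc, x0[3] * fd, x0[4]]))

    best = None
    for start in starts:
        start = np.clip(start, lower, upper)
        start[3] = min(max(start[3], lower[3] * 1.001), upper[3] * 0.999)
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(lower, upper),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                max_nfev=options.max_nfev,
            )
        except Exception:
            continue
        if not res.success:
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0] - 1e-15 or (abs(ssr - best[0]) <= 1e-15 and res.x[3] < best[1].x[3]):
            best = (ssr, res)

    if best is None:
        return SigmoidFit(
            params=failure_params,
            r_squared=float("-inf"),
            converged=False,
            n_points=t.size,
            residual_sum_squares=float("inf"),
            well_id=curve.well,
            is_reference=curve.metadata.is_reference,
            induced=curve.metadata.induced,
        )

    ssr, res = best
    params = SigmoidParams(*[float(v) for v in res.x])
    return SigmoidFit(
        params=params,
        r_squared=r_squared(curve, params),
        converged=True,
        n_points=t.size,
        residual_sum_squares=ssr,
        well_id=curve.well,
        is_reference=curve.metadata.is_reference,
        induced=curve.metadata.induced,
    )


def r_squared(curve: CultureRecord, params: SigmoidParams) -> float:
    """Coefficient of determination of the model on the raw signal.

    R² = 1 − SS_res/SS_tot with SS_tot about the signal mean; unbounded
    below, 1 for a perfect fit. Raw (not SNV) scattered light is used.
    """
    y = curve.scattered_light
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        raise DegenerateCurveError(f"{curve.well}: constant signal, R² undefined")
    ss_res = float(np.sum((extended_sigmoid(curve.times, params) - y) ** 2))
    return 1.0 - ss_res / ss_tot


def filter_fits(
    fits: list[SigmoidFit], threshold: float = DEFAULT_R2_THRESHOLD
) -> tuple[list[SigmoidFit], list[tuple[SigmoidFit, str]]]:
    """Split fits into kept (converged and R² > threshold) and excluded.

    Each excluded fit carries a reason tag; non-convergence takes
    precedence over a low R².
    """
    kept: list[SigmoidFit] = []
    excluded: list[tuple[SigmoidFit, str]] = []
    for fit in fits:
        if not fit.converged:
            excluded.append((fit, EXCLUDED_NOT_CONVERGED))
        elif fit.r_squared > threshold:
            kept.append(fit)
        else:
            excluded.append((fit, EXCLUDED_LOW_R2))
    return kept, excluded
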