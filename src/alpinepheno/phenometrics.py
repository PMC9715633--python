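"""Per-unit trajectory smoothing and phenological timepoint extraction.

Each experimental unit's seasonal series (leaf length, canopy greenness,
root area or vigour, scaled to percent of maximum) is fitted with a
penalized cubic B-spline: at most ``max_knots`` basis functions, with the
smoothing parameter selected by generalized cross-validation (GCV).
Scalar phenometrics (peak, quantile and maximum-rate dates, area under the
curve) are read off the fitted curve on a daily grid; the 50%-decline date
is interpolated between raw measurements instead, by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidInputError,
)
from .series import MeasurementSeries, SeasonWindow

__all__ = [
    "SmootherConfig",
    "SmoothFit",
    "PhenoMetrics",
    "scale_series",
    "fit_smoother",
    "peak_date",
    "half_decline_date",
    "quantile_date",
    "max_rate_date",
    "auc",
    "root_onset",
    "extract_metrics",
]

#: OLS slope (percent per day) a 3-point window must exceed for root onset.
ONSET_SLOPE_THRESHOLD = 0.5


@dataclass
class SmootherConfig:
    """Settings for the penalized-spline smoother.

    ``max_knots`` caps the number of B-spline basis functions (default 8);
    the effective number also shrinks with sample size.  ``lam_grid``
    is the log-spaced candidate grid for the GCV search.
    """

    max_knots: int = 8
    min_points: int = 4
    daily_grid_step: float = 1.0
    degree: int = 3
    lam_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-5, 7, 61)
    )

    def __post_init__(self) -> None:
        if self.max_knots < 4:
            raise InvalidInputError("max_knots must be >= 4")


@dataclass
class SmoothFit:
    """A fitted smoother evaluated on a daily grid."""

    unit_id: str
    variable: str
    grid: np.ndarray
    fitted_curve: np.ndarray
    edf: float
    r2: float
    residual_sd: float
    lam: float
    spline: BSpline

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.spline(np.asarray(x, dtype=float))


@dataclass
class PhenoMetrics:
    """Scalar timepoints and integrals for one unit and variable.

    Dates are day-of-year floats; ``None`` marks a sentinel (level never
    reached / rule never triggered).
    """

    unit_id: str
    group: str
    variable: str
    onset_doy: float | None = None
    peak_doy: float | None = None
    half_decline_doy: float | None = None
    q50_doy: float | None = None
    q80_doy: float | None = None
    max_rate_doy: float | None = None
    auc: float | None = None
    days_to_peak: float | None = None


def scale_series(s: MeasurementSeries, zero_at_start: bool = False) -> MeasurementSeries:
    """Scale a series to percent of its maximum (0-100).

    With ``zero_at_start`` (used for cumulative root area) the value at the
    first measurement is subtracted before scaling, so the series starts at
    0 and its seasonal maximum maps to 100.
    """
    v = s.value
    if np.ptp(v) == 0:
        raise DegenerateSeriesError(f"unit {s.unit_id}: constant series cannot be scaled")
    v0 = v[0] if zero_at_start else 0.0
    span = np.max(v) - v0
    if span <= 0:
        raise DegenerateSeriesError(
            f"unit {s.unit_id}: series has no positive range after zeroing"
        )
    return s.with_values(100.0 * (v - v0) / span, scaled=True)


def _basis(x: np.ndarray, n_basis: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with quantile-placed interior knots."""
    lo, hi = x[0], x[-1]
    n_interior = n_basis - (degree + 1)
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs)
    else:
        interior = np.array([])
    t = np.concatenate([np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)])
    # nudge the last point inside the support so design_matrix accepts it
    xe = np.clip(x, lo, np.nextafter(hi, lo))
    B = BSpline.design_matrix(xe, t, degree).toarray()
    return B, t


def fit_smoother(s: MeasurementSeries, cfg: SmootherConfig | None = None) -> SmoothFit:
    """Fit a GCV-penalized spline and evaluate it on a daily grid.

    The penalty is a second-order difference on the basis coefficients
    (P-spline); GCV(lam) = n*RSS / (n - edf)^2 is minimized over
    ``cfg.lam_grid``.
    """
    cfg = cfg or SmootherConfig()
    n = len(s)
    if n < cfg.min_points:
        raise InsufficientDataError(
            f"unit {s.unit_id}: {n} points < minimum {cfg.min_points}"
        )
    x, y = s.doy, s.value
    n_basis = min(cfg.max_knots, n)
    B, t = _basis(x, n_basis, cfg.degree)

    D = np.diff(np.eye(n_basis), n=2, axis=0)
    BtB = B.T @ B
    Bty = B.T @ y
    P = D.T @ D

    best = None
    for lam in np.atleast_1d(cfg.lam_grid):
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            Ainv_Bt = np.linalg.solve(A, B.T)
        except np.linalg.LinAlgError:  # pragma: no cover - grid extremes
            continue
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(B @ Ainv_Bt))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted, edf, rss)
    if best is None:  # pragma: no cover
        raise InvalidInputError("smoother failed for every smoothing value")

    _, lam, coef, fitted, edf, rss = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    resid_df = max(n - edf, 1.0)
    spline = BSpline(t, coef, cfg.degree, extrapolate=False)

    grid = np.arange(x[0], x[-1] + 0.5 * cfg.daily_grid_step, cfg.daily_grid_step)
    gx = np.clip(grid, x[0], np.nextafter(x[-1], x[0]))
    curve = spline(gx)
    return SmoothFit(
        unit_id=s.unit_id,
        variable=s.variable,
        grid=grid,
        fitted_curve=curve,
        edf=edf,
        r2=float(np.clip(r2, 0.0, 1.0)),
        residual_sd=float(np.sqrt(rss / resid_df)),
        lam=float(lam),
        spline=spline,
    )


def peak_date(fit: SmoothFit) -> float:
    """Day of the fitted curve's maximum (earliest day on ties)."""
    i = int(np.argmax(fit.fitted_curve))
    if i == fit.grid.size - 1 and fit.grid.size > 1:
        warnings.warn(
            f"unit {fit.unit_id}: fitted curve peaks at the series boundary",
            stacklevel=2,
        )
    return float(fit.grid[i])


def half_decline_date(s: MeasurementSeries, peak_doy: float) -> float | None:
    """Date of decline to 50% of the peak, interpolated on raw measurements.

    Uses the last post-peak measurement above 50% of the measured maximum
    and the first at or below it.  Returns ``None`` when the series never
    reaches 50%.
    """
    thr = 0.5 * float(np.max(s.value))
    post = s.doy >= peak_doy
    d, v = s.doy[post], s.value[post]
    below = np.nonzero(v <= thr)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if v[i] == thr:
        return float(d[i])
    if i == 0:
        # first post-peak measurement already below: no bracketing pair
        return float(d[0])
    j = i - 1
    frac = (v[j] - thr) / (v[j] - v[i])
    return float(d[j] + frac * (d[i] - d[j]))


def quantile_date(fit: SmoothFit, q: float) -> float:
    """First day the fitted cumulative curve reaches ``q`` of its maximum."""
    if not 0.0 < q <= 1.0:
        raise InvalidInputError(f"quantile must be in (0, 1], got {q}")
    curve = fit.fitted_curve
    peak = float(np.max(curve))
    if peak <= 0:
        raise InvalidInputError("fitted seasonal gain is not positive")
    target = q * peak
    idx = np.nonzero(curve >= target)[0]
    i = int(idx[0])
    if i == 0:
        return float(fit.grid[0])
    lo, hi = curve[i - 1], curve[i]
    frac = (target - lo) / (hi - lo) if hi > lo else 1.0
    return float(fit.grid[i - 1] + frac * (fit.grid[i] - fit.grid[i - 1]))


def max_rate_date(fit: SmoothFit) -> float:
    """Day of the steepest daily increase of the fitted curve."""
    rates = np.diff(fit.fitted_curve)
    if rates.size == 0:
        return float(fit.grid[0])
    if np.max(rates) <= 0:
        warnings.warn(
            f"unit {fit.unit_id}: curve never increases; max-rate date is nominal",
            stacklevel=2,
        )
    return float(fit.grid[int(np.argmax(rates))])


def auc(fit: SmoothFit, window: SeasonWindow) -> float:
    """Area under the fitted curve over ``[start, end)`` in percent-days.

    Rectangle rule at the daily grid step; negative fitted values are
    clipped to zero.  The window is clipped to the fitted range (with a
    warning) and an empty overlap is an error.
    """
    lo, hi = window.start_doy, window.end_doy
    if lo < fit.grid[0] or hi > fit.grid[-1] + fit.step:
        warnings.warn(
            f"unit {fit.unit_id}: window [{lo}, {hi}) clipped to fitted range",
            stacklevel=2,
        )
    mask = (fit.grid >= lo) & (fit.grid < hi)
    if not np.any(mask):
        raise InvalidInputError("window does not overlap the fitted range")
    vals = np.clip(fit.fitted_curve[mask], 0.0, None)
    return float(np.sum(vals) * fit.step)


def root_onset(s: MeasurementSeries, slope_threshold: float = ONSET_SLOPE_THRESHOLD) -> float | None:
    """Start of root growth by the 3-point moving-window slope rule.

    Slides a window over three adjacent measurement dates; the onset is the
    first date of the first window whose OLS slope strictly exceeds
    ``slope_threshold`` (percent per day).  Returns ``None`` when no
    window qualifies.
    """
    if len(s) < 3:
        raise InsufficientDataError("root onset needs at least 3 measurement dates")
    d, v = s.doy, s.value
    for i in range(len(s) - 2):
        x = d[i : i + 3]
        y = v[i : i + 3]
        xc = x - x.mean()
        slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        if slope > slope_threshold:
            return float(x[0])
    return None


def extract_metrics(
    s: MeasurementSeries,
    window: SeasonWindow,
    cfg: SmootherConfig | None = None,
    fit: SmoothFit | None = None,
) -> tuple[PhenoMetrics, SmoothFit]:
    """Convenience wrapper: fit (if needed) and extract all metrics."""
    fit = fit or fit_smoother(s, cfg)
    cumulative = s.variable == "root_area"
    with warnings.catch_warnings():
        if cumulative:
            # cumulative curves legitimately peak at the boundary
            warnings.filterwarnings("ignore", message=".*peaks at the series boundary")
        pk = peak_date(fit)
    m = PhenoMetrics(unit_id=s.unit_id, group=s.group, variable=s.variable)
    m.peak_doy = pk
    m.days_to_peak = pk - window.start_doy
    m.max_rate_doy = max_rate_date(fit)
    if cumulative:
        m.onset_doy = root_onset(s) if len(s) >= 3 else None
        m.q50_doy = quantile_date(fit, 0.5)
        m.q80_doy = quantile_date(fit, 0.8)
    else:
        m.half_decline_doy = half_decline_date(s, pk)
    if s.variable == "greenness":
        clipped = SeasonWindow(
            window.unit_id,
            max(window.start_doy, float(fit.grid[0])),
            min(window.end_doy, float(fit.grid[-1]) + fit.step),
            source=window.source,
        )
        m.auc = auc(fit, clipped)
    return m, fit
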