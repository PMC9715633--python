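"""Photosynthetic vigour index and the study's comparison statistics.

The vigour index multiplies maximum leaf length, a diminishing-returns
leaf-count term, the intact (non-brown) fraction and chlorophyll content;
it is unitless once scaled to percent of the per-species-per-group maximum.
Group comparisons use a one-way linear model with pooled residual variance
and unadjusted pairwise contrasts; the repeated-measures max-vs-last
comparison reduces exactly to a paired t-test in the two-timepoint case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSeriesError, InvalidInputError

__all__ = [
    "VigourInputs",
    "ContrastResult",
    "vigour_index",
    "scale_vigour",
    "group_contrasts",
    "paired_change",
    "simple_regression",
    "RegressionResult",
]


@dataclass
class VigourInputs:
    max_leaf_length: float  # cm
    n_leaves: float  # count >= 0
    brown_fraction: float  # proportion in [0, 1]
    chlorophyll: float  # fluorescence-ratio units >= 0

    def __post_init__(self) -> None:
        if min(self.max_leaf_length, self.n_leaves, self.chlorophyll, self.brown_fraction) < 0:
            raise InvalidInputError("vigour inputs must be non-negative")
        if self.brown_fraction > 1:
            raise InvalidInputError("brown_fraction must be <= 1")


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    t: float
    df: float
    p_two_sided: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    se_slope: float
    r2: float
    F: float
    p: float
    n: int


def vigour_index(v: VigourInputs) -> float:
    """Composite proxy for photosynthetically active tissue.

    length x (1 + sqrt(n_leaves)) x (1 - brown_fraction) x chlorophyll.
    """
    return (
        v.max_leaf_length
        * (1.0 + np.sqrt(v.n_leaves))
        * (1.0 - v.brown_fraction)
        * v.chlorophyll
    )


def scale_vigour(values: np.ndarray) -> np.ndarray:
    """Scale one species-by-group series to percent of its maximum."""
    values = np.asarray(values, dtype=float)
    top = np.max(values) if values.size else 0.0
    if top <= 0:
        raise DegenerateSeriesError("vigour series has no positive maximum")
    return 100.0 * values / top


def group_contrasts(values: np.ndarray, groups: np.ndarray) -> list[ContrastResult]:
    """Unadjusted pairwise group-mean contrasts from a one-way linear model.

    The residual variance is pooled across all groups; each contrast is a
    two-sided t-test with N - g degrees of freedom.  No multiplicity
    correction is applied, matching how the contrasts are reported.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # preserve first-seen order
    if len(labels) < 2:
        raise InvalidInputError("need at least two groups")
    by = {g: values[groups == g] for g in labels}
    for g, v in by.items():
        if v.size < 2:
            warnings.warn(f"group {g!r} has < 2 units; df may be unreliable", stacklevel=2)
    n_total = values.size
    df = n_total - len(labels)
    if df < 1:
        raise InvalidInputError("no residual degrees of freedom")
    ss_resid = sum(float(np.sum((v - v.mean()) ** 2)) for v in by.values())
    s2 = ss_resid / df
    out = []
    for a, b in combinations(labels, 2):
        est = float(by[b].mean() - by[a].mean())
        se = float(np.sqrt(s2 * (1.0 / by[a].size + 1.0 / by[b].size)))
        if se == 0:
            tval, p = 0.0, 1.0
        else:
            tval = est / se
            p = float(2.0 * sps.t.sf(abs(tval), df))
        out.append(ContrastResult(f"{b} - {a}", est, se, float(tval), float(df), p))
    return out


def paired_change(max_vals: np.ndarray, last_vals: np.ndarray) -> ContrastResult:
    """Mean percent change between per-unit maximum and last value.

    Per unit, change = 100 * (last - max) / max; the paired t-test on these
    changes is the exact two-timepoint reduction of a mixed model with a
    unit random intercept.
    """
    max_vals = np.asarray(max_vals, dtype=float)
    last_vals = np.asarray(last_vals, dtype=float)
    if max_vals.shape != last_vals.shape or max_vals.size < 2:
        raise InvalidInputError("paired inputs of equal length >= 2 required")
    if np.any(max_vals == 0):
        raise InvalidInputError("percent change undefined where max is 0")
    delta = 100.0 * (last_vals - max_vals) / max_vals
    n = delta.size
    mean = float(delta.mean())
    sd = float(delta.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0:
        warnings.warn("degenerate variance: all paired changes identical", stacklevel=2)
        return ContrastResult("last - max (%)", mean, 0.0, 0.0, df, 1.0)
    tval = mean / se
    p = float(2.0 * sps.t.sf(abs(tval), df))
    return ContrastResult("last - max (%)", mean, float(se), float(tval), float(df), p)


def simple_regression(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with slope F-test (F = t^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need n >= 3 paired observations")
    if np.var(x) == 0:
        raise InvalidInputError("x is constant")
    res = sps.linregress(x, y)
    n = x.size
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        r2=float(res.rvalue**2),
        F=float(t**2),
        p=float(res.pvalue),
        n=n,
    )
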