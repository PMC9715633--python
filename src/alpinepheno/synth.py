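"""Synthetic study generator with known ground truth.

Emulates the study design end to end: three experimental groups whose
growing seasons start ~134 d and ~70 d early or naturally, soil-temperature
logs with a snow-covered near-0 degC phase and a fluctuating summer phase,
rise-peak-decline leaf/greenness trajectories (optionally with a partial
second greening), sigmoidal cumulative root-area series (optionally with a
late decline), plus canopy photographs and rhizotron scan stacks.

Trajectories are built from logistic pieces so that the defining truth
dates (peak, 50% decline, growth quantiles, onset-slope crossing) have
closed forms; every generator returns a :class:`TruthRecord` for recovery
tests.  All randomness flows through a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit, logit

from .errors import DegenerateSeriesError, InvalidInputError
from .imaging import MM_PER_INCH, RGBImage, RhizotronStack
from .season import TemperatureSeries
from .series import MeasurementSeries

__all__ = [
    "TruthRecord",
    "StudyDesign",
    "GroupSpec",
    "TrajectoryParams",
    "leaf_params",
    "greenness_params",
    "root_params",
    "gen_temperature",
    "gen_trajectory",
    "gen_canopy_image",
    "gen_rhizotron_stack",
    "default_sampling_dates",
    "default_design",
    "generate_study",
]


@dataclass
class TruthRecord:
    """Ground-truth quantities for one generated unit/series."""

    unit_id: str
    true_peak_doy: float | None = None
    true_half_decline_doy: float | None = None
    true_root_onset_doy: float | None = None
    true_q80_doy: float | None = None
    true_auc: float | None = None
    true_green_fraction: float | None = None
    true_root_area_series: np.ndarray | None = None
    curve: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)


@dataclass
class GroupSpec:
    name: str
    season_start_doy: float
    season_end_doy: float
    n_units: int

    def __post_init__(self) -> None:
        if self.season_start_doy >= self.season_end_doy:
            raise InvalidInputError("season_start_doy must precede season_end_doy")
        if self.n_units < 1:
            raise InvalidInputError("n_units must be >= 1")


@dataclass
class StudyDesign:
    groups: list[GroupSpec]
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "leaf_length_cm": 0.15,
            "greenness": 0.004,
            "root_area": 0.25,
        }
    )
    seed: int = 0
    anchor: str = "start"  # {"start", "calendar"}; calendar fixes the peak DOY
    calendar_peak_doy: float = 227.0
    year: int = 2021


# ---------------------------------------------------------------------------
# temperature


def gen_temperature(
    season_start: float,
    season_end: float,
    summer_mean: float = 10.0,
    diurnal_amp: float = 4.5,
    step: int = 1,
    seed: int = 0,
    noise_sd: float = 0.3,
    pre_season_days: int = 40,
    winter_mean: float = 0.2,
    winter_sd: float = 0.1,
    unit_id: str = "T0",
    year: int = 2021,
) -> TemperatureSeries:
    """Soil-temperature series: snow-covered baseline, then summer regime.

    Before ``season_start`` values are ~N(winter_mean, winter_sd^2) clipped
    at -0.5 degC with no diurnal cycle; from ``season_start`` on, a constant
    seasonal mean plus a sinusoidal diurnal cycle (amplitude
    ``diurnal_amp``, warmest mid-afternoon) plus Gaussian noise.
    """
    if step not in (1, 2):
        raise InvalidInputError("step must be 1 or 2 hours")
    if diurnal_amp < 0:
        raise InvalidInputError("diurnal_amp must be >= 0")
    if season_end <= season_start:
        raise InvalidInputError("non-positive season duration")
    rng = np.random.default_rng(seed)
    t0 = max(1.0, season_start - pre_season_days)
    hours = np.arange(t0 * 24.0, season_end * 24.0, step)
    doy = hours / 24.0
    hod = hours % 24.0
    temp = np.empty_like(doy)
    pre = doy < season_start
    temp[pre] = np.clip(rng.normal(winter_mean, winter_sd, pre.sum()), -0.5, None)
    n_post = (~pre).sum()
    temp[~pre] = (
        summer_mean
        + diurnal_amp * np.sin(2 * np.pi * (hod[~pre] - 8.0) / 24.0)
        + (rng.normal(0.0, noise_sd, n_post) if noise_sd > 0 else 0.0)
    )
    origin = pd.Timestamp(year=year, month=1, day=1)
    stamps = origin + pd.to_timedelta(hours - 24.0, unit="h")
    return TemperatureSeries(unit_id=unit_id, timestamps=pd.DatetimeIndex(stamps), temp=temp)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryParams:
    """Parameters of one noise-free seasonal trajectory.

    Leaf/greenness: an asymmetric C1 bell — Gaussian flanks of width
    ``rise_width`` (left) and ``decline_width`` (right) joined at
    ``peak_doy`` — rising from ``baseline`` (hit exactly at season start)
    to ``peak_value``, optionally with a compact second-greening bump
    placed after the 50%-decline date.  Root: cumulative logistic anchored
    at 0 at season start, optionally with an exponential late loss after
    ``late_loss_start``.  All truth dates have closed forms; a sharper
    piecewise-logistic junction at the peak would bias every smoother of
    the allowed rank by several days.
    """

    kind: str  # {"leaf", "greenness", "root"}
    season_start: float
    season_end: float
    baseline: float = 0.0
    peak_value: float = 100.0
    peak_doy: float = 0.0
    rise_width: float = 18.0
    decline_width: float = 32.0
    second_amp: float = 0.0
    second_doy: float = 0.0
    second_width: float = 12.0
    growth_rate: float = 0.05  # root logistic steepness
    growth_mid: float = 0.0  # root logistic midpoint
    amplitude: float = 16.0  # root asymptotic gain
    late_loss_frac: float = 0.0
    late_loss_start: float = 0.0
    late_loss_tau: float = 40.0


def leaf_params(season_start: float, season_end: float, **kw) -> TrajectoryParams:
    """Leaf-length defaults: 0.5 cm at season start, peak ~44 d later."""
    p = TrajectoryParams(
        kind="leaf",
        season_start=season_start,
        season_end=season_end,
        baseline=0.5,
        peak_value=9.4,
        peak_doy=season_start + 44.0,
        rise_width=26.0,
        decline_width=30.0,
    )
    return replace(p, **kw)


def greenness_params(season_start: float, season_end: float, **kw) -> TrajectoryParams:
    """Canopy-greenness defaults: index units, peak ~39 d after start."""
    p = TrajectoryParams(
        kind="greenness",
        season_start=season_start,
        season_end=season_end,
        baseline=0.04,
        peak_value=0.44,
        peak_doy=season_start + 39.0,
        rise_width=18.0,
        decline_width=24.0,
    )
    return replace(p, **kw)


def root_params(season_start: float, season_end: float, **kw) -> TrajectoryParams:
    """Cumulative root-area defaults: sigmoid, 80% gain ~2 months in."""
    p = TrajectoryParams(
        kind="root",
        season_start=season_start,
        season_end=season_end,
        growth_rate=0.05,
        growth_mid=season_start + 35.0,
        amplitude=16.0,
    )
    return replace(p, **kw)


def _rise_decline_curve(p: TrajectoryParams) -> tuple[Callable, TruthRecord]:
    s0, tp = p.season_start, p.peak_doy
    if not s0 < tp < p.season_end:
        raise InvalidInputError("peak_doy must lie inside the season")
    if p.rise_width <= 0 or p.decline_width <= 0:
        raise InvalidInputError("flank widths must be positive")
    b, P = p.baseline, p.peak_value
    if P <= b:
        raise InvalidInputError("peak_value must exceed baseline")
    wr, wd = p.rise_width, p.decline_width
    er0 = np.exp(-((s0 - tp) ** 2) / (2.0 * wr**2))
    if er0 >= 1.0 - 1e-12:
        raise InvalidInputError("rise flank degenerate: season start at the peak")

    # closed-form 50%-of-peak crossing on the decline flank
    t_half = None
    if P / 2.0 > b:
        th = tp + wd * np.sqrt(2.0 * np.log((P - b) / (P / 2.0 - b)))
        if th < p.season_end:
            t_half = float(th)

    # second-greening bump: compact support, strictly after the 50% date
    amp2, t2, w2 = p.second_amp, p.second_doy, p.second_width
    if amp2 > 0:
        floor = (t_half if t_half is not None else tp) + 4.0 * w2 + 1.0
        t2 = max(t2, floor)

    def curve(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        er = np.exp(-((t - tp) ** 2) / (2.0 * wr**2))
        rise = b + (P - b) * (er - er0) / (1.0 - er0)
        decl = b + (P - b) * np.exp(-((t - tp) ** 2) / (2.0 * wd**2))
        out = np.where(t <= tp, rise, decl)
        if amp2 > 0:
            bump = amp2 * np.exp(-((t - t2) ** 2) / (2.0 * w2**2))
            out = out + np.where(t >= t2 - 4.0 * w2, bump, 0.0)
        return out

    truth = TruthRecord(unit_id="", true_peak_doy=float(tp), true_half_decline_doy=t_half)
    return curve, truth


def _root_curve(p: TrajectoryParams) -> tuple[Callable, TruthRecord]:
    s0, k, m, A = p.season_start, p.growth_rate, p.growth_mid, p.amplitude
    if k <= 0 or A <= 0:
        raise InvalidInputError("rates must be positive")
    sig0 = expit(k * (s0 - m))
    t_max = p.late_loss_start if p.late_loss_frac > 0 else p.season_end
    if not s0 < t_max <= p.season_end:
        raise InvalidInputError("late_loss_start must lie inside the season")
    g_max = A * (expit(k * (t_max - m)) - sig0)

    def base(t: np.ndarray) -> np.ndarray:
        return A * (expit(k * (t - m)) - sig0)

    def curve(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = base(np.minimum(t, t_max))
        if p.late_loss_frac > 0:
            dt = np.clip(t - t_max, 0.0, None)
            out = out * (1.0 - p.late_loss_frac * (1.0 - np.exp(-dt / p.late_loss_tau)))
        return out

    # q80: first crossing of 80% of the seasonal maximum (closed form)
    target = sig0 + 0.8 * (expit(k * (t_max - m)) - sig0)
    t_q80 = float(m + logit(target) / k)

    # onset: scaled slope d(100 g / g_max)/dt first exceeds 0.5 %/d
    c_on = 0.005 * g_max / (A * k)
    t_onset = None
    if c_on < 0.25:
        sig_on = (1.0 - np.sqrt(1.0 - 4.0 * c_on)) / 2.0
        cand = float(m + logit(sig_on) / k)
        t_onset = max(cand, s0)

    truth = TruthRecord(
        unit_id="",
        true_peak_doy=float(t_max),
        true_q80_doy=t_q80,
        true_root_onset_doy=t_onset,
    )
    return curve, truth


def gen_trajectory(
    kind: str,
    params: TrajectoryParams,
    sampling_dates: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    unit_id: str = "U0",
    group: str = "g",
) -> tuple[MeasurementSeries, TruthRecord]:
    """Sample a noise-free trajectory at the given dates and add noise.

    Returns the measured series plus a :class:`TruthRecord` holding the
    analytic peak/half-decline/quantile dates of the noise-free curve (the
    record also carries the curve itself for oracle checks).
    """
    dates = np.asarray(sorted(sampling_dates), dtype=float)
    if dates.size == 0 or dates[-1] < params.season_start:
        raise DegenerateSeriesError("all sampling dates precede the season")
    if kind != params.kind:
        raise InvalidInputError(f"params are for kind {params.kind!r}, not {kind!r}")
    if kind == "root":
        curve, truth = _root_curve(params)
        variable = "root_area"
    elif kind in ("leaf", "greenness"):
        curve, truth = _rise_decline_curve(params)
        variable = "leaf_length_cm" if kind == "leaf" else "greenness"
    else:
        raise InvalidInputError(f"unknown trajectory kind {kind!r}")

    values = curve(dates)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, dates.size)
    truth.unit_id = unit_id
    truth.curve = curve

    if kind == "greenness":
        # area under the scaled (percent-of-max) noise-free curve, fine grid
        tgrid = np.arange(params.season_start, params.season_end, 0.01)
        cg = curve(tgrid)
        truth.true_auc = float(np.trapezoid(100.0 * cg / cg.max(), tgrid))
    if kind == "root":
        truth.true_root_area_series = curve(dates)

    series = MeasurementSeries(
        unit_id=unit_id, group=group, variable=variable, doy=dates, value=values
    )
    return series, truth


def default_sampling_dates(
    season_start: float,
    season_end: float,
    dense_days: int = 30,
    dense_step: float = 3.5,
    sparse_step: float = 10.0,
) -> np.ndarray:
    """Twice-weekly visits for the first month, then longer intervals."""
    dense = np.arange(season_start, season_start + dense_days, dense_step)
    sparse = np.arange(season_start + dense_days, season_end + 1e-9, sparse_step)
    return np.round(np.concatenate([dense, sparse]), 1)


# ---------------------------------------------------------------------------
# canopy images


def gen_canopy_image(
    width: int,
    height: int,
    green_fraction: float,
    green_rgb: tuple[int, int, int] = (60, 140, 60),
    brown_rgb: tuple[int, int, int] = (120, 100, 70),
    jitter: float = 0.0,
    seed: int = 0,
    unit_id: str = "U0",
) -> tuple[RGBImage, TruthRecord]:
    """Two-population RGB raster with an exact green-pixel fraction.

    Exactly ``round(green_fraction * width * height)`` pixels are drawn
    from ``green_rgb`` (optionally jittered), the rest from ``brown_rgb``.
    """
    if not 0.0 <= green_fraction <= 1.0:
        raise InvalidInputError("green_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = width * height
    n_green = int(round(green_fraction * n))
    flat = np.empty((n, 3), dtype=float)
    flat[:] = brown_rgb
    idx = rng.permutation(n)[:n_green]
    flat[idx] = green_rgb
    if jitter > 0:
        flat += rng.normal(0.0, jitter, flat.shape)
    pixels = np.clip(np.round(flat), 0, 255).astype(np.uint8).reshape(height, width, 3)
    truth = TruthRecord(unit_id=unit_id, true_green_fraction=n_green / n)
    return RGBImage(pixels=pixels), truth


# ---------------------------------------------------------------------------
# rhizotron stacks


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def _stroke_points(
    shape: tuple[int, int], rng: np.random.Generator, length: float
) -> np.ndarray:
    """Sampled centre-line of one curvilinear (quadratic Bezier) stroke."""
    H, W = shape
    p0 = rng.uniform([0, 0], [H - 1, W - 1])
    ang = rng.uniform(0, 2 * np.pi)
    p2 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
    mid = (p0 + p2) / 2.0
    ctrl = mid + rng.normal(0.0, length / 4.0, 2)
    ts = np.linspace(0.0, 1.0, max(int(2 * length), 8))[:, None]
    return (1 - ts) ** 2 * p0 + 2 * (1 - ts) * ts * ctrl + ts**2 * p2


def _rasterize(pts: np.ndarray, shape: tuple[int, int], half_width: int) -> np.ndarray:
    """Boolean mask of a polyline thickened to the given half-width."""
    H, W = shape
    pix = np.round(pts).astype(int)
    keep = (pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)
    canvas = np.zeros(shape, dtype=bool)
    canvas[pix[keep, 0], pix[keep, 1]] = True
    if not canvas.any() or half_width < 1:
        return canvas
    return ndi.binary_dilation(canvas, structure=_disk(half_width))


def _soil_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Fine-grained soil background: lightly smoothed noise around mid-grey."""
    noise = rng.normal(0.0, 1.0, shape)
    tex = ndi.gaussian_filter(noise, 1.5)
    tex *= 8.0 / tex.std()
    return 95.0 + tex


def gen_rhizotron_stack(
    n_dates: int,
    image_size: tuple[int, int] = (512, 512),
    root_schedule: Sequence[float] | None = None,
    stripe_amp: float = 0.0,
    shifts: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    dpi: float = 1200.0,
    root_half_width_px: int = 5,
    root_level: float = 185.0,
    sensor_noise_sd: float = 2.0,
    area_tol: float = 0.02,
    unit_id: str = "U0",
    doys: Sequence[float] | None = None,
) -> tuple[RhizotronStack, TruthRecord]:
    """Synthetic scan stack: textured soil + growing bright root strokes.

    ``root_schedule`` gives cumulative target root areas (mm^2 cm^-2) per
    date; each date's truth mask hits its target within ``area_tol``.
    Column-constant stripes of amplitude ``stripe_amp`` and per-date planar
    shifts are applied after rendering, emulating acquisition artifacts.
    Truth masks are returned in the unshifted (aligned) frame.
    """
    H, W = image_size
    root_schedule = list(root_schedule if root_schedule is not None else [])
    if len(root_schedule) > n_dates:
        raise InvalidInputError("root_schedule longer than n_dates")
    if np.any(np.diff(root_schedule) < 0):
        raise InvalidInputError("root_schedule must be non-decreasing")
    while len(root_schedule) < n_dates:
        root_schedule.append(root_schedule[-1] if root_schedule else 0.0)
    shifts = list(shifts if shifts is not None else [(0, 0)] * n_dates)
    if len(shifts) != n_dates:
        raise InvalidInputError("one (dx, dy) shift per date required")
    for dx, dy in shifts:
        if abs(dx) >= W / 4 or abs(dy) >= H / 4:
            raise InvalidInputError("shifts must stay below a quarter of the image")

    rng = np.random.default_rng(seed)
    px_mm = MM_PER_INCH / dpi
    px_area_mm2 = px_mm**2
    image_area_cm2 = H * W * px_area_mm2 / 100.0

    # render on a larger canvas so per-date shifts are content shifts
    # (windowing), not edge-filled translations with seam artifacts
    pad = int(max(max(abs(dx) for dx, _ in shifts), max(abs(dy) for _, dy in shifts)))
    CH, CW = H + 2 * pad, W + 2 * pad
    background = _soil_texture((CH, CW), rng)
    canvas_mask = np.zeros((CH, CW), dtype=bool)
    center = (slice(pad, pad + H), slice(pad, pad + W))
    images, masks, areas = [], [], []
    for k in range(n_dates):
        target_px = root_schedule[k] * image_area_cm2 / px_area_mm2
        guard = 0
        while target_px > 0 and canvas_mask[center].sum() < (1.0 - area_tol) * target_px:
            guard += 1
            if guard > 500:  # pragma: no cover - safety valve
                break
            deficit = target_px - canvas_mask[center].sum()
            length = float(np.clip(deficit / (2 * root_half_width_px), 8, 150))
            pts = _stroke_points((CH, CW), rng, length)
            # trim the stroke rather than overshoot; the smallest unit is a
            # single full-width disk, so width (hence segmentability) is kept
            for frac in (1.0, 0.5, 0.25, 0.12, 0.06, 0.01):
                n_pts = max(2, int(len(pts) * frac))
                stroke = _rasterize(pts[:n_pts], (CH, CW), root_half_width_px)
                new = canvas_mask | stroke
                if new[center].sum() <= (1.0 + area_tol) * target_px:
                    canvas_mask = new
                    break
        canvas = background.copy()
        canvas[canvas_mask] = root_level + rng.normal(0.0, 4.0, int(canvas_mask.sum()))
        canvas = ndi.gaussian_filter(canvas, 0.6)
        dx, dy = shifts[k]
        # acquired frame shifted by (+dx, +dy) means the window moves opposite
        win = (slice(pad - dy, pad - dy + H), slice(pad - dx, pad - dx + W))
        img = canvas[win].copy()
        if stripe_amp > 0:
            img = img + stripe_amp * rng.standard_normal(W)[None, :]
        if sensor_noise_sd > 0:
            img = img + rng.normal(0.0, sensor_noise_sd, (H, W))
        images.append(np.clip(img, 0.0, 255.0))
        masks.append(canvas_mask[center].copy())
        areas.append(canvas_mask[center].sum() * px_area_mm2 / image_area_cm2)

    stack = RhizotronStack(
        images=images,
        doys=list(doys) if doys is not None else list(range(n_dates)),
        dpi=dpi,
        shifts=[(int(dx), int(dy)) for dx, dy in shifts],
        masks=masks,
        root_area=areas,
    )
    truth = TruthRecord(unit_id=unit_id, true_root_area_series=np.asarray(areas))
    return stack, truth


# ---------------------------------------------------------------------------
# whole-study generation


def default_design(seed: int = 0, anchor: str = "start") -> StudyDesign:
    """Three groups: season advanced by ~134 d, ~70 d, and natural start."""
    return StudyDesign(
        groups=[
            GroupSpec("plus4m", 49.0, 288.0, 8),
            GroupSpec("plus2m", 113.0, 288.0, 8),
            GroupSpec("field", 183.0, 288.0, 5),
        ],
        seed=seed,
        anchor=anchor,
    )


def generate_study(design: StudyDesign) -> dict:
    """Generate measurements, temperatures and truth for a whole study.

    Returns a dict with keys ``series`` (list of MeasurementSeries),
    ``temperature`` (list of TemperatureSeries), ``truth`` (dict keyed by
    (unit_id, variable)) and ``windows`` (unit_id -> (start, end, group)).
    """
    master = np.random.default_rng(design.seed)
    series: list[MeasurementSeries] = []
    temps: list[TemperatureSeries] = []
    truth: dict[tuple[str, str], TruthRecord] = {}
    windows: dict[str, tuple[float, float, str]] = {}
    for g in design.groups:
        dates = default_sampling_dates(g.season_start_doy, g.season_end_doy)
        for i in range(g.n_units):
            uid = f"{g.name}_{i + 1:02d}"
            sub = np.random.default_rng(master.integers(2**63))
            windows[uid] = (g.season_start_doy, g.season_end_doy, g.name)

            if design.anchor == "calendar":
                peak = design.calendar_peak_doy + sub.normal(0.0, 3.0)
                peak = float(np.clip(peak, g.season_start_doy + 5, g.season_end_doy - 30))
            else:
                peak = g.season_start_doy + 44.0 + sub.normal(0.0, 3.0)

            lp = leaf_params(
                g.season_start_doy,
                g.season_end_doy,
                peak_doy=peak,
                peak_value=9.4 + sub.normal(0.0, 0.6),
                decline_width=30.0 + sub.normal(0.0, 1.5),
            )
            s, t = gen_trajectory(
                "leaf", lp, dates, design.noise_sd["leaf_length_cm"],
                seed=int(sub.integers(2**31)), unit_id=uid, group=g.name,
            )
            series.append(s)
            truth[(uid, "leaf_length_cm")] = t

            gpk = peak - 5.0
            gp = greenness_params(
                g.season_start_doy,
                g.season_end_doy,
                peak_doy=gpk,
                decline_width=24.0 + sub.normal(0.0, 1.5),
                second_amp=0.03 if g.name != "field" else 0.0,
                second_doy=gpk + 90.0,
            )
            s, t = gen_trajectory(
                "greenness", gp, dates, design.noise_sd["greenness"],
                seed=int(sub.integers(2**31)), unit_id=uid, group=g.name,
            )
            series.append(s)
            truth[(uid, "greenness")] = t

            rp = root_params(
                g.season_start_doy,
                g.season_end_doy,
                growth_mid=g.season_start_doy + 35.0 + sub.normal(0.0, 2.0),
                amplitude=16.0 + sub.normal(0.0, 1.5),
                late_loss_frac=0.2 if g.name == "plus4m" else 0.0,
                late_loss_start=g.season_start_doy + 120.0,
            )
            s, t = gen_trajectory(
                "root", rp, dates, design.noise_sd["root_area"],
                seed=int(sub.integers(2**31)), unit_id=uid, group=g.name,
            )
            series.append(s)
            truth[(uid, "root_area")] = t

            temps.append(
                gen_temperature(
                    g.season_start_doy,
                    g.season_end_doy,
                    seed=int(sub.integers(2**31)),
                    unit_id=uid,
                    year=design.year,
                )
            )
    return {"series": series, "temperature": temps, "truth": truth, "windows": windows}
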