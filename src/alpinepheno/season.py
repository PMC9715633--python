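"""Season windows, temperature summaries and microsite growth rates.

Season start is detected from shallow soil temperature: under snow the
soil sits near 0 degC with almost no diurnal variation, so the first run of
days with warm means *and* a restored diurnal cycle marks snow
disappearance.  Season end is configured per year (it was set manually
from weather events, not detected).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidInputError, NoSeasonError
from .series import MeasurementSeries, SeasonWindow

__all__ = [
    "TemperatureSeries",
    "RateRecord",
    "STUDY_SEASON_ENDS",
    "detect_season_start",
    "season_end",
    "mean_temp",
    "gdh",
    "pool_visits",
    "phase_rates",
]

#: Configured meteorological season ends (month, day) for the study years.
STUDY_SEASON_ENDS: dict[int, tuple[int, int]] = {2020: (9, 25), 2021: (10, 15)}


@dataclass
class TemperatureSeries:
    """Soil-temperature log at a uniform 1 h or 2 h step."""

    unit_id: str
    timestamps: pd.DatetimeIndex
    temp: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp = np.asarray(self.temp, dtype=float)
        if len(self.timestamps) != self.temp.size:
            raise InvalidInputError("timestamps and temp must have equal length")
        if len(self.timestamps) >= 2:
            steps = np.diff(self.timestamps.asi8) / 3.6e12  # hours
            if np.any(steps <= 0):
                raise InvalidInputError("timestamps must be strictly increasing")
            med = np.median(steps)
            if np.any(np.abs(steps - med) > 0.1 * med):
                raise InvalidInputError("logging step must be uniform within 10%")

    @property
    def step_hours(self) -> float:
        if len(self.timestamps) < 2:
            return 1.0
        return float(np.median(np.diff(self.timestamps.asi8)) / 3.6e12)

    @property
    def doy(self) -> np.ndarray:
        """Fractional day-of-year of each sample."""
        ts = self.timestamps
        frac = (ts.hour + ts.minute / 60.0) / 24.0
        return ts.dayofyear.to_numpy(dtype=float) + frac

    def daily_frame(self) -> pd.DataFrame:
        """Per-calendar-day mean, min and max temperature."""
        df = pd.DataFrame({"doy": self.timestamps.dayofyear, "temp": self.temp})
        g = df.groupby("doy")["temp"]
        out = pd.DataFrame({"mean": g.mean(), "min": g.min(), "max": g.max()})
        out["range"] = out["max"] - out["min"]
        return out


@dataclass
class RateRecord:
    """A single elongation or browning rate over one measurement interval."""

    unit_id: str
    phase: str  # {"elongation", "browning"}
    doy_a: float
    doy_b: float
    rate: float  # signed, units of the measurement per day
    mean_temp: float | None = None
    gdh: float | None = None


def detect_season_start(
    t: TemperatureSeries,
    temp_floor: float = 3.0,
    min_diurnal_range: float = 0.5,
    persist_days: int = 3,
) -> float:
    """First day of ``persist_days`` consecutive warm, fluctuating days.

    A day qualifies when its mean exceeds ``temp_floor`` (degC) and its
    diurnal range is at least ``min_diurnal_range`` (K).  Raises
    :class:`NoSeasonError` when no qualifying run exists.
    """
    daily = t.daily_frame()
    ok = ((daily["mean"] > temp_floor) & (daily["range"] >= min_diurnal_range)).to_numpy()
    days = daily.index.to_numpy(dtype=float)
    run = 0
    for i, good in enumerate(ok):
        consecutive = good and (run == 0 or days[i] - days[i - 1] == 1)
        run = run + 1 if consecutive else (1 if good else 0)
        if run >= persist_days:
            return float(days[i - persist_days + 1])
    raise NoSeasonError(f"unit {t.unit_id}: no {persist_days}-day qualifying run found")


def season_end(year: int, ends: dict[int, tuple[int, int]] | None = None) -> int:
    """Configured meteorological season end as a day-of-year."""
    ends = STUDY_SEASON_ENDS if ends is None else ends
    if year not in ends:
        raise InvalidInputError(f"no configured season end for year {year}")
    month, day = ends[year]
    return date(year, month, day).timetuple().tm_yday


def mean_temp(
    t: TemperatureSeries,
    window: SeasonWindow,
    first_n_days: int,
    min_coverage: float = 0.9,
) -> float:
    """Mean temperature over the first ``first_n_days`` days of the season."""
    if first_n_days <= 0:
        raise InvalidInputError("first_n_days must be positive")
    lo = window.start_doy
    hi = lo + first_n_days
    doy = t.doy
    mask = (doy >= lo) & (doy < hi)
    expected = first_n_days * 24.0 / t.step_hours
    if mask.sum() < min_coverage * expected:
        raise CoverageError(
            f"unit {t.unit_id}: {mask.sum()} samples cover < {min_coverage:.0%} "
            f"of [{lo}, {hi})"
        )
    return float(np.mean(t.temp[mask]))


def gdh(t: TemperatureSeries, interval: tuple[float, float], base: float = 5.0) -> float:
    """Growing degree hours above ``base`` over ``[doy_a, doy_b)``.

    Each sample contributes ``max(T - base, 0) * step_hours``.
    """
    lo, hi = interval
    doy = t.doy
    mask = (doy >= lo) & (doy < hi)
    excess = np.clip(t.temp[mask] - base, 0.0, None)
    return float(np.sum(excess) * t.step_hours)


def pool_visits(
    doys: np.ndarray, values: np.ndarray, max_gap_days: float = 7.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pool visits closer than ``max_gap_days`` onto their mean date.

    Greedy left-to-right: a visit joins the current pool while its gap to
    the pool's last member is strictly below the threshold.  Pooled value
    and date are plain means.
    """
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    if doys.size == 0:
        return doys, values
    if np.any(np.diff(doys) < 0):
        raise InvalidInputError("visit dates must be sorted")
    pooled_d, pooled_v = [], []
    cur_d, cur_v = [doys[0]], [values[0]]
    for d, v in zip(doys[1:], values[1:]):
        if d - cur_d[-1] < max_gap_days:
            cur_d.append(d)
            cur_v.append(v)
        else:
            pooled_d.append(np.mean(cur_d))
            pooled_v.append(np.mean(cur_v))
            cur_d, cur_v = [d], [v]
    pooled_d.append(np.mean(cur_d))
    pooled_v.append(np.mean(cur_v))
    return np.asarray(pooled_d), np.asarray(pooled_v)


def phase_rates(
    s: MeasurementSeries,
    season_start: float,
    peak_doy: float,
    half_decline_doy: float | None,
    temperature: TemperatureSeries | None = None,
    pre_peak_margin: float = 14.0,
    post_peak_margin: float = 14.0,
    post_half_margin: float = 7.0,
) -> list[RateRecord]:
    """Per-interval elongation and browning rates around the peak.

    Elongation rates come from consecutive measurement pairs lying fully in
    ``[season_start, peak - pre_peak_margin]``; browning rates from pairs in
    ``[peak + post_peak_margin, half_decline + post_half_margin]``.  The
    peak itself, where rates are intrinsically low, is excluded by
    construction.  When a temperature series is supplied each record also
    carries the interval's mean temperature and growing degree hours.
    """
    records: list[RateRecord] = []
    elong_hi = peak_doy - pre_peak_margin
    brown_lo = peak_doy + post_peak_margin
    brown_hi = half_decline_doy + post_half_margin if half_decline_doy is not None else None
    for a, b, va, vb in zip(s.doy[:-1], s.doy[1:], s.value[:-1], s.value[1:]):
        phase = None
        if a >= season_start and b <= elong_hi:
            phase = "elongation"
        elif brown_hi is not None and a >= brown_lo and b <= brown_hi:
            phase = "browning"
        if phase is None:
            continue
        rec = RateRecord(
            unit_id=s.unit_id,
            phase=phase,
            doy_a=float(a),
            doy_b=float(b),
            rate=float((vb - va) / (b - a)),
        )
        if temperature is not None:
            doy = temperature.doy
            mask = (doy >= a) & (doy < b)
            if mask.any():
                rec.mean_temp = float(np.mean(temperature.temp[mask]))
                rec.gdh = gdh(temperature, (float(a), float(b)))
        records.append(rec)
    return records
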