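"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phenometrics import PhenoMetrics
from .season import TemperatureSeries
from .series import MeasurementSeries
from .vigour_stats import ContrastResult

MEASUREMENT_COLUMNS = ["unit_id", "group", "doy", "variable", "value"]


def write_measurements(path: str | Path, series: list[MeasurementSeries]) -> None:
    rows = []
    for s in series:
        for d, v in zip(s.doy, s.value):
            rows.append((s.unit_id, s.group, d, s.variable, v))
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path: str | Path) -> list[MeasurementSeries]:
    df = pd.read_csv(path)
    out = []
    for (uid, grp, var), sub in df.groupby(["unit_id", "group", "variable"], sort=False):
        sub = sub.sort_values("doy")
        out.append(
            MeasurementSeries(
                unit_id=str(uid),
                group=str(grp),
                variable=str(var),
                doy=sub["doy"].to_numpy(),
                value=sub["value"].to_numpy(),
            )
        )
    return out


def write_temperature(path: str | Path, temps: list[TemperatureSeries]) -> None:
    frames = [
        pd.DataFrame(
            {
                "unit_id": t.unit_id,
                "timestamp": t.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "temp_C": t.temp,
            }
        )
        for t in temps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_temperature(path: str | Path) -> list[TemperatureSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        TemperatureSeries(
            unit_id=str(uid),
            timestamps=pd.DatetimeIndex(sub["timestamp"]),
            temp=sub["temp_C"].to_numpy(),
        )
        for uid, sub in df.groupby("unit_id", sort=False)
    ]


def write_metrics(path: str | Path, metrics: list[PhenoMetrics]) -> None:
    pd.DataFrame([asdict(m) for m in metrics]).to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_contrasts(path: str | Path, contrasts: list[ContrastResult], metric: str = "") -> None:
    df = pd.DataFrame([asdict(c) for c in contrasts])
    if metric:
        df.insert(0, "metric", metric)
    df.to_csv(path, index=False)


def write_truth(path: str | Path, truth: dict) -> None:
    """Truth records as JSON, keyed by 'unit_id/variable'."""
    payload = {}
    for (uid, var), rec in truth.items():
        d = asdict(rec)
        d.pop("curve", None)
        if isinstance(d.get("true_root_area_series"), np.ndarray):
            d["true_root_area_series"] = d["true_root_area_series"].tolist()
        payload[f"{uid}/{var}"] = d
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
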