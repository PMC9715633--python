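"""End-to-end orchestration: series -> seasons -> phenometrics -> statistics.

A single :class:`RunConfig` (loadable from YAML) is the sole source of
thresholds; every value actually used is echoed into the structured log so
runs are auditable.  Stage failures are re-raised as :class:`StageError`
with the stage name and unit id attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .errors import StageError
from .phenometrics import PhenoMetrics, SmootherConfig, extract_metrics, scale_series
from .season import TemperatureSeries, detect_season_start
from .series import MeasurementSeries, SeasonWindow
from .vigour_stats import group_contrasts

log = logging.getLogger("alpinepheno")


@dataclass
class RunConfig:
    """Thresholds and settings for a full pipeline run."""

    seed: int = 0
    max_knots: int = 8
    onset_slope: float = 0.5
    half_decline_level: float = 0.5
    quantiles: tuple[float, float] = (0.5, 0.8)
    season_temp_floor: float = 3.0
    season_min_diurnal_range: float = 0.5
    season_persist_days: int = 3
    detect_seasons: bool = False
    season_ends: dict = field(default_factory=dict)  # unit_id or group -> end doy
    anchor: str = "start"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if "quantiles" in known:
            cfg.quantiles = tuple(cfg.quantiles)
        return cfg

    def log_values(self) -> None:
        for k, v in vars(self).items():
            log.info("config %s = %r", k, v)


def run_pipeline(
    cfg: RunConfig,
    series: list[MeasurementSeries],
    windows: dict[str, tuple[float, float, str]],
    temperatures: list[TemperatureSeries] | None = None,
) -> dict:
    """Fit, extract and compare metrics for all units of a study.

    ``windows`` maps unit_id to (season_start, season_end, group).  When
    ``cfg.detect_seasons`` is set and a temperature series exists for a
    unit, the start is re-detected from temperature instead.

    Returns dict with ``metrics`` (list of PhenoMetrics), ``metrics_table``
    (DataFrame), ``group_summary`` and ``contrasts`` (DataFrames).
    """
    cfg.log_values()
    temps = {t.unit_id: t for t in (temperatures or [])}
    scfg = SmootherConfig(max_knots=cfg.max_knots)
    metrics: list[PhenoMetrics] = []
    for s in series:
        uid = s.unit_id
        try:
            start, end, group = windows[uid]
            if cfg.detect_seasons and uid in temps:
                start = detect_season_start(
                    temps[uid],
                    temp_floor=cfg.season_temp_floor,
                    min_diurnal_range=cfg.season_min_diurnal_range,
                    persist_days=cfg.season_persist_days,
                )
                log.info("unit %s: detected season start doy %.1f", uid, start)
            window = SeasonWindow(uid, start, end, source="detected" if cfg.detect_seasons else "configured")
            scaled = scale_series(s, zero_at_start=(s.variable == "root_area"))
            m, _fit = extract_metrics(scaled, window, scfg)
            metrics.append(m)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StageError("phenometrics", uid, exc) from exc

    table = pd.DataFrame(
        [
            {
                "unit_id": m.unit_id,
                "group": m.group,
                "variable": m.variable,
                "onset_doy": m.onset_doy,
                "peak_doy": m.peak_doy,
                "half_decline_doy": m.half_decline_doy,
                "q50_doy": m.q50_doy,
                "q80_doy": m.q80_doy,
                "max_rate_doy": m.max_rate_doy,
                "auc": m.auc,
                "days_to_peak": m.days_to_peak,
            }
            for m in metrics
        ]
    )
    summary = summarize_groups(table)
    contrasts = []
    for var, sub in table.groupby("variable", sort=False):
        sub = sub.dropna(subset=["days_to_peak"])
        if sub["group"].nunique() >= 2 and (sub.groupby("group").size() >= 2).all():
            for c in group_contrasts(sub["days_to_peak"].to_numpy(), sub["group"].to_numpy()):
                contrasts.append(
                    {
                        "variable": var,
                        "metric": "days_to_peak",
                        "label": c.label,
                        "estimate": c.estimate,
                        "se": c.se,
                        "t": c.t,
                        "df": c.df,
                        "p": c.p_two_sided,
                    }
                )
    return {
        "metrics": metrics,
        "metrics_table": table,
        "group_summary": summary,
        "contrasts": pd.DataFrame(contrasts),
    }


def summarize_groups(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-variable mean, SE (sd/sqrt(n)) and n for each metric.

    SE is reported as missing for single-unit groups.
    """
    value_cols = [
        c for c in metrics_table.columns if c not in ("unit_id", "group", "variable")
    ]
    rows = []
    for (grp, var), sub in metrics_table.groupby(["group", "variable"], sort=False):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            rows.append(
                {"group": grp, "variable": var, "metric": col, "mean": mean, "se": se, "n": vals.size}
            )
    return pd.DataFrame(rows)


def write_outputs(outdir: str | Path, result: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aio.write_metrics(outdir / "metrics.csv", result["metrics"])
    result["group_summary"].to_csv(outdir / "group_summary.csv", index=False)
    result["contrasts"].to_csv(outdir / "contrasts.csv", index=False)
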