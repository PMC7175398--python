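"""Measurement-to-xylem-water processing pipeline.

Takes cavity-ring-down style raw time series (water mole fraction in ppm,
raw delta-18O and delta-2H, stem temperature) organized in measurement
cycles, and produces QC'd, calibrated, liquid-equivalent xylem water
compositions, plus tracer breakthrough timing and lag-based sap velocity.

Pipeline stages
---------------
1. ``average_cycle`` -- mean and SD over the trailing window (default 3 min
   of a 15-min cycle), when the measured values have stabilized.
2. ``borehole_rh`` -- reconstruct relative humidity in the borehole from
   the measured mole fraction and the saturation mole fraction at stem
   temperature; diagnoses unsaturated boreholes and suspected condensation.
3. ``qc_filter`` -- flag cycles whose raw-delta SDs exceed 0.5 permil
   (18O) or 1.5 permil (2H), or whose borehole RH is below 0.8. Flagged
   records are retained with flags, never silently dropped.
4. ``fit_standards`` / ``calibrate`` -- per-species linear calibration in
   vapor-delta space against headspace standards whose target vapor values
   are their known liquid values shifted by equilibrium fractionation at
   the recorded headspace temperature.
5. ``vapor_to_liquid_delta`` -- convert calibrated vapor deltas to
   liquid-equivalent xylem water via alpha+(T).
6. ``breakthrough_midpoint`` / ``velocity_from_lag`` -- label arrival time
   from the plateau midpoint of a breakthrough curve, and sap velocity from
   the arrival lag between two boreholes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotope_physics import (
    P0,
    Species,
    delta_to_ratio,
    equilibrium_alpha,
    ratio_to_delta,
    saturation_mole_fraction,
)

__all__ = [
    "RAW_COLUMNS",
    "QCThresholds",
    "ProcessedRecord",
    "StandardSet",
    "BreakthroughResult",
    "read_raw_csv",
    "split_cycles",
    "average_cycle",
    "borehole_rh",
    "qc_filter",
    "fit_standards",
    "calibrate",
    "vapor_to_liquid_delta",
    "liquid_to_vapor_delta",
    "breakthrough_midpoint",
    "velocity_from_lag",
    "predicted_arrival_hours",
    "process_campaign",
]

#: Raw CSV columns (RFC 4180, UTF-8, ISO 8601 UTC timestamps).
RAW_COLUMNS = [
    "timestamp",
    "channel",
    "h2o_ppm",
    "d18o_raw",
    "d2h_raw",
    "t_stem_c",
]

_SD_COL = {Species.O18: "d18o_sd", Species.H2: "d2h_sd"}
_MEAN_COL = {Species.O18: "d18o_raw", Species.H2: "d2h_raw"}


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; boundaries are inclusive-pass (SD <= limit and
    h >= rh_min both pass)."""

    sd_limit_o18: float = 0.5
    sd_limit_h2: float = 1.5
    rh_min: float = 0.8


@dataclass
class ProcessedRecord:
    """One averaged, QC'd measurement cycle."""

    channel: str
    time: pd.Timestamp  # cycle end time
    w_mean: float  # mole fraction (dimensionless)
    w_sd: float
    delta_mean: dict[Species, float]
    delta_sd: dict[Species, float]
    t_stem_c: float
    pressure_pa: float = P0
    n_samples: int = 0
    h: float | None = None
    delta_cal: dict[Species, float] = field(default_factory=dict)
    delta_liquid: dict[Species, float] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags)


def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw measurement CSV; validates required columns."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw CSV missing columns: {missing}")
    return df


def split_cycles(
    df: pd.DataFrame, gap_seconds: float = 60.0
) -> list[pd.DataFrame]:
    """Split a raw per-sample table into measurement cycles.

    Cycles are contiguous runs per channel; a new cycle starts after a time
    gap larger than ``gap_seconds`` (the inter-cycle flush period) or if a
    ``cycle`` column is present, at each change of its value.
    """
    cycles: list[pd.DataFrame] = []
    for _, chan in df.groupby("channel", sort=False):
        chan = chan.sort_values("timestamp")
        if "cycle" in chan.columns:
            key = chan["cycle"]
        else:
            gaps = chan["timestamp"].diff().dt.total_seconds()
            key = (gaps > gap_seconds).cumsum()
        for _, cyc in chan.groupby(key, sort=False):
            cycles.append(cyc.reset_index(drop=True))
    cycles.sort(key=lambda c: c["timestamp"].iloc[0])
    return cycles


def average_cycle(
    cycle: pd.DataFrame, window_seconds: float = 180.0
) -> ProcessedRecord:
    """Mean and SD over the trailing ``window_seconds`` of one cycle.

    The last minutes of a cycle are used because the earlier part still
    carries memory of the previous flow path. A cycle with fewer than 3
    samples inside the window is flagged SHORT_CYCLE (computed over
    whatever is available).
    """
    if cycle.empty:
        raise ValueError("empty cycle")
    t = pd.to_datetime(cycle["timestamp"])
    end = t.iloc[-1]
    duration = (end - t.iloc[0]).total_seconds()
    if window_seconds > duration + 1e-9 and len(cycle) > 1:
        flags = {"SHORT_CYCLE"}
    else:
        flags = set()
    mask = (end - t).dt.total_seconds() <= window_seconds
    win = cycle.loc[mask.values]
    if len(win) < 3:
        flags.add("SHORT_CYCLE")
        win = cycle

    pressure = (
        float(win["pressure_pa"].mean())
        if "pressure_pa" in win.columns
        else P0
    )
    rec = ProcessedRecord(
        channel=str(cycle["channel"].iloc[0]),
        time=end,
        w_mean=float(win["h2o_ppm"].mean()) * 1e-6,
        w_sd=float(win["h2o_ppm"].std(ddof=1)) * 1e-6 if len(win) > 1 else 0.0,
        delta_mean={
            s: float(win[_MEAN_COL[s]].mean()) for s in Species
        },
        delta_sd={
            s: (float(win[_MEAN_COL[s]].std(ddof=1)) if len(win) > 1 else 0.0)
            for s in Species
        },
        t_stem_c=float(win["t_stem_c"].mean()),
        pressure_pa=pressure,
        n_samples=int(len(win)),
        qc_flags=flags,
    )
    return rec


def borehole_rh(w_mean: float, T_stem: float, p: float = P0) -> float:
    """Relative humidity in the borehole: h = w / w_sat(T_stem, p)."""
    return w_mean / saturation_mole_fraction(T_stem, p)


def qc_filter(
    records: Sequence[ProcessedRecord],
    thresholds: QCThresholds = QCThresholds(),
) -> dict:
    """Set QC flags in place and return an exclusion summary.

    Flags: SD_O18, SD_H2 (raw-delta SD above the per-species limit), LOW_RH
    (borehole RH below the minimum; requires ``h`` to be set), plus any
    SHORT_CYCLE flags already present. A record is excluded iff it carries
    at least one flag. Returns counts and percentages; input cycles always
    satisfy n_input = n_clean + n_flagged.
    """
    for rec in records:
        if rec.delta_sd[Species.O18] > thresholds.sd_limit_o18:
            rec.qc_flags.add("SD_O18")
        if rec.delta_sd[Species.H2] > thresholds.sd_limit_h2:
            rec.qc_flags.add("SD_H2")
        if rec.h is None:
            rec.h = borehole_rh(rec.w_mean, rec.t_stem_c + 273.15,
                                rec.pressure_pa)
        if rec.h < thresholds.rh_min:
            rec.qc_flags.add("LOW_RH")
        if rec.h > 1.05:
            rec.qc_flags.add("CONDENSATION_SUSPECT")
    n = len(records)
    n_excluded = sum(1 for r in records if r.excluded)
    flag_counts: dict[str, int] = {}
    for r in records:
        for fl in r.qc_flags:
            flag_counts[fl] = flag_counts.get(fl, 0) + 1
    return {
        "n_input": n,
        "n_clean": n - n_excluded,
        "n_flagged": n_excluded,
        "excluded_percent": (100.0 * n_excluded / n) if n else 0.0,
        "flag_counts": flag_counts,
    }


@dataclass(frozen=True)
class StandardSet:
    """Per-species linear calibration fitted to headspace standards.

    ``slope``/``intercept`` map raw measured vapor delta to calibrated
    vapor delta: delta_cal = slope * delta_raw + intercept.
    """

    slope: dict[Species, float]
    intercept: dict[Species, float]
    n_standards: int


def fit_standards(standards: pd.DataFrame) -> StandardSet:
    """Fit the per-species calibration from a standards table.

    Columns: ``name, d18o_liquid, d2h_liquid, t_headspace_c, d18o_meas,
    d2h_meas``. Each standard's target vapor delta is its known liquid
    delta shifted into the vapor phase by equilibrium fractionation at the
    recorded headspace temperature; the calibration is an ordinary
    least-squares line through (measured, target) per species. With exactly
    two standards the line interpolates them exactly.
    """
    required = {"d18o_liquid", "d2h_liquid", "t_headspace_c",
                "d18o_meas", "d2h_meas"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns: {sorted(missing)}")
    if len(standards) < 2:
        raise ValueError("need at least 2 standards to fit a calibration")

    liquid_col = {Species.O18: "d18o_liquid", Species.H2: "d2h_liquid"}
    meas_col = {Species.O18: "d18o_meas", Species.H2: "d2h_meas"}
    T = standards["t_headspace_c"].to_numpy(float) + 273.15

    slope: dict[Species, float] = {}
    intercept: dict[Species, float] = {}
    for s in Species:
        target = np.array([
            liquid_to_vapor_delta(d, s, t)
            for d, t in zip(standards[liquid_col[s]].to_numpy(float), T)
        ])
        meas = standards[meas_col[s]].to_numpy(float)
        a, b = np.polyfit(meas, target, 1)
        slope[s], intercept[s] = float(a), float(b)
    return StandardSet(slope=slope, intercept=intercept,
                       n_standards=len(standards))


def calibrate(
    delta_raw: Mapping[Species, float] | float,
    standards: StandardSet,
    species: Species | None = None,
):
    """Apply the fitted linear calibration to raw vapor delta values."""
    if species is not None:
        s = Species(species)
        return standards.slope[s] * float(delta_raw) + standards.intercept[s]
    return {
        Species(s): standards.slope[Species(s)] * v
        + standards.intercept[Species(s)]
        for s, v in delta_raw.items()
    }


def vapor_to_liquid_delta(delta_vapor: float, species: Species, T: float) -> float:
    """Liquid-equivalent delta assuming liquid-vapor equilibrium at T (K)."""
    r_liquid = delta_to_ratio(delta_vapor) * equilibrium_alpha(species, T)
    return ratio_to_delta(r_liquid)


def liquid_to_vapor_delta(delta_liquid: float, species: Species, T: float) -> float:
    """Vapor in equilibrium with liquid of the given delta at T (K)."""
    r_vapor = delta_to_ratio(delta_liquid) / equilibrium_alpha(species, T)
    return ratio_to_delta(r_vapor)


@dataclass(frozen=True)
class BreakthroughResult:
    """Plateau levels and midpoint arrival time of a breakthrough curve."""

    initial_value: float
    final_value: float
    midpoint_value: float
    crossing_time: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]


def breakthrough_midpoint(
    times: Sequence[float],
    values: Sequence[float],
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> BreakthroughResult:
    """Label arrival time from the midpoint of a breakthrough curve.

    The initial and final plateaus are the means over the two stated
    windows; the midpoint is their mean; the crossing time is the first
    time the series crosses the midpoint, linearly interpolated between the
    bracketing samples. Windows are (start, end) in the same time units as
    ``times``.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be matching 1-D sequences")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    def plateau(window):
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 3:
            raise ValueError(
                f"plateau window {window} contains fewer than 3 points"
            )
        return float(v[mask].mean()), float(v[mask].std(ddof=1))

    pre, pre_sd = plateau(pre_window)
    post, post_sd = plateau(post_window)
    import warnings as _warnings

    if abs(post - pre) <= 2.0 * math.hypot(pre_sd, post_sd):
        _warnings.warn(
            "plateaus differ by less than combined noise; midpoint timing "
            "is unreliable",
            stacklevel=2,
        )
    mid = 0.5 * (pre + post)

    sign = np.sign(v - mid)
    # first index where the series reaches or crosses the midpoint after
    # the pre-window
    start_idx = int(np.searchsorted(t, pre_window[1]))
    for i in range(max(start_idx, 1), len(t)):
        if sign[i] == 0:
            t_cross = float(t[i])
            break
        if sign[i] != sign[i - 1] and sign[i - 1] != 0:
            # linear interpolation between bracketing samples
            frac = (mid - v[i - 1]) / (v[i] - v[i - 1])
            t_cross = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            break
    else:
        raise ValueError("series never crosses the plateau midpoint")

    return BreakthroughResult(
        initial_value=pre,
        final_value=post,
        midpoint_value=mid,
        crossing_time=t_cross,
        pre_window=tuple(pre_window),
        post_window=tuple(post_window),
    )


def velocity_from_lag(
    distance_m: float, t_first_h: float, t_second_h: float
) -> float:
    """Sap velocity (cm/h) from label arrival lag between two boreholes."""
    lag = t_second_h - t_first_h
    if lag <= 0:
        raise ValueError(f"arrival lag must be positive (got {lag} h)")
    if distance_m <= 0:
        raise ValueError(f"distance must be positive (got {distance_m} m)")
    return distance_m * 100.0 / lag


def predicted_arrival_hours(distance_m: float, velocity_cm_per_h: float) -> float:
    """Expected label arrival time (h) at a borehole ``distance_m`` away."""
    if velocity_cm_per_h <= 0 or distance_m <= 0:
        raise ValueError("distance and velocity must be positive")
    return distance_m * 100.0 / velocity_cm_per_h


def process_campaign(
    raw: pd.DataFrame,
    standards: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
    window_seconds: float = 180.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline on a raw per-sample table.

    Returns a processed-record table (one row per cycle, flags included,
    nothing silently dropped) and a run report (exclusion percentages,
    calibration coefficients).
    """
    cycles = split_cycles(raw)
    records = [average_cycle(c, window_seconds) for c in cycles]
    summary = qc_filter(records, thresholds)

    cal = fit_standards(standards) if standards is not None else None
    rows = []
    for rec in records:
        if cal is not None:
            rec.delta_cal = calibrate(rec.delta_mean, cal)
        else:
            rec.delta_cal = dict(rec.delta_mean)
        T = rec.t_stem_c + 273.15
        rec.delta_liquid = {
            s: vapor_to_liquid_delta(d, s, T) for s, d in rec.delta_cal.items()
        }
        rows.append(
            {
                "channel": rec.channel,
                "time": rec.time,
                "n_samples": rec.n_samples,
                "h2o_mole_fraction": rec.w_mean,
                "t_stem_c": rec.t_stem_c,
                "rh": rec.h,
                "d18o_raw": rec.delta_mean[Species.O18],
                "d2h_raw": rec.delta_mean[Species.H2],
                "d18o_sd": rec.delta_sd[Species.O18],
                "d2h_sd": rec.delta_sd[Species.H2],
                "d18o_vapor_cal": rec.delta_cal[Species.O18],
                "d2h_vapor_cal": rec.delta_cal[Species.H2],
                "d18o_liquid": rec.delta_liquid[Species.O18],
                "d2h_liquid": rec.delta_liquid[Species.H2],
                "qc_flags": ";".join(sorted(rec.qc_flags)),
                "excluded": rec.excluded,
            }
        )
    table = pd.DataFrame(rows)
    report = {
        "qc": summary,
        "calibration": (
            {
                "slope": {s.value: cal.slope[s] for s in Species},
                "intercept": {s.value: cal.intercept[s] for s in Species},
                "n_standards": cal.n_standards,
            }
            if cal is not None
            else None
        ),
    }
    return table, report
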