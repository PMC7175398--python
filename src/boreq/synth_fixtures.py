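"""Seeded generator of synthetic measurement campaigns and standards.

Emulates what a cavity-ring-down analyzer plumbed to a stem borehole
records during a labeling experiment: 15-min measurement cycles (after a
5-min flush) sampled every few hours, per-second raw series of water mole
fraction and raw deltas, a diurnal stem-temperature cycle, Gaussian
instrument noise, an affine instrument response, and occasional artifact
cycles (sub-saturated borehole air, noise bursts). The xylem water follows
a plateau-transition-plateau breakthrough: a pre-label plateau, a switch at
a configured time, and relaxation toward the post-label plateau.

Every campaign comes with a ground-truth record (true plateaus, switch
time, injected artifacts, instrument coefficients) sufficient to score the
processing pipeline without re-generation. Identical seed and config give
byte-identical outputs.

Not emulated: instrument spectroscopy and memory effects, autocorrelated
noise, and condensation Rayleigh distillation in sample lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope_physics import P0, Species, saturation_mole_fraction
from .field_processing import liquid_to_vapor_delta

__all__ = [
    "SyntheticCampaignConfig",
    "generate_campaign",
    "generate_standards",
    "write_campaign",
    "DEFAULT_STANDARDS",
]

#: Four isotopically distinct headspace standards spanning natural
#: abundance plus a deuterium label (light, medium, heavy, label), liquid per-mil values.
DEFAULT_STANDARDS = pd.DataFrame(
    {
        "name": ["light", "medium", "heavy", "label"],
        "d18o_liquid": [-14.9, -9.4, 3.4, -9.2],
        "d2h_liquid": [-110.8, -66.3, 3.8, 367.7],
    }
)


@dataclass(frozen=True)
class SyntheticCampaignConfig:
    """Study conditions for one synthetic labeling campaign.

    Defaults mirror the whole-root labeling experiment: natural-abundance
    xylem water switching to a deuterium label, 3-h sampling of 15-min
    cycles (preceded by 5-min flushes) at 1 Hz, stem temperature
    16.8 +/- 1.3 degC diurnal, near-saturated borehole air, and per-sample
    noise SDs at the QC thresholds (0.5 / 1.5 permil).
    """

    # liquid xylem water plateaus (per mil)
    pre_plateau: dict[str, float] = field(
        default_factory=lambda: {"O18": -8.43, "H2": -59.28}
    )
    post_plateau: dict[str, float] = field(
        default_factory=lambda: {"O18": -9.22, "H2": 297.57}
    )
    switch_time_h: float = 72.0
    transition_tau_h: float = 12.0
    transition_shape: str = "exponential"  # or "logistic"
    duration_h: float = 240.0
    sampling_interval_h: float = 3.0
    cycle_minutes: float = 15.0
    flush_minutes: float = 5.0
    sample_period_s: float = 1.0
    # instrument noise (per-sample SD, per mil; h2o in ppm)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"O18": 0.5, "H2": 1.5}
    )
    h2o_noise_ppm: float = 30.0
    # borehole environment
    t_stem_mean_c: float = 16.8
    t_stem_amplitude_c: float = 1.3
    rh: float = 0.98
    pressure_pa: float = P0
    # artifacts
    low_rh_rate: float = 0.0
    sd_burst_rate: float = 0.0
    low_rh_value: float = 0.6
    sd_burst_factor: float = 3.0
    # affine instrument response: raw = slope*true + offset, per species
    instrument_slope: dict[str, float] = field(
        default_factory=lambda: {"O18": 1.0, "H2": 1.0}
    )
    instrument_offset: dict[str, float] = field(
        default_factory=lambda: {"O18": 0.0, "H2": 0.0}
    )
    channel: str = "borehole_1"
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.noise_sd.items():
            if v < 0:
                raise ValueError(f"noise SD for {k} must be >= 0")
        for name, p in (("low_rh_rate", self.low_rh_rate),
                        ("sd_burst_rate", self.sd_burst_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {p})")
        if self.transition_shape not in ("exponential", "logistic"):
            raise ValueError(
                f"unknown transition shape {self.transition_shape!r}"
            )


def _true_liquid_delta(cfg: SyntheticCampaignConfig, t_h: float,
                       species: str) -> float:
    """Xylem liquid delta at time t_h: plateau-transition-plateau."""
    pre = cfg.pre_plateau[species]
    post = cfg.post_plateau[species]
    if cfg.transition_shape == "exponential":
        if t_h < cfg.switch_time_h:
            return pre
        z = (t_h - cfg.switch_time_h) / cfg.transition_tau_h
        return post + (pre - post) * math.exp(-z)
    # logistic centered so the curve passes its midpoint at switch_time_h
    z = (t_h - cfg.switch_time_h) / cfg.transition_tau_h
    return pre + (post - pre) / (1.0 + math.exp(-z))


def _stem_temperature_c(cfg: SyntheticCampaignConfig, t_h: float) -> float:
    """Diurnal sinusoid peaking mid-afternoon (hour 15)."""
    return cfg.t_stem_mean_c + cfg.t_stem_amplitude_c * math.sin(
        2.0 * math.pi * (t_h - 9.0) / 24.0
    )


def generate_campaign(
    cfg: SyntheticCampaignConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate per-sample raw cycles and the matching ground truth.

    Returns a raw table in the pipeline's CSV dialect (timestamp, channel,
    h2o_ppm, d18o_raw, d2h_raw, t_stem_c, pressure_pa, cycle) and a truth
    dict holding, per cycle, the cycle time, true vapor and liquid deltas,
    true RH and injected artifacts, plus the global configuration, switch
    time and instrument coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    origin = pd.Timestamp("2018-11-18T00:00:00Z")
    n_cycles = int(cfg.duration_h // cfg.sampling_interval_h) + 1
    n_samples = int(round(cfg.cycle_minutes * 60.0 / cfg.sample_period_s))

    frames = []
    truth_cycles = []
    for k in range(n_cycles):
        t_start_h = k * cfg.sampling_interval_h + cfg.flush_minutes / 60.0
        t_mid_h = t_start_h + cfg.cycle_minutes / 120.0
        T_c = _stem_temperature_c(cfg, t_mid_h)
        T_k = T_c + 273.15

        is_low_rh = bool(rng.random() < cfg.low_rh_rate)
        is_burst = bool(rng.random() < cfg.sd_burst_rate)
        h_true = cfg.low_rh_value if is_low_rh else cfg.rh
        w_ppm = h_true * saturation_mole_fraction(T_k, cfg.pressure_pa) * 1e6

        true_liquid = {
            s: _true_liquid_delta(cfg, t_mid_h, s) for s in ("O18", "H2")
        }
        true_vapor = {
            s: liquid_to_vapor_delta(true_liquid[s], Species(s), T_k)
            for s in ("O18", "H2")
        }
        raw_center = {
            s: cfg.instrument_slope[s] * true_vapor[s]
            + cfg.instrument_offset[s]
            for s in ("O18", "H2")
        }

        burst = cfg.sd_burst_factor if is_burst else 1.0
        times = origin + pd.to_timedelta(
            t_start_h * 3600.0 + np.arange(n_samples) * cfg.sample_period_s,
            unit="s",
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": times,
                    "channel": cfg.channel,
                    "h2o_ppm": w_ppm
                    + rng.normal(0.0, cfg.h2o_noise_ppm, n_samples),
                    "d18o_raw": raw_center["O18"]
                    + rng.normal(0.0, burst * cfg.noise_sd["O18"], n_samples),
                    "d2h_raw": raw_center["H2"]
                    + rng.normal(0.0, burst * cfg.noise_sd["H2"], n_samples),
                    "t_stem_c": T_c,
                    "pressure_pa": cfg.pressure_pa,
                    "cycle": k,
                }
            )
        )
        truth_cycles.append(
            {
                "cycle": k,
                "time_h": t_mid_h,
                "t_stem_c": T_c,
                "rh_true": h_true,
                "low_rh_artifact": is_low_rh,
                "sd_burst_artifact": is_burst,
                "true_liquid_delta": true_liquid,
                "true_vapor_delta": true_vapor,
            }
        )

    raw = pd.concat(frames, ignore_index=True)
    truth = {
        "config": asdict(cfg),
        "n_cycles": n_cycles,
        "switch_time_h": cfg.switch_time_h,
        "pre_plateau": dict(cfg.pre_plateau),
        "post_plateau": dict(cfg.post_plateau),
        # calibration that the pipeline should recover:
        # cal = (raw - offset)/slope
        "calibration_slope": {
            s: 1.0 / cfg.instrument_slope[s] for s in ("O18", "H2")
        },
        "calibration_intercept": {
            s: -cfg.instrument_offset[s] / cfg.instrument_slope[s]
            for s in ("O18", "H2")
        },
        "cycles": truth_cycles,
    }
    return raw, truth


def generate_standards(
    instrument_slope: dict[str, float],
    instrument_offset: dict[str, float],
    liquid_deltas: pd.DataFrame | None = None,
    t_headspace_c: float = 20.0,
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic headspace-standards table for calibration fitting.

    Measured vapor values are the equilibrium vapor targets passed through
    the same affine instrument response used by :func:`generate_campaign`
    (raw = slope*true + offset), optionally with Gaussian noise.
    """
    liquid = DEFAULT_STANDARDS if liquid_deltas is None else liquid_deltas
    if len(liquid) < 2:
        raise ValueError("need at least 2 standards")
    rng = np.random.default_rng(seed)
    noise = noise_sd or {"O18": 0.0, "H2": 0.0}

    rows = []
    for _, std in liquid.iterrows():
        T_k = t_headspace_c + 273.15
        target = {
            "O18": liquid_to_vapor_delta(std["d18o_liquid"], Species.O18, T_k),
            "H2": liquid_to_vapor_delta(std["d2h_liquid"], Species.H2, T_k),
        }
        rows.append(
            {
                "name": std["name"],
                "d18o_liquid": std["d18o_liquid"],
                "d2h_liquid": std["d2h_liquid"],
                "t_headspace_c": t_headspace_c,
                "d18o_meas": instrument_slope["O18"] * target["O18"]
                + instrument_offset["O18"]
                + rng.normal(0.0, noise["O18"]),
                "d2h_meas": instrument_slope["H2"] * target["H2"]
                + instrument_offset["H2"]
                + rng.normal(0.0, noise["H2"]),
            }
        )
    return pd.DataFrame(rows)


def write_campaign(
    cfg: SyntheticCampaignConfig, outdir: str | Path
) -> tuple[Path, Path]:
    """Write raw.csv and truth.json for a campaign; returns the two paths.

    Float formatting is fixed so identical seed+config give identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw, truth = generate_campaign(cfg)
    raw_path = outdir / "raw.csv"
    truth_path = outdir / "truth.json"
    raw.to_csv(raw_path, index=False, float_format="%.6f")
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return raw_path, truth_path
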