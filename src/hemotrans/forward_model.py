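"""Synthetic stand-in for the in-vitro recirculating blood circuit.

The generator emulates a bench experiment in which bovine blood is pumped
through an oxygenator loop, stepped through oxygen saturation levels at a
series of hemoglobin concentrations, and probed by clamp-on dual-wavelength
(680/850 nm) transmission sensors while a blood gas analyzer (BGA) provides
paired reference measurements.

Light transport through the tube is modeled as a modified Beer-Lambert law
in which scattering is lumped into an attenuation term proportional to
hemoglobin concentration:

    ln I(lambda) = ln(gain) - path * [eps_mix(lambda, SO2) + mu_s(lambda)] * Hgb

with eps_mix = (SO2/100) * eps_HbO2 + (1 - SO2/100) * eps_Hb.  Deoxygenated
hemoglobin absorbs more strongly at 680 nm and oxygenated hemoglobin at
850 nm, so raising saturation raises the 680 nm intensity and lowers the
850 nm intensity, and raising concentration lowers both.  This reproduces
the empirically observed structure (near-linear SO2-vs-R within hemoglobin
bins, with slope and intercept drifting with concentration); it makes no
claim to be a transport-accurate photon model.

Default extinction strengths are compiled hemoglobin molar extinction
spectra converted to per (g/dL)*mm units; the effective scattering strength
is far below textbook whole-blood reduced scattering because a transmission
detector pressed against the tube collects most forward-scattered light.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientBinError,
    InsufficientVariationError,
    ProtocolError,
)
from .preprocessing import PULSE_MAX, ADC_MAX

#: ln(10) / MW(hemoglobin monomer) -- converts molar extinction in
#: cm^-1 / (mol/L) to attenuation per (g/dL) per mm.
MOLAR_TO_GDL_MM = math.log(10) / 64500.0

#: Fixed front-end factor mapping dimensionless model intensity to
#: counts-per-pulse when emitting a raw 20 Hz ADC stream.
FRONTEND_ADC_SCALE = 0.02

SAMPLING_HZ = 20
WINDOW_SECONDS = 60
SAMPLE_INTERVAL_S = 1200.0  # 20-minute gas-change cadence
DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class OpticalConstants:
    """Absorption/scattering strengths per (g/dL)*mm and path length in mm."""

    eps_hb_680: float = 0.0939
    eps_hbo2_680: float = 0.0105
    eps_hb_850: float = 0.0247
    eps_hbo2_850: float = 0.0378
    mu_s_680: float = 0.033
    mu_s_850: float = 0.030
    path_mm: float = 7.5

    def __post_init__(self) -> None:
        for name in (
            "eps_hb_680",
            "eps_hbo2_680",
            "eps_hb_850",
            "eps_hbo2_850",
            "mu_s_680",
            "mu_s_850",
            "path_mm",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        # strict inequality gives strict monotonicity in SO2; equality is
        # allowed so fully degenerate (all-zero) constants stay expressible
        if self.eps_hb_680 < self.eps_hbo2_680:
            raise DomainError("deoxyhemoglobin must absorb at least as much at 680 nm")
        if self.eps_hbo2_850 < self.eps_hb_850:
            raise DomainError("oxyhemoglobin must absorb at least as much at 850 nm")


@dataclass(frozen=True)
class SensorProfile:
    """Per-device source-detector gain and measurement noise."""

    sensor_id: int
    gain680: float
    gain850: float
    noise_sigma: float = 0.005

    def __post_init__(self) -> None:
        if self.gain680 <= 0 or self.gain850 <= 0:
            raise DomainError("gains must be positive")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be non-negative")


def default_profiles() -> list[SensorProfile]:
    """Two sensors with distinct gains, emulating manufacturing spread."""
    return [
        SensorProfile(sensor_id=1, gain680=160000.0, gain850=165000.0),
        SensorProfile(sensor_id=2, gain680=190000.0, gain850=138000.0),
    ]


@dataclass(frozen=True)
class ExperimentProtocol:
    """Bench-study schedule: concentration levels, saturation steps, noise."""

    n_days: int = 7
    hgb_levels: tuple = tuple(float(h) for h in range(6, 15))
    so2_steps: tuple = (50.0, 60.0, 70.0, 80.0, 90.0, 100.0)
    samples_total: int = 86
    bga_hgb_sigma: float = 0.1
    bga_so2_sigma: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.samples_total < 1:
            raise ProtocolError("n_days and samples_total must be >= 1")
        if not self.hgb_levels or not self.so2_steps:
            raise ProtocolError("hgb_levels and so2_steps must be non-empty")
        if min(self.hgb_levels) <= 0:
            raise ProtocolError("hgb_levels must be positive")
        if min(self.so2_steps) < 0 or max(self.so2_steps) > 100:
            raise ProtocolError("so2_steps must lie in [0, 100]")
        if self.bga_hgb_sigma < 0 or self.bga_so2_sigma < 0:
            raise ProtocolError("reference noise sigmas must be non-negative")


def forward_log_intensity(
    hgb: float,
    so2: float,
    wavelength: int,
    constants: OpticalConstants,
    profile: SensorProfile,
):
    """Noiseless log intensity for one wavelength; vectorized over hgb/so2."""
    hgb = np.asarray(hgb, dtype=float)
    so2 = np.asarray(so2, dtype=float)
    if np.any(hgb <= 0):
        raise DomainError("hgb must be positive")
    if np.any((so2 < 0) | (so2 > 100)):
        raise DomainError("so2 must lie in [0, 100]")
    if wavelength == 680:
        gain, eps_hb, eps_hbo2, mu_s = (
            profile.gain680,
            constants.eps_hb_680,
            constants.eps_hbo2_680,
            constants.mu_s_680,
        )
    elif wavelength == 850:
        gain, eps_hb, eps_hbo2, mu_s = (
            profile.gain850,
            constants.eps_hb_850,
            constants.eps_hbo2_850,
            constants.mu_s_850,
        )
    else:
        raise DomainError(f"unsupported wavelength {wavelength}")
    frac = so2 / 100.0
    eps_mix = frac * eps_hbo2 + (1.0 - frac) * eps_hb
    out = math.log(gain) - constants.path_mm * (eps_mix + mu_s) * hgb
    return float(out) if out.ndim == 0 else out


def build_schedule(protocol: ExperimentProtocol) -> pd.DataFrame:
    """Deterministic sample schedule: (sample_id, day_id, timestamp, truth).

    Hemoglobin levels are assigned to days round-robin; within a day the
    saturation steps are swept low to high for each of the day's levels,
    cycling until the day's sample count is met.  Day counts split
    ``samples_total`` as evenly as possible with the remainder going to the
    earliest days.
    """
    n_days = protocol.n_days
    base, rem = divmod(protocol.samples_total, n_days)
    day_counts = [base + (1 if d < rem else 0) for d in range(n_days)]
    day_levels: list[list[float]] = [[] for _ in range(n_days)]
    for i, lvl in enumerate(protocol.hgb_levels):
        day_levels[i % n_days].append(float(lvl))
    for d in range(n_days):
        if not day_levels[d]:
            day_levels[d] = [float(protocol.hgb_levels[d % len(protocol.hgb_levels)])]

    rows = []
    sample_id = 1
    for d in range(n_days):
        pairs = [(lvl, s) for lvl in day_levels[d] for s in protocol.so2_steps]
        for k in range(day_counts[d]):
            lvl, s = pairs[k % len(pairs)]
            rows.append(
                {
                    "sample_id": sample_id,
                    "day_id": d + 1,
                    "timestamp_s": d * DAY_SECONDS + (k + 1) * SAMPLE_INTERVAL_S,
                    "hgb_true": lvl,
                    "so2_true": float(s),
                }
            )
            sample_id += 1
    return pd.DataFrame(rows)


def simulate_experiment(
    protocol: Optional[ExperimentProtocol] = None,
    constants: Optional[OpticalConstants] = None,
    profiles: Optional[Sequence[SensorProfile]] = None,
    emit_timeseries: bool = False,
):
    """Generate a paired synthetic dataset.

    Returns ``(windows, bloodgas)`` DataFrames, or
    ``(windows, bloodgas, timeseries)`` when ``emit_timeseries`` is set.

    * ``windows``: one row per (sample, sensor) with window-mean normalized
      intensities ``i680``/``i850`` (log-intensity perturbed by centered
      Gaussian noise of sd ``profile.noise_sigma``).
    * ``bloodgas``: one BGA reference row per sample; the true grid values
      perturbed by the reference sigmas and truncated to valid ranges.
    * ``timeseries``: optional raw 20 Hz ADC stream; each window's
      equilibrium intensity repeated with fresh per-point noise, mapped
      into the 16-bit ADC range with a per-(sensor, day, wavelength) pulse
      number, emulating the front end's pulse-count adjustment.
    """
    protocol = protocol or ExperimentProtocol()
    constants = constants or OpticalConstants()
    profiles = list(profiles) if profiles is not None else default_profiles()
    if not profiles:
        raise ProtocolError("at least one sensor profile is required")

    schedule = build_schedule(protocol)
    rng = np.random.default_rng(protocol.seed)

    bg_rows, win_rows = [], []
    for row in schedule.itertuples(index=False):
        hgb_ref = row.hgb_true + rng.normal(0.0, protocol.bga_hgb_sigma)
        so2_ref = row.so2_true + rng.normal(0.0, protocol.bga_so2_sigma)
        hgb_ref = max(hgb_ref, 0.2)
        so2_ref = min(max(so2_ref, 0.0), 100.0)
        bg_rows.append(
            {
                "sample_id": row.sample_id,
                "day_id": row.day_id,
                "timestamp_s": row.timestamp_s,
                "hgb_gdl": hgb_ref,
                "so2_pct": so2_ref,
            }
        )
        for prof in profiles:
            ln680 = forward_log_intensity(row.hgb_true, row.so2_true, 680, constants, prof)
            ln850 = forward_log_intensity(row.hgb_true, row.so2_true, 850, constants, prof)
            ln680 += rng.normal(0.0, prof.noise_sigma)
            ln850 += rng.normal(0.0, prof.noise_sigma)
            win_rows.append(
                {
                    "sample_id": row.sample_id,
                    "sensor_id": prof.sensor_id,
                    "day_id": row.day_id,
                    "i680": math.exp(ln680),
                    "i850": math.exp(ln850),
                    "n_points": SAMPLING_HZ * WINDOW_SECONDS,
                }
            )
    windows = pd.DataFrame(win_rows)
    bloodgas = pd.DataFrame(bg_rows)
    if not emit_timeseries:
        return windows, bloodgas
    timeseries = _emit_timeseries(windows, bloodgas, profiles, rng)
    return windows, bloodgas, timeseries


def _emit_timeseries(
    windows: pd.DataFrame,
    bloodgas: pd.DataFrame,
    profiles: Sequence[SensorProfile],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw 20 Hz stream: equilibrium window values plus per-point noise."""
    sigma = {p.sensor_id: p.noise_sigma for p in profiles}
    ts_of = dict(zip(bloodgas["sample_id"], bloodgas["timestamp_s"]))
    n_pts = SAMPLING_HZ * WINDOW_SECONDS

    # Pulse number per (sensor, day, wavelength): largest count that keeps
    # the summed ADC value inside 16 bits, mimicking the front-end tuning
    # against saturation (low Hgb) and starvation (high Hgb).
    pulse: dict[tuple, int] = {}
    for (sensor, day), grp in windows.groupby(["sensor_id", "day_id"]):
        for wl, col in ((680, "i680"), (850, "i850")):
            peak = grp[col].max() * FRONTEND_ADC_SCALE * 1.05
            p = int(ADC_MAX * 0.9 / max(peak, 1e-12))
            pulse[(sensor, day, wl)] = min(max(p, 1), PULSE_MAX)

    frames = []
    for row in windows.itertuples(index=False):
        t0 = ts_of[row.sample_id] - WINDOW_SECONDS
        t = t0 + np.arange(n_pts) / SAMPLING_HZ
        for wl, val in ((680, row.i680), (850, row.i850)):
            p = pulse[(row.sensor_id, row.day_id, wl)]
            noise = rng.normal(0.0, sigma[row.sensor_id], n_pts)
            counts = np.rint(
                val * FRONTEND_ADC_SCALE * p * np.exp(noise)
            ).clip(0, ADC_MAX).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp_s": t,
                        "sensor_id": row.sensor_id,
                        "wavelength_nm": wl,
                        "adc_counts": counts,
                        "pulse_number": p,
                    }
                )
            )
    ts = pd.concat(frames, ignore_index=True)
    return ts.sort_values(
        ["timestamp_s", "sensor_id", "wavelength_nm"], kind="stable"
    ).reset_index(drop=True)


def check_ratio_linearity(
    dataset: pd.DataFrame, hgb_center: float, halfwidth: float = 0.5
) -> float:
    """R^2 of the OLS line SO2 = alpha*R + beta within one hemoglobin bin.

    ``dataset`` must carry columns ``hgb_gdl``, ``so2_pct`` and ``ratio``.
    """
    for col in ("hgb_gdl", "so2_pct", "ratio"):
        if col not in dataset.columns:
            raise DomainError(f"dataset lacks required column {col!r}")
    mask = (dataset["hgb_gdl"] - hgb_center).abs() <= halfwidth
    sub = dataset.loc[mask]
    if len(sub) < 3:
        raise InsufficientBinError(
            f"bin {hgb_center}+-{halfwidth} holds {len(sub)} < 3 samples"
        )
    so2 = sub["so2_pct"].to_numpy(float)
    ratio = sub["ratio"].to_numpy(float)
    if np.ptp(so2) == 0:
        raise InsufficientVariationError("SO2 constant within bin; R^2 undefined")
    coef = np.polyfit(ratio, so2, 1)
    resid = so2 - np.polyval(coef, ratio)
    ss_tot = float(np.sum((so2 - so2.mean()) ** 2))
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# JSON config plumbing

def config_to_dict(
    protocol: ExperimentProtocol,
    constants: OpticalConstants,
    profiles: Sequence[SensorProfile],
) -> dict:
    return {
        "schema_version": 1,
        "protocol": dataclasses.asdict(protocol),
        "constants": dataclasses.asdict(constants),
        "profiles": [dataclasses.asdict(p) for p in profiles],
    }


def config_from_dict(cfg: dict):
    """Inverse of :func:`config_to_dict`; missing keys take defaults."""
    proto_kw = dict(cfg.get("protocol", {}))
    for key in ("hgb_levels", "so2_steps"):
        if key in proto_kw:
            proto_kw[key] = tuple(float(v) for v in proto_kw[key])
    protocol = ExperimentProtocol(**proto_kw)
    constants = OpticalConstants(**cfg.get("constants", {}))
    raw_profiles = cfg.get("profiles")
    profiles = (
        [SensorProfile(**p) for p in raw_profiles] if raw_profiles else default_profiles()
    )
    return protocol, constants, profiles
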