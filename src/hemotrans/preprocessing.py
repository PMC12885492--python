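"""From raw per-pulse ADC streams to calibration inputs.

The analog front end sums a preset number of laser pulses (up to 127) into
one 16-bit ADC reading, so raw counts are first normalized by the pulse
number.  One-minute windows sampled at 20 Hz are averaged into a single
dual-wavelength intensity pair per blood sample.  Because nominally
identical sensors differ in source-detector gain, per-sensor scale factors
are computed that equalize the mean normalized intensity across sensors at
each wavelength; the scaled intensities then feed a single, sensor
independent calibration.

The nine-term polynomial feature library used by the hemoglobin model is

    [ln(I680)^2, ln(I850)^2, R^2, ln(I680), ln(I850), R,
     ln(I680)*ln(I850), ln(I680)*R, 1]

with R = ln(I680)/ln(I850) computed from scaled intensities.  Note the
library is deliberately asymmetric: it contains ln(I680)*R but no
ln(I850)*R term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateDenominatorError,
    DomainError,
    IncompleteWindowError,
    InvalidRecordError,
    MissingSensorError,
)

#: Guard band on |ln(I850)| below which the ratio R is considered unstable.
EPS_LN_DENOMINATOR = 1e-6

#: Supported laser wavelengths in nm.
WAVELENGTHS = (680, 850)

#: Names of the nine feature-library terms, in model order.
FEATURE_NAMES = (
    "ln680_sq",
    "ln850_sq",
    "ratio_sq",
    "ln680",
    "ln850",
    "ratio",
    "ln680_ln850",
    "ln680_ratio",
    "const",
)

ADC_MAX = 65535
PULSE_MAX = 127


@dataclass(frozen=True)
class RawIntensityRecord:
    """One 20 Hz reading from one sensor at one wavelength."""

    timestamp_s: float
    sensor_id: int
    wavelength_nm: int
    adc_counts: int
    pulse_number: int

    def __post_init__(self) -> None:
        if self.wavelength_nm not in WAVELENGTHS:
            raise InvalidRecordError(
                f"wavelength_nm must be one of {WAVELENGTHS}, got {self.wavelength_nm}"
            )
        if not 0 <= self.adc_counts <= ADC_MAX:
            raise InvalidRecordError(
                f"adc_counts must be in [0, {ADC_MAX}], got {self.adc_counts}"
            )
        if not 1 <= self.pulse_number <= PULSE_MAX:
            raise InvalidRecordError(
                f"pulse_number must be in [1, {PULSE_MAX}], got {self.pulse_number}"
            )


@dataclass(frozen=True)
class IntensityWindow:
    """Window-averaged normalized intensities for one sensor and sample."""

    sample_id: int
    sensor_id: int
    day_id: int
    i680: float
    i850: float
    n_points: int

    def __post_init__(self) -> None:
        if self.i680 <= 0 or self.i850 <= 0:
            raise DomainError("window intensities must be positive")
        if self.n_points < 1:
            raise DomainError("n_points must be >= 1")


@dataclass(frozen=True)
class SensorScaling:
    """Multiplicative per-wavelength scale factors for one sensor."""

    sensor_id: int
    scale680: float
    scale850: float

    def __post_init__(self) -> None:
        if self.scale680 <= 0 or self.scale850 <= 0:
            raise DomainError("scale factors must be positive")


@dataclass(frozen=True)
class FeatureVector:
    """The nine-term function library evaluated for one sample."""

    ln680: float
    ln850: float
    ratio: float
    terms: tuple

    @classmethod
    def from_scaled(cls, scaled_i680: float, scaled_i850: float) -> "FeatureVector":
        if scaled_i680 <= 0 or scaled_i850 <= 0:
            raise DomainError("scaled intensities must be positive")
        ln680 = math.log(scaled_i680)
        ln850 = math.log(scaled_i850)
        if abs(ln850) <= EPS_LN_DENOMINATOR:
            raise DegenerateDenominatorError(
                f"|ln(I850)| = {abs(ln850):.3g} <= {EPS_LN_DENOMINATOR}; ratio undefined"
            )
        ratio = ln680 / ln850
        terms = (
            ln680 ** 2,
            ln850 ** 2,
            ratio ** 2,
            ln680,
            ln850,
            ratio,
            ln680 * ln850,
            ln680 * ratio,
            1.0,
        )
        return cls(ln680=ln680, ln850=ln850, ratio=ratio, terms=terms)


def normalize_by_pulse_count(record: RawIntensityRecord) -> float:
    """Normalized intensity: summed ADC counts divided by the pulse number."""
    if record.pulse_number < 1:
        raise InvalidRecordError("pulse_number must be >= 1")
    return record.adc_counts / record.pulse_number


def window_average(
    records: Sequence[RawIntensityRecord],
    sample_id: int = 0,
    day_id: int = 0,
) -> IntensityWindow:
    """Average the normalized intensities of one window into per-wavelength means.

    All records must come from a single sensor, and both wavelengths must be
    present.  ``n_points`` stores the smaller of the two per-wavelength
    record counts.
    """
    if not records:
        raise IncompleteWindowError("empty window")
    sensor_ids = {r.sensor_id for r in records}
    if len(sensor_ids) != 1:
        raise InvalidRecordError(f"window mixes sensors {sorted(sensor_ids)}")
    by_wl: dict[int, list[float]] = {wl: [] for wl in WAVELENGTHS}
    for r in records:
        by_wl[r.wavelength_nm].append(normalize_by_pulse_count(r))
    missing = [wl for wl, vals in by_wl.items() if not vals]
    if missing:
        raise IncompleteWindowError(f"window missing wavelength(s) {missing}")
    return IntensityWindow(
        sample_id=sample_id,
        sensor_id=next(iter(sensor_ids)),
        day_id=day_id,
        i680=float(np.mean(by_wl[680])),
        i850=float(np.mean(by_wl[850])),
        n_points=min(len(by_wl[680]), len(by_wl[850])),
    )


def compute_sensor_scaling(windows: Iterable[IntensityWindow]) -> list[SensorScaling]:
    """Per-sensor scale factors that equalize mean intensities across sensors.

    For each wavelength, ``scale_s = grand_mean / sensor_mean`` where the
    grand mean is the unweighted mean of the per-sensor means.  A single
    sensor therefore always receives unit scales.
    """
    windows = list(windows)
    if not windows:
        raise MissingSensorError("no windows provided")
    sensors = sorted({w.sensor_id for w in windows})
    means680, means850 = {}, {}
    for s in sensors:
        ws = [w for w in windows if w.sensor_id == s]
        if not ws:  # pragma: no cover - sensors derived from windows
            raise MissingSensorError(f"sensor {s} has no windows")
        means680[s] = float(np.mean([w.i680 for w in ws]))
        means850[s] = float(np.mean([w.i850 for w in ws]))
    grand680 = float(np.mean(list(means680.values())))
    grand850 = float(np.mean(list(means850.values())))
    return [
        SensorScaling(
            sensor_id=s,
            scale680=grand680 / means680[s],
            scale850=grand850 / means850[s],
        )
        for s in sensors
    ]


def scaling_for(scalings: Iterable[SensorScaling], sensor_id: int) -> SensorScaling:
    """Look up the scaling entry for a sensor."""
    for sc in scalings:
        if sc.sensor_id == sensor_id:
            return sc
    from .errors import UnknownSensorError

    raise UnknownSensorError(f"sensor {sensor_id} not present in scalings")


def build_features(window: IntensityWindow, scaling: SensorScaling) -> FeatureVector:
    """Evaluate the nine-term library on one scaled window."""
    if window.sensor_id != scaling.sensor_id:
        raise InvalidRecordError(
            f"scaling for sensor {scaling.sensor_id} applied to window "
            f"from sensor {window.sensor_id}"
        )
    return FeatureVector.from_scaled(
        window.i680 * scaling.scale680, window.i850 * scaling.scale850
    )


def feature_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n, 9) design matrix."""
    return np.asarray([f.terms for f in features], dtype=float)
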