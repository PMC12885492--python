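"""Accuracy and agreement statistics for sensor-vs-reference comparisons.

Implements the standard device-evaluation suite: mean absolute difference
(MAD), accuracy root-mean-square error (ARMS), coefficient of determination
with its adjusted form, Bland-Altman bias and 1.96-sd limits of agreement,
and per-day MAD summaries.

R^2 is computed against the identity line by default (residuals are
predicted - reference), making it a pure accuracy measure: a biased
predictor scores low even if perfectly correlated with the reference.  The
squared-Pearson alternative is available via ``convention="pearson"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
    UndefinedR2Error,
)

LOA_MULTIPLIER = 1.96

#: Non-constant model terms feeding the adjusted-R^2 penalty, per parameter.
N_PREDICTORS = {"hgb": 8, "so2": 4}


@dataclass(frozen=True)
class PairedMeasurements:
    """Predicted vs blood-gas reference values for one (sensor, split)."""

    predicted: tuple
    reference: tuple
    sensor_id: Optional[int] = None
    split_label: str = "all"
    day_ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.reference):
            raise ParameterError("predicted and reference must have equal length")
        if self.day_ids is not None and len(self.day_ids) != len(self.predicted):
            raise ParameterError("day_ids must match the number of pairs")

    @classmethod
    def from_arrays(cls, predicted, reference, **kw) -> "PairedMeasurements":
        return cls(
            predicted=tuple(float(v) for v in predicted),
            reference=tuple(float(v) for v in reference),
            **kw,
        )

    @property
    def n(self) -> int:
        return len(self.predicted)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.predicted) - np.asarray(self.reference)


@dataclass
class AgreementReport:
    """All accuracy statistics for one (sensor, split, parameter)."""

    n: int
    arms: float
    mad: float
    r2: float
    adj_r2: float
    bias: float
    loa_low: float
    loa_high: float
    per_day_mad: dict = field(default_factory=dict)
    sensor_id: Optional[int] = None
    split_label: str = "all"
    parameter: str = ""


def mad(pairs: PairedMeasurements) -> float:
    """Mean absolute difference between prediction and reference."""
    if pairs.n == 0:
        raise EmptyInputError("no pairs")
    return float(np.mean(np.abs(pairs.differences)))


def arms(pairs: PairedMeasurements) -> float:
    """Accuracy root-mean-square error, sqrt(mean((s - b)^2))."""
    if pairs.n == 0:
        raise EmptyInputError("no pairs")
    return float(np.sqrt(np.mean(pairs.differences ** 2)))


def bland_altman(pairs: PairedMeasurements):
    """Bias and limits of agreement: bias +- 1.96 * sd(differences, ddof=1)."""
    if pairs.n < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd


def r_squared(
    pairs: PairedMeasurements, n_predictors: int, convention: str = "identity"
):
    """(R^2, adjusted R^2) of predictions against the reference.

    ``identity``: 1 - sum((s-b)^2) / sum((b-mean(b))^2).
    ``pearson``: squared Pearson correlation of s and b.
    adjusted = 1 - (1 - R^2) * (n - 1) / (n - n_predictors - 1).
    """
    if pairs.n < n_predictors + 2:
        raise InsufficientDataError(
            f"need n >= {n_predictors + 2} pairs for adjusted R^2, got {pairs.n}"
        )
    b = np.asarray(pairs.reference)
    s = np.asarray(pairs.predicted)
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedR2Error("reference values have zero variance")
    if convention == "identity":
        r2 = 1.0 - float(np.sum((s - b) ** 2)) / ss_tot
    elif convention == "pearson":
        if np.ptp(s) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(s, b)[0, 1] ** 2)
    else:
        raise ParameterError(f"unknown R^2 convention {convention!r}")
    adj = 1.0 - (1.0 - r2) * (pairs.n - 1) / (pairs.n - n_predictors - 1)
    return r2, adj


def per_day_mad(pairs: PairedMeasurements) -> dict:
    """Eq.-style MAD within each experiment day."""
    if pairs.day_ids is None:
        raise ParameterError("pairs carry no day_ids")
    if pairs.n == 0:
        raise EmptyInputError("no pairs")
    d = np.abs(pairs.differences)
    days = np.asarray(pairs.day_ids)
    return {int(day): float(d[days == day].mean()) for day in sorted(set(days))}


def compute_report(
    pairs: PairedMeasurements,
    n_predictors: int,
    parameter: str = "",
    convention: str = "identity",
) -> AgreementReport:
    """Bundle every statistic into one AgreementReport."""
    bias, lo, hi = bland_altman(pairs)
    r2, adj = r_squared(pairs, n_predictors, convention=convention)
    return AgreementReport(
        n=pairs.n,
        arms=arms(pairs),
        mad=mad(pairs),
        r2=r2,
        adj_r2=adj,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        per_day_mad=per_day_mad(pairs) if pairs.day_ids is not None else {},
        sensor_id=pairs.sensor_id,
        split_label=pairs.split_label,
        parameter=parameter,
    )
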