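"""Two-stage empirical calibration.

Stage one estimates total hemoglobin concentration from the nine-term
log-intensity library by elastic-net regression,

    Hgb = a1*ln(I680)^2 + a2*ln(I850)^2 + a3*R^2 + a4*ln(I680)
          + a5*ln(I850) + a6*R + a7*ln(I680)*ln(I850) + a8*ln(I680)*R + a9,

with the penalty weight and L1/L2 mixing chosen by k-fold cross-validation.
Stage two exploits the near-linear relation between the log-intensity ratio
R and oxygen saturation at fixed concentration:

    SO2  = alpha * R + beta
    alpha = m_alpha * Hgb + b_alpha
    beta  = m_beta  * Hgb + b_beta

where alpha and beta are obtained from per-bin ordinary least squares of
SO2 on R at binned hemoglobin values (+-0.5 g/dL), followed by unweighted
linear fits of the bin coefficients against the bin centers.  During
calibration the bins use the BGA reference concentration; at inference the
correction uses the stage-one concentration estimate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .errors import (
    FoldError,
    InsufficientDataError,
    InsufficientStructureError,
    NotFittedError,
    ParameterError,
    RankDeficiencyError,
)
from .preprocessing import FEATURE_NAMES, FeatureVector, SensorScaling, feature_matrix

logger = logging.getLogger("hemotrans")

DEFAULT_MIXING_GRID = (0.1, 0.5, 0.9)
SCHEMA_VERSION = 1


def default_lambda_grid() -> np.ndarray:
    """50-point logarithmic penalty ladder."""
    return np.logspace(-5, 0, 50)


@dataclass
class HgbModel:
    """Fitted stage-one coefficients a1..a9 plus regularization metadata.

    ``coeffs`` are on the raw feature scale (de-standardized); the
    standardization used during fitting is retained for provenance.
    """

    coeffs: list
    penalty_lambda: float
    mixing: float
    cv_folds: int
    feature_means: list
    feature_scales: list
    cv_mse: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.coeffs) != 9:
            raise ParameterError("coeffs must have length 9")


@dataclass
class BinFit:
    """One hemoglobin bin's SO2-vs-R line."""

    hgb_center: float
    alpha: float
    beta: float
    r2: float
    n: int


@dataclass
class SO2Model:
    """Stage-two coefficients of the concentration-corrected ratio model."""

    m_alpha: float
    b_alpha: float
    m_beta: float
    b_beta: float
    bin_halfwidth: float = 0.5
    bin_fits: list = field(default_factory=list)


def split_calibration_validation(
    samples: pd.DataFrame, fraction: float = 0.5, seed: int = 0
):
    """Stratified-by-day split of sample ids into (calibration, validation).

    ``samples`` needs columns ``sample_id`` and ``day_id``.  Each day
    contributes approximately ``fraction`` of its samples to calibration,
    with at least one sample of every day in each group.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    cal, val = [], []
    for day in sorted(samples["day_id"].unique()):
        ids = samples.loc[samples["day_id"] == day, "sample_id"].to_numpy()
        if len(ids) < 2:
            raise InsufficientDataError(
                f"day {day} has {len(ids)} sample(s); need >= 2 for a stratified split"
            )
        ids = ids[np.argsort(ids)]
        perm = rng.permutation(len(ids))
        k = int(math.floor(fraction * len(ids) + 0.5))
        k = min(max(k, 1), len(ids) - 1)
        cal.extend(ids[perm[:k]])
        val.extend(ids[perm[k:]])
    return sorted(cal), sorted(val)


def _as_design(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        X = feature_matrix(list(features))
    if X.ndim != 2 or X.shape[1] != 9:
        raise ParameterError("features must form an (n, 9) design matrix")
    return X


def _solve_enet(Xs: np.ndarray, y: np.ndarray, lam: float, mix: float):
    """Elastic net on a standardized design; exact least squares at lam=0."""
    if lam == 0.0:
        A = np.column_stack([Xs, np.ones(len(Xs))])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        return sol[:-1], float(sol[-1])
    model = ElasticNet(
        alpha=lam, l1_ratio=mix, fit_intercept=True, max_iter=100000, tol=1e-10
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    return model.coef_.copy(), float(model.intercept_)


def fit_hgb_model(
    features,
    truth_hgb: Sequence[float],
    cv_folds: int = 5,
    mixing_grid: Sequence[float] = DEFAULT_MIXING_GRID,
    lambda_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> HgbModel:
    """Fit the stage-one hemoglobin model with cross-validated elastic net.

    The penalized objective on standardized non-constant features is

        (1/2n) * sum (y - Xw - a9)^2
        + lam * [mix * sum|w| + (1 - mix)/2 * sum w^2]

    and ``(lam, mix)`` minimizing the mean squared error across seeded
    k-fold splits is selected (ties to the smaller ``lam``, then the
    smaller ``mix``).  Returned coefficients are de-standardized; a
    ``lam = 0`` entry in the grid reduces to ordinary least squares.
    """
    X = _as_design(features)
    y = np.asarray(truth_hgb, dtype=float)
    if len(y) != len(X):
        raise ParameterError("features and truth_hgb length mismatch")
    n = len(y)
    if n < cv_folds:
        raise FoldError(f"{n} samples < {cv_folds} folds")
    if cv_folds < 2:
        raise ParameterError("cv_folds must be >= 2")
    if np.any((y < 2.0) | (y > 20.0)):
        logger.warning("reference Hgb outside the 2-20 g/dL physiological range")

    lambda_grid = (
        default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    )
    if np.any(lambda_grid < 0):
        raise ParameterError("penalty weights must be non-negative")

    X8 = X[:, :8]
    means = X8.mean(axis=0)
    scales = X8.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = (X8 - means) / scales

    folds = list(KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(Xs))
    best = None  # (mse, lam, mix)
    for mix in sorted(mixing_grid):
        for lam in sorted(lambda_grid):
            errs = []
            for tr, te in folds:
                w, b = _solve_enet(Xs[tr], y[tr], float(lam), float(mix))
                errs.append(np.mean((y[te] - Xs[te] @ w - b) ** 2))
            mse = float(np.mean(errs))
            if best is None or mse < best[0] - 1e-15 * max(1.0, abs(best[0])):
                best = (mse, float(lam), float(mix))
    cv_mse, lam, mix = best

    if lam == 0.0:
        A = np.column_stack([Xs, np.ones(n)])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise RankDeficiencyError("design is singular; OLS (lam=0) is not identifiable")
    w, b = _solve_enet(Xs, y, lam, mix)

    coeffs = np.zeros(9)
    coeffs[:8] = w / scales
    coeffs[8] = b - float(np.sum(w * means / scales))
    return HgbModel(
        coeffs=[float(c) for c in coeffs],
        penalty_lambda=lam,
        mixing=mix,
        cv_folds=cv_folds,
        feature_means=[float(m) for m in means],
        feature_scales=[float(s) for s in scales],
        cv_mse=cv_mse,
    )


def predict_hgb(feature: Union[FeatureVector, np.ndarray], model: HgbModel) -> float:
    """Stage-one prediction: dot product of raw-scale coefficients and terms."""
    if model is None or model.coeffs is None:
        raise NotFittedError("hemoglobin model is not fitted")
    terms = feature.terms if isinstance(feature, FeatureVector) else np.asarray(feature)
    value = float(np.dot(model.coeffs, terms))
    if not 2.0 <= value <= 20.0:
        logger.info("predicted Hgb %.2f g/dL outside the 2-20 g/dL range", value)
    return value


def predict_hgb_many(features, model: HgbModel) -> np.ndarray:
    X = _as_design(features)
    if model is None or model.coeffs is None:
        raise NotFittedError("hemoglobin model is not fitted")
    return X @ np.asarray(model.coeffs)


def _bin_center(hgb: float) -> int:
    """Nearest integer g/dL center, ties assigned to the lower center."""
    return int(math.ceil(hgb - 0.5))


def fit_so2_model(
    features,
    truth_so2: Sequence[float],
    hgb_for_binning: Sequence[float],
    bin_halfwidth: float = 0.5,
    min_bin_size: int = 3,
) -> SO2Model:
    """Fit the stage-two ratio model on binned calibration data.

    Stage one of the fit: within each retained integer-centered hemoglobin
    bin, OLS of SO2 on R gives (alpha_j, beta_j, r2_j).  Stage two: OLS of
    alpha_j and of beta_j on the bin centers gives the linear concentration
    corrections.  Bins need ``min_bin_size`` samples and non-degenerate R
    variance to be retained; at least two retained bins are required.
    """
    if bin_halfwidth <= 0:
        raise ParameterError("bin_halfwidth must be positive")
    X = _as_design(features)
    so2 = np.asarray(truth_so2, dtype=float)
    hgb = np.asarray(hgb_for_binning, dtype=float)
    if not (len(X) == len(so2) == len(hgb)):
        raise ParameterError("features, truth_so2 and hgb_for_binning length mismatch")
    ratio = X[:, FEATURE_NAMES.index("ratio")]

    centers = sorted({_bin_center(h) for h in hgb})
    fits: list[BinFit] = []
    for c in centers:
        mask = np.abs(hgb - c) <= bin_halfwidth
        # ties on the bin edge go to the lower center
        mask &= np.array([_bin_center(h) == c for h in hgb])
        n = int(mask.sum())
        if n < min_bin_size:
            continue
        r, s = ratio[mask], so2[mask]
        if np.ptp(r) == 0 or np.ptp(s) == 0:
            continue
        alpha, beta = np.polyfit(r, s, 1)
        resid = s - (alpha * r + beta)
        r2 = 1.0 - float(np.sum(resid ** 2)) / float(np.sum((s - s.mean()) ** 2))
        fits.append(BinFit(hgb_center=float(c), alpha=float(alpha), beta=float(beta), r2=r2, n=n))

    if len(fits) < 2:
        raise InsufficientStructureError(
            f"only {len(fits)} usable hemoglobin bin(s); need >= 2"
        )
    cs = np.array([f.hgb_center for f in fits])
    m_alpha, b_alpha = np.polyfit(cs, [f.alpha for f in fits], 1)
    m_beta, b_beta = np.polyfit(cs, [f.beta for f in fits], 1)
    return SO2Model(
        m_alpha=float(m_alpha),
        b_alpha=float(b_alpha),
        m_beta=float(m_beta),
        b_beta=float(b_beta),
        bin_halfwidth=bin_halfwidth,
        bin_fits=fits,
    )


def predict_so2(
    feature: Union[FeatureVector, float],
    hgb_estimate: float,
    model: SO2Model,
):
    """Stage-two prediction; returns ``(so2_pct, clamped)``.

    ``feature`` may be a FeatureVector or the ratio R directly.  Saturation
    is clamped to [0, 100]; concentration is deliberately never clamped so
    that calibration failures stay visible.
    """
    if model is None:
        raise NotFittedError("saturation model is not fitted")
    ratio = feature.ratio if isinstance(feature, FeatureVector) else float(feature)
    alpha = model.m_alpha * hgb_estimate + model.b_alpha
    beta = model.m_beta * hgb_estimate + model.b_beta
    so2 = alpha * ratio + beta
    clamped = so2 < 0.0 or so2 > 100.0
    return min(max(so2, 0.0), 100.0), clamped


# ---------------------------------------------------------------------------
# Bundle serialization


@dataclass
class CalibrationBundle:
    """Everything needed to run a fitted calibration on new data."""

    hgb_model: HgbModel
    so2_model: SO2Model
    scalings: list
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "hgb_model": dataclasses.asdict(self.hgb_model),
            "so2_model": dataclasses.asdict(self.so2_model),
            "scalings": [dataclasses.asdict(s) for s in self.scalings],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationBundle":
        so2_raw = dict(d["so2_model"])
        so2_raw["bin_fits"] = [BinFit(**bf) for bf in so2_raw.get("bin_fits", [])]
        return cls(
            hgb_model=HgbModel(**d["hgb_model"]),
            so2_model=SO2Model(**so2_raw),
            scalings=[SensorScaling(**s) for s in d["scalings"]],
            provenance=d.get("provenance", {}),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CalibrationBundle":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
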