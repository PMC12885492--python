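"""End-to-end orchestration: simulate -> scale -> fit -> predict -> report.

All randomness flows from one top-level seed that is split into named
substreams (simulation, calibration/validation split, cross-validation
folds), so a full study is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import forward_model as fm
from .agreement import N_PREDICTORS, AgreementReport, PairedMeasurements, compute_report
from .calibration import (
    CalibrationBundle,
    fit_hgb_model,
    fit_so2_model,
    predict_hgb,
    predict_so2,
    split_calibration_validation,
)
from .errors import DataIntegrityError
from .preprocessing import (
    FeatureVector,
    IntensityWindow,
    compute_sensor_scaling,
    build_features,
    scaling_for,
)

WINDOW_COLUMNS = ["sample_id", "sensor_id", "day_id", "i680", "i850", "n_points"]
BLOODGAS_COLUMNS = ["sample_id", "day_id", "timestamp_s", "hgb_gdl", "so2_pct"]


def derive_seeds(seed: int) -> dict:
    """Split one top-level seed into named substream seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulation", "split", "cv_folds")
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def _windows_as_objects(windows: pd.DataFrame) -> list[IntensityWindow]:
    return [
        IntensityWindow(
            sample_id=int(r.sample_id),
            sensor_id=int(r.sensor_id),
            day_id=int(r.day_id),
            i680=float(r.i680),
            i850=float(r.i850),
            n_points=int(r.n_points),
        )
        for r in windows.itertuples(index=False)
    ]


def check_join(windows: pd.DataFrame, bloodgas: pd.DataFrame) -> None:
    """Every window sample_id must have a blood-gas row, and vice versa."""
    w_ids = set(windows["sample_id"])
    b_ids = set(bloodgas["sample_id"])
    orphans = sorted(w_ids ^ b_ids)
    if orphans:
        raise DataIntegrityError(
            f"sample_ids present on only one side of the join: {orphans[:20]}"
        )


def features_for_windows(windows: pd.DataFrame, scalings) -> list[FeatureVector]:
    """Scaled feature vectors aligned with the rows of ``windows``."""
    return [
        build_features(w, scaling_for(scalings, w.sensor_id))
        for w in _windows_as_objects(windows)
    ]


def scaled_ratio_table(
    windows: pd.DataFrame, bloodgas: pd.DataFrame, scalings
) -> pd.DataFrame:
    """Join windows with reference values and attach the scaled ratio R."""
    check_join(windows, bloodgas)
    feats = features_for_windows(windows, scalings)
    out = windows.merge(bloodgas[["sample_id", "hgb_gdl", "so2_pct"]], on="sample_id")
    out = out.copy()
    out["ratio"] = [f.ratio for f in feats]
    out["ln680"] = [f.ln680 for f in feats]
    out["ln850"] = [f.ln850 for f in feats]
    return out


def fit_bundle(
    windows: pd.DataFrame,
    bloodgas: pd.DataFrame,
    split_fraction: float = 0.5,
    split_seed: int = 0,
    cv_seed: int = 0,
    cv_folds: int = 5,
    mixing_grid: Sequence[float] = (0.1, 0.5, 0.9),
    lambda_grid=None,
    bin_halfwidth: float = 0.5,
    min_bin_size: int = 3,
    provenance: Optional[dict] = None,
):
    """Fit a full calibration bundle on the stratified calibration half.

    Returns ``(bundle, cal_ids, val_ids)``.  Sensor scalings are computed
    from calibration-split windows only, then applied everywhere.
    """
    check_join(windows, bloodgas)
    cal_ids, val_ids = split_calibration_validation(
        bloodgas, fraction=split_fraction, seed=split_seed
    )
    cal_windows = windows[windows["sample_id"].isin(cal_ids)]
    scalings = compute_sensor_scaling(_windows_as_objects(cal_windows))

    feats = features_for_windows(cal_windows, scalings)
    ref = bloodgas.set_index("sample_id")
    hgb_ref = ref.loc[cal_windows["sample_id"], "hgb_gdl"].to_numpy(float)
    so2_ref = ref.loc[cal_windows["sample_id"], "so2_pct"].to_numpy(float)

    hgb_model = fit_hgb_model(
        feats,
        hgb_ref,
        cv_folds=cv_folds,
        mixing_grid=mixing_grid,
        lambda_grid=lambda_grid,
        seed=cv_seed,
    )
    so2_model = fit_so2_model(
        feats,
        so2_ref,
        hgb_for_binning=hgb_ref,
        bin_halfwidth=bin_halfwidth,
        min_bin_size=min_bin_size,
    )
    prov = {
        "split_fraction": split_fraction,
        "split_seed": split_seed,
        "cv_seed": cv_seed,
        "calibration_sample_ids": [int(i) for i in cal_ids],
        "validation_sample_ids": [int(i) for i in val_ids],
    }
    if provenance:
        prov.update(provenance)
    bundle = CalibrationBundle(
        hgb_model=hgb_model, so2_model=so2_model, scalings=scalings, provenance=prov
    )
    return bundle, cal_ids, val_ids


def apply_bundle(bundle: CalibrationBundle, windows: pd.DataFrame) -> pd.DataFrame:
    """Predict Hgb then SO2 (using predicted Hgb) for every window row."""
    feats = features_for_windows(windows, bundle.scalings)
    rows = []
    for w, f in zip(windows.itertuples(index=False), feats):
        hgb = predict_hgb(f, bundle.hgb_model)
        so2, clamped = predict_so2(f, hgb, bundle.so2_model)
        rows.append(
            {
                "sample_id": int(w.sample_id),
                "sensor_id": int(w.sensor_id),
                "hgb_pred_gdl": hgb,
                "so2_pred_pct": so2,
                "so2_clamped": bool(clamped),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "sensor_id", "hgb_pred_gdl", "so2_pred_pct", "so2_clamped"],
    )


def evaluate_predictions(
    predictions: pd.DataFrame,
    bloodgas: pd.DataFrame,
    split_of: Optional[dict] = None,
) -> list[AgreementReport]:
    """Agreement reports per (sensor, split, parameter).

    ``split_of`` maps sample_id -> split label; without it all rows are
    labeled ``"all"``.
    """
    merged = predictions.merge(bloodgas, on="sample_id", how="inner")
    if len(merged) < 2:
        raise DataIntegrityError("fewer than 2 joined prediction/reference rows")
    merged = merged.copy()
    merged["split"] = (
        merged["sample_id"].map(split_of).fillna("all") if split_of else "all"
    )
    reports = []
    for sensor in sorted(merged["sensor_id"].unique()):
        for split in sorted(merged.loc[merged["sensor_id"] == sensor, "split"].unique()):
            sub = merged[(merged["sensor_id"] == sensor) & (merged["split"] == split)]
            for parameter, pred_col, ref_col in (
                ("hgb", "hgb_pred_gdl", "hgb_gdl"),
                ("so2", "so2_pred_pct", "so2_pct"),
            ):
                pairs = PairedMeasurements.from_arrays(
                    sub[pred_col],
                    sub[ref_col],
                    sensor_id=int(sensor),
                    split_label=str(split),
                    day_ids=tuple(int(d) for d in sub["day_id"]),
                )
                reports.append(
                    compute_report(pairs, N_PREDICTORS[parameter], parameter=parameter)
                )
    return reports


def reports_to_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Tidy one-row-per-report table."""
    return pd.DataFrame(
        [
            {
                "sensor_id": r.sensor_id,
                "split": r.split_label,
                "parameter": r.parameter,
                "n": r.n,
                "arms": r.arms,
                "mad": r.mad,
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "bias": r.bias,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
            }
            for r in reports
        ]
    )


@dataclass
class StudyResult:
    """Everything produced by one seeded synthetic study."""

    protocol: fm.ExperimentProtocol
    seeds: dict
    windows: pd.DataFrame
    bloodgas: pd.DataFrame
    bundle: CalibrationBundle
    cal_ids: list
    val_ids: list
    predictions: pd.DataFrame
    reports: list = field(default_factory=list)

    @property
    def report_frame(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)

    def mean_validation_arms(self, parameter: str) -> float:
        """Validation ARMS averaged over sensors for one parameter."""
        vals = [
            r.arms
            for r in self.reports
            if r.parameter == parameter and r.split_label == "validation"
        ]
        return float(np.mean(vals))


def run_study(
    protocol: Optional[fm.ExperimentProtocol] = None,
    constants: Optional[fm.OpticalConstants] = None,
    profiles: Optional[Sequence[fm.SensorProfile]] = None,
    split_fraction: float = 0.5,
    seed: Optional[int] = None,
    cv_folds: int = 5,
    lambda_grid=None,
) -> StudyResult:
    """Run the full synthetic study.

    ``seed`` is the single top-level seed; when omitted, the protocol's own
    seed is used as the top-level seed.
    """
    protocol = protocol or fm.ExperimentProtocol()
    top_seed = protocol.seed if seed is None else int(seed)
    seeds = derive_seeds(top_seed)
    protocol = replace(protocol, seed=seeds["simulation"])

    windows, bloodgas = fm.simulate_experiment(protocol, constants, profiles)
    bundle, cal_ids, val_ids = fit_bundle(
        windows,
        bloodgas,
        split_fraction=split_fraction,
        split_seed=seeds["split"],
        cv_seed=seeds["cv_folds"],
        cv_folds=cv_folds,
        lambda_grid=lambda_grid,
        provenance={"top_seed": top_seed},
    )
    predictions = apply_bundle(bundle, windows)
    split_of = {i: "calibration" for i in cal_ids}
    split_of.update({i: "validation" for i in val_ids})
    reports = evaluate_predictions(predictions, bloodgas, split_of)
    return StudyResult(
        protocol=protocol,
        seeds=seeds,
        windows=windows,
        bloodgas=bloodgas,
        bundle=bundle,
        cal_ids=cal_ids,
        val_ids=val_ids,
        predictions=predictions,
        reports=reports,
    )
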