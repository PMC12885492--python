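"""CSV/JSON input and output.

Dialect everywhere: comma-separated, header row, UTF-8, '.' decimal.
Readers validate the schema and name the missing column on failure; every
writer drops a ``<name>.meta.json`` sidecar recording the seed and config
snapshot that produced the file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FormatError
from .forward_model import SAMPLING_HZ, WINDOW_SECONDS
from .preprocessing import IntensityWindow

INTENSITY_COLUMNS = ["timestamp_s", "sensor_id", "wavelength_nm", "adc_counts", "pulse_number"]
WINDOW_COLUMNS = ["sample_id", "sensor_id", "day_id", "i680", "i850", "n_points"]
BLOODGAS_COLUMNS = ["sample_id", "day_id", "timestamp_s", "hgb_gdl", "so2_pct"]
PREDICTION_COLUMNS = ["sample_id", "sensor_id", "hgb_pred_gdl", "so2_pred_pct", "so2_clamped"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: {exc}") from exc
    _require_columns(df, columns, path)
    return df


def read_windows(path) -> pd.DataFrame:
    return read_csv(path, WINDOW_COLUMNS)


def read_bloodgas(path) -> pd.DataFrame:
    return read_csv(path, BLOODGAS_COLUMNS)


def read_intensity(path) -> pd.DataFrame:
    return read_csv(path, INTENSITY_COLUMNS)


def read_predictions(path) -> pd.DataFrame:
    return read_csv(path, PREDICTION_COLUMNS)


def write_csv_with_meta(
    df: pd.DataFrame, path, seed: Optional[int] = None, config: Optional[dict] = None
) -> None:
    """Write a CSV plus its ``.meta.json`` provenance sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {"schema_version": 1, "rows": int(len(df)), "seed": seed, "config": config}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def windows_from_timeseries(
    intensity: pd.DataFrame,
    bloodgas: pd.DataFrame,
    window_s: float = WINDOW_SECONDS,
) -> pd.DataFrame:
    """Reduce a raw 20 Hz stream to per-sample windows.

    Each blood-gas sample claims the ``window_s`` seconds of records
    preceding its timestamp (the draw happens right after the optical
    recording).  Normalization by pulse number happens here.
    """
    _require_columns(intensity, INTENSITY_COLUMNS, "intensity")
    _require_columns(bloodgas, BLOODGAS_COLUMNS, "bloodgas")
    rows = []
    for bg in bloodgas.itertuples(index=False):
        in_window = intensity[
            (intensity["timestamp_s"] >= bg.timestamp_s - window_s)
            & (intensity["timestamp_s"] <= bg.timestamp_s)
        ]
        for sensor in sorted(in_window["sensor_id"].unique()):
            sub = in_window[in_window["sensor_id"] == sensor]
            norm = sub["adc_counts"] / sub["pulse_number"]
            means, counts = {}, {}
            for wl in (680, 850):
                sel = sub["wavelength_nm"] == wl
                counts[wl] = int(sel.sum())
                means[wl] = float(norm[sel].mean()) if counts[wl] else float("nan")
            if min(counts.values()) == 0:
                from .errors import IncompleteWindowError

                raise IncompleteWindowError(
                    f"sample {bg.sample_id} sensor {sensor}: missing wavelength data"
                )
            rows.append(
                IntensityWindow(
                    sample_id=int(bg.sample_id),
                    sensor_id=int(sensor),
                    day_id=int(bg.day_id),
                    i680=means[680],
                    i850=means[850],
                    n_points=min(counts.values()),
                )
            )
    return pd.DataFrame([vars(w) for w in rows], columns=WINDOW_COLUMNS)
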