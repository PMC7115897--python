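"""Reading cohort tables, exporting weights, traces and model reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PhenotypeDataset
from .errors import MissingGroupError, SchemaError
from .models import ModelFit, effective_control_count
from .tuning import PipelineResult
from .windows import WeightVector

logger = logging.getLogger("softwin.io")

#: JSON report schema version; bump on any structural change.
REPORT_SCHEMA_VERSION = 1

DEFAULT_COLUMNS = {
    "date": "date_of_experiment",
    "response": "response",
    "group": "biological_sample_group",
    "sex": "sex",
    "weight": "weight",
    "batch": "batch",
}

MANDATORY = ("date", "response", "group")


def _parse_times(raw: pd.Series) -> pd.Series:
    """Dates as ISO-8601 strings or epoch seconds -> pandas timestamps."""
    if pd.api.types.is_numeric_dtype(raw):
        return pd.to_datetime(raw, unit="s")
    return pd.to_datetime(raw, format="ISO8601")


def read_cohort(
    path,
    mapping: dict | None = None,
    delimiter: str = ",",
    require_mutants: bool = False,
) -> PhenotypeDataset:
    """Read a delimited cohort table into a :class:`PhenotypeDataset`.

    ``mapping`` overrides the default column names (keys: date, response,
    group, sex, weight, batch).  Times become float days since the earliest
    observation; rows with an unparseable response are dropped and counted
    in the log; the batch defaults to the calendar day when no batch column
    is present.  Group values equal to ``control`` (case-insensitive) are
    controls, everything else is treated as mutant.
    """
    cols = {**DEFAULT_COLUMNS, **(mapping or {})}
    raw = pd.read_csv(path, sep=delimiter)
    missing = [cols[key] for key in MANDATORY if cols[key] not in raw.columns]
    if missing:
        raise SchemaError(missing)

    stamps = _parse_times(raw[cols["date"]])
    response = pd.to_numeric(raw[cols["response"]], errors="coerce")
    dropped = int(response.isna().sum())
    if dropped:
        logger.info("dropped %d rows with unparseable response", dropped)
    keep = response.notna()

    group = (
        raw[cols["group"]]
        .astype(str)
        .str.lower()
        .map(lambda g: "control" if g == "control" else "mutant")
    )
    sex = raw[cols["sex"]] if cols["sex"] in raw.columns else pd.Series("F", index=raw.index)
    weight = (
        pd.to_numeric(raw[cols["weight"]], errors="coerce")
        if cols["weight"] in raw.columns
        else pd.Series(np.nan, index=raw.index)
    )
    batch = (
        raw[cols["batch"]].astype(str)
        if cols["batch"] in raw.columns
        else stamps.dt.strftime("%Y-%m-%d")
    )

    t0 = stamps[keep].min()
    frame = pd.DataFrame(
        {
            "time": (stamps - t0).dt.total_seconds() / 86400.0,
            "response": response,
            "group": group,
            "sex": sex.astype(str),
            "body_weight": weight,
            "batch": batch,
        }
    )[keep].reset_index(drop=True)
    data = PhenotypeDataset(frame)
    if require_mutants and not data.is_mutant.any():
        raise MissingGroupError(f"{path}: no mutant rows")
    return data


def write_cohort(data: PhenotypeDataset, path, origin: str = "2016-01-01") -> None:
    """Write a cohort CSV with the standard column names (inverse of read)."""
    t0 = pd.Timestamp(origin)
    out = pd.DataFrame(
        {
            "date_of_experiment": (
                t0 + pd.to_timedelta(data.times, unit="D")
            ).strftime("%Y-%m-%dT%H:%M:%S"),
            "response": data.response,
            "biological_sample_group": data.data["group"],
            "sex": data.data["sex"],
            "weight": data.data.get("body_weight"),
            "batch": data.data["batch"],
        }
    )
    out.to_csv(path, index=False)


def write_weights(path, wv: WeightVector, peaks=None) -> None:
    """Export weights as CSV (time, weight, is_peak) at full double precision."""
    peaks = np.asarray(peaks if peaks is not None else [], dtype=float)
    is_peak = np.isin(wv.times, peaks)
    frame = pd.DataFrame(
        {"time": wv.times, "weight": wv.weights, "is_peak": is_peak.astype(int)}
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_weights(path) -> WeightVector:
    frame = pd.read_csv(path, float_precision="round_trip")
    return WeightVector(
        times=frame["time"].to_numpy(dtype=float),
        weights=frame["weight"].to_numpy(dtype=float),
    )


def _fit_block(fit: ModelFit) -> dict:
    return {
        "model_kind": fit.model_kind,
        "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
        "stderr": {k: float(v) for k, v in fit.stderr.items()},
        "term_pvalues": {k: float(v) for k, v in fit.term_pvalues.items()},
        "notes": list(fit.notes),
    }


def build_report(result: PipelineResult, data: PhenotypeDataset) -> dict:
    """Machine-readable model report comparing windowed vs non-windowed."""
    sel = result.selection
    groups = data.data["group"].to_numpy()
    windowed_w = result.windowed.weights
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_observations": int(data.n),
        "selection": {
            "l_star": None if sel.l_star is None else float(sel.l_star),
            "k_star": None if sel.k_star is None else float(sel.k_star),
            "T": float(sel.T),
            "peaks": [float(p) for p in sel.peaks],
            "fallback": bool(sel.fallback),
            "notes": list(sel.notes),
        },
        "windowed": _fit_block(result.windowed),
        "nonwindowed": _fit_block(result.nonwindowed),
        "effective_controls": {
            "windowed": effective_control_count(windowed_w, groups),
            "nonwindowed": effective_control_count(
                result.nonwindowed.weights, groups
            ),
        },
    }


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
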