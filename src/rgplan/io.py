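"""File formats and provenance.

Plain-text interchange only: calibration sweeps as CSV (columns ``rg,
signal_integral, noise_rms, fid_max, n_averages``) with a JSON metadata
sidecar, FIDs as CSV (``time, real, imag``) with a JSON sidecar, plans and
quantification reports as JSON.  Every CLI-produced JSON carries a
provenance block (command, parameters, package version, seed) and is
written with sorted keys so identical configurations yield byte-identical
output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationCurve, CalibrationPoint, build_calibration
from .errors import SchemaError
from .physics import get_nucleus
from .quantify import FIDRecord

__all__ = [
    "CALIBRATION_COLUMNS",
    "read_calibration_table",
    "write_calibration_csv",
    "load_curve",
    "save_curve",
    "write_fid",
    "read_fid",
    "write_json",
    "read_json",
    "provenance",
    "plan_to_dict",
]

CALIBRATION_COLUMNS = ("rg", "signal_integral", "noise_rms", "fid_max")


def provenance(command: str, params: dict, seed: int | None = None) -> dict:
    """Machine-readable run record embedded in every output JSON."""
    return {
        "command": command,
        "package": "rgplan",
        "version": __version__,
        "seed": seed,
        "parameters": {k: params[k] for k in sorted(params)},
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_calibration_table(path, rg_units: str = "linear") -> list[CalibrationPoint]:
    """Parse a calibration CSV into points; missing columns raise SchemaError.

    With ``rg_units="db"`` the rg column is converted to the linear
    amplitude convention (``10**(dB/20)``) before validation, so dB-valued
    gains (which may be negative) are accepted.
    """
    from .calibration import rg_from_db

    df = pd.read_csv(path)
    for col in CALIBRATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"calibration CSV is missing column {col!r}")
    if "n_averages" not in df.columns:
        df["n_averages"] = 1
    if rg_units == "db":
        df["rg"] = rg_from_db(df["rg"].to_numpy())
    return [
        CalibrationPoint(
            rg=float(r.rg),
            signal_integral=float(r.signal_integral),
            noise_rms=float(r.noise_rms),
            fid_max=float(r.fid_max),
            n_averages=int(r.n_averages),
        )
        for r in df.itertuples()
    ]


def write_calibration_csv(curve: CalibrationCurve, path) -> None:
    pd.DataFrame(
        {
            "rg": curve.rgs,
            "signal_integral": curve.signals,
            "noise_rms": curve.noises,
            "fid_max": curve.fid_maxes,
            "n_averages": [p.n_averages for p in curve.points],
        }
    ).to_csv(path, index=False)


def save_curve(curve: CalibrationCurve, csv_path, meta_path) -> None:
    """Write a curve as CSV + metadata JSON (always linear rg in the CSV)."""
    write_calibration_csv(curve, csv_path)
    meta = {
        "nucleus": curve.nucleus.name if curve.nucleus else None,
        "field_T": curve.field,
        "temperature_K": curve.temperature,
        "alpha_ref_deg": curve.alpha_ref,
        "p_ref": curve.p_ref,
        "c_ref_M": curve.c_ref,
        "rg_units": curve.rg_units,
        "slope_integral": curve.slope_integral,
        "slope_fid": curve.slope_fid,
    }
    write_json(meta, meta_path)


def load_curve(csv_path, meta_path=None) -> CalibrationCurve:
    """Load a curve from CSV (+ optional metadata JSON) and refit slopes."""
    points = read_calibration_table(csv_path)
    meta = read_json(meta_path) if meta_path else {}
    nucleus = get_nucleus(meta["nucleus"]) if meta.get("nucleus") else None
    return build_calibration(
        points,
        alpha_ref=meta.get("alpha_ref_deg", 90.0),
        p_ref=meta.get("p_ref", 1.0),
        c_ref=meta.get("c_ref_M", 1.0),
        nucleus=nucleus,
        field=meta.get("field_T"),
        temperature=meta.get("temperature_K"),
        rg_units=meta.get("rg_units", "linear"),
        normalize_averages=False,
    )


def write_fid(fid: FIDRecord, csv_path, meta_path=None) -> None:
    t = np.arange(fid.samples.size) * fid.dwell
    pd.DataFrame(
        {"time": t, "real": fid.samples.real, "imag": fid.samples.imag}
    ).to_csv(csv_path, index=False)
    if meta_path:
        meta = {
            "dwell_s": fid.dwell,
            "rg": fid.rg,
            "alpha_deg": fid.alpha,
            "clipped": fid.clipped,
            "meta": {
                k: v for k, v in fid.meta.items() if isinstance(v, (int, float, str))
            },
        }
        write_json(meta, meta_path)


def read_fid(csv_path, meta_path=None) -> FIDRecord:
    df = pd.read_csv(csv_path)
    for col in ("time", "real", "imag"):
        if col not in df.columns:
            raise SchemaError(f"FID CSV is missing column {col!r}")
    samples = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    t = df["time"].to_numpy()
    dwell = float(t[1] - t[0]) if t.size > 1 else 1.0
    meta = read_json(meta_path) if meta_path else {}
    return FIDRecord(
        samples,
        meta.get("dwell_s", dwell),
        rg=meta.get("rg", 1.0),
        alpha=meta.get("alpha_deg", 90.0),
        clipped=bool(meta.get("clipped", False)),
        meta=meta.get("meta", {}),
    )


def plan_to_dict(plan, include_maps: bool = False) -> dict:
    """Serialize a PlanResult for plan.json."""
    out = {
        "rg_opt": plan.rg_opt,
        "alpha_opt_deg": plan.alpha_opt,
        "snr_pred": plan.snr_pred,
        "fid_max_pred": plan.fid_max_pred,
        "clip_margin": plan.clip_margin,
    }
    if include_maps:
        out["maps"] = {
            "rg_grid": plan.rg_grid.tolist(),
            "alpha_grid_deg": plan.alpha_grid.tolist(),
            "snr": plan.snr_map.tolist(),
            "signal": plan.signal_map.tolist(),
            "feasible": plan.feasible.astype(int).tolist(),
        }
    return out
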