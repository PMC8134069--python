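"""Delimited-text readers (unit-converting, schema-validated) and JSON reports.

All on-disk tables are CSV or TSV (delimiter auto-detected).  Display units
follow the field's conventions -- displacements in um or nm, stiffness in
uN/m, forces in pN, gating forces in fN -- and are converted to SI on read.
Reports are JSON with the resolved configuration, the model conventions in
force, and every seed embedded, so a run is reproducible from its report.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fluctuation import FluctuationTrace
from .frap import FrapSeries
from .gating_spring import StiffnessCurve
from .qpcr import validate_ct_table

__all__ = [
    "read_table",
    "load_stiffness_curve",
    "load_force_steps",
    "load_frap_series",
    "load_fluctuation_trace",
    "load_manifest",
    "load_ct_table",
    "write_report",
    "CONVENTIONS",
]

#: modelling conventions embedded in every report
CONVENTIONS = {
    "stiffness_model": "K(X) = K_inf - sum_j N_j z_j^2/(kB T) p_j(1-p_j), "
                       "Boltzmann p_j(X) = 1/(1+exp(-z_j (X - X0_j)/(kB T)))",
    "K_GS": "K_inf - K_steady",
    "NL": "dK / K_inf with dK_j = N_j z_j^2 / (4 kB T)",
    "energy_gain": "T_eff/T_bath - 1 with T_eff = K_receiver <x^2> / kB; "
                   "also reported in joules as kB (T_eff - T_bath)",
    "sign": "positive displacement = anterior deflection (labelling convention)",
}


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()
    if not sample:
        raise ValueError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample[0], delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_table(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    """Read a CSV/TSV file and validate its header against a schema.

    ``required`` columns must be present (error names the missing column);
    numeric parse failures are reported with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in list(required) + [c for c in optional if c in df.columns]:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                for i, v in enumerate(df[col]):
                    try:
                        float(v)
                    except (ValueError, TypeError):
                        raise ValueError(
                            f"{path}: unparseable numeric value {v!r} at line {i + 2}, "
                            f"column '{col}'") from None
    return df


def load_stiffness_curve(path) -> StiffnessCurve:
    """Columns: displacement_um, stiffness_uN_per_m[, stiffness_err] (uN/m)."""
    df = read_table(path, ["displacement_um", "stiffness_uN_per_m"], ["stiffness_err"])
    df = df.sort_values("displacement_um")
    err = df["stiffness_err"].to_numpy() * 1e-6 if "stiffness_err" in df.columns else None
    return StiffnessCurve(X=df["displacement_um"].to_numpy() * 1e-6,
                          K=df["stiffness_uN_per_m"].to_numpy() * 1e-6,
                          K_err=err)


def load_force_steps(path) -> list[tuple[float, float]]:
    """Columns: force_pN, displacement_um -> SI (force N, displacement m) pairs."""
    df = read_table(path, ["force_pN", "displacement_um"])
    return [(f * 1e-12, x * 1e-6)
            for f, x in zip(df["force_pN"], df["displacement_um"])]


def load_frap_series(path) -> list[FrapSeries]:
    """Columns: animal_id, t_hr, relative_fluorescence; one series per animal."""
    df = read_table(path, ["t_hr", "relative_fluorescence"])
    if "animal_id" not in df.columns:
        df["animal_id"] = "pooled"
    out = []
    for animal, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("t_hr")
        out.append(FrapSeries(t=sub["t_hr"].to_numpy(),
                              F=sub["relative_fluorescence"].to_numpy(),
                              animal_id=str(animal)))
    return out


def load_fluctuation_trace(path, T_bath: float, K_receiver: float,
                           animal_id: str = "") -> FluctuationTrace:
    """Columns: t_s, displacement_nm; fs inferred from the time column."""
    df = read_table(path, ["t_s", "displacement_nm"])
    t = df["t_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) < 1 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return FluctuationTrace(x=df["displacement_nm"].to_numpy() * 1e-9,
                            fs=1.0 / dt[0], T_bath=T_bath,
                            K_receiver=K_receiver, animal_id=animal_id)


def load_manifest(path) -> pd.DataFrame:
    """Cohort manifest: columns file, condition, animal_id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    df.columns = [c.strip() for c in df.columns]
    for col in ("file", "condition", "animal_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def load_ct_table(path) -> pd.DataFrame:
    """Long-format qPCR table; see qpcr.CT_COLUMNS for the schema."""
    path = Path(path)
    # keep_default_na=False: 'nan' is a legitimate gene symbol (Nanchung)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return validate_ct_table(df)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    if callable(obj):
        return None
    return obj


def write_report(results: dict, out_dir, name: str = "report",
                 config: dict | None = None) -> Path:
    """Write a JSON report embedding results, config, and conventions."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "software": {"name": "mechanostat", "version": __version__},
        "conventions": CONVENTIONS,
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    return path
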