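"""CSV / JSON schemas shared across the pipeline.

Bench units are used on disk — substrate in nM, activator in μM, rates in
nM/s, time in seconds — and converted to the package's internal molar /
seconds convention on read.

Schemas
-------
progress curves (long format)
    ``well, compound_id, S_nM, A_uM, time_s, fluorescence``
rate tables
    ``compound_id, activator_id, S_nM, A_uM, rate_nM_per_s,
    window_start_s, window_end_s, r2, flag`` (only the concentration and
    rate columns are required on read)
screening plates (per-well rates)
    ``well, compound_id, role, rate_nM_per_s`` with role in
    basal | positive | compound
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .beacon import BeaconDesign, ProgressCurve
from .fitting import FitResult, ModelComparison, RateTable
from .rate_laws import ActivationParameters, AssayCondition, Mechanism

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "read_rate_table",
    "write_rate_table",
    "write_progress_curves",
    "read_progress_curves",
    "read_plate",
    "write_plate",
    "fit_report",
    "write_fit_report",
]

NM = 1e-9
UM = 1e-6


# ------------------------------------------------------------------ params
def params_to_dict(params: ActivationParameters) -> Dict:
    """Serialize activation parameters to bench units (nM, μM, 1/s)."""
    d = {
        "mechanism": params.mechanism.value,
        "Km_nM": params.Km / NM,
        "Ka_uM": params.Ka / UM,
        "V_nM_per_s": params.V / NM,
    }
    if params.kcat is not None:
        d["kcat_per_s"] = params.kcat
    if params.Et is not None:
        d["Et_nM"] = params.Et / NM
    if params.alpha is not None:
        d["alpha"] = params.alpha
    if params.beta is not None:
        d["beta"] = params.beta
    return d


def params_from_dict(d: Dict) -> ActivationParameters:
    """Inverse of :func:`params_to_dict`."""
    kw = dict(
        mechanism=Mechanism(d["mechanism"]),
        Km=float(d["Km_nM"]) * NM,
        Ka=float(d["Ka_uM"]) * UM,
        alpha=d.get("alpha"),
        beta=d.get("beta"),
    )
    if "kcat_per_s" in d and "Et_nM" in d:
        kw.update(kcat=float(d["kcat_per_s"]), Et=float(d["Et_nM"]) * NM)
        if "V_nM_per_s" in d:
            kw["V"] = float(d["V_nM_per_s"]) * NM
    else:
        kw["V"] = float(d["V_nM_per_s"]) * NM
        if "Et_nM" in d:
            kw["Et"] = float(d["Et_nM"]) * NM
    return ActivationParameters(**kw)


# ------------------------------------------------------------------ rates
def write_rate_table(table: RateTable, path: Union[str, Path]) -> None:
    df = table.data
    out = pd.DataFrame(
        {
            "compound_id": df.get("compound_id", ""),
            "activator_id": df.get("activator_id", table.activator_id),
            "S_nM": df["S"] / NM,
            "A_uM": df["A"] / UM,
            "rate_nM_per_s": df["rate"] / NM,
            "window_start_s": df.get("window_start", np.nan),
            "window_end_s": df.get("window_end", np.nan),
            "r2": df.get("r2", np.nan),
            "flag": df.get("flag", ""),
        }
    )
    out.to_csv(path, index=False)


def read_rate_table(path: Union[str, Path], Et: Optional[float] = None) -> RateTable:
    raw = pd.read_csv(path)
    for col in ("S_nM", "A_uM", "rate_nM_per_s"):
        if col not in raw.columns:
            raise ValueError(f"rate-table CSV lacks required column {col!r}")
    data = pd.DataFrame(
        {
            "S": raw["S_nM"].astype(float) * NM,
            "A": raw["A_uM"].astype(float) * UM,
            "rate": raw["rate_nM_per_s"].astype(float) * NM,
        }
    )
    activator = ""
    if "activator_id" in raw.columns and raw["activator_id"].notna().any():
        ids = raw["activator_id"].dropna().unique()
        activator = str(ids[0]) if len(ids) == 1 else ""
    return RateTable(data, activator_id=activator, Et=Et)


# ------------------------------------------------------------------ curves
def write_progress_curves(curves: List[ProgressCurve], path: Union[str, Path]) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well": c.well,
                    "compound_id": c.compound_id,
                    "S_nM": c.condition.S / NM,
                    "A_uM": c.condition.A / UM,
                    "time_s": c.times,
                    "fluorescence": c.fluorescence,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_progress_curves(
    path: Union[str, Path],
    Et: float = 0.0,
    design: Optional[BeaconDesign] = None,
) -> List[ProgressCurve]:
    raw = pd.read_csv(path)
    design = design or BeaconDesign()
    curves = []
    for (well, cid, s_nM, a_uM), grp in raw.groupby(
        ["well", "compound_id", "S_nM", "A_uM"], dropna=False, sort=False
    ):
        grp = grp.sort_values("time_s")
        cond = AssayCondition(
            S=float(s_nM) * NM, A=float(a_uM) * UM, Et=Et,
            activator_id=str(cid) if pd.notna(cid) else "",
        )
        curves.append(
            ProgressCurve(
                condition=cond,
                design=design,
                times=grp["time_s"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                well=str(well),
                compound_id=str(cid) if pd.notna(cid) else "",
            )
        )
    return curves


# ------------------------------------------------------------------ plates
def write_plate(plate: pd.DataFrame, path: Union[str, Path]) -> None:
    out = plate.copy()
    out["rate_nM_per_s"] = out.pop("rate") / NM
    out.to_csv(path, index=False)


def read_plate(path: Union[str, Path]) -> pd.DataFrame:
    raw = pd.read_csv(path)
    for col in ("role", "rate_nM_per_s"):
        if col not in raw.columns:
            raise ValueError(f"plate CSV lacks required column {col!r}")
    raw["rate"] = raw.pop("rate_nM_per_s").astype(float) * NM
    return raw


# ------------------------------------------------------------------ reports
def fit_report(comparison: ModelComparison) -> Dict:
    """JSON-serializable summary of a mechanism comparison."""
    report: Dict = {
        "selected": comparison.selected,
        "ambiguous": comparison.ambiguous,
        "delta_aicc": comparison.delta_aicc,
        "failures": comparison.failures,
        "fits": {},
    }
    for name, fr in comparison.fits.items():
        report["fits"][name] = {
            "parameters": params_to_dict(fr.estimates),
            "standard_errors": {
                k: (v / NM if k == "V" else v) for k, v in fr.standard_errors.items()
            },
            "sse": fr.sse,
            "n_obs": fr.n_obs,
            "n_params": fr.n_params,
            "aicc": fr.aicc,
            "converged": fr.converged,
            "n_starts_used": fr.n_starts_used,
        }
    if comparison.f_test is not None:
        report["f_test"] = comparison.f_test
    return report


def write_fit_report(comparison: ModelComparison, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(fit_report(comparison), indent=2))
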