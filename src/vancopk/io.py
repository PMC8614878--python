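"""Dataset I/O in a NONMEM-style rectangular CSV format, plus configuration.

Columns (fixed order): ID, TIME (h since the subject's first dose), AMT (mg),
RATE (mg/h), DV (mg/L), EVID (1 = dose, 0 = observation), MDV (1 = missing
DV), WT (kg), ALB (g/L), UFR (mL/kg/h).  Dose rows carry AMT > 0, RATE > 0,
EVID = 1, MDV = 1 and an empty DV; observation rows carry EVID = 0, MDV = 0
and a DV.  Covariates are constant within a subject; infusion duration is
derived as AMT / RATE.  Numerics are written with 6 significant digits and an
observation sharing its time with a dose sorts before the dose (trough
sample drawn just before the infusion starts).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Observation, PopulationDataset, SubjectRecord
from .model import DoseEvent, PatientCovariates

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "load_config"]

COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "WT", "ALB", "UFR"]


class DatasetFormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_dataset(dataset: PopulationDataset, path) -> None:
    """Write a dataset as the rectangular CSV dialect (deterministic bytes)."""
    lines = [",".join(COLUMNS)]
    for s in dataset.subjects:
        wt, alb, ufr = s.covariates.weight, s.covariates.albumin, s.covariates.ufr
        rows = []
        for o in s.observations:
            rows.append((o.time, 0, (0.0, 0.0, o.conc, 0, 0)))
        for d in s.doses:
            rows.append((d.time, 1, (d.amount, d.rate, None, 1, 1)))
        rows.sort(key=lambda r: (r[0], r[1]))
        for time, _evid, (amt, rate, dv, evid, mdv) in rows:
            dv_s = "" if dv is None else _fmt(dv)
            amt_s = "" if evid == 0 else _fmt(amt)
            rate_s = "" if evid == 0 else _fmt(rate)
            lines.append(
                f"{s.subject_id},{_fmt(time)},{amt_s},{rate_s},{dv_s},"
                f"{evid},{mdv},{_fmt(wt)},{_fmt(alb)},{_fmt(ufr)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _require(cond: bool, row: int, msg: str) -> None:
    if not cond:
        raise DatasetFormatError(f"row {row}: {msg}")


def read_dataset(path) -> PopulationDataset:
    """Parse the rectangular CSV into a PopulationDataset, validating the
    format invariants; violations raise with the offending CSV row number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"ID": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("TIME", "EVID", "MDV", "WT", "ALB", "UFR"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2
            raise DatasetFormatError(f"row {row}: non-numeric or empty {col}")
    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        g = g.reset_index()
        for col in ("WT", "ALB", "UFR"):
            _require(
                g[col].nunique() == 1,
                int(g.loc[g[col] != g[col].iloc[0], "index"].iloc[0]) + 2
                if g[col].nunique() > 1
                else 0,
                f"covariate {col} not constant within subject {sid}",
            )
        times = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            bad = int(g["index"][1:][np.diff(times) < 0].iloc[0]) + 2
            raise DatasetFormatError(
                f"row {bad}: TIME not non-decreasing within subject {sid}"
            )
        cov = PatientCovariates(
            weight=float(g["WT"].iloc[0]),
            albumin=float(g["ALB"].iloc[0]),
            ufr=float(g["UFR"].iloc[0]),
        )
        doses = []
        observations = []
        for _, r in g.iterrows():
            row = int(r["index"]) + 2
            evid = int(r["EVID"])
            mdv = int(r["MDV"])
            if evid == 1:
                _require(r["AMT"] > 0, row, "dose row requires AMT > 0")
                _require(
                    np.isfinite(r["RATE"]) and r["RATE"] > 0,
                    row,
                    "dose row requires RATE > 0",
                )
                _require(mdv == 1, row, "dose row requires MDV = 1")
                doses.append(
                    DoseEvent(
                        time=float(r["TIME"]),
                        amount=float(r["AMT"]),
                        duration=float(r["AMT"]) / float(r["RATE"]),
                    )
                )
            elif evid == 0:
                _require(mdv == 0, row, "observation row requires MDV = 0")
                _require(
                    np.isfinite(r["DV"]), row, "observation row with MDV=0 requires DV"
                )
                observations.append(Observation(float(r["TIME"]), float(r["DV"])))
            else:
                raise DatasetFormatError(f"row {row}: EVID must be 0 or 1")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                covariates=cov,
                doses=tuple(doses),
                observations=tuple(observations),
            )
        )
    return PopulationDataset(tuple(subjects))


def load_config(path) -> dict:
    """Load a flat YAML configuration file (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
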