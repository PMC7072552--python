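"""Readers and writers for viability tables and analysis reports.

Two input dialects are supported:

* long CSV — one row per well: ``cell_line, drug, conc_nM (or conc_uM, or
  conc + unit), viability`` for normalized data, or ``raw`` (plus
  ``is_control`` or ``control``) for un-normalized plate readings. Optional
  ``replicate`` column.
* wide CSV (GDSC-like) — one row per cell line x drug, a ``control`` column,
  and one column per dose with the dose encoded in the header (e.g. ``5nM``,
  ``0.01uM``).

Concentrations are canonicalized to nM on read. Parse errors name the
offending row; no row is ever dropped silently.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .curve import DoseResponseCurve, to_nM
from .models import KD2_RESISTANT_NM

__all__ = ["read_long_csv", "read_wide_table", "write_long_csv",
           "curves_to_frame", "report_to_json", "report_to_tsv"]

_DOSE_HEADER = re.compile(r"^\s*([0-9.eE+-]+)\s*(nM|uM|µM|mM|M)\s*$")


def _conc_columns(df: pd.DataFrame) -> pd.Series:
    """Extract concentrations in nM from whichever dialect is present."""
    if "conc_nM" in df.columns:
        return df["conc_nM"].astype(float)
    if "conc_uM" in df.columns:
        return df["conc_uM"].astype(float) * 1e3
    if "conc" in df.columns and "unit" in df.columns:
        return pd.Series(
            [to_nM(v, u) for v, u in zip(df["conc"], df["unit"])], index=df.index)
    raise ValueError(
        "no concentration column: expected conc_nM, conc_uM, or conc + unit")


def read_long_csv(path: str | Path):
    """Read a long-format viability CSV.

    Returns a list of :class:`DoseResponseCurve` when a ``viability`` column
    is present, otherwise the raw table (``raw`` readings, canonicalized
    ``conc_nM``) ready for :func:`biphasefit.classify.normalize_viability`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("cell_line", "drug"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    is_raw = "raw" in df.columns
    if not is_raw and "viability" not in df.columns:
        raise ValueError(f"{path}: need a viability or raw column")
    value_col = "raw" if is_raw else "viability"
    bad = df.index[pd.to_numeric(df[value_col], errors="coerce").isna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric {value_col} at row(s) {list(bad[:5])}")
    try:
        conc = _conc_columns(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    bad = df.index[~np.isfinite(conc.to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"{path}: unparseable concentration at row(s) {list(bad[:5])}")
    if (conc.to_numpy(dtype=float) < 0).any():
        rows = df.index[conc.to_numpy(dtype=float) < 0]
        raise ValueError(f"{path}: negative concentration at row(s) {list(rows[:5])}")
    out = df.copy()
    out["conc_nM"] = conc.to_numpy(dtype=float)
    if is_raw:
        return out
    curves = []
    for (cell, drug), grp in out.groupby(["cell_line", "drug"], sort=True):
        rep = grp["replicate"].to_numpy() if "replicate" in grp.columns \
            else np.zeros(len(grp), dtype=int)
        curves.append(DoseResponseCurve(
            str(cell), str(drug), grp["conc_nM"].to_numpy(dtype=float),
            grp["viability"].to_numpy(dtype=float), rep))
    return curves


def read_wide_table(path: str | Path) -> pd.DataFrame:
    """Read a wide GDSC-like table into the canonical long raw format.

    Header columns matching ``<number><unit>`` (e.g. ``5nM``, ``1.28uM``)
    are doses; a ``control`` column must be present. Returns long rows
    (cell_line, drug, conc_nM, raw, control); the uptick control rule is
    applied downstream by :func:`normalize_viability`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("cell_line", "drug"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "control" not in df.columns:
        raise ValueError(f"{path}: missing control column")
    dose_cols: list[tuple[str, float]] = []
    for col in df.columns:
        m = _DOSE_HEADER.match(col)
        if m:
            dose_cols.append((col, to_nM(float(m.group(1)), m.group(2))))
    if not dose_cols:
        raise ValueError(f"{path}: no dose columns found (expected e.g. '5nM')")
    known = {"cell_line", "drug", "control"} | {c for c, _ in dose_cols}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"{path}: ambiguous non-dose columns {unknown}")
    records = []
    for _, row in df.iterrows():
        for col, conc in dose_cols:
            records.append({
                "cell_line": row["cell_line"], "drug": row["drug"],
                "conc_nM": conc, "raw": float(row[col]),
                "control": float(row["control"]),
            })
    long = pd.DataFrame.from_records(records)
    return long.sort_values(["cell_line", "drug", "conc_nM"]).reset_index(drop=True)


def curves_to_frame(curves: Iterable[DoseResponseCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for conc, via, rep in zip(c.conc_nM, c.viability, c.replicate_id):
            rows.append({"cell_line": c.cell_line, "drug": c.drug,
                         "conc_nM": conc, "viability": via, "replicate": rep})
    return pd.DataFrame(rows,
                        columns=["cell_line", "drug", "conc_nM", "viability",
                                 "replicate"])


def write_long_csv(curves: Iterable[DoseResponseCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_to_json(report: dict, path: str | Path) -> None:
    """Write a report dict (full numeric precision) as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")


def format_kd(value_nM: float, at_bound: bool = False) -> str:
    """Human display of a Kd: values beyond 1000 uM render as a bound."""
    if value_nM > KD2_RESISTANT_NM:
        return "> 1000 uM"
    if at_bound:
        return f"> {value_nM / 1e3:.4g} uM"
    return f"{value_nM:.4g} nM"


def report_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular report as TSV with 4 significant figures."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)
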