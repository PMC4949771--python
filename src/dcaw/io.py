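"""Cohort CSV readers and result serialization.

Cohort files are delimited text with a header row: one binary outcome
column, one column of predicted risks per model, and optionally a binary
decision column and a true-threshold column (simulation ground truth).
Rows with missing values in any mapped column are dropped with a count in
the log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .compare import ComparisonResult
from .core import Cohort, NetBenefitCurve, ThresholdGrid
from .exceptions import InputError
from .threshold_dist import ThresholdCDF

__all__ = [
    "read_cohort",
    "write_curves_csv",
    "read_curves_csv",
    "write_cdf",
    "read_cdf",
    "write_comparison_json",
    "read_comparison_json",
    "write_results",
]

logger = logging.getLogger("dcaw")


def read_cohort(
    path,
    risk_cols: "Mapping[str, str] | Sequence[str]",
    y_col: str = "y",
    z_col: str | None = None,
    pt_col: str | None = None,
    delimiter: str = ",",
) -> Cohort:
    """Read a patient-level cohort from a delimited text file.

    ``risk_cols`` maps model labels to column names (or is a sequence of
    column names used as their own labels).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if isinstance(risk_cols, Mapping):
        risk_map = dict(risk_cols)
    else:
        risk_map = {c: c for c in risk_cols}
    needed = [y_col, *risk_map.values()]
    if z_col is not None:
        needed.append(z_col)
    if pt_col is not None:
        needed.append(pt_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    before = len(df)
    df = df.dropna(subset=needed)
    dropped = before - len(df)
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path, dropped)
    if len(df) == 0:
        raise InputError(f"{path}: no complete rows")
    try:
        return Cohort(
            y=df[y_col].to_numpy(),
            risks={label: df[col].to_numpy() for label, col in risk_map.items()},
            z=df[z_col].to_numpy() if z_col is not None else None,
            pt_true=df[pt_col].to_numpy() if pt_col is not None else None,
        )
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_curves_csv(curves: Sequence[NetBenefitCurve], path) -> None:
    """Write one or more curves as CSV with columns threshold, model_label, net_benefit."""
    frames = [
        pd.DataFrame(
            {
                "threshold": c.grid.values,
                "model_label": c.model_label,
                "net_benefit": c.nb,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> list[NetBenefitCurve]:
    df = pd.read_csv(path)
    out = []
    for label, sub in df.groupby("model_label", sort=False):
        grid = ThresholdGrid(sub["threshold"].to_numpy())
        out.append(
            NetBenefitCurve(
                grid=grid,
                nb=sub["net_benefit"].to_numpy(),
                model_label=str(label),
                n=0,
            )
        )
    return out


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_cdf(cdf: ThresholdCDF, path) -> None:
    """CSV with columns threshold, cdf plus a JSON sidecar with convergence metadata."""
    pd.DataFrame({"threshold": cdf.grid, "cdf": cdf.cdf}).to_csv(path, index=False)
    meta = {
        "iterations_run": int(cdf.iterations_run),
        "converged": bool(cdf.converged),
        "sup_change_final": float(cdf.sup_change_final),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_cdf(path) -> ThresholdCDF:
    df = pd.read_csv(path)
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ThresholdCDF(
        grid=df["threshold"].to_numpy(),
        cdf=df["cdf"].to_numpy(),
        iterations_run=meta.get("iterations_run", 0),
        converged=meta.get("converged", True),
        sup_change_final=meta.get("sup_change_final", 0.0),
    )


def write_comparison_json(result: ComparisonResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def read_comparison_json(path) -> ComparisonResult:
    return ComparisonResult.from_dict(json.loads(Path(path).read_text()))


def write_results(result, path, format: str | None = None) -> None:
    """Serialize a dcaw result object, dispatching on its type.

    ``format`` is inferred from the type when omitted: curves and CDFs go to
    CSV (the CDF with a JSON sidecar), comparison results to JSON.
    """
    if isinstance(result, ComparisonResult):
        if format not in (None, "json"):
            raise InputError("ComparisonResult serializes to JSON")
        write_comparison_json(result, path)
    elif isinstance(result, ThresholdCDF):
        if format not in (None, "csv"):
            raise InputError("ThresholdCDF serializes to CSV (+ JSON sidecar)")
        write_cdf(result, path)
    elif isinstance(result, NetBenefitCurve):
        write_curves_csv([result], path)
    elif isinstance(result, (list, tuple)) and all(
        isinstance(c, NetBenefitCurve) for c in result
    ):
        write_curves_csv(result, path)
    else:
        raise InputError(f"do not know how to serialize {type(result).__name__}")
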