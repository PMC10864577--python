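"""Orthogonal grid orchestration, best-frequency tally and file I/O.

The full experiment evaluates every combination of the 5 pre-processing
options and the 10 selection options (both including "none") against one
shared SPXY split and one shared CV fold seed — 50 pipeline recipes in
total.  Per pre-processing group and per metric, the best selection method
is tallied, which summarizes how often each selector wins across the six
metrics (three cross-validated calibration, three prediction).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_eval import PipelineSpec, ResultRow, evaluate_pipeline, spxy_split
from .preprocessing import PREPROCESS_METHODS
from .selection import SELECT_METHODS
from .synthetic import SpectralDataset

__all__ = [
    "ResultTable",
    "FrequencyTally",
    "derive_seed",
    "run_grid",
    "best_frequency",
    "read_spectra_csv",
    "write_results",
    "read_results_csv",
]

#: (column, lower-is-better) pairs defining "best" per metric
METRIC_DIRECTIONS = (
    ("rmse_c", True),
    ("mape_c", True),
    ("rpd_c", False),
    ("rmse_p", True),
    ("mape_p", True),
    ("rpd_p", False),
)

RESULT_COLUMNS = [
    "preprocess", "select", "n",
    "rmse_c", "mape_c", "rpd_c", "rmse_p", "mape_p", "rpd_p",
    "failed", "reason",
]


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-component seed: adding a component never shifts others."""
    return (int(master_seed) * 1000003 + zlib.crc32(name.encode())) % (2**31)


@dataclass
class ResultTable:
    """Grid results keyed by (preprocess, select), plus run metadata."""

    rows: list[ResultRow]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [dataclasses.asdict(r) for r in self.rows]
        return pd.DataFrame(recs, columns=RESULT_COLUMNS)


@dataclass
class FrequencyTally:
    """Best-performance counts: pre-processing groups x selection methods."""

    counts: pd.DataFrame  # index: preprocess, columns: select

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


def run_grid(
    dataset: SpectralDataset,
    master_seed: int = 0,
    pre_methods=PREPROCESS_METHODS,
    sel_methods=SELECT_METHODS,
    ratio: str = "3:1",
    folds: int = 5,
    select_params: dict | None = None,
) -> ResultTable:
    """Evaluate every (pre-processing, selection) recipe on one SPXY split.

    All cells share the split and the CV fold seed; stochastic selectors get
    per-cell seeds derived from the master seed by stable hashing, so the
    whole table is reproducible from one integer.  Per-row failures are
    recorded, never raised.
    """
    split = spxy_split(dataset.reflectance, dataset.ssc, ratio=ratio)
    cv_seed = derive_seed(master_seed, "cv-folds")
    select_params = select_params or {}
    rows = []
    for pre in pre_methods:
        for sel in sel_methods:
            spec = PipelineSpec(
                preprocess=pre,
                select=sel,
                select_params=dict(select_params.get(sel, {})),
                seed=derive_seed(master_seed, f"{pre}:{sel}"),
            )
            rows.append(evaluate_pipeline(spec, dataset, split, folds=folds, seed=cv_seed))
    meta = {
        "master_seed": int(master_seed),
        "cv_seed": int(cv_seed),
        "ratio": ratio,
        "folds": folds,
        "n_samples": dataset.n_samples,
        "n_wavelengths": dataset.n_wavelengths,
        "cal_size": int(split.cal_idx.size),
        "pred_size": int(split.pred_idx.size),
        "pre_methods": list(pre_methods),
        "sel_methods": list(sel_methods),
    }
    return ResultTable(rows, meta)


def best_frequency(table: ResultTable) -> FrequencyTally:
    """Tally, per pre-processing group and metric, the winning selector.

    Comparison is at full floating precision.  Ties are broken by the
    canonical method order with a warning; failed (NA) rows never win; a
    group with no usable rows contributes a zero row with a warning.
    """
    df = table.to_frame()
    pres = list(dict.fromkeys(df["preprocess"]))
    sels = [m for m in SELECT_METHODS if m in set(df["select"])]
    counts = pd.DataFrame(0, index=pres, columns=sels, dtype=int)
    for pre in pres:
        grp = df[(df["preprocess"] == pre) & (~df["failed"])]
        if grp.empty:
            warnings.warn(f"all rows failed in group {pre!r}; zero tally row", RuntimeWarning)
            continue
        for col, lower in METRIC_DIRECTIONS:
            vals = grp[col].to_numpy()
            finite = np.isfinite(vals)
            if lower:
                ok = finite
                best_val = vals[ok].min() if ok.any() else None
            else:
                ok = np.ones_like(finite)  # +inf RPD is a legitimate winner
                best_val = vals.max()
            if best_val is None:
                warnings.warn(f"no finite {col} in group {pre!r}", RuntimeWarning)
                continue
            winners = grp.loc[np.asarray(ok) & (vals == best_val), "select"].tolist()
            if len(winners) > 1:
                warnings.warn(
                    f"tie on {col} in group {pre!r}: {winners}; canonical order breaks it",
                    RuntimeWarning,
                )
            winner = min(winners, key=SELECT_METHODS.index)
            counts.loc[pre, winner] += 1
    return FrequencyTally(counts)


def selection_helps_flags(table: ResultTable) -> pd.DataFrame:
    """Per group, mark selectors beating the no-selection baseline on both RMSEs."""
    df = table.to_frame()
    out = []
    for pre, grp in df.groupby("preprocess", sort=False):
        base = grp[grp["select"] == "none"]
        if base.empty or bool(base["failed"].iloc[0]):
            continue
        b_c, b_p = float(base["rmse_c"].iloc[0]), float(base["rmse_p"].iloc[0])
        for _, row in grp[grp["select"] != "none"].iterrows():
            out.append(
                {
                    "preprocess": pre,
                    "select": row["select"],
                    "beats_baseline": bool(
                        not row["failed"] and row["rmse_c"] < b_c and row["rmse_p"] < b_p
                    ),
                }
            )
    return pd.DataFrame(out, columns=["preprocess", "select", "beats_baseline"])


def read_spectra_csv(path) -> SpectralDataset:
    """Read the wide CSV layout written by the synthetic generator.

    Header contract: ``sample_id,ssc,<nm>,<nm>,...`` with numeric,
    strictly ascending wavelength column names.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "ssc" not in df.columns:
        raise ValueError("spectra CSV must have 'sample_id' and 'ssc' columns")
    ids = df["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample ids in spectra CSV")
    wl_cols = [c for c in df.columns if c not in ("sample_id", "ssc")]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError("wavelength column names must be numeric (nm)") from exc
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength columns must be strictly ascending")
    return SpectralDataset(ids, wl, df[wl_cols].to_numpy(float), df["ssc"].to_numpy(float))


def write_results(table: ResultTable, out_dir) -> None:
    """Emit results.csv (one row per grid cell) and results.json (metadata)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(out / "results.csv", index=False)
    payload = {
        "metadata": table.metadata,
        "rows": [dataclasses.asdict(r) for r in table.rows],
    }
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_results_csv(path) -> ResultTable:
    """Reload a results CSV into a ResultTable (metadata not recovered)."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        n = r["n"]
        rows.append(
            ResultRow(
                str(r["preprocess"]),
                str(r["select"]),
                None if pd.isna(n) else int(n),
                *(float(r[c]) if pd.notna(r[c]) else float("nan")
                  for c in ("rmse_c", "mape_c", "rpd_c", "rmse_p", "mape_p", "rpd_p")),
                failed=bool(r["failed"]),
                reason="" if pd.isna(r.get("reason")) else str(r["reason"]),
            )
        )
    return ResultTable(rows)
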