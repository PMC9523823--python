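"""Cohort and results I/O.

Cohorts travel as plain CSV.  The wide layout has one row per individual:
``id, A, Z0, M_0..M_K [, L_0..L_K], T, E`` (mediator columns NaN after the
event).  A long layout ``id, time, variable, value`` is also accepted and
converted.  Validation is deliberately warning-based for soft invariants
(e.g. E = 0 with T below the administrative horizon) and error-based for
structural problems (missing mandatory columns, non-numeric event times).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_cohort", "write_cohort", "validate_cohort", "cohort_to_long", "cohort_from_long"]

logger = logging.getLogger(__name__)

MANDATORY = ("id", "A", "T", "E")


def validate_cohort(df: pd.DataFrame, admin_censor_time: float | None = None) -> pd.DataFrame:
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing mandatory column(s): {missing}")
    if not np.issubdtype(df["T"].dtype, np.number):
        raise ValueError("column T must be numeric")
    if not df["E"].isin([0, 1]).all():
        raise ValueError("column E must be 0/1")
    if admin_censor_time is not None:
        odd = (df["E"] == 0) & (df["T"] != admin_censor_time)
        if odd.any():
            warnings.warn(
                f"{int(odd.sum())} censored rows have T != administrative "
                f"censoring time {admin_censor_time}",
                stacklevel=2,
            )
    return df


def cohort_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Wide cohort -> long (id, time, variable, value); static columns keep
    time = NaN."""
    value_cols = [c for c in df.columns if c.startswith(("M_", "L_"))]
    static = [c for c in df.columns if c not in value_cols]
    long = df.melt(id_vars=["id"], value_vars=value_cols, var_name="key")
    long["variable"] = long["key"].str.split("_").str[0]
    long["time"] = long["key"].str.split("_", n=1).str[1].astype(float)
    long = long.drop(columns="key")[["id", "time", "variable", "value"]]
    stat = df[static].melt(id_vars=["id"], var_name="variable", value_name="value")
    stat.insert(1, "time", np.nan)
    return pd.concat([stat, long], ignore_index=True)


def cohort_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`cohort_to_long` (row order canonicalised by id)."""
    from .dgm import fmt_time

    stat = long[long["time"].isna()].pivot(index="id", columns="variable", values="value")
    dyn = long[long["time"].notna()].copy()
    dyn["col"] = dyn["variable"] + "_" + dyn["time"].map(fmt_time)
    wide = dyn.pivot(index="id", columns="col", values="value")
    out = stat.join(wide).reset_index()
    out.columns.name = None
    for c in ("A", "Z0", "E"):
        if c in out.columns:
            out[c] = out[c].astype(int)
    return out


def write_cohort(cohort: pd.DataFrame, path, layout: str = "wide") -> None:
    path = Path(path)
    if layout == "wide":
        cohort.to_csv(path, index=False)
    elif layout == "long":
        cohort_to_long(cohort).to_csv(path, index=False)
    else:
        raise ValueError("layout must be 'wide' or 'long'")


def read_cohort(path, admin_censor_time: float | None = None) -> pd.DataFrame:
    """Read a cohort CSV, auto-detecting wide vs long layout."""
    df = pd.read_csv(path)
    if set(df.columns) >= {"id", "time", "variable", "value"}:
        df = cohort_from_long(df)
    return validate_cohort(df, admin_censor_time=admin_censor_time)
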