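"""Reading and writing the package-standard twin-pair CSV.

Schema (UTF-8, '.' decimal separator, one row per pair)::

    family_id, zygosity, ses, sex1, sex2, ea1, ea2, pgs1, pgs2

with ``zygosity`` in {MZ, DZ}, ``ses`` in {1, 2, 3, 4} (1 = lowest),
``sex1``/``sex2`` in {F, M}, empty fields denoting missing values.
Censoring flags are never stored: a score equal to the ceiling (550 by
default) is flagged censored on load.
"""
from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_FLOOR,
    DEFAULT_THRESHOLD,
    TwinPairRecord,
)
from .exceptions import DataValidationError

SCHEMA = (
    "family_id", "zygosity", "ses", "sex1", "sex2", "ea1", "ea2", "pgs1", "pgs2"
)
_INTERNAL = SCHEMA[:7] + ("cens1", "cens2") + SCHEMA[7:]


def write_dataset(data: pd.DataFrame, path) -> None:
    """Write a twin frame in the standard schema (flags are dropped)."""
    out = data.loc[:, list(SCHEMA)]
    # %.17g round-trips float64 exactly
    out.to_csv(path, index=False, float_format="%.17g")


def read_dataset(
    path,
    threshold: float = DEFAULT_THRESHOLD,
    floor_value: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Load and validate a twin CSV; hard-fails with per-row diagnostics.

    Scores equal to ``threshold`` are auto-flagged as censored.
    """
    df = pd.read_csv(
        path,
        dtype={"family_id": str, "zygosity": str, "sex1": str, "sex2": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in SCHEMA if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"missing columns: {missing_cols}")
    errors: List[str] = []

    def complain(mask, message):
        for row in np.flatnonzero(np.asarray(mask))[:20]:
            errors.append(f"row {row + 2}: {message}")  # +2: header + 1-basing

    complain(~df["zygosity"].isin(["MZ", "DZ"]), "unknown zygosity code")
    ses_num = pd.to_numeric(df["ses"], errors="coerce")
    complain(~ses_num.isin([1, 2, 3, 4]), "SES must be 1..4")
    for s in ("1", "2"):
        complain(~df[f"sex{s}"].isin(["F", "M"]), f"unknown sex{s} code")
        ea = pd.to_numeric(df[f"ea{s}"], errors="coerce")
        bad_range = ea.notna() & ((ea < floor_value) | (ea > threshold))
        complain(
            bad_range,
            f"ea{s} outside [{floor_value:g}, {threshold:g}]",
        )
        df[f"ea{s}"] = ea
        df[f"pgs{s}"] = pd.to_numeric(df[f"pgs{s}"], errors="coerce")
    complain(
        (df["zygosity"] == "MZ") & (df["sex1"] != df["sex2"]),
        "MZ pair with discordant sexes",
    )
    complain(df["ea1"].isna() & df["ea2"].isna(), "both EA values missing")
    if errors:
        raise DataValidationError(
            "invalid twin CSV:\n" + "\n".join(errors)
        )
    df["ses"] = ses_num.astype(int)
    for s in ("1", "2"):
        df[f"cens{s}"] = df[f"ea{s}"].to_numpy() >= threshold - 1e-8
        df[f"cens{s}"] = df[f"cens{s}"].fillna(False).astype(bool)
    return df.loc[:, list(_INTERNAL)]


def frame_to_records(data: pd.DataFrame) -> List[TwinPairRecord]:
    """Convert a twin frame to validated :class:`TwinPairRecord` objects."""
    records = []
    for row in data.itertuples(index=False):
        records.append(
            TwinPairRecord(
                family_id=str(row.family_id),
                zygosity=row.zygosity,
                ses=int(row.ses),
                sex1=row.sex1,
                sex2=row.sex2,
                ea1=None if pd.isna(row.ea1) else float(row.ea1),
                ea2=None if pd.isna(row.ea2) else float(row.ea2),
                cens1=bool(getattr(row, "cens1", False)),
                cens2=bool(getattr(row, "cens2", False)),
                pgs1=None if pd.isna(row.pgs1) else float(row.pgs1),
                pgs2=None if pd.isna(row.pgs2) else float(row.pgs2),
            )
        )
    return records


def records_to_frame(records: List[TwinPairRecord]) -> pd.DataFrame:
    """Inverse of :func:`frame_to_records`."""
    rows = []
    for r in records:
        rows.append(
            {
                "family_id": r.family_id,
                "zygosity": r.zygosity,
                "ses": r.ses,
                "sex1": r.sex1,
                "sex2": r.sex2,
                "ea1": np.nan if r.ea1 is None else r.ea1,
                "ea2": np.nan if r.ea2 is None else r.ea2,
                "cens1": r.cens1,
                "cens2": r.cens2,
                "pgs1": np.nan if r.pgs1 is None else r.pgs1,
                "pgs2": np.nan if r.pgs2 is None else r.pgs2,
            }
        )
    return pd.DataFrame(rows, columns=list(_INTERNAL))
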