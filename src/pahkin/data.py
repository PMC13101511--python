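"""Tidy time-course container shared by the fitting, bootstrap and IO layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["TimeCourseData", "PARENT", "INTERMEDIATE"]

PARENT = "parent"
INTERMEDIATE = "intermediate"

_COLUMNS = ["time_d", "compound", "replicate", "conc_mg_per_L", "below_lod", "lod_mg_per_L"]


@dataclass(frozen=True)
class TimeCourseData:
    """Replicate concentration observations for parent and intermediate series.

    Wraps a tidy :class:`pandas.DataFrame` with columns ``time_d`` (days),
    ``compound`` (``"parent"`` / ``"intermediate"``), ``replicate``,
    ``conc_mg_per_L``, ``below_lod`` (bool) and optional ``lod_mg_per_L``.
    Rows are canonically sorted on construction so that every downstream
    computation is invariant to the order of the input records.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ("time_d", "compound", "replicate", "conc_mg_per_L") if c not in df.columns]
        if missing:
            raise ValidationError(f"time-course table missing columns: {missing}")
        if "below_lod" not in df.columns:
            df["below_lod"] = False
        if "lod_mg_per_L" not in df.columns:
            df["lod_mg_per_L"] = np.nan

        df["time_d"] = df["time_d"].astype(float)
        df["conc_mg_per_L"] = df["conc_mg_per_L"].astype(float)
        df["below_lod"] = df["below_lod"].astype(bool)
        df["lod_mg_per_L"] = df["lod_mg_per_L"].astype(float)
        df["compound"] = df["compound"].astype(str)
        df["replicate"] = df["replicate"].astype(str)

        if np.any(df["time_d"].to_numpy() < 0):
            raise ValidationError("time-course times must be >= 0 days")
        if not np.all(np.isfinite(df["time_d"].to_numpy())):
            raise ValidationError("time-course times must be finite")
        quantified = ~df["below_lod"].to_numpy()
        conc = df["conc_mg_per_L"].to_numpy()
        if np.any(~np.isfinite(conc[quantified])):
            raise ValidationError("quantified concentrations must be finite")
        if np.any(conc[quantified] < 0):
            raise ValidationError("concentrations must be >= 0 unless flagged below_lod")

        dup = df.duplicated(subset=["time_d", "compound", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["time_d", "compound", "replicate"]].to_dict("records")
            raise ValidationError(f"duplicate (time, compound, replicate) records: {rows[:3]}")

        df = df[_COLUMNS].sort_values(["compound", "time_d", "replicate"], kind="mergesort")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @classmethod
    def from_records(cls, records) -> "TimeCourseData":
        return cls(pd.DataFrame.from_records(records))

    def series(self, compound: str) -> pd.DataFrame:
        """Rows for one compound, canonically ordered."""
        return self.table[self.table["compound"] == compound].reset_index(drop=True)

    @property
    def compounds(self) -> list[str]:
        return sorted(self.table["compound"].unique())

    def n_distinct_times(self, compound: str) -> int:
        return self.series(compound)["time_d"].nunique()

    def __len__(self) -> int:
        return len(self.table)
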