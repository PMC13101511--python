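"""Mole-based conversion and molar-yield computations.

Mass concentrations (mg/L) of parent and intermediate are not directly
comparable because the two compounds differ in molecular weight; yield
accounting therefore converts both to molar units.  A molar yield of 40%
means that 40% of the degraded parent molecules are currently present as the
intermediate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .data import INTERMEDIATE, PARENT, TimeCourseData
from .exceptions import ValidationError

__all__ = [
    "CompoundSpec",
    "COMPOUND_REGISTRY",
    "PYRENE",
    "DIPHENIC_ACID",
    "mass_to_molar",
    "molar_yield_percent",
    "timecourse_molar_yield",
]


@dataclass(frozen=True)
class CompoundSpec:
    """A named compound with its formula weight in g/mol."""

    name: str
    molecular_weight: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.molecular_weight) and self.molecular_weight > 0):
            raise ValidationError(f"molecular weight must be > 0, got {self.molecular_weight}")


def _load_registry() -> dict[str, CompoundSpec]:
    raw = json.loads(resources.files("pahkin").joinpath("compounds.json").read_text())
    return {name: CompoundSpec(name, mw) for name, mw in raw.items()}


#: Formula weights (g/mol) of the compounds handled by the package; editable
#: by shipping a modified compounds.json or passing explicit CompoundSpec.
COMPOUND_REGISTRY = _load_registry()

PYRENE = COMPOUND_REGISTRY["pyrene"]
DIPHENIC_ACID = COMPOUND_REGISTRY["2,2'-diphenic acid"]


def mass_to_molar(conc: float, compound: CompoundSpec) -> float:
    """Convert mg/L to mmol/L by dividing by the formula weight."""
    if not (math.isfinite(conc) and conc >= 0):
        raise ValidationError(f"concentration must be >= 0, got {conc}")
    return conc / compound.molecular_weight


def molar_yield_percent(
    intermediate_formed: float,
    intermediate_cmpd: CompoundSpec,
    parent_degraded: float,
    parent_cmpd: CompoundSpec,
) -> float:
    """Percent of degraded parent moles currently present as intermediate.

    ``100 * (intermediate_formed / MW_int) / (parent_degraded / MW_parent)``,
    with both amounts in mg/L.
    """
    if not (math.isfinite(parent_degraded) and parent_degraded > 0):
        raise ValidationError(f"parent_degraded must be > 0, got {parent_degraded}")
    if not (math.isfinite(intermediate_formed) and intermediate_formed >= 0):
        raise ValidationError(f"intermediate_formed must be >= 0, got {intermediate_formed}")
    return 100.0 * mass_to_molar(intermediate_formed, intermediate_cmpd) / mass_to_molar(
        parent_degraded, parent_cmpd
    )


def timecourse_molar_yield(
    data: TimeCourseData,
    parent_cmpd: CompoundSpec = PYRENE,
    intermediate_cmpd: CompoundSpec = DIPHENIC_ACID,
) -> pd.DataFrame:
    """Per-time molar yield of the intermediate against cumulative parent loss.

    Replicates are averaged per time point.  At each sampled time t the yield
    is ``molar_yield_percent(P(t) - P(0), S(0) - S(t))``; rows where the
    parent depletion is <= 0 (including t = 0) are flagged undefined.

    Returns
    -------
    pandas.DataFrame
        Columns time_d, parent_mean, intermediate_mean, parent_degraded,
        intermediate_formed, molar_yield_percent (NaN where undefined),
        defined (bool).
    """
    means = (
        data.table[~data.table["below_lod"]]
        .groupby(["compound", "time_d"])["conc_mg_per_L"]
        .mean()
        .unstack("compound")
    )
    if PARENT not in means.columns or INTERMEDIATE not in means.columns:
        raise ValidationError("time course must contain both parent and intermediate series")
    if 0.0 not in means.index or not math.isfinite(means.loc[0.0, PARENT]):
        raise ValidationError("time course must contain a quantified parent observation at t=0")

    s0 = float(means.loc[0.0, PARENT])
    p0 = float(means.loc[0.0, INTERMEDIATE]) if math.isfinite(means.loc[0.0].get(INTERMEDIATE, np.nan)) else 0.0

    out = pd.DataFrame(
        {
            "time_d": means.index.to_numpy(float),
            "parent_mean": means[PARENT].to_numpy(float),
            "intermediate_mean": means[INTERMEDIATE].to_numpy(float),
        }
    ).reset_index(drop=True)
    out["parent_degraded"] = s0 - out["parent_mean"]
    out["intermediate_formed"] = out["intermediate_mean"] - p0
    defined = (out["parent_degraded"] > 0) & np.isfinite(out["intermediate_formed"])
    yields = np.full(len(out), np.nan)
    for i in np.flatnonzero(defined.to_numpy()):
        yields[i] = molar_yield_percent(
            max(float(out.loc[i, "intermediate_formed"]), 0.0),
            intermediate_cmpd,
            float(out.loc[i, "parent_degraded"]),
            parent_cmpd,
        )
    out["molar_yield_percent"] = yields
    out["defined"] = defined
    return out
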