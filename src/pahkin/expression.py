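"""Relative gene expression from qPCR cycle thresholds (2^-ddCt, Livak).

Ct tables are tidy DataFrames with columns ``gene``, ``condition``,
``bio_rep``, ``tech_rep``, ``ct``.  Technical replicates are averaged first;
dCt = Ct_target - Ct_reference is formed within each (condition, biological
replicate); ddCt subtracts the mean control-condition dCt of the same gene;
the fold change 2^-ddCt is computed per biological replicate and reported as
its mean with dispersion.  The reference gene's own fold change is exactly
1.0 in every condition by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "delta_delta_ct",
    "expression_call",
    "DEFAULT_REFERENCE_GENE",
    "DEFAULT_CONTROL_CONDITION",
]

#: 16S rRNA as internal reference; glucose-grown cultures as the control.
DEFAULT_REFERENCE_GENE = "16S"
DEFAULT_CONTROL_CONDITION = "glucose"

_CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def _validate_ct_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    df = records[_CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    if not np.all(np.isfinite(df["ct"].to_numpy())):
        raise ValidationError("Ct values must be finite")
    return df


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_condition: str = DEFAULT_CONTROL_CONDITION,
) -> pd.DataFrame:
    """Relative expression of every gene and condition by the 2^-ddCt method.

    Returns
    -------
    pandas.DataFrame
        Columns gene, condition, fold_change (mean of per-bio-rep 2^-ddCt),
        fold_sd, log2_fold_change, n_bio.

    Raises
    ------
    ValidationError
        If the reference gene is missing from any (condition, bio_rep)
        stratum (the offending stratum is named) or the control condition is
        absent.
    """
    df = _validate_ct_table(records)
    if control_condition not in set(df["condition"]):
        raise ValidationError(f"control condition {control_condition!r} absent from Ct table")

    # technical replicates -> one Ct per (gene, condition, bio_rep)
    ct = df.groupby(["gene", "condition", "bio_rep"], as_index=False)["ct"].mean()

    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "bio_rep"])["ct"]
    strata = ct.groupby(["condition", "bio_rep"]).groups.keys()
    missing = [s for s in strata if s not in ref.index]
    if missing:
        raise ValidationError(
            f"reference gene {reference_gene!r} missing in (condition, bio_rep) strata: {sorted(missing)}"
        )

    ct = ct.assign(
        d_ct=ct["ct"].to_numpy()
        - ref.loc[list(zip(ct["condition"], ct["bio_rep"]))].to_numpy()
    )

    control_mean = (
        ct[ct["condition"] == control_condition].groupby("gene")["d_ct"].mean()
    )
    absent = sorted(set(ct["gene"]) - set(control_mean.index))
    if absent:
        raise ValidationError(f"genes absent from control condition: {absent}")

    ct = ct.assign(dd_ct=ct["d_ct"].to_numpy() - control_mean.loc[ct["gene"]].to_numpy())
    ct = ct.assign(fold=np.exp2(-ct["dd_ct"]))

    out = (
        ct.groupby(["gene", "condition"], as_index=False)
        .agg(fold_change=("fold", "mean"), fold_sd=("fold", "std"), n_bio=("fold", "size"))
        .fillna({"fold_sd": 0.0})
    )
    out["log2_fold_change"] = np.log2(out["fold_change"])
    return out.sort_values(["gene", "condition"], kind="mergesort").reset_index(drop=True)


def expression_call(rel: pd.DataFrame, threshold_fold: float = 2.0) -> pd.DataFrame:
    """Flag genes whose mean fold change exceeds a threshold (default 2x).

    A purely descriptive call on the point estimate; no significance testing
    is performed.
    """
    if "fold_change" not in rel.columns:
        raise ValidationError("expected a delta_delta_ct result with a fold_change column")
    out = rel.copy()
    out["induced"] = out["fold_change"] > threshold_fold
    return out
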