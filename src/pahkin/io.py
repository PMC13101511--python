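"""CSV readers/writers, analysis configuration, and the full pipeline driver.

The tidy time-course dialect is fixed: UTF-8, comma-separated, "." decimal
separator, required header ``time_d,compound,replicate,conc_mg_per_L,
below_lod`` with optional ``lod_mg_per_L``; ``below_lod`` is 0/1 and a
flagged row may leave the concentration empty.  Writing is canonical
(sorted rows, ``%g`` number formatting) so that read -> write round-trips
canonical files byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import branching_robustness, parametric_bootstrap
from .data import TimeCourseData
from .exceptions import ParseError, ValidationError
from .fitting import fit_branched_model
from .kinetics import KineticParams, half_life, intermediate_peak
from .stoichiometry import COMPOUND_REGISTRY, CompoundSpec, DIPHENIC_ACID, PYRENE, timecourse_molar_yield

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_ct_csv",
    "write_ct_csv",
    "AnalysisConfig",
    "run_full_analysis",
]

logger = logging.getLogger("pahkin")

_TC_REQUIRED = ["time_d", "compound", "replicate", "conc_mg_per_L", "below_lod"]
_CT_REQUIRED = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def _fmt(x: float) -> str:
    if not np.isfinite(x):
        return ""
    return format(float(x), ".12g")


def read_timecourse_csv(path) -> TimeCourseData:
    """Parse the tidy time-course dialect with line-numbered diagnostics."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = [c for c in _TC_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        has_lod = "lod_mg_per_L" in reader.fieldnames
        rows = []
        for lineno, rec in enumerate(reader, start=2):
            try:
                below = rec["below_lod"].strip()
                if below not in ("0", "1"):
                    raise ValueError(f"below_lod must be 0 or 1, got {below!r}")
                below_lod = below == "1"
                conc_str = (rec["conc_mg_per_L"] or "").strip()
                if conc_str == "":
                    if not below_lod:
                        raise ValueError("empty concentration on a quantified row")
                    conc = float("nan")
                else:
                    conc = float(conc_str)
                lod = float(rec["lod_mg_per_L"]) if has_lod and (rec["lod_mg_per_L"] or "").strip() else float("nan")
                rows.append(
                    {
                        "time_d": float(rec["time_d"]),
                        "compound": rec["compound"].strip(),
                        "replicate": rec["replicate"].strip(),
                        "conc_mg_per_L": conc,
                        "below_lod": below_lod,
                        "lod_mg_per_L": lod,
                    }
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no data rows")
    try:
        return TimeCourseData(pd.DataFrame(rows))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse_csv(data: TimeCourseData, path) -> None:
    """Write the canonical tidy dialect (sorted rows, %g numbers)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TC_REQUIRED + ["lod_mg_per_L"])
        for rec in data.table.itertuples(index=False):
            writer.writerow(
                [
                    _fmt(rec.time_d),
                    rec.compound,
                    rec.replicate,
                    _fmt(rec.conc_mg_per_L),
                    "1" if rec.below_lod else "0",
                    _fmt(rec.lod_mg_per_L),
                ]
            )


def read_ct_csv(path) -> pd.DataFrame:
    """Parse a tidy Ct table (gene, condition, bio_rep, tech_rep, ct)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = [c for c in _CT_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        rows = []
        for lineno, rec in enumerate(reader, start=2):
            try:
                rows.append(
                    {
                        "gene": rec["gene"].strip(),
                        "condition": rec["condition"].strip(),
                        "bio_rep": rec["bio_rep"].strip(),
                        "tech_rep": rec["tech_rep"].strip(),
                        "ct": float(rec["ct"]),
                    }
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows)


def write_ct_csv(records: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CT_REQUIRED)
        for rec in records[_CT_REQUIRED].itertuples(index=False):
            writer.writerow([rec.gene, rec.condition, rec.bio_rep, rec.tech_rep, _fmt(rec.ct)])


@dataclass
class AnalysisConfig:
    """Options for the full fit -> bootstrap -> derived-quantities pipeline."""

    input_timecourse: Optional[str] = None
    output_dir: str = "pahkin_results"
    fix_S0: bool = False
    weighting: str = "none"
    lod_policy: str = "drop"
    use_replicate_means: bool = False
    bootstrap_n: int = 500
    seed: int = 0
    parent_compound: str = "pyrene"
    intermediate_compound: str = "2,2'-diphenic acid"
    compound_overrides: dict = field(default_factory=dict)

    def compound(self, name: str) -> CompoundSpec:
        if name in self.compound_overrides:
            return CompoundSpec(name, float(self.compound_overrides[name]))
        if name in COMPOUND_REGISTRY:
            return COMPOUND_REGISTRY[name]
        raise ValidationError(f"unknown compound {name!r}; add it to compound_overrides")

    def as_dict(self) -> dict:
        return {
            "input_timecourse": self.input_timecourse,
            "output_dir": self.output_dir,
            "fix_S0": self.fix_S0,
            "weighting": self.weighting,
            "lod_policy": self.lod_policy,
            "use_replicate_means": self.use_replicate_means,
            "bootstrap_n": self.bootstrap_n,
            "seed": self.seed,
            "parent_compound": self.parent_compound,
            "intermediate_compound": self.intermediate_compound,
            "compound_overrides": dict(self.compound_overrides),
        }


def run_full_analysis(
    config: AnalysisConfig,
    data: Optional[TimeCourseData] = None,
    include_timestamp: bool = True,
) -> dict:
    """Run fit, bootstrap and derived quantities; write the report bundle.

    Writes ``report.json``, ``fit_residuals.csv``, ``bootstrap_draws.csv``
    and ``molar_yield.csv`` into ``config.output_dir``.  Apart from the
    report's timestamp field, all outputs are byte-identical across reruns
    with the same inputs, config and seed.

    Parameters
    ----------
    config : AnalysisConfig
    data : TimeCourseData, optional
        In-memory input; if omitted, ``config.input_timecourse`` is read.

    Returns
    -------
    dict
        The report, as also written to ``report.json``.
    """
    if data is None:
        if config.input_timecourse is None:
            raise ValidationError("no input: provide data or config.input_timecourse")
        logger.info("reading time course from %s", config.input_timecourse)
        data = read_timecourse_csv(config.input_timecourse)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("fitting branched first-order model (%d records)", len(data))
    try:
        fit = fit_branched_model(
            data,
            fix_S0=config.fix_S0,
            weighting=config.weighting,
            lod_policy=config.lod_policy,
            use_replicate_means=config.use_replicate_means,
        )
    except Exception as exc:
        raise type(exc)(f"fit stage: {exc}") from exc

    logger.info("parametric bootstrap: n=%d seed=%d", config.bootstrap_n, config.seed)
    try:
        boot = parametric_bootstrap(fit, data, n=config.bootstrap_n, seed=config.seed)
        robustness = branching_robustness(boot)
    except Exception as exc:
        raise type(exc)(f"bootstrap stage: {exc}") from exc

    p = fit.params_hat
    try:
        peak_time, peak_conc = intermediate_peak(p)
    except ValidationError:
        peak_time = peak_conc = None

    try:
        yields = timecourse_molar_yield(
            data,
            parent_cmpd=config.compound(config.parent_compound),
            intermediate_cmpd=config.compound(config.intermediate_compound),
        )
    except Exception as exc:
        raise type(exc)(f"molar-yield stage: {exc}") from exc

    report = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "fit": fit.to_dict(),
        "derived": {
            "half_life_days": half_life(p.k_tot),
            "k_a": p.k_a,
            "intermediate_peak_time_d": peak_time,
            "intermediate_peak_conc_mg_per_L": peak_conc,
        },
        "bootstrap": boot.to_dict(),
        "branching_robustness": {
            "f_interval": list(robustness["f_interval"]),
            "dominance_fraction": robustness["dominance_fraction"],
            "cv": robustness["cv"],
            "n_draws": robustness["n_draws"],
        },
    }
    if include_timestamp:
        report["generated_at"] = datetime.now(timezone.utc).isoformat()

    fit.residuals.to_csv(outdir / "fit_residuals.csv", index=False, float_format="%.12g")
    boot.draws.to_csv(outdir / "bootstrap_draws.csv", index=False, float_format="%.12g")
    yields.to_csv(outdir / "molar_yield.csv", index=False, float_format="%.12g")
    with (outdir / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", outdir / "report.json")
    return report
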