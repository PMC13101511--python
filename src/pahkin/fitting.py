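"""Global nonlinear least-squares fitting of the branched first-order model.

Both concentration series (parent and intermediate) are fitted jointly: the
objective pools the squared residuals of the parent decay curve and the
Bateman intermediate curve over all replicates and time points, so a single
parameter vector (k_tot, f, k2, S0) explains both datasets at once.

Parameter constraints (k_tot > 0, k2 > 0, 0 < f < 1, S0 > 0) are enforced by
optimizing rates and S0 on the log scale and the branching fraction on the
logit scale, which keeps the optimizer unconstrained while guaranteeing
admissible estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import INTERMEDIATE, PARENT, TimeCourseData
from .exceptions import FittingError, ValidationError
from .kinetics import KineticParams, intermediate_concentration, parent_concentration

__all__ = [
    "FitResult",
    "fit_branched_model",
    "fit_single_first_order",
    "goodness_of_fit",
    "percent_degraded",
]

_TOL = 1e-12  # optimizer ftol/xtol/gtol; noiseless data must be recovered to ~1e-6 relative


@dataclass(frozen=True)
class FitResult:
    """Point estimates and diagnostics from a least-squares fit.

    Attributes
    ----------
    params_hat : KineticParams
        Fitted parameter vector; ``k_a_hat`` is derived from it exactly.
    residuals : pandas.DataFrame
        Per-observation table (time_d, compound, replicate, observed,
        predicted, residual) in canonical order, raw mg/L scale.
    r_squared : float
        Pooled coefficient of determination over both series (per-series
        means in the total sum of squares).
    r_squared_by_series : dict
        Per-series R^2 for transparency.
    sigma_hat : dict
        Per-series residual standard deviation, mg/L.
    objective_value : float
        Sum of squared (weighted) residuals at the optimum.
    options : dict
        The fitting options used; consumed by the parametric bootstrap to
        refit resampled datasets identically.
    """

    params_hat: KineticParams
    residuals: pd.DataFrame
    r_squared: float
    r_squared_by_series: dict
    sigma_hat: dict
    converged: bool
    n_obs: int
    objective_value: float
    options: dict = field(default_factory=dict)

    @property
    def k_a_hat(self) -> float:
        return self.params_hat.k_a

    def to_dict(self) -> dict:
        p = self.params_hat
        return {
            "k_tot": p.k_tot,
            "f": p.f,
            "k2": p.k2,
            "k_a": p.k_a,
            "S0": p.S0,
            "r_squared": self.r_squared,
            "r_squared_parent": self.r_squared_by_series.get(PARENT),
            "r_squared_intermediate": self.r_squared_by_series.get(INTERMEDIATE),
            "sigma_parent": self.sigma_hat.get(PARENT),
            "sigma_intermediate": self.sigma_hat.get(INTERMEDIATE),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "objective_value": self.objective_value,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _usable_observations(
    data: TimeCourseData, lod_policy: str, use_replicate_means: bool
) -> pd.DataFrame:
    """Observations entering the objective, after LOD handling and optional averaging."""
    df = data.table.copy()
    if lod_policy == "drop":
        df = df[~df["below_lod"]]
    elif lod_policy == "half_lod":
        lod = df["lod_mg_per_L"].to_numpy()
        flagged = df["below_lod"].to_numpy()
        if np.any(flagged & ~np.isfinite(lod)):
            raise ValidationError("lod_policy='half_lod' requires lod_mg_per_L on flagged rows")
        df = df.copy()
        df.loc[df["below_lod"], "conc_mg_per_L"] = lod[flagged] / 2.0
    else:
        raise ValidationError(f"unknown lod_policy {lod_policy!r}; use 'drop' or 'half_lod'")
    df = df.reset_index(drop=True)
    if use_replicate_means:
        df = (
            df.groupby(["compound", "time_d"], as_index=False)
            .agg(conc_mg_per_L=("conc_mg_per_L", "mean"))
            .assign(replicate="mean")
        )
        df = df.sort_values(["compound", "time_d"], kind="mergesort").reset_index(drop=True)
    return df


def _initial_decay_rate(times: np.ndarray, conc: np.ndarray) -> float:
    """Log-linear regression slope of the parent series, as a cheap k_tot start."""
    pos = conc > 0
    if pos.sum() >= 2 and np.unique(times[pos]).size >= 2:
        slope = np.polyfit(times[pos], np.log(conc[pos]), 1)[0]
        if slope < -1e-12:
            return float(-slope)
    return 1e-4


def _check_fittable(obs: pd.DataFrame, compounds: list[str]) -> None:
    if len(obs) < 4:
        raise FittingError(f"only {len(obs)} usable observations; at least 4 required")
    for c in compounds:
        sub = obs[obs["compound"] == c]
        if sub.empty:
            raise FittingError(f"series {c!r} has no usable observations (all censored or absent)")
        if sub["time_d"].nunique() < 3:
            raise FittingError(f"series {c!r} has fewer than 3 distinct time points")


def _finalize(
    params: KineticParams,
    obs: pd.DataFrame,
    opt_result,
    options: dict,
) -> FitResult:
    pred = np.empty(len(obs))
    for compound, fn in ((PARENT, parent_concentration), (INTERMEDIATE, intermediate_concentration)):
        mask = (obs["compound"] == compound).to_numpy()
        if mask.any():
            pred[mask] = fn(params, obs.loc[mask, "time_d"].to_numpy())
    residuals = obs["conc_mg_per_L"].to_numpy() - pred
    table = pd.DataFrame(
        {
            "time_d": obs["time_d"].to_numpy(),
            "compound": obs["compound"].to_numpy(),
            "replicate": obs["replicate"].to_numpy(),
            "observed": obs["conc_mg_per_L"].to_numpy(),
            "predicted": pred,
            "residual": residuals,
        }
    )

    r2_by = {}
    sigma = {}
    ssr_total = 0.0
    sst_total = 0.0
    for compound in table["compound"].unique():
        sub = table[table["compound"] == compound]
        ssr = float(np.sum(sub["residual"] ** 2))
        sst = float(np.sum((sub["observed"] - sub["observed"].mean()) ** 2))
        ssr_total += ssr
        sst_total += sst
        r2_by[compound] = 1.0 - ssr / sst if sst > 0 else float("nan")
        sigma[compound] = math.sqrt(ssr / max(len(sub) - 2, 1))
    r_squared = 1.0 - ssr_total / sst_total if sst_total > 0 else float("nan")

    return FitResult(
        params_hat=params,
        residuals=table,
        r_squared=r_squared,
        r_squared_by_series=r2_by,
        sigma_hat=sigma,
        converged=bool(opt_result.success),
        n_obs=len(table),
        objective_value=float(2.0 * opt_result.cost),
        options=options,
    )


def fit_branched_model(
    data: TimeCourseData,
    init: Optional[KineticParams] = None,
    fix_S0: bool = False,
    weighting: str = "none",
    lod_policy: str = "drop",
    use_replicate_means: bool = False,
) -> FitResult:
    """Globally fit (k_tot, f, k2, S0) to paired parent/intermediate data.

    Parameters
    ----------
    data : TimeCourseData
        Must contain both a ``parent`` and an ``intermediate`` series with at
        least 3 distinct usable time points each.
    init : KineticParams, optional
        Starting values; by default k_tot comes from a log-linear regression
        of the parent series, f = 0.5, k2 = k_tot and S0 = the earliest
        parent observation.
    fix_S0 : bool
        Fix S0 at its initial value (e.g. the nominal spiked concentration)
        instead of estimating it.
    weighting : {"none", "inverse_variance"}
        ``"none"`` minimizes raw mg/L residuals; ``"inverse_variance"``
        refits with per-series weights 1/sigma from a first unweighted pass.
    lod_policy : {"drop", "half_lod"}
        Below-LOD observations are excluded (default) or replaced by LOD/2.
    use_replicate_means : bool
        Fit per-time replicate means instead of all replicate points.

    Raises
    ------
    FittingError
        Too few usable observations, a fully censored series, or optimizer
        non-convergence (message carries the optimizer diagnostics).
    """
    if weighting not in ("none", "inverse_variance"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    obs = _usable_observations(data, lod_policy, use_replicate_means)
    _check_fittable(obs, [PARENT, INTERMEDIATE])

    par = obs[obs["compound"] == PARENT]
    t_par = par["time_d"].to_numpy()
    c_par = par["conc_mg_per_L"].to_numpy()
    if init is None:
        k0 = _initial_decay_rate(t_par, c_par)
        s0 = float(c_par[np.argmin(t_par)])
        init = KineticParams(k_tot=k0, f=0.5, k2=k0, S0=max(s0, 1e-6))

    options = {
        "model": "branched",
        "fix_S0": fix_S0,
        "weighting": weighting,
        "lod_policy": lod_policy,
        "use_replicate_means": use_replicate_means,
    }

    t_obs = obs["time_d"].to_numpy()
    c_obs = obs["conc_mg_per_L"].to_numpy()
    is_par = (obs["compound"] == PARENT).to_numpy()
    is_int = (obs["compound"] == INTERMEDIATE).to_numpy()

    def unpack(theta) -> KineticParams:
        k_tot = math.exp(theta[0])
        f = 1.0 / (1.0 + math.exp(-theta[1]))
        k2 = math.exp(theta[2])
        s0_val = init.S0 if fix_S0 else math.exp(theta[3])
        return KineticParams(k_tot=k_tot, f=f, k2=k2, S0=s0_val)

    def pack(p: KineticParams) -> np.ndarray:
        f_c = min(max(p.f, 1e-12), 1 - 1e-12)
        theta = [
            math.log(p.k_tot),
            math.log(f_c / (1 - f_c)),
            math.log(max(p.k2, 1e-12)),
        ]
        if not fix_S0:
            theta.append(math.log(max(p.S0, 1e-12)))
        return np.asarray(theta)

    def run(weights: np.ndarray) -> tuple:
        def residual_fn(theta):
            p = unpack(theta)
            pred = np.empty_like(c_obs)
            pred[is_par] = parent_concentration(p, t_obs[is_par])
            pred[is_int] = intermediate_concentration(p, t_obs[is_int])
            return (c_obs - pred) * weights

        res = least_squares(
            residual_fn, pack(init), method="trf", ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=2000
        )
        return unpack(res.x), res

    params, res = run(np.ones_like(c_obs))
    if weighting == "inverse_variance":
        stage1 = _finalize(params, obs, res, options)
        w = np.where(
            is_par,
            1.0 / max(stage1.sigma_hat.get(PARENT, 1.0), 1e-9),
            1.0 / max(stage1.sigma_hat.get(INTERMEDIATE, 1.0), 1e-9),
        )
        params, res = run(w)
    if not res.success:
        raise FittingError(f"global fit did not converge: status={res.status}, {res.message}")
    return _finalize(params, obs, res, options)


def fit_single_first_order(
    data: TimeCourseData,
    init: Optional[KineticParams] = None,
    fix_S0: bool = False,
    lod_policy: str = "drop",
    use_replicate_means: bool = False,
) -> FitResult:
    """Fit a single-substrate exponential decay ``S(t) = S0 exp(-k t)``.

    Uses the parent series only; suited to substrates tracked without an
    intermediate (e.g. fluorene or phenanthrene depletion curves).
    """
    obs = _usable_observations(data, lod_policy, use_replicate_means)
    obs = obs[obs["compound"] == PARENT].reset_index(drop=True)
    _check_fittable(obs, [PARENT])

    t_obs = obs["time_d"].to_numpy()
    c_obs = obs["conc_mg_per_L"].to_numpy()
    if init is None:
        k0 = _initial_decay_rate(t_obs, c_obs)
        init = KineticParams(k_tot=k0, f=0.0, k2=0.0, S0=max(float(c_obs[np.argmin(t_obs)]), 1e-6))

    options = {
        "model": "single",
        "fix_S0": fix_S0,
        "weighting": "none",
        "lod_policy": lod_policy,
        "use_replicate_means": use_replicate_means,
    }

    def unpack(theta) -> KineticParams:
        k = math.exp(theta[0])
        s0_val = init.S0 if fix_S0 else math.exp(theta[1])
        return KineticParams(k_tot=k, f=0.0, k2=0.0, S0=s0_val)

    theta0 = [math.log(init.k_tot)] + ([] if fix_S0 else [math.log(max(init.S0, 1e-12))])

    def residual_fn(theta):
        p = unpack(theta)
        return c_obs - parent_concentration(p, t_obs)

    res = least_squares(
        residual_fn, np.asarray(theta0), method="trf", ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=2000
    )
    if not res.success:
        raise FittingError(f"single first-order fit did not converge: status={res.status}, {res.message}")
    return _finalize(unpack(res.x), obs, res, options)


def goodness_of_fit(result: FitResult) -> float:
    """Pooled R^2 = 1 - SSR/SST over all fitted series.

    SSR pools squared residuals over the series; SST pools squared deviations
    of each series' observations from that series' own mean, so a flat-mean
    predictor scores exactly 0.

    Raises
    ------
    ValidationError
        If the total sum of squares is zero (all observations identical).
    """
    table = result.residuals
    ssr = 0.0
    sst = 0.0
    for compound in table["compound"].unique():
        sub = table[table["compound"] == compound]
        ssr += float(np.sum(sub["residual"] ** 2))
        sst += float(np.sum((sub["observed"] - sub["observed"].mean()) ** 2))
    if sst == 0:
        raise ValidationError("R^2 undefined: zero total sum of squares (all observations identical)")
    return 1.0 - ssr / sst


def percent_degraded(initial: float, residual: float) -> float:
    """Percent of substrate removed: ``100 (initial - residual) / initial``.

    ``initial`` is the starting or abiotic-control concentration and
    ``residual`` the remaining concentration, both mg/L.  Floored at 0 when
    the residual exceeds the initial value (apparent negative removal).
    """
    if not (math.isfinite(initial) and initial > 0):
        raise ValidationError(f"initial concentration must be > 0, got {initial}")
    if not (math.isfinite(residual) and residual >= 0):
        raise ValidationError(f"residual concentration must be >= 0, got {residual}")
    return max(100.0 * (initial - residual) / initial, 0.0)
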