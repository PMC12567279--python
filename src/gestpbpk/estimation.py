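"""Weighted-least-squares parameter estimation with multi-start Nelder–Mead.

Estimates the absorption rate constant (k_a), the gut hybrid flow parameter
(Q_gut) and the partition-coefficient scalar (Kp scalar) from observed
concentration–time data. The objective is sum_i w_i (obs_i - pred_i)^2 with
proportional-error weighting w_i = 1/obs_i^2 by default (also: uniform or
1/obs). Parameters are optimized in log space to enforce positivity, and
the simplex search is restarted from log-uniform draws within bounds; the
global best across restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .compound import CompoundRecord
from .errors import ConfigError, EstimationError, UsageError
from .pbpk import DoseRegimen, SimulationSettings, simulate_individual
from .physiology import PhysiologySnapshot

FITTABLE = ("k_absorption", "q_gut", "kp_scalar")
WEIGHTINGS = ("proportional", "uniform", "inverse")


@dataclass(frozen=True)
class FitSpec:
    """What to fit, within which bounds, and how hard to try."""

    parameters: tuple[str, ...] = FITTABLE
    bounds: Mapping[str, tuple[float, float]] | None = None
    weighting: str = "proportional"
    n_restarts: int = 100
    seed: int = 0
    maxiter: int = 400
    xatol: float = 1e-4
    fatol: float = 1e-8

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.weighting not in WEIGHTINGS:
            raise ConfigError(f"weighting must be one of {WEIGHTINGS}")
        unknown = set(self.parameters) - set(FITTABLE)
        if unknown:
            raise ConfigError(f"cannot fit parameter(s): {sorted(unknown)}")

    def resolved_bounds(self, compound: CompoundRecord) -> dict[str, tuple[float, float]]:
        """Default bounds: a factor of 4 either side of the compound default."""
        out = {}
        for p in self.parameters:
            if self.bounds and p in self.bounds:
                lo, hi = self.bounds[p]
            else:
                v = getattr(compound, p)
                lo, hi = v / 4.0, v * 4.0
            if lo <= 0 or hi <= lo:
                raise ConfigError(f"bounds for {p} must be positive with hi > lo")
            out[p] = (lo, hi)
        return out


@dataclass
class FitResult:
    """Best-fit values with the per-restart trace."""

    parameters: dict[str, float]
    objective: float
    n_restarts: int
    restarts: pd.DataFrame        # one row per restart: start/final values, objective, converged
    converged: bool

    def __repr__(self):
        vals = ", ".join(f"{k}={v:.4g}" for k, v in self.parameters.items())
        return f"FitResult({vals}, objective={self.objective:.4g})"


def _weights(obs: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "proportional":
        return 1.0 / obs**2
    if scheme == "inverse":
        return 1.0 / obs
    return np.ones_like(obs)


def fit_parameters(
    observed,
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    regimen: DoseRegimen,
    spec: FitSpec | None = None,
    settings: SimulationSettings | None = None,
) -> FitResult:
    """Fit the spec'd parameters to observed maternal concentrations.

    ``observed`` is an ObservedDataset or any DataFrame-like with columns
    ``time_h`` (hours after the final dose of the regimen) and
    ``conc_ng_per_ml`` (maternal site only). All subjects are pooled; the
    model prediction is the default-individual profile, so the fit is a
    naive-pooled-data estimate.
    """
    spec = spec or FitSpec()
    settings = settings or SimulationSettings(grid_dt=0.25)
    df = getattr(observed, "frame", observed)
    if "site" in df:
        df = df[df["site"] == "maternal"]
    t_obs = np.asarray(df["time_h"], dtype=float)
    c_obs = np.asarray(df["conc_ng_per_ml"], dtype=float)
    if len(t_obs) < len(spec.parameters) + 1:
        raise UsageError(
            f"need at least {len(spec.parameters) + 1} observations to fit "
            f"{len(spec.parameters)} parameters"
        )
    if np.any(c_obs <= 0):
        raise UsageError("observed concentrations must be positive")
    # observation clock starts at the final dose
    t_abs = (regimen.n_doses - 1) * regimen.interval + t_obs
    if t_abs.max() > regimen.duration + 1e-9:
        raise UsageError("observation beyond the simulated horizon")
    w = _weights(c_obs, spec.weighting)
    bounds = spec.resolved_bounds(compound)
    names = list(spec.parameters)
    log_lo = np.log([bounds[p][0] for p in names])
    log_hi = np.log([bounds[p][1] for p in names])

    def objective(log_theta: np.ndarray) -> float:
        if np.any(log_theta < log_lo - 1e-12) or np.any(log_theta > log_hi + 1e-12):
            return np.inf
        trial = compound.with_updates(**dict(zip(names, np.exp(log_theta))))
        prof = simulate_individual(trial, physiology, regimen, settings)
        pred = np.interp(t_abs, prof.times, prof.maternal_plasma)
        return float(np.sum(w * (c_obs - pred) ** 2))

    rng = np.random.default_rng(spec.seed)
    rows = []
    best = None
    for k in range(spec.n_restarts):
        x0 = rng.uniform(log_lo, log_hi)
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": spec.maxiter, "xatol": spec.xatol,
                     "fatol": spec.fatol, "adaptive": True},
        )
        rows.append({
            "restart": k,
            **{f"start_{p}": np.exp(x0[i]) for i, p in enumerate(names)},
            **{f"fit_{p}": np.exp(res.x[i]) for i, p in enumerate(names)},
            "objective": res.fun,
            "converged": bool(res.success),
        })
        if res.success and (best is None or res.fun < best.fun):
            best = res
    trace = pd.DataFrame(rows)
    if best is None:
        raise EstimationError("no restart converged", trace)
    return FitResult(
        parameters=dict(zip(names, np.exp(best.x))),
        objective=float(best.fun),
        n_restarts=spec.n_restarts,
        restarts=trace,
        converged=True,
    )
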