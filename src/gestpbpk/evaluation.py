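"""PK summary metrics, model-qualification statistics and Morris screening.

Qualification follows the conventional criteria for PBPK models: the
prediction ratio (predicted/observed, acceptable within 0.7–1.3), the
absolute average fold error AAFE = 10^(mean |log10(pred/obs)|) with
AAFE < 2 acceptable, and the fraction of observed points falling inside
the simulated 5th–95th percentile band. Global sensitivity uses the Morris
elementary-effects method: r one-at-a-time trajectories on a p-level grid,
summarized per parameter by mu* (mean absolute elementary effect, used for
ranking) and sigma (interaction/nonlinearity indicator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError
from .pbpk import ConcentrationProfile

RATIO_BOUNDS = (0.7, 1.3)
AAFE_BOUND = 2.0


@dataclass(frozen=True)
class PKSummary:
    """Steady-state exposure metrics over one dosing interval."""

    c_max: float      # ng/mL
    t_max: float      # h after the last dose
    auc: float        # ng*h/mL over the interval (trapezoidal)
    c_min_ss: float   # ng/mL
    c_avg_ss: float   # ng/mL (= AUC_tau / tau)
    c_max_ss: float   # ng/mL (alias of c_max at steady state)


def compute_pk_metrics(profile: ConcentrationProfile, interval: float = 24.0) -> PKSummary:
    """Metrics on the final dosing interval of a simulated profile."""
    t_end = profile.times[-1]
    mask = profile.times >= t_end - interval - 1e-9
    if np.ptp(profile.times[mask]) < interval - 1e-6:
        raise UsageError("profile does not cover one full dosing interval")
    t = profile.times[mask]
    c = profile.maternal_plasma[mask]
    auc = float(np.trapezoid(c, t))
    i_max = int(np.argmax(c))
    return PKSummary(
        c_max=float(c[i_max]),
        t_max=float(t[i_max] - t[0]),
        auc=auc,
        c_min_ss=float(c.min()),
        c_avg_ss=auc / interval,
        c_max_ss=float(c[i_max]),
    )


def prediction_ratio(predicted: float, observed: float) -> tuple[float, bool]:
    """Predicted/observed quotient and its 0.7–1.3 acceptability flag."""
    if observed <= 0:
        raise DomainError("observed value must be positive")
    r = predicted / observed
    return r, RATIO_BOUNDS[0] <= r <= RATIO_BOUNDS[1]


def aafe(pairs: Sequence[tuple[float, float]]) -> float:
    """Absolute average fold error, 10^(mean |log10(predicted/observed)|)."""
    if len(pairs) == 0:
        raise DomainError("aafe requires at least one pair")
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise DomainError("aafe requires positive predicted and observed values")
        logs.append(abs(np.log10(pred / obs)))
    return float(10.0 ** np.mean(logs))


@dataclass
class VerificationReport:
    """Qualification summary for a predicted-vs-observed comparison."""

    prediction_ratios: dict[str, float]
    ratio_acceptable: dict[str, bool]
    aafe: float
    n_pairs: int
    coverage_fraction: float | None = None

    @property
    def aafe_acceptable(self) -> bool:
        return self.aafe < AAFE_BOUND

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "prediction_ratio": v, "acceptable": self.ratio_acceptable[k]}
            for k, v in self.prediction_ratios.items()
        ]
        return pd.DataFrame(rows)


def verification_report(
    metric_pairs: Mapping[str, tuple[float, float]],
    coverage: float | None = None,
) -> VerificationReport:
    """Build a report from named (predicted, observed) metric pairs."""
    ratios, flags = {}, {}
    for name, (pred, obs) in metric_pairs.items():
        ratios[name], flags[name] = prediction_ratio(pred, obs)
    return VerificationReport(
        prediction_ratios=ratios,
        ratio_acceptable=flags,
        aafe=aafe(list(metric_pairs.values())),
        n_pairs=len(metric_pairs),
        coverage_fraction=coverage,
    )


def coverage_check(observed, band, time_offset: float = 0.0) -> float:
    """Fraction of observed points inside the simulated 5th–95th band.

    ``observed`` needs ``time_h`` and ``conc_ng_per_ml`` columns (an
    ObservedDataset or its DataFrame); ``band`` is a PopulationSummary with
    times and the percentile profiles. The band is interpolated linearly at
    the observation times. ``time_offset`` shifts observation clocks that
    start at the final dose onto the band's absolute time axis (pass
    ``(n_doses - 1) * interval`` for steady-state sampling).
    """
    df = getattr(observed, "frame", observed)
    if len(df) == 0:
        raise UsageError("observed dataset is empty")
    t = np.asarray(df["time_h"], dtype=float) + time_offset
    c = np.asarray(df["conc_ng_per_ml"], dtype=float)
    if t.min() < band.times[0] - 1e-9 or t.max() > band.times[-1] + 1e-9:
        raise UsageError("observation times fall outside the simulated band")
    lo = np.interp(t, band.times, band.p5)
    hi = np.interp(t, band.times, band.p95)
    return float(np.mean((c >= lo) & (c <= hi)))


@dataclass
class MorrisResult:
    """Elementary-effects screening summary per output."""

    parameters: list[str]
    mu_star: dict[str, np.ndarray]   # output -> per-parameter mu*
    sigma: dict[str, np.ndarray]
    n_trajectories: int

    def ranking(self, output: str) -> list[str]:
        order = np.argsort(self.mu_star[output])[::-1]
        return [self.parameters[i] for i in order]

    def top(self, output: str, k: int = 3) -> set[str]:
        return set(self.ranking(output)[:k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for out in self.mu_star:
            for i, p in enumerate(self.parameters):
                rows.append({"output": out, "parameter": p,
                             "mu_star": self.mu_star[out][i],
                             "sigma": self.sigma[out][i]})
        return pd.DataFrame(rows)


def morris_screening(
    model: Callable[[Mapping[str, float]], Mapping[str, float]],
    parameter_ranges: Mapping[str, tuple[float, float]],
    r: int = 20,
    levels: int = 4,
    seed: int = 0,
) -> MorrisResult:
    """Morris one-at-a-time elementary-effects screening.

    ``model`` maps a parameter dict to a dict of scalar outputs. Each of the
    ``r`` trajectories starts from a random point on a ``levels``-level grid
    in the unit hypercube and perturbs each parameter once by
    delta = levels / (2*(levels-1)), in random order and random direction.
    Elementary effects are computed on the unit scale, so mu* is comparable
    across parameters. Model failures on a sampled point are recorded and
    that trajectory's affected effects are excluded.
    """
    if r < 4:
        raise DomainError("at least 4 trajectories are required")
    names = list(parameter_ranges)
    lo = np.array([parameter_ranges[p][0] for p in names])
    hi = np.array([parameter_ranges[p][1] for p in names])
    if np.any(hi <= lo):
        raise DomainError("parameter ranges must have positive width")
    k = len(names)
    delta = levels / (2.0 * (levels - 1))
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0 - delta, levels // 2)

    effects: dict[str, list[list[float]]] = {}
    failures = 0

    def evaluate(u: np.ndarray):
        x = lo + u * (hi - lo)
        try:
            return dict(model(dict(zip(names, x))))
        except Exception:
            return None

    for _ in range(r):
        u = rng.choice(grid, size=k)
        y0 = evaluate(u)
        order = rng.permutation(k)
        for j in order:
            step = delta if u[j] + delta <= 1.0 + 1e-12 else -delta
            u_new = u.copy()
            u_new[j] = min(u[j] + step, 1.0)
            y1 = evaluate(u_new)
            if y0 is None or y1 is None:
                failures += 1
            else:
                for out in y1:
                    effects.setdefault(out, [[] for _ in range(k)])
                    effects[out][j].append((y1[out] - y0[out]) / step)
            u, y0 = u_new, y1

    mu_star = {
        out: np.array([np.mean(np.abs(e)) if e else 0.0 for e in per_param])
        for out, per_param in effects.items()
    }
    sigma = {
        out: np.array([np.std(e) if e else 0.0 for e in per_param])
        for out, per_param in effects.items()
    }
    result = MorrisResult(parameters=names, mu_star=mu_star, sigma=sigma, n_trajectories=r)
    if failures:
        import warnings
        warnings.warn(f"{failures} model evaluations failed and were excluded")
    return result
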