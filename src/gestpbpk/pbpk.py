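"""Whole-body maternal PBPK engine for oral multiple dosing.

The disposition model is a perfusion-limited whole-body system: a lumped
blood pool, eleven explicit tissues plus a rest-of-body compartment, a
first-order oral depot emptying into the liver (with gut first-pass
availability applied as a bioavailable fraction), well-stirred hepatic
elimination and GFR-scaled renal elimination from blood. Between dose events
the system is linear and time-invariant,

    dx/dt = M x,

so the default integrator propagates the state with the matrix exponential
of ``M * dt`` — exact for the linear system at any step size — while an
adaptive stiff ODE solver (LSODA) is available as an independent
cross-check. Repeated doses are depot-replenishment events at which the
propagation is restarted, so no discontinuity ever crosses an integration
step.

Amounts are carried in µg and volumes in L, so concentrations come out in
µg/L = ng/mL without further conversion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .compound import CompoundRecord, FetalParameters, predict_kp, whole_liver_intrinsic_clearance
from .errors import DomainError, NumericalError, UsageError
from .physiology import PhysiologySnapshot, scale_fraction_unbound

MG_TO_UG = 1000.0


@dataclass(frozen=True)
class DoseRegimen:
    """An oral (or, for diagnostics, intravenous-bolus) dosing schedule."""

    dose: float            # mg
    interval: float = 24.0  # h
    n_doses: int = 10
    route: str = "oral"

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError("dose must be non-negative")
        if self.interval <= 0:
            raise DomainError("dose interval must be positive")
        if self.n_doses < 1:
            raise DomainError("n_doses must be >= 1")
        if self.route not in ("oral", "iv_bolus"):
            raise DomainError(f"unsupported route {self.route!r}")

    @property
    def duration(self) -> float:
        return self.interval * self.n_doses


@dataclass(frozen=True)
class SimulationSettings:
    """Solver configuration.

    ``method`` selects the propagator: ``"matrix_exponential"`` (default,
    exact for the linear system) or ``"lsoda"`` (adaptive cross-check using
    ``rtol``/``atol``). ``grid_dt`` is the output grid spacing in hours and
    must divide the dose interval.
    """

    method: str = "matrix_exponential"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 0.1
    mass_balance_check: bool = True
    mass_balance_rtol: float = 1e-6

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.grid_dt <= 0:
            raise DomainError("solver tolerances and grid spacing must be positive")
        if self.method not in ("matrix_exponential", "lsoda"):
            raise DomainError(f"unknown solver method {self.method!r}")


@dataclass
class ConcentrationProfile:
    """Concentration–time series for one individual or a population summary."""

    times: np.ndarray                 # h
    maternal_plasma: np.ndarray       # ng/mL
    fetal_plasma: np.ndarray | None = None
    amniotic: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.maternal_plasma = np.asarray(self.maternal_plasma, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("profile times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_h, compartment, conc_ng_per_ml."""
        parts = [pd.DataFrame({
            "time_h": self.times, "compartment": "maternal_plasma",
            "conc_ng_per_ml": self.maternal_plasma,
        })]
        if self.fetal_plasma is not None:
            parts.append(pd.DataFrame({
                "time_h": self.times, "compartment": "fetal_plasma",
                "conc_ng_per_ml": self.fetal_plasma,
            }))
        if self.amniotic is not None:
            parts.append(pd.DataFrame({
                "time_h": self.times, "compartment": "amniotic_fluid",
                "conc_ng_per_ml": self.amniotic,
            }))
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        """Write the profile CSV with a commented metadata header block."""
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationProfile":
        meta = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                else:
                    lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)))
        wide = df.pivot(index="time_h", columns="compartment", values="conc_ng_per_ml")
        return cls(
            times=wide.index.to_numpy(),
            maternal_plasma=wide["maternal_plasma"].to_numpy(),
            fetal_plasma=wide["fetal_plasma"].to_numpy() if "fetal_plasma" in wide else None,
            amniotic=wide["amniotic_fluid"].to_numpy() if "amniotic_fluid" in wide else None,
            metadata=meta,
        )


@dataclass
class LinearSystem:
    """Assembled linear PBPK system and its bookkeeping."""

    matrix: np.ndarray
    state_names: list[str]
    i_depot: int
    i_blood: int
    i_liver: int
    blood_volume: float
    blood_to_plasma: float
    fu_plasma: float
    fu_blood: float
    clu_int: float             # whole-liver unbound intrinsic clearance, L/h
    f_gut: float
    cl_renal: float            # plasma-referenced renal clearance at this GW, L/h
    hepatic_blood_flow: float
    kps: dict[str, float]
    i_fetal_plasma: int | None = None
    i_amniotic: int | None = None
    fetal_plasma_volume: float | None = None
    amniotic_volume_l: float | None = None
    fu_fetal: float | None = None

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def plasma_concentration(self, states: np.ndarray) -> np.ndarray:
        """Maternal plasma concentration (ng/mL) from state amounts (µg)."""
        return states[..., self.i_blood] / self.blood_volume / self.blood_to_plasma


def gut_first_pass(compound: CompoundRecord, physiology: PhysiologySnapshot | None = None) -> float:
    """Fraction escaping gut-wall first-pass metabolism.

    Hybrid-flow formulation: Fg = Q_gut / (Q_gut + fu_gut * CLu_int,gut);
    unity when the gut intrinsic clearance is zero.
    """
    if compound.q_gut <= 0:
        raise DomainError("q_gut must be positive")
    return compound.q_gut / (compound.q_gut + compound.fu_gut * compound.clint_gut_unbound)


def wellstirred_hepatic_clearance(q_h: float, fu_blood: float, clu_int: float) -> float:
    """Well-stirred hepatic blood clearance: Qh*fuB*CLu/(Qh + fuB*CLu)."""
    if min(q_h, fu_blood, clu_int) < 0:
        raise DomainError("inputs must be non-negative")
    denom = q_h + fu_blood * clu_int
    if denom == 0.0:
        return 0.0
    return q_h * fu_blood * clu_int / denom


def build_system(
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    phenotype_multipliers: Mapping[str, float] | None = None,
    fetal_params: FetalParameters | None = None,
) -> LinearSystem:
    """Assemble the linear disposition matrix at one gestational age.

    Gut and spleen drain through the portal vein into the liver; all other
    tissues exchange directly with the lumped blood pool. The gestational
    snapshot supplies flows, volumes, hematocrit, GFR and enzyme-activity
    multipliers; the fraction unbound is rescaled for the gestational
    binding-protein level and the partition coefficients are re-predicted at
    that fu and hematocrit. Passing ``fetal_params`` appends the
    permeability-limited placenta, fetal plasma and amniotic compartments
    (transfer driven by unbound concentrations; see the fetoplacental
    module).
    """
    bp = compound.blood_to_plasma
    protein_ratio = physiology.binding_protein_conc_ratio
    fu = scale_fraction_unbound(compound.fu_plasma, protein_ratio)
    fu_b = fu / bp
    hct = physiology.hematocrit
    kps = predict_kp(compound, fu_plasma=fu, hematocrit=hct)
    clu = whole_liver_intrinsic_clearance(compound, physiology, phenotype_multipliers)
    fg = gut_first_pass(compound, physiology)
    # renal clearance scaled by the GFR ratio to its baseline fixture value
    cl_renal = compound.cl_renal_adult * physiology.gfr / _baseline_gfr(physiology)

    tissues = [t for t in physiology.tissue_volumes if t != "plasma"]
    v_plasma = physiology.plasma_volume
    v_blood = v_plasma / (1.0 - hct)

    names = ["depot"] + tissues + ["blood", "eliminated_hepatic",
                                   "eliminated_renal", "first_pass_loss"]
    idx = {n: i for i, n in enumerate(names)}
    fetal = fetal_params is not None
    if fetal:
        for n in ("placenta", "fetal_plasma", "amniotic"):
            idx[n] = len(names)
            names.append(n)

    n = len(names)
    m = np.zeros((n, n))
    i_dep, i_bl, i_liv = idx["depot"], idx["blood"], idx["liver"]
    q_h = physiology.hepatic_blood_flow

    # oral depot -> liver (bioavailable fraction) and first-pass loss bucket
    m[i_dep, i_dep] -= compound.k_absorption
    m[i_liv, i_dep] += compound.k_absorption * compound.f_absorbed * fg
    m[idx["first_pass_loss"], i_dep] += compound.k_absorption * (1.0 - compound.f_absorbed * fg)

    for t in tissues:
        i = idx[t]
        q = physiology.tissue_flows[t]
        kp_b = kps[t] / bp          # tissue:blood partition
        k_out = q / (physiology.tissue_volumes[t] * kp_b)
        m[i, i_bl] += q / v_blood
        m[i_bl, i_bl] -= q / v_blood
        if t in ("gut", "spleen"):
            m[i_liv, i] += k_out     # portal drainage
            m[i, i] -= k_out
        elif t == "liver":
            k_liv = 1.0 / (physiology.tissue_volumes[t] * kp_b)
            m[i, i] -= (q_h + clu * fu_b) * k_liv
            m[i_bl, i] += q_h * k_liv
            m[idx["eliminated_hepatic"], i] += clu * fu_b * k_liv
        else:
            m[i_bl, i] += k_out
            m[i, i] -= k_out

    # renal elimination from blood at the plasma-referenced clearance
    k_ren = cl_renal / bp / v_blood
    m[idx["eliminated_renal"], i_bl] += k_ren
    m[i_bl, i_bl] -= k_ren

    system = LinearSystem(
        matrix=m, state_names=names, i_depot=i_dep, i_blood=i_bl, i_liver=i_liv,
        blood_volume=v_blood, blood_to_plasma=bp, fu_plasma=fu, fu_blood=fu_b,
        clu_int=clu, f_gut=fg, cl_renal=cl_renal, hepatic_blood_flow=q_h, kps=kps,
    )

    if fetal:
        _attach_fetoplacental(system, idx, compound, physiology, fetal_params, fu)
    return system


def _baseline_gfr(physiology: PhysiologySnapshot) -> float:
    coeffs = physiology._coefficients
    if coeffs is not None and "gfr" in coeffs:
        return coeffs["gfr"].baseline_value
    return 121.0


def _attach_fetoplacental(system, idx, compound, physiology, fetal_params, fu_maternal):
    """Wire the placenta / fetal plasma / amniotic states into the matrix."""
    m = system.matrix
    bp = compound.blood_to_plasma
    i_bl, i_pl = system.i_blood, idx["placenta"]
    i_fp, i_am = idx["fetal_plasma"], idx["amniotic"]

    fw = physiology.fetal_weight
    v_pl = 0.5                                   # placental tissue node, L
    v_fp = 0.045 * fw                            # fetal plasma, L
    v_am = physiology.amniotic_volume / 1000.0   # mL -> L
    fu_f = scale_fraction_unbound(
        compound.fu_plasma, fetal_params.fetal_binding_protein_ratio
    )
    cl_ren_f = fetal_params.cl_renal_fetal * fw  # L/h at current fetal weight
    cl_sw = fetal_params.cl_swallowing * fw

    # maternal plasma <-> placental node, driven by unbound concentration
    k_m = compound.cl_pdm * fu_maternal / (system.blood_volume * bp)
    m[i_pl, i_bl] += k_m
    m[i_bl, i_bl] -= k_m
    m[i_bl, i_pl] += compound.cl_pdm / v_pl
    m[i_pl, i_pl] -= compound.cl_pdm / v_pl
    # placental node <-> fetal plasma
    m[i_fp, i_pl] += compound.cl_pdf / v_pl
    m[i_pl, i_pl] -= compound.cl_pdf / v_pl
    m[i_pl, i_fp] += compound.cl_pdf * fu_f / v_fp
    m[i_fp, i_fp] -= compound.cl_pdf * fu_f / v_fp
    # fetal renal: fetal plasma -> amniotic fluid
    m[i_am, i_fp] += cl_ren_f / v_fp
    m[i_fp, i_fp] -= cl_ren_f / v_fp
    # swallowing: amniotic fluid -> fetal gut, fully reabsorbed to fetal plasma
    m[i_fp, i_am] += cl_sw / v_am
    m[i_am, i_am] -= cl_sw / v_am

    system.i_fetal_plasma = i_fp
    system.i_amniotic = i_am
    system.fetal_plasma_volume = v_fp
    system.amniotic_volume_l = v_am
    system.fu_fetal = fu_f


def _propagate(system: LinearSystem, regimen: DoseRegimen,
               settings: SimulationSettings) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the dosing schedule; returns (times, state trajectory)."""
    dt = settings.grid_dt
    steps = regimen.interval / dt
    if abs(steps - round(steps)) > 1e-9:
        raise DomainError("grid_dt must divide the dose interval")
    steps = int(round(steps))

    n = system.n_states
    dose_ug = regimen.dose * MG_TO_UG
    i_in = system.i_depot if regimen.route == "oral" else system.i_blood

    times = np.empty(regimen.n_doses * steps + 1)
    states = np.empty((regimen.n_doses * steps + 1, n))
    x = np.zeros(n)
    times[0] = 0.0
    states[0] = x
    k = 1

    if settings.method == "matrix_exponential":
        e = expm(system.matrix * dt)
        for d in range(regimen.n_doses):
            x = x.copy()
            x[i_in] += dose_ug
            for _ in range(steps):
                x = e @ x
                times[k] = k * dt
                states[k] = x
                k += 1
    else:
        grid = np.linspace(0.0, regimen.interval, steps + 1)
        for d in range(regimen.n_doses):
            x = x.copy()
            x[i_in] += dose_ug
            sol = solve_ivp(
                lambda t, y: system.matrix @ y, (0.0, regimen.interval), x,
                method="LSODA", t_eval=grid, rtol=settings.rtol, atol=settings.atol,
            )
            if not sol.success:
                raise NumericalError(f"LSODA failed on dose {d + 1}: {sol.message}")
            seg = sol.y.T[1:]
            nseg = seg.shape[0]
            times[k:k + nseg] = d * regimen.interval + grid[1:]
            states[k:k + nseg] = seg
            x = seg[-1]
            k += nseg

    if settings.mass_balance_check and regimen.dose > 0:
        total = states[-1].sum()
        administered = dose_ug * regimen.n_doses
        if abs(total - administered) > settings.mass_balance_rtol * administered * 10:
            raise NumericalError(
                f"mass balance violated: recovered {total:.6g} µg of "
                f"{administered:.6g} µg administered"
            )
    return times, states


def simulate_individual(
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    regimen: DoseRegimen,
    settings: SimulationSettings | None = None,
    phenotype_multipliers: Mapping[str, float] | None = None,
) -> ConcentrationProfile:
    """Simulate a maternal concentration–time profile for a dosing schedule."""
    settings = settings or SimulationSettings()
    system = build_system(compound, physiology, phenotype_multipliers)
    times, states = _propagate(system, regimen, settings)
    return ConcentrationProfile(
        times=times,
        maternal_plasma=system.plasma_concentration(states),
        metadata={
            "gw": physiology.gestational_week,
            "dose_mg": regimen.dose,
            "interval_h": regimen.interval,
            "n_doses": regimen.n_doses,
            "route": regimen.route,
            "method": settings.method,
        },
    )
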