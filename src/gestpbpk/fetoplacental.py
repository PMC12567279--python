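"""Permeability-limited placenta, fetal plasma and amniotic fluid.

The fetoplacental unit extends the maternal system from gestational week 15
with two sequential diffusion barriers in series through a small placental
tissue node: maternal plasma <-> placenta (CL_PDM) and placenta <-> fetal
plasma (CL_PDF), both driven by unbound concentrations. Fetal elimination
is a conservative loop: fetal renal clearance moves drug from fetal plasma
into the amniotic fluid and fetal swallowing returns it (fully reabsorbed),
so the only true exit from the fetoplacental unit is back-transfer to the
mother.

A consequence worth noting: at the periodic steady state the dosing-
interval averages satisfy fu_m * <C_maternal> = fu_f * <C_fetal> exactly
(zero net placental flux over a period), so the total-concentration
cord-to-maternal ratio equals the maternal:fetal ratio of fractions
unbound. The sub-unity clinical ratio of this drug therefore arises from
the weaker protein binding in fetal plasma.
"""

from __future__ import annotations

import numpy as np

from .compound import CompoundRecord, FetalParameters
from .errors import DomainError, UsageError
from .pbpk import (
    ConcentrationProfile,
    DoseRegimen,
    LinearSystem,
    SimulationSettings,
    _propagate,
    build_system,
)
from .physiology import FETAL_ONSET_WEEK, PhysiologySnapshot


class FetoplacentalState:
    """Derived fetoplacental quantities of an assembled system (read-only)."""

    def __init__(self, system: LinearSystem, compound: CompoundRecord,
                 physiology: PhysiologySnapshot, fetal_params: FetalParameters):
        self.cl_pdm = compound.cl_pdm
        self.cl_pdf = compound.cl_pdf
        self.fetal_plasma_volume = system.fetal_plasma_volume
        self.amniotic_volume = system.amniotic_volume_l
        self.fu_fetal = system.fu_fetal
        fw = physiology.fetal_weight
        self.cl_renal_fetal = fetal_params.cl_renal_fetal * fw  # L/h
        self.cl_swallowing = fetal_params.cl_swallowing * fw    # L/h


def simulate_pregnant_with_fetus(
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    regimen: DoseRegimen,
    settings: SimulationSettings | None = None,
    fetal_params: FetalParameters | None = None,
    phenotype_multipliers=None,
) -> ConcentrationProfile:
    """Simulate maternal + fetal (cord) + amniotic concentration profiles.

    Only valid from gestational week 15, when the permeability-limited
    placental model is active.
    """
    if physiology.gestational_week < FETAL_ONSET_WEEK:
        raise DomainError(
            f"the fetoplacental unit is implemented from gestational week "
            f"{FETAL_ONSET_WEEK:g}; got gw={physiology.gestational_week}"
        )
    settings = settings or SimulationSettings()
    fetal_params = fetal_params or FetalParameters(cl_renal_adult=compound.cl_renal_adult)
    system = build_system(compound, physiology, phenotype_multipliers, fetal_params)
    times, states = _propagate(system, regimen, settings)
    return ConcentrationProfile(
        times=times,
        maternal_plasma=system.plasma_concentration(states),
        fetal_plasma=states[:, system.i_fetal_plasma] / system.fetal_plasma_volume,
        amniotic=states[:, system.i_amniotic] / system.amniotic_volume_l,
        metadata={
            "gw": physiology.gestational_week,
            "dose_mg": regimen.dose,
            "interval_h": regimen.interval,
            "n_doses": regimen.n_doses,
            "fu_fetal": system.fu_fetal,
            "method": settings.method,
        },
    )


def cord_to_maternal_ratio(profile: ConcentrationProfile, interval: float = 24.0) -> float:
    """Fetal:maternal plasma concentration ratio over the final dosing interval.

    Time-averaged definition: ratio of the interval-averaged fetal (cord)
    concentration to the interval-averaged maternal concentration. The
    trough-based ratio is available via the profile arrays directly.
    """
    if profile.fetal_plasma is None:
        raise UsageError("profile has no fetal plasma series")
    t_end = profile.times[-1]
    mask = profile.times >= t_end - interval
    if mask.sum() < 2:
        raise UsageError("profile shorter than one dosing interval")
    t = profile.times[mask]
    auc_m = np.trapezoid(profile.maternal_plasma[mask], t)
    auc_f = np.trapezoid(profile.fetal_plasma[mask], t)
    if auc_m <= 0:
        raise UsageError("maternal exposure is zero over the final interval")
    return float(auc_f / auc_m)
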