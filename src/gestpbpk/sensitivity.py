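"""The canonical nine-parameter Morris screen of the nonpregnant model.

The screened parameters are the drug-specific inputs of the absorption,
distribution and elimination blocks — fa, ka, fu_gut, Q_gut, logP, Kp
scalar, and the three per-isoform intrinsic clearances — each over a
±50% range around its default. Outputs are Cmax and AUC (full-horizon
trapezoid, an AUC(0–inf) surrogate) of the single-dose 20 mg nonpregnant
simulation, the design used for model verification. The two binding ratios
fu_p and B/P are deliberately not screened: both rescale the reported
plasma concentration (and clearance) in a directly monotone, almost
unit-like way that would dominate the ranking without adding disposition
insight; logP instead probes lipophilicity through the mechanistic
partitioning equations.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .compound import CompoundRecord
from .pbpk import DoseRegimen, SimulationSettings, simulate_individual
from .physiology import build_physiology

MORRIS_PARAMETERS = (
    "f_absorbed", "k_absorption", "fu_gut", "q_gut", "logp",
    "kp_scalar", "clint_CYP2C19", "clint_CYP2D6", "clint_CYP3A4",
)


def DEFAULT_MORRIS_RANGES(compound: CompoundRecord) -> dict[str, tuple[float, float]]:
    """±50% ranges around the compound defaults (fractions capped at 1)."""
    base = {
        "f_absorbed": compound.f_absorbed,
        "k_absorption": compound.k_absorption,
        "fu_gut": compound.fu_gut,
        "q_gut": compound.q_gut,
        "logp": compound.logp,
        "kp_scalar": compound.kp_scalar,
        "clint_CYP2C19": compound.clint_by_isoform["CYP2C19"],
        "clint_CYP2D6": compound.clint_by_isoform["CYP2D6"],
        "clint_CYP3A4": compound.clint_by_isoform["CYP3A4"],
    }
    ranges = {}
    for name, v in base.items():
        lo, hi = 0.5 * v, 1.5 * v
        if name in ("f_absorbed", "fu_gut"):
            hi = min(hi, 1.0)
        ranges[name] = (lo, hi)
    return ranges


def default_morris_model(compound: CompoundRecord, physiology_overrides=None,
                         dose_mg: float = 20.0):
    """Build the parameter-vector -> {cmax, auc} function for the screen."""
    physiology = build_physiology(0.0, physiology_overrides)
    regimen = DoseRegimen(dose=dose_mg, interval=24.0, n_doses=1)
    # single dose followed to 10 days so the AUC tail is essentially complete
    horizon = DoseRegimen(dose=dose_mg, interval=240.0, n_doses=1)
    settings = SimulationSettings(grid_dt=0.25)

    def model(params: Mapping[str, float]) -> dict[str, float]:
        clint = dict(compound.clint_by_isoform)
        updates = {}
        for name, value in params.items():
            if name.startswith("clint_"):
                clint[name.removeprefix("clint_")] = value
            else:
                updates[name] = value
        trial = compound.with_updates(clint_by_isoform=clint, **updates)
        prof = simulate_individual(trial, physiology, horizon, settings)
        return {
            "cmax": float(prof.maternal_plasma.max()),
            "auc": float(np.trapezoid(prof.maternal_plasma, prof.times)),
        }

    return model
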