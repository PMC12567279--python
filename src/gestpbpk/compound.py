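"""Drug-specific parameters and the quantities derived from them.

Houses the compound record (physicochemistry, binding, absorption,
per-isoform intrinsic clearances, renal and placental clearances), the
closed-form fetal clearances (amniotic swallowing and fetal renal), the
mechanistic tissue-to-plasma partitioning for moderate-to-strong monoprotic
bases, the steady-state volume of distribution, and the microsome-to-whole-
liver intrinsic clearance scale-up.

Unit conventions used throughout the package: clearances L/h, volumes L,
concentrations ng/mL; microsomal intrinsic clearances enter in
µL/min/pmol of isoform and are converted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .physiology import ISOFORMS, PhysiologySnapshot

# intracellular, erythrocyte and plasma pH of the partitioning equations
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_ERYTHROCYTE = 7.22


def ul_per_min_to_l_per_h(x: float) -> float:
    """Convert a clearance in µL/min to L/h (the single unit conversion hub)."""
    return x * 60.0 / 1.0e6


@dataclass(frozen=True)
class CompoundRecord:
    """All drug-specific model inputs for one compound."""

    name: str
    molecular_weight: float          # g/mol
    logp: float
    pka: float
    blood_to_plasma: float           # B/P
    fu_plasma: float
    f_absorbed: float                # fa
    k_absorption: float              # 1/h
    fu_gut: float
    q_gut: float                     # L/h
    kp_scalar: float
    clint_by_isoform: Mapping[str, float]  # µL/min/pmol
    cl_renal_adult: float            # L/h
    cl_pdm: float                    # L/h
    cl_pdf: float                    # L/h
    clint_gut_unbound: float = 0.0   # L/h, lumped gut first-pass CLu
    compound_type: str = "monoprotic_base"

    def __post_init__(self):
        for name in ("fu_plasma", "f_absorbed", "fu_gut"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {v}")
        for name in ("k_absorption", "cl_renal_adult", "cl_pdm", "cl_pdf",
                     "clint_gut_unbound", "kp_scalar", "q_gut"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if any(v < 0 for v in self.clint_by_isoform.values()):
            raise DomainError("intrinsic clearances must be non-negative")

    @property
    def fu_blood(self) -> float:
        """Fraction unbound referenced to whole-blood concentration."""
        return self.fu_plasma / self.blood_to_plasma

    def with_updates(self, **kwargs) -> "CompoundRecord":
        """Return a copy with selected parameters replaced."""
        if "clint_by_isoform" in kwargs:
            kwargs["clint_by_isoform"] = dict(kwargs["clint_by_isoform"])
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FetalParameters:
    """Fetal disposition inputs; the derived clearances are computed on build."""

    swallowed_volume: float = 750.0      # mL/day
    fetal_weight: float = 3.7            # kg
    fetal_gfr: float = 4.92              # mL/min
    adult_gfr: float = 121.0             # mL/min
    cl_renal_adult: float = 4.0          # L/h
    fetal_binding_protein_ratio: float = 0.37
    cl_swallowing: float = field(init=False)   # L/h per kg fetal weight
    cl_renal_fetal: float = field(init=False)  # L/h per kg fetal weight

    def __post_init__(self):
        object.__setattr__(
            self, "cl_swallowing",
            fetal_swallowing_clearance(self.swallowed_volume, self.fetal_weight),
        )
        object.__setattr__(
            self, "cl_renal_fetal",
            fetal_renal_clearance(
                self.cl_renal_adult, self.fetal_gfr, self.adult_gfr, self.fetal_weight
            ),
        )


def fetal_swallowing_clearance(swallowed_volume: float, fetal_weight: float) -> float:
    """Clearance of amniotic fluid by fetal swallowing, L/h per kg fetal weight.

    ``swallowed_volume`` is in mL/day; the term value of 750 mL/day with a
    3.7 kg fetus gives 0.00844 L/h/kg.
    """
    if fetal_weight <= 0:
        raise DomainError("fetal weight must be positive")
    if swallowed_volume < 0:
        raise DomainError("swallowed volume must be non-negative")
    return swallowed_volume / 24.0 / 1000.0 / fetal_weight


def fetal_renal_clearance(
    cl_renal_adult: float, fetal_gfr: float, adult_gfr: float, fetal_weight: float
) -> float:
    """Fetal renal clearance, L/h per kg fetal weight.

    Scales the adult renal clearance by the fetal:adult GFR ratio and
    normalizes by fetal weight: CL_R,adult * GFR_fetal / (W_fetal * GFR_adult).
    """
    if min(cl_renal_adult, fetal_gfr, adult_gfr, fetal_weight) <= 0:
        raise DomainError("all fetal renal clearance inputs must be positive")
    return cl_renal_adult * fetal_gfr / (fetal_weight * adult_gfr)


def load_tissue_composition() -> pd.DataFrame:
    """Published tissue-composition constants for the partitioning equations."""
    with resources.files("gestpbpk.data").joinpath("tissue_composition.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("tissue")


def load_compound(path=None) -> tuple[CompoundRecord, FetalParameters]:
    """Load a compound parameter file (defaults to the escitalopram fixture)."""
    if path is None:
        src = resources.files("gestpbpk.data").joinpath("escitalopram.yaml").open()
    else:
        src = open(path)
    with src as fh:
        raw = yaml.safe_load(fh)
    fet = raw.pop("fetal", {})
    compound = CompoundRecord(
        name=raw["name"],
        molecular_weight=raw["molecular_weight"],
        logp=raw["logp"],
        pka=raw["pka"],
        blood_to_plasma=raw["blood_to_plasma"],
        fu_plasma=raw["fu_plasma"],
        f_absorbed=raw["f_absorbed"],
        k_absorption=raw["k_absorption"],
        fu_gut=raw["fu_gut"],
        q_gut=raw["q_gut"],
        kp_scalar=raw["kp_scalar"],
        clint_by_isoform=dict(raw["clint_by_isoform"]),
        cl_renal_adult=raw["cl_renal_adult"],
        cl_pdm=raw["cl_pdm"],
        cl_pdf=raw["cl_pdf"],
        clint_gut_unbound=raw.get("clint_gut_unbound", 0.0),
        compound_type=raw.get("compound_type", "monoprotic_base"),
    )
    fetal = FetalParameters(
        swallowed_volume=fet.get("swallowed_volume_ml_per_day", 750.0),
        fetal_weight=fet.get("fetal_weight_kg", 3.7),
        fetal_gfr=fet.get("fetal_gfr_ml_per_min", 4.92),
        adult_gfr=fet.get("adult_gfr_ml_per_min", 121.0),
        cl_renal_adult=compound.cl_renal_adult,
        fetal_binding_protein_ratio=fet.get("fetal_binding_protein_ratio", 0.37),
    )
    return compound, fetal


def erythrocyte_partition(compound: CompoundRecord, hematocrit: float,
                          fu_plasma: float | None = None) -> float:
    """Unbound erythrocyte:plasma partition (Kpu,BC) from the B/P ratio."""
    fu = compound.fu_plasma if fu_plasma is None else fu_plasma
    return (compound.blood_to_plasma - (1.0 - hematocrit)) / (hematocrit * fu)


def predict_kp(
    compound: CompoundRecord,
    tissue_composition: pd.DataFrame | None = None,
    *,
    fu_plasma: float | None = None,
    hematocrit: float = 0.40,
) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients for a moderate-to-strong base.

    Implements the mechanistic equations in which ionic association with
    tissue acidic phospholipids dominates; the association constant is
    back-calculated from erythrocyte binding (via B/P, hematocrit and fu).
    Each Kp is multiplied by the compound's ``kp_scalar``. ``fu_plasma`` may
    be supplied to evaluate partitioning at a gestationally altered binding
    level (the default is the compound's baseline fu).
    """
    if compound.pka <= 7 or compound.compound_type != "monoprotic_base":
        raise DomainError("partitioning equations apply to monoprotic bases with pKa > 7")
    comp = load_tissue_composition() if tissue_composition is None else tissue_composition
    fu = compound.fu_plasma if fu_plasma is None else fu_plasma

    p = 10.0 ** compound.logp
    x = 10.0 ** (compound.pka - PH_PLASMA)
    y = 10.0 ** (compound.pka - PH_INTRACELLULAR)
    z = 10.0 ** (compound.pka - PH_ERYTHROCYTE)

    try:
        bc = comp.loc["blood_cells"]
    except KeyError:
        raise ConfigError("composition table must contain a blood_cells row")
    kpu_bc = erythrocyte_partition(compound, hematocrit, fu)
    pterm_bc = (p * bc["f_nl"] + (0.3 * p + 0.7) * bc["f_np"]) / (1.0 + x)
    ka_ap = (
        (kpu_bc - (1.0 + z) / (1.0 + x) * bc["f_iw"] - pterm_bc)
        * (1.0 + x) / (bc["ap_mg_per_g"] * z)
    )

    logd_adipose = 1.115 * compound.logp - 1.35  # vegetable-oil:water for adipose
    kps: dict[str, float] = {}
    for tissue, row in comp.drop(index="blood_cells").iterrows():
        pt = 10.0 ** logd_adipose if tissue == "adipose" else p
        pterm = (pt * row["f_nl"] + (0.3 * pt + 0.7) * row["f_np"]) / (1.0 + x)
        kpu = (
            row["f_ew"]
            + (1.0 + y) / (1.0 + x) * row["f_iw"]
            + ka_ap * row["ap_mg_per_g"] * y / (1.0 + x)
            + pterm
        )
        kps[tissue] = kpu * fu * compound.kp_scalar
    return kps


def predict_vss(
    kps: Mapping[str, float],
    physiology: PhysiologySnapshot,
    compound: CompoundRecord,
) -> float:
    """Steady-state volume of distribution, L per kg body weight.

    Vss = (V_plasma + Kp_BC*fu*V_ery + sum_t Kp_t*V_t) / BW, referenced to
    plasma concentration.
    """
    tissues = [t for t in physiology.tissue_volumes if t != "plasma"]
    missing = [t for t in tissues if t not in kps]
    if missing:
        raise ConfigError(f"partition coefficients missing for tissues: {missing}")
    v = physiology.plasma_volume
    v += (
        erythrocyte_partition(compound, physiology.hematocrit)
        * compound.fu_plasma
        * physiology.erythrocyte_volume
    )
    v += sum(kps[t] * physiology.tissue_volumes[t] for t in tissues)
    return v / physiology.body_weight


def whole_liver_intrinsic_clearance(
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    phenotype_multipliers: Mapping[str, float] | None = None,
) -> float:
    """Whole-organ unbound hepatic intrinsic clearance, L/h.

    Scale-up: sum over isoforms of CLint (µL/min/pmol) x abundance (pmol/mg)
    x MPPGL (mg/g) x liver weight (g) x gestational activity multiplier x
    phenotype multiplier, converted to L/h. Additive across isoforms and
    linear in every factor.
    """
    phenotype_multipliers = dict(phenotype_multipliers or {})
    if any(m < 0 for m in phenotype_multipliers.values()):
        raise DomainError("phenotype multipliers must be non-negative")
    total_ul_min = 0.0
    for iso in ISOFORMS:
        clint = compound.clint_by_isoform.get(iso, 0.0)
        if clint == 0.0:
            continue
        if iso not in physiology.enzyme_abundance:
            raise ConfigError(f"no abundance for isoform {iso}")
        total_ul_min += (
            clint
            * physiology.enzyme_abundance[iso]
            * physiology.mppgl
            * physiology.liver_weight
            * physiology.enzyme_activity_multiplier.get(iso, 1.0)
            * phenotype_multipliers.get(iso, 1.0)
        )
    return ul_per_min_to_l_per_h(total_ul_min)
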