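"""Maternal and fetal physiology as continuous functions of gestational age.

Every pregnancy-adapted parameter follows the same gestational scaling law

    value(GW) = value(0) * (1 + b1*GW + b2*GW^2 + b3*GW^3 + b4*GW^4)

with per-parameter polynomial coefficients shipped as a versioned fixture
(``data/pregnancy_coefficients.csv``). Hepatic CYP2D6 and CYP3A4 activities
rise with gestation; CYP2C19 activity is held constant (all coefficients
zero). The fetoplacental fields (fetal weight, amniotic fluid volume) are
populated from gestational week 15 onward, the week the permeability-limited
placenta becomes active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import ConfigError, DomainError

ISOFORMS = ("CYP2C19", "CYP2D6", "CYP3A4")

#: gestational week from which the fetoplacental unit is simulated
FETAL_ONSET_WEEK = 15.0

#: reference enzyme abundances, pmol per mg microsomal protein
DEFAULT_ABUNDANCE = {"CYP2C19": 14.0, "CYP2D6": 8.0, "CYP3A4": 137.0}
DEFAULT_MPPGL = 40.0       # mg microsomal protein per g liver
DEFAULT_LIVER_WEIGHT = 1500.0  # g
DEFAULT_BODY_WEIGHT = 60.0     # kg, reference nonpregnant female

#: mean fetal weight (kg) and daily swallowed amniotic volume (mL) at term
TERM_FETAL_WEIGHT = 3.7
TERM_AMNIOTIC_VOLUME_ML = 750.0


@dataclass(frozen=True)
class PregnancyScalingCoefficients:
    """Polynomial gestational-age scaling of one physiological parameter.

    ``baseline_value`` is the quantity at gestational week 0 in its native
    units; ``b1``..``b4`` multiply successive powers of gestational week.
    """

    baseline_value: float
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0
    units: str = ""


def scale_parameter(coeffs: PregnancyScalingCoefficients, gw: float) -> float:
    """Evaluate the gestational scaling polynomial at week ``gw``.

    Returns ``baseline * (1 + b1*gw + b2*gw^2 + b3*gw^3 + b4*gw^4)``;
    at gw = 0 this is the baseline exactly, and all-zero coefficients give
    a constant trajectory.
    """
    if gw < 0:
        raise DomainError(f"gestational week must be non-negative, got {gw}")
    poly = 1.0 + coeffs.b1 * gw + coeffs.b2 * gw**2 + coeffs.b3 * gw**3 + coeffs.b4 * gw**4
    return coeffs.baseline_value * poly


def scale_fraction_unbound(fu_baseline: float, protein_ratio: float) -> float:
    """Rescale a plasma fraction unbound for a changed binding-protein level.

    Assumes linear (non-saturable) binding to a single protein, so the
    bound:unbound ratio scales with the protein concentration:

        fu = 1 / (1 + ((1 - fu0) / fu0) * protein_ratio)

    ``protein_ratio`` is the binding-protein concentration as a fraction of
    its gestational-week-0 value; a ratio of 1 returns ``fu_baseline``.
    """
    if not 0.0 < fu_baseline <= 1.0:
        raise DomainError(f"fu_baseline must be in (0, 1], got {fu_baseline}")
    if protein_ratio <= 0:
        raise DomainError(f"protein_ratio must be positive, got {protein_ratio}")
    return 1.0 / (1.0 + (1.0 - fu_baseline) / fu_baseline * protein_ratio)


def fetal_weight(gw: float) -> float:
    """Fetal weight (kg), a smooth monotone curve anchored to 3.7 kg at term."""
    if gw < 0:
        raise DomainError("gestational week must be non-negative")
    return TERM_FETAL_WEIGHT * (gw / 40.0) ** 3


def amniotic_volume_ml(gw: float) -> float:
    """Amniotic fluid volume (mL), anchored to 750 mL at term."""
    if gw < 0:
        raise DomainError("gestational week must be non-negative")
    return TERM_AMNIOTIC_VOLUME_ML * (gw / 40.0) ** 1.5


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("gestpbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_baseline_physiology() -> pd.DataFrame:
    """Baseline (GW 0) tissue volumes and blood flows as a DataFrame."""
    return _read_fixture("baseline_physiology.csv").set_index("tissue")


def load_pregnancy_coefficients() -> dict[str, PregnancyScalingCoefficients]:
    """Gestational scaling coefficient sets keyed by parameter name."""
    df = _read_fixture("pregnancy_coefficients.csv")
    return {
        row["name"]: PregnancyScalingCoefficients(
            baseline_value=row["baseline"],
            b1=row["b1"], b2=row["b2"], b3=row["b3"], b4=row["b4"],
            units=row["units"],
        )
        for _, row in df.iterrows()
    }


@dataclass
class PhysiologySnapshot:
    """All physiological inputs the PBPK system needs at one gestational age.

    Volumes are L, flows L/h, GFR mL/min, enzyme abundances pmol/mg
    microsomal protein. ``binding_protein_conc_ratio`` is the drug-binding
    protein concentration relative to gestational week 0 and feeds
    :func:`scale_fraction_unbound`. Fetal fields are ``None`` before week 15.
    """

    gestational_week: float
    tissue_volumes: dict[str, float]
    tissue_flows: dict[str, float]
    cardiac_output: float
    hepatic_blood_flow: float
    gfr: float
    hematocrit: float
    binding_protein_conc_ratio: float
    liver_weight: float
    mppgl: float
    enzyme_abundance: dict[str, float]
    enzyme_activity_multiplier: dict[str, float]
    body_weight: float = DEFAULT_BODY_WEIGHT
    fetal_weight: float | None = None
    amniotic_volume: float | None = None
    _coefficients: dict[str, PregnancyScalingCoefficients] = field(
        default=None, repr=False, compare=False
    )

    @property
    def plasma_volume(self) -> float:
        return self.tissue_volumes["plasma"]

    @property
    def blood_volume(self) -> float:
        """Total blood volume implied by plasma volume and hematocrit."""
        return self.plasma_volume / (1.0 - self.hematocrit)

    @property
    def erythrocyte_volume(self) -> float:
        return self.blood_volume - self.plasma_volume


_OVERRIDABLE_SCALARS = {
    "hematocrit", "mppgl", "liver_weight", "body_weight",
    "cardiac_output", "gfr", "plasma_volume", "binding_protein",
}


def build_physiology(
    gw: float,
    overrides: Mapping[str, float] | None = None,
) -> PhysiologySnapshot:
    """Assemble a complete physiological snapshot at gestational week ``gw``.

    Pregnancy trajectories (cardiac output, plasma volume, GFR, binding
    protein, hematocrit, enzyme activities) are evaluated through the
    polynomial scaling law; tissue blood flows are rescaled proportionally
    with cardiac output so their sum tracks it. ``overrides`` may replace the
    baseline value of any trajectory row or scalar listed in the fixture;
    unknown keys raise :class:`ConfigError`.
    """
    if gw < 0:
        raise DomainError(f"gestational week must be non-negative, got {gw}")
    if gw > 40:
        raise DomainError(f"gestational week must be <= 40, got {gw}")

    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDABLE_SCALARS
    if unknown:
        raise ConfigError(f"unknown physiology override(s): {sorted(unknown)}")

    coeffs = load_pregnancy_coefficients()
    base = load_baseline_physiology()

    def traj(name: str, override_key: str | None = None) -> float:
        c = coeffs[name]
        key = override_key or name
        if key in overrides:
            c = PregnancyScalingCoefficients(
                overrides[key], c.b1, c.b2, c.b3, c.b4, c.units
            )
        return scale_parameter(c, gw)

    co = traj("cardiac_output")
    # flow fixture corresponds to the fixture baseline cardiac output
    co_ratio = co / coeffs["cardiac_output"].baseline_value

    volumes = dict(base["volume_l"])
    volumes["plasma"] = traj("plasma_volume")
    flows = {
        t: q * co_ratio
        for t, q in base["flow_l_per_h"].dropna().items()
    }
    hepatic_flow = flows["liver"] + flows["gut"] + flows["spleen"]

    hct = traj("hematocrit")
    if not 0.0 < hct < 1.0:
        raise DomainError(f"hematocrit out of (0,1): {hct}")
    if "hematocrit" in overrides and not 0.0 < overrides["hematocrit"] < 1.0:
        raise DomainError("hematocrit override out of (0,1)")

    activity = {
        "CYP2C19": scale_parameter(coeffs["cyp2c19_activity"], gw),
        "CYP2D6": scale_parameter(coeffs["cyp2d6_activity"], gw),
        "CYP3A4": scale_parameter(coeffs["cyp3a4_activity"], gw),
    }

    snapshot = PhysiologySnapshot(
        gestational_week=gw,
        tissue_volumes=volumes,
        tissue_flows=flows,
        cardiac_output=co,
        hepatic_blood_flow=hepatic_flow,
        gfr=traj("gfr"),
        hematocrit=hct,
        binding_protein_conc_ratio=traj("binding_protein"),
        liver_weight=overrides.get("liver_weight", DEFAULT_LIVER_WEIGHT),
        mppgl=overrides.get("mppgl", DEFAULT_MPPGL),
        enzyme_abundance=dict(DEFAULT_ABUNDANCE),
        enzyme_activity_multiplier=activity,
        body_weight=overrides.get("body_weight", DEFAULT_BODY_WEIGHT),
        fetal_weight=fetal_weight(gw) if gw >= FETAL_ONSET_WEEK else None,
        amniotic_volume=amniotic_volume_ml(gw) if gw >= FETAL_ONSET_WEEK else None,
        _coefficients=coeffs,
    )

    flow_sum = sum(flows.values())
    if not math.isclose(flow_sum, co, rel_tol=0.01):
        raise ConfigError(
            f"tissue flows ({flow_sum:.2f} L/h) do not sum to cardiac output ({co:.2f} L/h)"
        )
    return snapshot
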