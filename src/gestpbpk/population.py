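"""Virtual populations: parameter variability and CYP2C19 phenotype structure.

Individuals are sampled around the default compound record with
median-preserving log-normal variability (X = default * exp(sigma*Z) with
sigma = sqrt(ln(1 + CV^2))) on the per-isoform intrinsic clearances, the
absorption rate constant, the Kp scalar and the fraction unbound. CYP2C19
phenotype is assigned by population frequency and acts as a multiplier on
the CYP2C19 intrinsic clearance. Trial-design simulation mirrors the
repeated-trial convention: n_trials trials of n_subjects each, summarized
as the mean profile with 5th and 95th percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .compound import CompoundRecord, FetalParameters
from .errors import ConfigError
from .fetoplacental import simulate_pregnant_with_fetus
from .pbpk import ConcentrationProfile, DoseRegimen, SimulationSettings, simulate_individual
from .physiology import PhysiologySnapshot

#: default phenotype activity multipliers on CYP2C19 intrinsic clearance
DEFAULT_PHENOTYPE_MULTIPLIERS = {"UM": 1.5, "NM": 1.0, "IM": 0.45, "PM": 0.05}

#: Caucasian phenotype frequency fixture (PM ~2% anchored; remainder documented)
DEFAULT_PHENOTYPE_FREQUENCIES = {"PM": 0.02, "IM": 0.26, "NM": 0.60, "UM": 0.12}

#: default coefficients of variation for the perturbed parameters
DEFAULT_CV = {
    "clint_CYP2C19": 0.35,
    "clint_CYP2D6": 0.35,
    "clint_CYP3A4": 0.35,
    "k_absorption": 0.25,
    "kp_scalar": 0.20,
    "fu_plasma": 0.15,
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """One CYP2C19 phenotype class in a population."""

    phenotype: str            # UM / NM / IM / PM
    frequency: float
    activity_multiplier: float

    def __post_init__(self):
        if self.frequency < 0:
            raise ConfigError("phenotype frequency must be non-negative")
        if self.activity_multiplier < 0:
            raise ConfigError("activity multiplier must be non-negative")


def default_phenotypes(frequencies: Mapping[str, float] | None = None,
                       multipliers: Mapping[str, float] | None = None) -> list[PhenotypeSpec]:
    freqs = dict(frequencies or DEFAULT_PHENOTYPE_FREQUENCIES)
    mults = dict(DEFAULT_PHENOTYPE_MULTIPLIERS)
    mults.update(multipliers or {})
    total = sum(freqs.values())
    return [PhenotypeSpec(p, f / total, mults[p]) for p, f in freqs.items()]


@dataclass(frozen=True)
class PopulationSpec:
    """Trial design: n_trials x n_subjects_per_trial with parameter CVs."""

    n_subjects_per_trial: int = 10
    n_trials: int = 10
    gw: float = 0.0
    age_range: tuple[float, float] = (18.0, 45.0)
    cv_map: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CV))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_trial < 1 or self.n_trials < 1:
            raise ConfigError("trial counts must be >= 1")
        if any(cv < 0 for cv in self.cv_map.values()):
            raise ConfigError("coefficients of variation must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_subjects_per_trial * self.n_trials


@dataclass
class Individual:
    """One sampled virtual subject."""

    subject_id: int
    compound: CompoundRecord
    phenotype: str
    phenotype_multiplier: float


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(np.exp(sigma * rng.standard_normal()))


def sample_individuals(
    spec: PopulationSpec,
    compound: CompoundRecord,
    phenotypes: Sequence[PhenotypeSpec] | None = None,
) -> list[Individual]:
    """Draw the full population reproducibly from the spec's seed."""
    phenotypes = list(phenotypes) if phenotypes is not None else default_phenotypes()
    total = sum(p.frequency for p in phenotypes)
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"phenotype frequencies must sum to 1, got {total}")
    rng = np.random.default_rng(spec.seed)
    cv = dict(spec.cv_map)
    freqs = np.array([p.frequency for p in phenotypes])

    individuals = []
    for sid in range(spec.n_total):
        ph = phenotypes[rng.choice(len(phenotypes), p=freqs)]
        clint = {
            iso: v * _lognormal_factor(rng, cv.get(f"clint_{iso}", 0.0))
            for iso, v in compound.clint_by_isoform.items()
        }
        indiv = compound.with_updates(
            clint_by_isoform=clint,
            k_absorption=compound.k_absorption * _lognormal_factor(rng, cv.get("k_absorption", 0.0)),
            kp_scalar=compound.kp_scalar * _lognormal_factor(rng, cv.get("kp_scalar", 0.0)),
            fu_plasma=min(1.0, compound.fu_plasma * _lognormal_factor(rng, cv.get("fu_plasma", 0.0))),
        )
        individuals.append(Individual(sid, indiv, ph.phenotype, ph.activity_multiplier))
    return individuals


@dataclass
class PopulationSummary:
    """Mean and 5th/95th percentile profiles plus per-subject PK summaries."""

    times: np.ndarray
    mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    subject_auc: np.ndarray       # ng*h/mL over the final dosing interval
    subject_cmax: np.ndarray
    subject_cmin: np.ndarray
    phenotypes: list[str]
    mean_fetal: np.ndarray | None = None

    @property
    def mean_profile(self) -> ConcentrationProfile:
        return ConcentrationProfile(
            times=self.times, maternal_plasma=self.mean,
            fetal_plasma=self.mean_fetal,
            metadata={"kind": "population_mean"},
        )


def run_population(
    spec: PopulationSpec,
    compound: CompoundRecord,
    regimen: DoseRegimen,
    gw: float | None = None,
    physiology: PhysiologySnapshot | None = None,
    phenotypes: Sequence[PhenotypeSpec] | None = None,
    settings: SimulationSettings | None = None,
    fetal_params: FetalParameters | None = None,
) -> PopulationSummary:
    """Simulate every sampled individual and aggregate percentile bands.

    ``physiology`` may be passed to reuse a snapshot; otherwise it is built
    at ``gw`` (or ``spec.gw``). When ``fetal_params`` is given the
    fetoplacental unit is simulated and the mean fetal profile is included.
    """
    from .physiology import build_physiology

    if physiology is None:
        physiology = build_physiology(spec.gw if gw is None else gw)
    settings = settings or SimulationSettings(grid_dt=0.25)
    individuals = sample_individuals(spec, compound, phenotypes)

    profiles = []
    fetal_profiles = []
    auc, cmax, cmin = [], [], []
    tau = regimen.interval
    times = None
    for ind in individuals:
        mult = {"CYP2C19": ind.phenotype_multiplier}
        try:
            if fetal_params is not None:
                prof = simulate_pregnant_with_fetus(
                    ind.compound, physiology, regimen, settings,
                    fetal_params, mult,
                )
                fetal_profiles.append(prof.fetal_plasma)
            else:
                prof = simulate_individual(ind.compound, physiology, regimen, settings, mult)
        except Exception as exc:  # annotate propagated solver errors
            raise type(exc)(f"subject {ind.subject_id}: {exc}") from exc
        times = prof.times
        profiles.append(prof.maternal_plasma)
        mask = times >= times[-1] - tau
        c = prof.maternal_plasma[mask]
        auc.append(np.trapezoid(c, times[mask]))
        cmax.append(c.max())
        cmin.append(c.min())

    arr = np.array(profiles)
    return PopulationSummary(
        times=times,
        mean=arr.mean(axis=0),
        p5=np.percentile(arr, 5, axis=0),
        p95=np.percentile(arr, 95, axis=0),
        subject_auc=np.array(auc),
        subject_cmax=np.array(cmax),
        subject_cmin=np.array(cmin),
        phenotypes=[ind.phenotype for ind in individuals],
        mean_fetal=np.array(fetal_profiles).mean(axis=0) if fetal_profiles else None,
    )
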