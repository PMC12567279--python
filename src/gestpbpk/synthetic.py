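"""Synthetic "observed" datasets with the error structure the pipeline assumes.

No clinical concentration data are redistributed with this package; the
verification and estimation stages are exercised on synthetic observations
generated from the model itself: per subject, individual parameters are
drawn from the population model, the profile is simulated, sampled at
sparse clinical-style times and multiplied by a proportional log-normal
residual. The residual is median-preserving (sigma = sqrt(ln(1 + CV^2))),
matching the 1/obs^2 weighting assumption of the estimation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compound import CompoundRecord, FetalParameters
from .errors import UsageError
from .fetoplacental import simulate_pregnant_with_fetus
from .pbpk import DoseRegimen, SimulationSettings, simulate_individual
from .physiology import PhysiologySnapshot
from .population import DEFAULT_CV, PopulationSpec, PhenotypeSpec, sample_individuals

#: sparse steady-state sampling grid (h after the final dose)
DEFAULT_SAMPLING_TIMES = (1.0, 2.0, 4.0, 6.0, 12.0, 24.0)

#: richer grid used for parameter-estimation datasets
RICH_SAMPLING_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0)


@dataclass
class ObservedDataset:
    """Observed concentration records plus generating provenance."""

    frame: pd.DataFrame   # subject_id, gw, dose_mg, time_h, conc_ng_per_ml, site
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.frame)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"# {k}: {v}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservedDataset":
        meta, lines = {}, []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                else:
                    lines.append(line)
        import io
        return cls(frame=pd.read_csv(io.StringIO("".join(lines))), provenance=meta)


def generate_observed(
    compound: CompoundRecord,
    physiology: PhysiologySnapshot,
    regimen: DoseRegimen,
    sampling_times=DEFAULT_SAMPLING_TIMES,
    noise_cv: float = 0.15,
    n_subjects: int = 10,
    seed: int = 0,
    population_cv: dict | None = None,
    phenotypes: list[PhenotypeSpec] | None = None,
    fetal_params: FetalParameters | None = None,
    settings: SimulationSettings | None = None,
) -> ObservedDataset:
    """Generate a synthetic sparse-sampled dataset around model predictions.

    Sampling times are hours after the final dose; a cord+maternal pair at
    delivery is produced by passing ``fetal_params`` (the last sampling time
    then also yields a ``cord`` record). ``population_cv`` overrides the
    between-subject CV map (use an empty dict for residual error only).
    """
    if noise_cv < 0:
        raise UsageError("noise_cv must be non-negative")
    times = np.asarray(sampling_times, dtype=float)
    if np.any(times < 0) or np.any(times > regimen.interval):
        raise UsageError("sampling times must lie within the final dosing interval")
    settings = settings or SimulationSettings(grid_dt=0.25)

    cv = dict(population_cv) if population_cv is not None else dict(DEFAULT_CV)
    spec = PopulationSpec(
        n_subjects_per_trial=n_subjects, n_trials=1, gw=physiology.gestational_week,
        cv_map=cv, seed=seed,
    )
    phenos = phenotypes or [PhenotypeSpec("NM", 1.0, 1.0)]
    individuals = sample_individuals(spec, compound, phenos)
    rng = np.random.default_rng(seed + 1)
    sigma = np.sqrt(np.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    t_abs = (regimen.n_doses - 1) * regimen.interval + times
    records = []
    for ind in individuals:
        mult = {"CYP2C19": ind.phenotype_multiplier}
        if fetal_params is not None:
            prof = simulate_pregnant_with_fetus(
                ind.compound, physiology, regimen, settings, fetal_params, mult
            )
        else:
            prof = simulate_individual(ind.compound, physiology, regimen, settings, mult)
        pred_m = np.interp(t_abs, prof.times, prof.maternal_plasma)
        noise = np.exp(sigma * rng.standard_normal(len(t_abs))) if sigma else np.ones(len(t_abs))
        for t, c in zip(times, pred_m * noise):
            records.append({
                "subject_id": ind.subject_id, "gw": physiology.gestational_week,
                "dose_mg": regimen.dose, "time_h": t, "conc_ng_per_ml": c,
                "site": "maternal",
            })
        if fetal_params is not None:
            c_f = np.interp(t_abs[-1], prof.times, prof.fetal_plasma)
            f_noise = float(np.exp(sigma * rng.standard_normal())) if sigma else 1.0
            records.append({
                "subject_id": ind.subject_id, "gw": physiology.gestational_week,
                "dose_mg": regimen.dose, "time_h": times[-1],
                "conc_ng_per_ml": c_f * f_noise, "site": "cord",
            })

    return ObservedDataset(
        frame=pd.DataFrame.from_records(records),
        provenance={
            "seed": seed, "noise_cv": noise_cv, "n_subjects": n_subjects,
            "gw": physiology.gestational_week, "dose_mg": regimen.dose,
            "truth_k_absorption": compound.k_absorption,
            "truth_q_gut": compound.q_gut,
            "truth_kp_scalar": compound.kp_scalar,
        },
    )
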