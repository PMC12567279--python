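"""Therapeutic-window dose assessment across phenotypes and trimesters.

The reference therapeutic range for this drug is a steady-state trough of
15–80 ng/mL with a 160 ng/mL laboratory alert level; a steady-state average
concentration of >= 17 ng/mL is the threshold associated with adequate
serotonin-transporter occupancy. Regimens are classified per
(dose, gestational week, phenotype) cell on the population mean profile:

* ``subtherapeutic`` — trough below the lower bound,
* ``within``        — trough >= lower bound and peak <= upper bound,
* ``above``         — peak above the upper bound,
* ``alert``         — peak at or above the alert level.

Troughs within 20% below the lower bound are additionally flagged ``near``
(reported separately, never merged into ``within``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .compound import CompoundRecord
from .errors import DomainError
from .evaluation import PKSummary, compute_pk_metrics
from .pbpk import DoseRegimen, SimulationSettings
from .physiology import build_physiology
from .population import (
    DEFAULT_PHENOTYPE_MULTIPLIERS,
    PhenotypeSpec,
    PopulationSpec,
    run_population,
)

#: gestational weeks representing the three trimesters in dose scans
TRIMESTER_WEEKS = (7.0, 21.0, 35.0)


@dataclass(frozen=True)
class TherapeuticWindow:
    trough_lower: float = 15.0    # ng/mL
    trough_upper: float = 80.0    # ng/mL
    alert_level: float = 160.0    # ng/mL
    cavg_threshold: float = 17.0  # ng/mL

    def __post_init__(self):
        if not self.trough_lower < self.trough_upper < self.alert_level:
            raise DomainError("window must satisfy lower < upper < alert")

    def classify(self, metrics: PKSummary) -> str:
        if metrics.c_max_ss >= self.alert_level:
            return "alert"
        if metrics.c_max_ss > self.trough_upper:
            return "above"
        if metrics.c_min_ss < self.trough_lower:
            return "subtherapeutic"
        return "within"

    def near_lower(self, metrics: PKSummary) -> bool:
        """Trough within 20% below the lower bound."""
        return 0.8 * self.trough_lower <= metrics.c_min_ss < self.trough_lower

    def meets_cavg(self, metrics: PKSummary) -> bool:
        return metrics.c_avg_ss >= self.cavg_threshold


@dataclass
class DoseAssessment:
    """Per-cell steady-state metrics and classification."""

    table: pd.DataFrame   # dose_mg, gw, phenotype, cmin_ss, cavg_ss, cmax_ss,
                          # classification, near_lower, cavg_flag (+ p5 trough)

    def cell(self, dose: float, gw: float, phenotype: str) -> pd.Series:
        t = self.table
        row = t[(t.dose_mg == dose) & (t.gw == gw) & (t.phenotype == phenotype)]
        if len(row) != 1:
            raise KeyError((dose, gw, phenotype))
        return row.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def assess_regimen(
    compound: CompoundRecord,
    doses: Sequence[float] = (10.0, 20.0),
    gws: Sequence[float] = TRIMESTER_WEEKS,
    phenotype_multipliers: Mapping[str, float] | None = None,
    window: TherapeuticWindow | None = None,
    population: PopulationSpec | None = None,
    settings: SimulationSettings | None = None,
    interval: float = 24.0,
    n_days: int = 10,
) -> DoseAssessment:
    """Evaluate once-daily regimens against the therapeutic window.

    Each phenotype is simulated as a pure population (every subject carries
    that phenotype's CYP2C19 activity multiplier) with the population spec's
    trial design; classification uses the population mean profile, and the
    5th-percentile subject's trough is reported alongside.
    """
    window = window or TherapeuticWindow()
    multipliers = dict(phenotype_multipliers or DEFAULT_PHENOTYPE_MULTIPLIERS)
    population = population or PopulationSpec(n_subjects_per_trial=20, n_trials=20)
    settings = settings or SimulationSettings(grid_dt=0.25)

    rows = []
    for gw in gws:
        physiology = build_physiology(gw)
        for phenotype, mult in multipliers.items():
            pure = [PhenotypeSpec(phenotype, 1.0, mult)]
            for dose in doses:
                regimen = DoseRegimen(dose=dose, interval=interval, n_doses=n_days)
                summary = run_population(
                    population, compound, regimen,
                    physiology=physiology, phenotypes=pure, settings=settings,
                )
                metrics = compute_pk_metrics(summary.mean_profile, interval)
                rows.append({
                    "dose_mg": dose,
                    "gw": gw,
                    "phenotype": phenotype,
                    "cmin_ss": metrics.c_min_ss,
                    "cavg_ss": metrics.c_avg_ss,
                    "cmax_ss": metrics.c_max_ss,
                    "classification": window.classify(metrics),
                    "near_lower": window.near_lower(metrics),
                    "cavg_flag": window.meets_cavg(metrics),
                    "p5_subject_cmin": float(pd.Series(summary.subject_cmin).quantile(0.05)),
                    "mean_subject_auc": float(summary.subject_auc.mean()),
                })
    return DoseAssessment(table=pd.DataFrame(rows))
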