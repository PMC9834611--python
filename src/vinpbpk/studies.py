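"""Ready-made study configurations: species, drug scenario, dose, duration.

These bundle the dosing designs the model is validated against: 2 mg/kg IV
bolus in wild-type and Mdr1a/b(-/-) mice observed over 6 h, a 2.5 mg/m2
canine bolus observed over 24 h, and weight-matched human bolus studies
(0.23 mg/kg at 43 kg; 0.2 mg/kg at 59 kg) evaluated over 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import physiology
from .pbpk_core import DrugParameters, vinblastine_dog_human, vinblastine_mouse
from .physiology import SpeciesPhysiology
from .simulate import DoseEvent, apply_scenario, dose_mg_from_bsa

__all__ = ["Study", "mouse_wild_type", "mouse_knockout", "dog_trial",
           "human_study_1", "human_study_3", "human_study"]


#: Observation schedules (h). Simulated NCA quantities reported for a study
#: are evaluated at these times, like-for-like with the observed analysis
#: (the first sample of an IV-bolus study is minutes post-dose, so the
#: seconds-scale central distribution spike is not part of a measured AUC).
MOUSE_TIMES = (0.083, 0.5, 1.0, 2.0, 4.0, 6.0)
DOG_TIMES = (0.0833, 0.1667, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0,
             12.0, 24.0)
HUMAN_TIMES = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class Study:
    name: str
    physiology: SpeciesPhysiology
    drug: DrugParameters
    dose: DoseEvent
    t_end: float  # h, simulation/AUC horizon
    schedule: tuple[float, ...] = ()  # observation times for reported NCA


def mouse_wild_type(body_weight: float | None = None) -> Study:
    return Study(
        name="mouse_wild_type",
        physiology=physiology.mouse(body_weight),
        drug=vinblastine_mouse(),
        dose=DoseEvent(dose_per_kg=2.0),
        t_end=6.0,
        schedule=MOUSE_TIMES,
    )


def mouse_knockout(body_weight: float | None = None) -> Study:
    return Study(
        name="mouse_knockout",
        physiology=physiology.mouse(body_weight),
        drug=apply_scenario(vinblastine_mouse(), "mdr1a1b_knockout"),
        dose=DoseEvent(dose_per_kg=2.0),
        t_end=6.0,
        schedule=MOUSE_TIMES,
    )


def dog_trial(
    body_weight: float | None = None, dose_mg_per_m2: float = 2.5
) -> Study:
    phys = physiology.dog(body_weight)
    mg = dose_mg_from_bsa(dose_mg_per_m2, phys.body_weight)
    return Study(
        name="dog_trial",
        physiology=phys,
        drug=vinblastine_dog_human(),
        dose=DoseEvent(dose_per_kg=mg / phys.body_weight),
        t_end=24.0,
        schedule=DOG_TIMES,
    )


def human_study(
    dose_mg_per_kg: float, body_weight: float, name: str = "human_study",
    t_end: float = 24.0,
) -> Study:
    return Study(
        name=name,
        physiology=physiology.human(body_weight),
        drug=vinblastine_dog_human(),
        dose=DoseEvent(dose_per_kg=dose_mg_per_kg),
        t_end=t_end,
        schedule=HUMAN_TIMES,
    )


def human_study_1() -> Study:
    """Advanced-cancer cohort: 0.23 mg/kg at a 43 kg mean body weight."""
    return human_study(0.23, 43.0, name="human_study_1")


def human_study_3() -> Study:
    """Metastatic hypernephroma patient: 0.2 mg/kg at 59 kg."""
    return human_study(0.2, 59.0, name="human_study_3")


def study_nca(sim, compartment: str, schedule, min_points: int = 3):
    """NCA of a simulated compartment evaluated on a study schedule.

    AUC runs from the first to the last scheduled sample (lin-log
    trapezoidal); the terminal half-life regresses the last ``min_points``
    scheduled samples, mirroring how the observed profiles are analyzed.
    """
    from .nca import ConcentrationSeries, nca_summary

    times, conc = sim.at_times(compartment, schedule)
    series = ConcentrationSeries(times, conc, tissue=compartment)
    return nca_summary(series, float(times[0]), float(times[-1]),
                       min_points=min_points)
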