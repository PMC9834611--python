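"""Synthetic observation generators for testing calibration, NCA and metrics.

These emulate the structure of the experimental designs the model is meant to
be confronted with: destructive mouse sampling (each time point is a separate
group of animals), sparse longitudinal clinical sampling (dog, human), and
microsomal velocity-vs-substrate tables. Noise is multiplicative lognormal by
default; values below an LLOQ-like floor are censored but kept (flagged) so
downstream LLOQ policies can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nca import ConcentrationSeries
from .simulate import SimulationResult

__all__ = [
    "NoiseModel",
    "SamplingSchedule",
    "generate_observations",
    "generate_microsomal_dataset",
    "MOUSE_SCHEDULE",
    "DOG_SCHEDULE",
    "HUMAN_SCHEDULE",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: lognormal or proportional+additive, with an
    LLOQ-like censoring floor (nM)."""

    kind: str = "lognormal"
    cv: float = 0.15
    additive_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "proportional_additive"):
            raise ValueError("kind must be lognormal or proportional_additive")
        if self.cv < 0 or self.additive_floor < 0:
            raise ValueError("cv and additive_floor must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            return values.copy()
        if self.kind == "lognormal":
            sigma = np.sqrt(np.log1p(self.cv**2))
            return values * rng.lognormal(-0.5 * sigma**2, sigma, values.shape)
        noise = rng.standard_normal(values.shape)
        return np.maximum(values * (1.0 + self.cv * noise), 0.0)


@dataclass(frozen=True)
class SamplingSchedule:
    """Observation times (h) with a replication structure.

    ``destructive`` designs (mouse) draw independent subjects at every time;
    ``longitudinal`` designs (dog, human) follow one subject over time.
    """

    times: tuple[float, ...]
    replicates_per_time: int = 1
    design: str = "longitudinal"

    def __post_init__(self) -> None:
        if self.design not in ("destructive", "longitudinal"):
            raise ValueError("design must be destructive or longitudinal")
        if self.replicates_per_time < 1:
            raise ValueError("replicates_per_time must be >= 1")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


#: Destructive mouse design: 0.08-6 h, three animals per time point.
MOUSE_SCHEDULE = SamplingSchedule(
    times=(0.083, 0.5, 1.0, 2.0, 4.0, 6.0),
    replicates_per_time=3,
    design="destructive",
)

#: Canine clinical sampling: 5 min - 24 h post-bolus.
DOG_SCHEDULE = SamplingSchedule(
    times=(0.0833, 0.1667, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0,
           12.0, 24.0),
)

#: Sparse human clinical sampling.
HUMAN_SCHEDULE = SamplingSchedule(
    times=(0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0),
)


def generate_observations(
    truth: SimulationResult,
    schedule: SamplingSchedule,
    noise: NoiseModel,
    compartment: str = "blood",
) -> list[ConcentrationSeries]:
    """Sample noisy observations of one simulated compartment.

    Returns one ``ConcentrationSeries`` per replicate (destructive designs
    interleave replicates as separate series so each series reads like a
    pooled-animal profile). Values below ``noise.additive_floor`` are kept
    but flagged in ``censored``.
    """
    times = np.asarray(schedule.times)
    if times[0] < truth.times[0] or times[-1] > truth.times[-1]:
        raise ValueError("schedule times outside the simulated range")
    clean = np.interp(times, truth.times, truth.concentrations[compartment])
    rng = np.random.default_rng(noise.seed)
    series = []
    for rep in range(schedule.replicates_per_time):
        noisy = noise.apply(clean, rng)
        censored = noisy < noise.additive_floor
        series.append(
            ConcentrationSeries(
                times=times,
                concentrations=noisy,
                tissue=compartment,
                source=f"{schedule.design}_rep{rep}",
                censored=censored,
            )
        )
    return series


def generate_microsomal_dataset(
    vmax: float,
    km: float,
    substrate_grid: np.ndarray,
    noise: NoiseModel,
    replicates: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-vs-substrate table from Michaelis-Menten kinetics.

    ``replicates=2`` mirrors a technical-doublet design: the grid is repeated
    with independent noise draws. Returns (substrate, velocity) arrays.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    s = np.asarray(substrate_grid, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    rng = np.random.default_rng(noise.seed)
    s_all, v_all = [], []
    for _ in range(replicates):
        v = vmax * s / (km + s)
        v_all.append(noise.apply(v, rng))
        s_all.append(s)
    return np.concatenate(s_all), np.concatenate(v_all)
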