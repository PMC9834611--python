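"""Predictive-performance metrics: per-point prediction error and summaries.

For a measured/predicted concentration pair the percent prediction error is

    PE = 100 * (C_measured - C_predicted) / C_predicted

and a set of pairs is summarized by the median absolute prediction error
(MAPE%, precision), the median signed prediction error (MPE%, bias), and the
root-mean-square prediction error (RMSPE%, accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nca import ConcentrationSeries

__all__ = [
    "PairedObservation",
    "PerformanceReport",
    "prediction_error",
    "summarize_performance",
    "pair_observations",
]


@dataclass(frozen=True)
class PairedObservation:
    """One measured concentration matched to a model prediction."""

    c_measured: float
    c_predicted: float
    time: float = np.nan
    tissue: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.c_measured < 0:
            raise ValueError("measured concentration must be non-negative")
        if self.c_predicted <= 0:
            raise ValueError(
                f"predicted concentration must be positive at t={self.time} "
                f"({self.tissue})"
            )


@dataclass
class PerformanceReport:
    """MAPE/MPE/RMSPE summary of a set of prediction errors (all in %)."""

    pe_list: list[float]
    mape: float
    mpe: float
    rmspe: float
    n: int
    group: str = ""


def prediction_error(pair: PairedObservation) -> float:
    """Percent prediction error for one pair."""
    return 100.0 * (pair.c_measured - pair.c_predicted) / pair.c_predicted


def summarize_performance(
    pairs: list[PairedObservation], group: str = ""
) -> PerformanceReport:
    """Summarize prediction errors: MAPE% (median |PE|), MPE% (median PE),
    RMSPE% (sqrt of mean squared PE). Even-length medians are midpoints."""
    if not pairs:
        raise ValueError("summarize_performance requires at least one pair")
    pe = np.array([prediction_error(p) for p in pairs])
    return PerformanceReport(
        pe_list=[float(v) for v in pe],
        mape=float(np.median(np.abs(pe))),
        mpe=float(np.median(pe)),
        rmspe=float(np.sqrt(np.mean(pe**2))),
        n=pe.size,
        group=group,
    )


def pair_observations(
    observed: ConcentrationSeries,
    predicted: ConcentrationSeries,
    lloq: float | None = None,
    lloq_policy: str = "exclude",
    group: str = "",
) -> list[PairedObservation]:
    """Match observed points to the predicted curve at the observed times.

    The predicted curve is linearly interpolated at each observed time (the
    observed times must lie within the predicted range). Observations below
    ``lloq`` are excluded by default or replaced with ``lloq/2`` when
    ``lloq_policy="half"``.
    """
    if lloq_policy not in ("exclude", "half"):
        raise ValueError("lloq_policy must be 'exclude' or 'half'")
    t_obs = observed.times
    if t_obs[0] < predicted.times[0] or t_obs[-1] > predicted.times[-1]:
        raise ValueError("observed times outside the predicted time range")
    c_pred = np.interp(t_obs, predicted.times, predicted.concentrations)
    pairs: list[PairedObservation] = []
    for t, c_obs, c_hat in zip(t_obs, observed.concentrations, c_pred):
        if lloq is not None and c_obs < lloq:
            if lloq_policy == "exclude":
                continue
            c_obs = lloq / 2.0
        pairs.append(
            PairedObservation(
                c_measured=float(c_obs),
                c_predicted=float(c_hat),
                time=float(t),
                tissue=observed.tissue,
                group=group,
            )
        )
    return pairs
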