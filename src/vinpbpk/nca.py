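"""Noncompartmental analysis: linear-log trapezoidal AUC and terminal t1/2.

AUC uses the linear-log trapezoidal rule: a linear trapezoid where the curve
is flat, rising, or touches zero, and the log trapezoid
``(C1 - C2) * dt / ln(C1/C2)`` on declining segments with positive endpoints
(exact for mono-exponential decline). The terminal half-life comes from
ordinary least squares of ln(C) on t over a terminal window after the
observed maximum; a non-negative slope is reported as "terminal phase not
achieved" rather than an error, mirroring how rising profiles (e.g. knockout
brain) are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "NCAResult",
    "auc_linlog",
    "terminal_half_life",
    "nca_summary",
]


@dataclass
class ConcentrationSeries:
    """A concentration-time profile for one tissue/source."""

    times: np.ndarray
    concentrations: np.ndarray
    tissue: str = ""
    source: str = ""
    censored: np.ndarray | None = None  # True where below quantitation limit

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class NCAResult:
    """AUC over an interval and/or terminal-phase regression summary."""

    auc: float | None = None
    t_half: float | None = None
    interval: tuple[float, float] | None = None
    n_terminal_points: int = 0
    regression_r2: float | None = None
    reason: str | None = None  # why t_half is undefined, when it is
    tissue: str = ""
    source: str = ""


def _interp_boundary(times, conc, t):
    """Interpolate consistently with the integration rule: log-linear inside
    declining positive segments, linear otherwise (keeps AUC additive over
    adjacent intervals)."""
    i = int(np.searchsorted(times, t, side="right")) - 1
    if i < 0:
        return float(conc[0])
    if i >= times.size - 1:
        return float(conc[-1])
    c1, c2 = conc[i], conc[i + 1]
    if c1 > c2 > 0.0:
        w = (t - times[i]) / (times[i + 1] - times[i])
        return float(c1 * (c2 / c1) ** w)
    return float(np.interp(t, times, conc))


def _segment_auc(t1, t2, c1, c2) -> float:
    dt = t2 - t1
    if c1 > c2 > 0.0:
        return (c1 - c2) * dt / np.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def auc_linlog(series: ConcentrationSeries, t0: float, t1: float) -> float:
    """Linear-log trapezoidal AUC of ``series`` over [t0, t1] (nM*h).

    Endpoints falling between samples are obtained by linear interpolation;
    [t0, t1] must lie within the sampled range.
    """
    if t1 <= t0:
        raise ValueError("require t1 > t0")
    times, conc = series.times, series.concentrations
    if len(series) < 2:
        raise ValueError("AUC requires at least 2 points")
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(
            f"[{t0}, {t1}] outside sampled range [{times[0]}, {times[-1]}]"
        )
    inside = (times > t0) & (times < t1)
    ts = np.concatenate([[t0], times[inside], [t1]])
    cs = np.concatenate(
        [
            [_interp_boundary(times, conc, t0)],
            conc[inside],
            [_interp_boundary(times, conc, t1)],
        ]
    )
    total = 0.0
    for i in range(ts.size - 1):
        total += _segment_auc(ts[i], ts[i + 1], cs[i], cs[i + 1])
    return total


def terminal_half_life(
    series: ConcentrationSeries,
    min_points: int = 3,
    adaptive: bool = False,
) -> NCAResult:
    """Terminal half-life by log-linear regression after the observed maximum.

    The default window is the last ``min_points`` positive concentrations
    after (and excluding) the time of maximum; with ``adaptive=True`` every
    window size from ``min_points`` up to all post-maximum points is tried
    and the best-r2 window is kept. Returns an undefined result (with
    ``reason``) rather than raising when no terminal phase exists.
    """
    times, conc = series.times, series.concentrations
    result = NCAResult(tissue=series.tissue, source=series.source)
    if len(series) == 0:
        result.reason = "empty series"
        return result
    i_max = int(np.argmax(conc))
    mask = np.zeros(times.size, dtype=bool)
    mask[i_max + 1 :] = conc[i_max + 1 :] > 0.0
    t_post, c_post = times[mask], conc[mask]
    if t_post.size < min_points:
        result.reason = "terminal phase not achieved"
        return result

    def _fit(ts, cs):
        logc = np.log(cs)
        slope, intercept = np.polyfit(ts, logc, 1)
        pred = slope * ts + intercept
        ss_res = float(np.sum((logc - pred) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, r2

    windows = (
        range(min_points, t_post.size + 1) if adaptive else (min_points,)
    )
    best = None
    for k in windows:
        slope, r2 = _fit(t_post[-k:], c_post[-k:])
        if best is None or r2 > best[1]:
            best = (slope, r2, k)
    slope, r2, k = best
    result.n_terminal_points = k
    result.regression_r2 = r2
    if slope >= 0.0:
        result.reason = "terminal phase not achieved"
        return result
    result.t_half = float(np.log(2.0) / -slope)
    return result


def nca_summary(
    series: ConcentrationSeries,
    t0: float,
    t1: float,
    min_points: int = 3,
    adaptive: bool = False,
    extrapolate_to_inf: bool = False,
) -> NCAResult:
    """AUC over [t0, t1] plus terminal half-life in one result.

    With ``extrapolate_to_inf`` the AUC is extended by ``C_last / k_terminal``
    (only possible when a terminal phase exists).
    """
    result = terminal_half_life(series, min_points=min_points, adaptive=adaptive)
    result.auc = auc_linlog(series, t0, t1)
    result.interval = (t0, t1)
    if extrapolate_to_inf:
        if result.t_half is None:
            raise ValueError(
                "cannot extrapolate to infinity: " + (result.reason or "no t1/2")
            )
        k = np.log(2.0) / result.t_half
        c_last = series.concentrations[series.times <= t1][-1]
        result.auc += float(c_last) / k
        result.interval = (t0, np.inf)
    return result
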