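"""Parameter estimation against concentration-time data.

``fit_model`` wraps bounded nonlinear least squares around the simulator:
free parameters are addressed by dotted paths into the drug or physiology
objects (e.g. ``drug.PC.kidney``, ``drug.PSA_ml_per_h``), residuals pool all
tissues in the dataset, and model variants are compared by AIC/BIC computed
from the residual sum of squares. Residuals are taken on the log scale by
default because tissue concentrations span several orders of magnitude.

``fit_michaelis_menten`` estimates (Vmax, Km) from microsomal
velocity-vs-substrate data, and ``scale_vmax_ivive`` scales a microsomal Vmax
to the whole liver via mg microsomal protein per gram liver.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .nca import ConcentrationSeries
from .pbpk_core import DrugParameters
from .physiology import SpeciesPhysiology
from .simulate import DoseEvent, simulate_iv_bolus

__all__ = [
    "FreeParameter",
    "FitSpec",
    "FitResult",
    "MichaelisMentenFit",
    "fit_model",
    "fit_michaelis_menten",
    "scale_vmax_ivive",
    "information_criteria",
]

#: Observation tissue labels -> model compartment names.
TISSUE_ALIASES = {
    "serum": "blood",
    "plasma": "blood",
    "brain": "brain_tissue",
}


def _resolve_compartment(tissue: str) -> str:
    return TISSUE_ALIASES.get(tissue, tissue)


@dataclass(frozen=True)
class FreeParameter:
    """One optimized parameter: dotted path, bounds, and initial value."""

    path: str  # e.g. "drug.PC.kidney" or "phys.body_weight"
    lower: float
    upper: float
    initial: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.path}: require lower < upper bound")
        if not self.lower <= self.initial <= self.upper:
            raise ValueError(f"{self.path}: initial value outside bounds")


@dataclass
class FitSpec:
    """Free parameters, dataset, and loss configuration for ``fit_model``."""

    free_parameters: list[FreeParameter]
    dataset: list[ConcentrationSeries]
    log_scale: bool = True
    weighting: str = "none"  # none | inv_y | inv_y2  (linear scale only)

    def __post_init__(self) -> None:
        if self.weighting not in ("none", "inv_y", "inv_y2"):
            raise ValueError("weighting must be none, inv_y, or inv_y2")


@dataclass
class FitResult:
    estimates: dict[str, float]
    residual_norm: float  # sum of squared residuals at the optimum
    aic: float
    bic: float
    n_obs: int
    converged: bool
    message: str = ""


@dataclass
class MichaelisMentenFit:
    vmax: float  # velocity units of the input data (e.g. ng/ml/min)
    km: float  # substrate units of the input data
    residual_norm: float = 0.0
    identifiable: bool = True
    note: str = ""


def _get_by_path(phys: SpeciesPhysiology, drug: DrugParameters, path: str):
    root, *rest = path.split(".")
    obj = {"drug": drug, "phys": phys, "physiology": phys}[root]
    for key in rest:
        obj = obj[key] if isinstance(obj, dict) else getattr(obj, key)
    return obj


def _set_by_path(phys, drug, path: str, value: float) -> None:
    root, *rest = path.split(".")
    obj = {"drug": drug, "phys": phys, "physiology": phys}[root]
    for key in rest[:-1]:
        obj = obj[key] if isinstance(obj, dict) else getattr(obj, key)
    if isinstance(obj, dict):
        obj[rest[-1]] = value
    else:
        setattr(obj, rest[-1], value)


def information_criteria(ssr: float, n: int, k: int) -> tuple[float, float]:
    """AIC and BIC for a least-squares fit: ``n ln(SSR/n) + penalty``."""
    if n < 1 or ssr <= 0:
        raise ValueError("require n >= 1 and SSR > 0")
    base = n * np.log(ssr / n)
    return base + 2 * k, base + k * np.log(n)


def fit_model(
    spec: FitSpec,
    physiology: SpeciesPhysiology,
    drug: DrugParameters,
    dose: DoseEvent,
    t_end: float | None = None,
    floor: float = 1e-9,
    **sim_kwargs,
) -> FitResult:
    """Fit the free parameters to pooled concentration-time data.

    Each objective evaluation runs one forward simulation and interpolates
    the relevant compartment at every observed time. ``floor`` (nM) guards
    the log transform against zero concentrations.
    """
    if not spec.dataset:
        raise ValueError("dataset must be non-empty")
    t_max = max(float(s.times[-1]) for s in spec.dataset)
    t_end = t_end or t_max
    if t_end < t_max:
        raise ValueError("t_end shorter than the dataset")
    names = [p.path for p in spec.free_parameters]

    def residuals(theta: np.ndarray) -> np.ndarray:
        phys = copy.deepcopy(physiology)
        d = copy.deepcopy(drug)
        for path, value in zip(names, theta):
            _set_by_path(phys, d, path, float(value))
        d.validate()
        sim = simulate_iv_bolus(phys, d, dose, t_end=t_end, **sim_kwargs)
        res = []
        for series in spec.dataset:
            comp = _resolve_compartment(series.tissue)
            pred = np.interp(
                series.times, sim.times, sim.concentrations[comp]
            )
            obs = series.concentrations
            if spec.log_scale:
                r = np.log(np.maximum(pred, floor)) - np.log(
                    np.maximum(obs, floor)
                )
            else:
                r = pred - obs
                if spec.weighting == "inv_y":
                    r = r / np.sqrt(np.maximum(obs, floor))
                elif spec.weighting == "inv_y2":
                    r = r / np.maximum(obs, floor)
            res.append(r)
        return np.concatenate(res)

    n_obs = sum(len(s) for s in spec.dataset)
    if not spec.free_parameters:
        ssr = float(np.sum(residuals(np.empty(0)) ** 2))
        aic, bic = information_criteria(ssr, n_obs, 0)
        return FitResult({}, ssr, aic, bic, n_obs, True, "residual evaluation")

    x0 = np.array([p.initial for p in spec.free_parameters])
    bounds = (
        np.array([p.lower for p in spec.free_parameters]),
        np.array([p.upper for p in spec.free_parameters]),
    )
    sol = least_squares(
        residuals, x0, bounds=bounds, method="trf",
        x_scale=np.maximum(np.abs(x0), 1e-12), diff_step=1e-4,
    )
    ssr = float(2.0 * sol.cost)
    k = len(names)
    aic, bic = information_criteria(ssr, n_obs, k)
    return FitResult(
        estimates={name: float(v) for name, v in zip(names, sol.x)},
        residual_norm=ssr,
        aic=aic,
        bic=bic,
        n_obs=n_obs,
        converged=bool(sol.success),
        message=sol.message,
    )


def fit_michaelis_menten(
    substrate: np.ndarray, velocity: np.ndarray
) -> MichaelisMentenFit:
    """Fit ``v = Vmax * S / (Km + S)`` by nonlinear least squares.

    Requires at least 3 distinct substrate levels. When the design never
    approaches saturation (all S well below the fitted Km), Vmax and Km are
    individually unidentifiable (only Vmax/Km is) and the fit is flagged.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if s.shape != v.shape:
        raise ValueError("substrate and velocity must have equal length")
    if np.unique(s).size < 3:
        raise ValueError("need at least 3 distinct substrate levels")
    if np.any(s <= 0) or np.any(v < 0):
        raise ValueError("substrate must be positive, velocity non-negative")

    vmax0 = float(v.max()) * 1.5
    km0 = float(np.median(s))

    def resid(theta):
        vmax, km = theta
        return vmax * s / (km + s) - v

    sol = least_squares(
        resid, [max(vmax0, 1e-12), max(km0, 1e-12)],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), method="trf",
    )
    vmax, km = (float(x) for x in sol.x)
    identifiable = bool(s.max() >= 0.2 * km)
    return MichaelisMentenFit(
        vmax=vmax,
        km=km,
        residual_norm=float(2.0 * sol.cost),
        identifiable=identifiable,
        note="" if identifiable else (
            "substrate range far below Km: only Vmax/Km is identifiable"
        ),
    )


def scale_vmax_ivive(
    vmax_mic: float,
    protein_mg_per_ml: float,
    pmic_mg_per_g: float,
    molecular_weight: float,
) -> float:
    """Scale a microsomal Vmax to whole-liver units (umol/L liver/h).

    ``vmax_mic`` is the incubation velocity in ng/ml/min at the stated
    microsomal protein concentration (mg/ml). The velocity is normalized per
    mg protein, scaled by ``pmic`` (mg microsomal protein per g liver),
    converted from mass to moles, and referenced to liver volume at unit
    tissue density (1 g liver = 1 ml).
    """
    if protein_mg_per_ml <= 0:
        raise ValueError("protein concentration must be positive")
    if pmic_mg_per_g < 0 or vmax_mic < 0:
        raise ValueError("vmax and pmic must be non-negative")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    ng_per_min_per_mg = vmax_mic / protein_mg_per_ml
    ng_per_h_per_g_liver = ng_per_min_per_mg * 60.0 * pmic_mg_per_g
    nmol_per_h_per_g = ng_per_h_per_g_liver / molecular_weight
    nmol_per_h_per_l = nmol_per_h_per_g * 1000.0  # 1 g liver = 1 ml
    return nmol_per_h_per_l / 1000.0  # -> umol/L/h
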