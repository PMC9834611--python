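"""Species physiology: tissue volumes, blood flows, and model assembly.

The model partitions the body into a fixed set of lumped tissues. Each tissue
is specified as a percentage of body weight (volume, at unit density) and a
percentage of cardiac output (perfusion). The brain is split into a tissue
(CNS) sub-volume and a vascular sub-volume (97% / 3% of total brain volume)
because drug exchange across the blood-brain barrier is permeability-limited
rather than flow-limited.

Cardiac output, where not given directly, follows an allometric power law
``QC = a * BW**b`` with a configurable coefficient and exponent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "TISSUES",
    "FLOW_TISSUES",
    "SpeciesPhysiology",
    "ResolvedCompartment",
    "allometric_cardiac_output",
    "resolve_physiology",
    "load_physiology",
    "dump_physiology",
    "mouse",
    "dog",
    "human",
]

#: The fixed lumped-tissue set. ``blood`` is the central mixing pool; the lung
#: is handled separately (it sits in the central blood path and carries total
#: cardiac output).
TISSUES = (
    "brain",
    "bone_marrow",
    "kidney",
    "liver",
    "gut",
    "slowly_perfused",
    "rapidly_perfused",
    "blood",
)

#: Tissues that receive a fractional share of cardiac output (all but blood).
FLOW_TISSUES = tuple(t for t in TISSUES if t != "blood")

#: Default allometric cardiac-output coefficient, L/h per kg**exponent
#: (0.235 L/min/kg^0.75, a standard unanesthetized-mammal relationship).
CO_COEFFICIENT = 14.1
CO_EXPONENT = 0.75


class ConfigurationError(ValueError):
    """A species or drug parameter set is incomplete or inconsistent."""


def allometric_cardiac_output(
    body_weight: float,
    coefficient: float = CO_COEFFICIENT,
    exponent: float = CO_EXPONENT,
) -> float:
    """Cardiac output in L/h from an allometric power law of body weight (kg)."""
    if body_weight <= 0:
        raise ValueError(f"body_weight must be positive, got {body_weight}")
    if coefficient <= 0:
        raise ValueError(f"coefficient must be positive, got {coefficient}")
    return coefficient * body_weight**exponent


@dataclass
class SpeciesPhysiology:
    """Species-level physiological parameters.

    Parameters
    ----------
    species_name
        Label, e.g. ``"mouse"``.
    body_weight
        kg.
    hematocrit
        Fraction (0-1). Stored for provenance; the model equates serum and
        blood-pool concentrations (PC_blood = 1) and applies no hematocrit
        correction.
    tissue_weight_fraction
        Percent of body weight per tissue, for the fixed 8-tissue set.
    tissue_flow_fraction
        Percent of cardiac output per perfused tissue (blood excluded).
    cardiac_output
        L/h. ``None`` means derive allometrically from body weight.
    lung_weight_fraction
        Percent of body weight assigned to the lung, which rides the central
        blood path with total cardiac output. ``None`` disables the lung
        compartment.
    """

    species_name: str
    body_weight: float
    hematocrit: float
    tissue_weight_fraction: dict[str, float]
    tissue_flow_fraction: dict[str, float]
    cardiac_output: float | None = None
    co_coefficient: float = CO_COEFFICIENT
    co_exponent: float = CO_EXPONENT
    lung_weight_fraction: float | None = None
    brain_tissue_fraction: float = 0.97
    brain_blood_fraction: float = 0.03
    density: float = 1.0  # kg/L, all tissues

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(
                f"body_weight must be positive, got {self.body_weight}"
            )
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if abs(self.brain_tissue_fraction + self.brain_blood_fraction - 1.0) > 1e-12:
            raise ValueError("brain tissue + blood fractions must sum to 1")
        for tissue in TISSUES:
            if tissue not in self.tissue_weight_fraction:
                raise ConfigurationError(
                    f"missing weight fraction for tissue {tissue!r}"
                )
        for tissue in FLOW_TISSUES:
            if tissue not in self.tissue_flow_fraction:
                raise ConfigurationError(
                    f"missing flow fraction for tissue {tissue!r}"
                )
        for name, frac in self.tissue_weight_fraction.items():
            if frac <= 0:
                raise ValueError(f"weight fraction for {name!r} must be positive")
        for name, frac in self.tissue_flow_fraction.items():
            if frac <= 0:
                raise ValueError(f"flow fraction for {name!r} must be positive")
        if sum(self.tissue_weight_fraction.values()) > 100.0 + 1e-9:
            raise ValueError("tissue weight fractions exceed 100% of body weight")
        if sum(self.tissue_flow_fraction.values()) > 100.0 + 1e-9:
            raise ValueError("tissue flow fractions exceed 100% of cardiac output")

    def total_cardiac_output(self) -> float:
        """Cardiac output in L/h (direct value or allometric)."""
        if self.cardiac_output is not None:
            return self.cardiac_output
        return allometric_cardiac_output(
            self.body_weight, self.co_coefficient, self.co_exponent
        )

    def with_(self, **changes) -> "SpeciesPhysiology":
        """Copy with fields replaced (maps are shallow-copied)."""
        out = replace(
            self,
            tissue_weight_fraction=dict(self.tissue_weight_fraction),
            tissue_flow_fraction=dict(self.tissue_flow_fraction),
        )
        for key, value in changes.items():
            setattr(out, key, value)
        out.validate()
        return out


@dataclass(frozen=True)
class ResolvedCompartment:
    """A tissue with absolute volume (L) and perfusion (L/h)."""

    name: str
    volume: float
    flow: float
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be positive")
        if self.flow < 0:
            raise ValueError(f"{self.name}: flow must be non-negative")


def resolve_physiology(phys: SpeciesPhysiology) -> dict[str, ResolvedCompartment]:
    """Turn fractional physiology into absolute compartment volumes and flows.

    Returns a mapping with one entry per tissue; the brain is returned as two
    compartments, ``brain_tissue`` (97% of brain volume, permeability-limited)
    and ``brain_vascular`` (3%, perfused at the brain's share of cardiac
    output). The lung, when enabled, carries total cardiac output.
    """
    phys.validate()
    qc = phys.total_cardiac_output()
    bw, rho = phys.body_weight, phys.density
    lung_frac = phys.lung_weight_fraction
    if lung_frac is not None and (
        lung_frac >= phys.tissue_weight_fraction["rapidly_perfused"]
    ):
        raise ValueError(
            "lung weight fraction must be smaller than the rapidly perfused "
            "fraction it is carved from"
        )
    out: dict[str, ResolvedCompartment] = {}
    for tissue in TISSUES:
        frac = phys.tissue_weight_fraction[tissue]
        if tissue == "rapidly_perfused" and lung_frac is not None:
            # the lung is carved out of the rapidly perfused lump so total
            # tissue volume stays within the body weight
            frac -= lung_frac
        volume = bw * frac / 100.0 / rho
        flow = (
            qc * phys.tissue_flow_fraction[tissue] / 100.0
            if tissue in phys.tissue_flow_fraction
            else 0.0
        )
        if tissue == "brain":
            out["brain_tissue"] = ResolvedCompartment(
                "brain_tissue", volume * phys.brain_tissue_fraction, 0.0, rho
            )
            out["brain_vascular"] = ResolvedCompartment(
                "brain_vascular", volume * phys.brain_blood_fraction, flow, rho
            )
        else:
            out[tissue] = ResolvedCompartment(tissue, volume, flow, rho)
    if phys.lung_weight_fraction is not None:
        out["lung"] = ResolvedCompartment(
            "lung", bw * phys.lung_weight_fraction / 100.0 / rho, qc, rho
        )
    return out


# ---------------------------------------------------------------------------
# Config I/O

def dump_physiology(phys: SpeciesPhysiology, stream=None) -> str | None:
    """Serialize to YAML (keys mirror the parameter-table names)."""
    doc = {
        "species": phys.species_name,
        "body_weight_kg": phys.body_weight,
        "hematocrit": phys.hematocrit,
        "cardiac_output_L_per_h": phys.cardiac_output,
        "co_allometry": {
            "coefficient": phys.co_coefficient,
            "exponent": phys.co_exponent,
        },
        "percent_body_weight": dict(phys.tissue_weight_fraction),
        "percent_cardiac_output": dict(phys.tissue_flow_fraction),
        "lung_percent_body_weight": phys.lung_weight_fraction,
        "brain_tissue_fraction": phys.brain_tissue_fraction,
        "brain_blood_fraction": phys.brain_blood_fraction,
    }
    return yaml.safe_dump(doc, stream, sort_keys=False)


def load_physiology(source) -> SpeciesPhysiology:
    """Load a species config from a YAML path, stream, or string."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, (str, bytes)):
        doc = yaml.safe_load(io.StringIO(source))
    else:
        doc = yaml.safe_load(source)
    allo = doc.get("co_allometry") or {}
    return SpeciesPhysiology(
        species_name=doc["species"],
        body_weight=doc["body_weight_kg"],
        hematocrit=doc["hematocrit"],
        tissue_weight_fraction=dict(doc["percent_body_weight"]),
        tissue_flow_fraction=dict(doc["percent_cardiac_output"]),
        cardiac_output=doc.get("cardiac_output_L_per_h"),
        co_coefficient=allo.get("coefficient", CO_COEFFICIENT),
        co_exponent=allo.get("exponent", CO_EXPONENT),
        lung_weight_fraction=doc.get("lung_percent_body_weight"),
        brain_tissue_fraction=doc.get("brain_tissue_fraction", 0.97),
        brain_blood_fraction=doc.get("brain_blood_fraction", 0.03),
    )


# ---------------------------------------------------------------------------
# Shipped species defaults (reference physiology tables; lung weight fractions
# are standard reference values since the lumped-tissue table omits the lung).

_WEIGHT = {
    "mouse": {
        "brain": 1.65, "bone_marrow": 3.1, "kidney": 1.67, "liver": 5.49,
        "gut": 4.22, "slowly_perfused": 70.5, "rapidly_perfused": 8.43,
        "blood": 4.9,
    },
    "dog": {
        "brain": 0.78, "bone_marrow": 1.2, "kidney": 0.5, "liver": 3.3,
        "gut": 3.68, "slowly_perfused": 75.8, "rapidly_perfused": 6.53,
        "blood": 8.2,
    },
    "human": {
        "brain": 2.0, "bone_marrow": 1.1, "kidney": 0.44, "liver": 2.57,
        "gut": 2.83, "slowly_perfused": 77.3, "rapidly_perfused": 5.86,
        "blood": 7.9,
    },
}

_FLOW = {
    "mouse": {
        "brain": 3.3, "bone_marrow": 1.0, "kidney": 9.1, "liver": 2.0,
        "gut": 13.0, "slowly_perfused": 35.0, "rapidly_perfused": 36.6,
    },
    "dog": {
        "brain": 2.0, "bone_marrow": 3.0, "kidney": 17.3, "liver": 4.6,
        "gut": 25.1, "slowly_perfused": 38.0, "rapidly_perfused": 10.0,
    },
    "human": {
        "brain": 11.4, "bone_marrow": 3.0, "kidney": 17.5, "liver": 4.6,
        "gut": 18.1, "slowly_perfused": 34.3, "rapidly_perfused": 11.1,
    },
}

_LUNG_WEIGHT = {"mouse": 0.73, "dog": 0.89, "human": 0.76}
_DEFAULT_BW = {"mouse": 0.025, "dog": 25.0, "human": 70.0}
_HEMATOCRIT = {"mouse": 0.45, "dog": 0.45, "human": 0.42}


def _species(name: str, body_weight: float | None) -> SpeciesPhysiology:
    return SpeciesPhysiology(
        species_name=name,
        body_weight=_DEFAULT_BW[name] if body_weight is None else body_weight,
        hematocrit=_HEMATOCRIT[name],
        tissue_weight_fraction=dict(_WEIGHT[name]),
        tissue_flow_fraction=dict(_FLOW[name]),
        lung_weight_fraction=_LUNG_WEIGHT[name],
    )


def mouse(body_weight: float | None = None) -> SpeciesPhysiology:
    """Default mouse physiology (0.025 kg adult female unless overridden)."""
    return _species("mouse", body_weight)


def dog(body_weight: float | None = None) -> SpeciesPhysiology:
    """Default dog physiology (25 kg unless overridden)."""
    return _species("dog", body_weight)


def human(body_weight: float | None = None) -> SpeciesPhysiology:
    """Default human physiology (70 kg unless overridden)."""
    return _species("human", body_weight)


def get_species(name: str, body_weight: float | None = None) -> SpeciesPhysiology:
    """Look up a shipped species by name."""
    try:
        return _species(name, body_weight)
    except KeyError:
        raise ConfigurationError(
            f"unknown species {name!r}; available: {sorted(_WEIGHT)}"
        ) from None


def shipped_config_path(name: str):
    """Path to a shipped parameter YAML (``mouse``, ``dog``, ``human``,
    ``vinblastine_mouse``, ``vinblastine_dog_human``)."""
    from importlib.resources import files

    path = files("vinpbpk.data").joinpath(f"{name}.yaml")
    if not path.is_file():
        raise ConfigurationError(f"no shipped config named {name!r}")
    return path
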