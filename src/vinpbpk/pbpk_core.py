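"""Drug parameters and the PBPK ODE right-hand side.

Model structure
---------------
All tissues except the brain are flow-limited: the venous concentration
leaving a tissue is the free (unbound) tissue concentration, obtained from the
nonlinear tubulin-binding relation

    CT = CVT * (PC + BC / (KD + CVT))

where ``CT`` is total tissue concentration, ``PC`` the tissue:plasma partition
coefficient, ``BC`` the saturable tubulin binding capacity (nmol/kg, used as
nM at unit tissue density) and ``KD`` the drug-tubulin dissociation constant.
The unique non-negative root ``CVT`` of the equivalent quadratic is computed
in closed form.

The brain is permeability-limited: a small vascular sub-compartment exchanges
with arterial blood by flow, and with the brain tissue through a
permeability-surface-area (PSA) term; ABCB1 pumps free brain-tissue drug back
into the vascular space with Michaelis-Menten kinetics.

Gut, liver and kidney express ABCB1; their saturable efflux is scaled by a
tissue expression factor and routed to excretory sinks (gut -> feces,
kidney -> urine); the liver's efflux is the biliary route. Systemic
elimination (CYP metabolism, biliary transport, glomerular filtration) is by
default driven by the central blood concentration and drawn from the blood
pool; a ``liver_free`` option drives the hepatic terms by the liver free
concentration and draws them from the liver compartment instead.

Internal units: amounts nmol, volumes L, times h, concentrations nM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .physiology import (
    ConfigurationError,
    ResolvedCompartment,
    SpeciesPhysiology,
    resolve_physiology,
)

__all__ = [
    "DrugParameters",
    "ModelState",
    "PBPKModel",
    "tissue_free_concentration",
    "rhs_flow_limited",
    "rhs_abcb1_tissue",
    "rhs_brain",
    "rhs_elimination",
    "vinblastine_mouse",
    "vinblastine_dog_human",
]

#: Tissues with ABCB1 expression scaling factors (peripheral efflux set plus
#: the brain, whose efflux lives in the barrier sub-model).
ABCB1_TISSUES = ("brain", "gut", "liver", "kidney")

ML_PER_L = 1e-3  # PSA is specified in ml/h; flows are L/h internally
UMOL_TO_NMOL = 1e3


@dataclass
class DrugParameters:
    """Drug-specific binding, transport, and clearance parameters.

    Units follow the source tables: tubulin ``KD`` and ABCB1/biliary constants
    in nM, metabolic constants in umol/L(/h) (converted internally), ``PSA``
    in ml/h, ``BC`` in nmol/kg tissue.
    """

    molecular_weight: float  # g/mol
    KD_tubulin: float  # nM
    BC: dict[str, float]  # nmol/kg per tissue
    PC: dict[str, float]  # dimensionless per tissue
    SF_ABCB1: dict[str, float]  # expression scaling, subset of ABCB1_TISSUES
    Vmax_ABCB1: float  # nmol/L/h
    Km_ABCB1: float  # nmol/L
    Vmax_met: float  # umol/L/h (liver-volume referenced)
    Km_met: float  # umol/L
    Vmax_bil: float  # nmol/L/h
    Km_bil: float  # nmol/L (after any load-time unit conversion)
    SF_bil: float = 1.0  # expression scaling on the biliary route
    PSA_ml_per_h: float = 0.379  # blood-brain barrier permeability x area
    GFR_fraction: float = 0.11  # fraction of renal blood flow filtered
    fraction_bound_plasma: float = 0.75  # stored; not used in the fluxes
    fu: float = 1.0  # optional free-fraction multiplier on clearance drivers
    scenario: str = "wild_type"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.KD_tubulin <= 0:
            raise ValueError("KD_tubulin must be positive")
        for label, value in (
            ("Vmax_ABCB1", self.Vmax_ABCB1),
            ("Km_ABCB1", self.Km_ABCB1),
            ("Vmax_met", self.Vmax_met),
            ("Km_met", self.Km_met),
            ("Vmax_bil", self.Vmax_bil),
            ("Km_bil", self.Km_bil),
            ("PSA_ml_per_h", self.PSA_ml_per_h),
            ("GFR_fraction", self.GFR_fraction),
        ):
            if value < 0:
                raise ValueError(f"{label} must be non-negative, got {value}")
        for name, value in self.BC.items():
            if value < 0:
                raise ValueError(f"BC[{name!r}] must be non-negative")
        for name, value in self.PC.items():
            if value <= 0:
                raise ValueError(f"PC[{name!r}] must be positive")
        unknown = set(self.SF_ABCB1) - set(ABCB1_TISSUES)
        if unknown:
            raise ConfigurationError(
                f"SF_ABCB1 entries only allowed for {ABCB1_TISSUES}, got {unknown}"
            )

    def with_(self, **changes) -> "DrugParameters":
        out = replace(self, BC=dict(self.BC), PC=dict(self.PC),
                      SF_ABCB1=dict(self.SF_ABCB1))
        for key, value in changes.items():
            setattr(out, key, value)
        out.validate()
        return out

    def parameter_hash(self) -> str:
        doc = {k: (dict(v) if isinstance(v, dict) else v)
               for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:12]


# Tubulin binding capacities, nmol/kg. The slowly perfused lump carries the
# muscle value; blood has no saturable binding.
_BC_DEFAULT = {
    "brain": 10710.0,
    "lung": 2580.0,
    "kidney": 1470.0,
    "liver": 3510.0,
    "gut": 1080.0,
    "slowly_perfused": 900.0,
    "rapidly_perfused": 3420.0,
    "bone_marrow": 371.25,
    "blood": 0.0,
}

# Tissue:plasma partition coefficients. Values for gut/kidney/liver/bone
# marrow/CNS were calibrated to knockout-mouse tissue data; unlisted tissues
# default to 1.0.
_PC_DEFAULT = {
    "gut": 1.08,
    "kidney": 3.73,
    "liver": 2.26,
    "bone_marrow": 1.0,
    "brain": 1.21,
    "blood": 1.0,
    "lung": 1.0,
    "slowly_perfused": 1.0,
    "rapidly_perfused": 1.0,
}

_SF_DEFAULT = {"brain": 1.0, "gut": 0.14, "liver": 0.28, "kidney": 0.78}

MOLECULAR_WEIGHT = 811.0  # vinblastine free base, g/mol
KD_TUBULIN = 196.08  # nM


def vinblastine_mouse() -> DrugParameters:
    """Wild-type mouse parameter set (microsome-derived metabolism; ABCB1 and
    biliary constants calibrated to in vivo mouse data)."""
    return DrugParameters(
        molecular_weight=MOLECULAR_WEIGHT,
        KD_tubulin=KD_TUBULIN,
        BC=dict(_BC_DEFAULT),
        PC=dict(_PC_DEFAULT),
        SF_ABCB1=dict(_SF_DEFAULT),
        Vmax_ABCB1=928.8,
        Km_ABCB1=6.41,
        Vmax_met=1794.9,
        Km_met=11.6,
        Vmax_bil=928.8,
        Km_bil=6.41,
        SF_bil=_SF_DEFAULT["liver"],
        scenario="wild_type",
    )


def vinblastine_dog_human() -> DrugParameters:
    """Dog/human parameter set (dog-microsome metabolism; ABCB1 Km from human
    ATPase activity, Vmax calibrated to canine PK)."""
    return DrugParameters(
        molecular_weight=MOLECULAR_WEIGHT,
        KD_tubulin=KD_TUBULIN,
        BC=dict(_BC_DEFAULT),
        PC=dict(_PC_DEFAULT),
        SF_ABCB1=dict(_SF_DEFAULT),
        Vmax_ABCB1=64.54,
        Km_ABCB1=5760.0,
        Vmax_met=189.6,
        Km_met=9.53,
        Vmax_bil=64.54,
        Km_bil=5760.0,
        SF_bil=_SF_DEFAULT["liver"],
        scenario="wild_type",
    )


# ---------------------------------------------------------------------------
# Elementary flux terms


def tissue_free_concentration(ct, pc, bc, kd):
    """Free (venous) concentration for total tissue concentration ``ct``.

    Solves ``pc*x**2 + (pc*kd + bc - ct)*x - ct*kd = 0`` for its unique
    non-negative root, using the cancellation-safe branch of the quadratic
    formula. Accepts scalars or numpy arrays.
    """
    ct = np.asarray(ct, dtype=float)
    if np.any(ct < 0):
        raise ValueError("tissue concentration must be non-negative")
    pc_a, bc_a, kd_a = (np.asarray(v, dtype=float) for v in (pc, bc, kd))
    if np.any(pc_a <= 0) or np.any(bc_a < 0) or np.any(kd_a <= 0):
        raise ValueError("require PC > 0, BC >= 0, KD > 0")
    b = pc_a * kd_a + bc_a - ct
    disc = np.sqrt(b * b + 4.0 * pc_a * ct * kd_a)
    # root = (-b + disc) / (2 pc); rewrite as 2*ct*kd/(b + disc) when b >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(
            b >= 0.0,
            np.where(ct == 0.0, 0.0, 2.0 * ct * kd_a / (b + disc)),
            (disc - b) / (2.0 * pc_a),
        )
    out = np.maximum(safe, 0.0)
    return float(out) if out.ndim == 0 else out


def _efflux_rate(sf, volume, vmax, km, c_free):
    """Saturable ABCB1 efflux in nmol/h: ``sf * V * Vmax * C / (Km + C)``."""
    if c_free <= 0.0:
        return 0.0
    return sf * volume * vmax * c_free / (km + c_free)


def rhs_flow_limited(
    ct: float,
    compartment: ResolvedCompartment,
    ca: float,
    drug: DrugParameters,
) -> float:
    """Rate of change (nmol/h) of drug amount in a flow-limited tissue."""
    cvt = tissue_free_concentration(
        ct, drug.PC[compartment.name], drug.BC[compartment.name], drug.KD_tubulin
    )
    return compartment.flow * (ca - cvt)


def rhs_abcb1_tissue(
    ct: float,
    compartment: ResolvedCompartment,
    ca: float,
    drug: DrugParameters,
) -> tuple[float, float]:
    """Flow-limited balance minus ABCB1 efflux for gut/liver/kidney.

    Returns ``(dA/dt, efflux)`` in nmol/h; the efflux is routed by the caller
    to the appropriate excretory sink.
    """
    name = compartment.name
    if name not in drug.SF_ABCB1:
        raise ConfigurationError(f"no ABCB1 scaling factor for tissue {name!r}")
    cvt = tissue_free_concentration(
        ct, drug.PC[name], drug.BC[name], drug.KD_tubulin
    )
    efflux = _efflux_rate(
        drug.SF_ABCB1[name], compartment.volume, drug.Vmax_ABCB1,
        drug.Km_ABCB1, cvt,
    )
    return compartment.flow * (ca - cvt) - efflux, efflux


def rhs_brain(
    c_cns: float,
    c_vascular: float,
    brain_tissue: ResolvedCompartment,
    brain_vascular: ResolvedCompartment,
    ca: float,
    drug: DrugParameters,
) -> tuple[float, float]:
    """Permeability-limited brain balance.

    Returns ``(dA_tissue/dt, dA_vascular/dt)`` in nmol/h. Transfer across the
    barrier is ``PSA * (C_vascular - C_free)``; ABCB1 pumps free tissue drug
    back into the vascular space.
    """
    psa = drug.PSA_ml_per_h * ML_PER_L  # L/h
    c_free = tissue_free_concentration(
        c_cns, drug.PC["brain"], drug.BC["brain"], drug.KD_tubulin
    )
    efflux = _efflux_rate(
        drug.SF_ABCB1.get("brain", 0.0), brain_tissue.volume,
        drug.Vmax_ABCB1, drug.Km_ABCB1, c_free,
    )
    barrier = psa * (drug.fu * c_vascular - c_free)
    d_tissue = barrier - efflux
    d_vascular = brain_vascular.flow * (ca - c_vascular) - barrier + efflux
    return d_tissue, d_vascular


def rhs_elimination(
    ca: float,
    c_liver_free: float,
    liver: ResolvedCompartment,
    kidney: ResolvedCompartment,
    drug: DrugParameters,
    driving: str = "blood",
) -> tuple[float, float, float]:
    """Metabolic, biliary, and filtration elimination rates (nmol/h).

    ``driving`` selects the concentration driving the hepatic terms: the
    central venous blood concentration (default) or the liver free
    concentration (``"liver_free"``). Filtration is always driven by blood.
    """
    cv = drug.fu * (ca if driving == "blood" else c_liver_free)
    vmax_met = drug.Vmax_met * UMOL_TO_NMOL
    km_met = drug.Km_met * UMOL_TO_NMOL
    met = liver.volume * vmax_met * cv / (km_met + cv) if cv > 0 else 0.0
    bil = _efflux_rate(drug.SF_bil, liver.volume, drug.Vmax_bil, drug.Km_bil, cv)
    filt = drug.GFR_fraction * kidney.flow * drug.fu * ca if ca > 0 else 0.0
    return met, bil, filt


# ---------------------------------------------------------------------------
# Assembled model


@dataclass
class ModelState:
    """Named view of the packed state vector (amounts in nmol)."""

    labels: tuple[str, ...]
    y: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.y[self.labels.index(name)])


class PBPKModel:
    """A fully resolved species + drug model exposing the packed ODE RHS.

    State layout: one amount (nmol) per compartment -- blood, flow-limited
    tissues, brain tissue, brain vascular -- followed by three cumulative
    elimination sinks: metabolized, feces (biliary + gut efflux), urine
    (filtration + kidney tubular secretion).
    """

    #: flow-limited peripheral tissues (lung appended when enabled)
    PERIPHERAL = ("bone_marrow", "kidney", "liver", "gut",
                  "slowly_perfused", "rapidly_perfused")
    SINKS = ("metabolized", "feces", "urine")

    def __init__(
        self,
        physiology: SpeciesPhysiology,
        drug: DrugParameters,
        include_lung: bool = True,
        elimination_driving: str = "blood",
    ):
        if elimination_driving not in ("blood", "liver_free"):
            raise ValueError("elimination_driving must be 'blood' or 'liver_free'")
        self.physiology = physiology
        self.drug = drug
        self.elimination_driving = elimination_driving
        self.compartments = resolve_physiology(physiology)
        if not include_lung:
            self.compartments.pop("lung", None)
        peripheral = list(self.PERIPHERAL)
        if "lung" in self.compartments:
            peripheral.append("lung")
        self.peripheral = tuple(peripheral)
        self.labels = (
            ("blood",) + self.peripheral + ("brain_tissue", "brain_vascular")
            + self.SINKS
        )
        self.n_state = len(self.labels)
        self._ix = {name: i for i, name in enumerate(self.labels)}
        for name in self.peripheral:
            if name not in drug.BC or name not in drug.PC:
                raise ConfigurationError(
                    f"drug parameters missing BC/PC for tissue {name!r}"
                )
        # packed arrays for the vectorized RHS
        comps = [self.compartments[name] for name in self.peripheral]
        self._vol = np.array([c.volume for c in comps])
        self._flow = np.array([c.flow for c in comps])
        self._pc = np.array([drug.PC[name] for name in self.peripheral])
        self._bc = np.array([drug.BC[name] for name in self.peripheral])
        # The liver's ABCB1 efflux IS the biliary route (handled by the
        # elimination terms), so it is excluded from the peripheral efflux
        # set; gut efflux drains to feces, kidney efflux to urine.
        self._sf = np.array(
            [
                0.0 if name == "liver" else drug.SF_ABCB1.get(name, 0.0)
                for name in self.peripheral
            ]
        )
        self._v_blood = self.compartments["blood"].volume

    def index(self, name: str) -> int:
        return self._ix[name]

    def state(self, y: np.ndarray) -> ModelState:
        return ModelState(self.labels, np.asarray(y))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Packed right-hand side, d(amount)/dt in nmol/h."""
        drug = self.drug
        kd = drug.KD_tubulin
        ca = max(y[0], 0.0) / self._v_blood
        ct = np.maximum(y[1 : 1 + len(self.peripheral)], 0.0) / self._vol
        cvt = tissue_free_concentration(ct, self._pc, self._bc, kd)
        efflux = self._sf * self._vol * drug.Vmax_ABCB1 * cvt / (
            drug.Km_ABCB1 + cvt
        ) if drug.Vmax_ABCB1 > 0 else np.zeros_like(cvt)
        d_per = self._flow * (ca - cvt) - efflux

        bt = self.compartments["brain_tissue"]
        bv = self.compartments["brain_vascular"]
        c_cns = max(y[self._ix["brain_tissue"]], 0.0) / bt.volume
        c_bb = max(y[self._ix["brain_vascular"]], 0.0) / bv.volume
        d_cns, d_bb = rhs_brain(c_cns, c_bb, bt, bv, ca, drug)

        i_liver = self.peripheral.index("liver")
        met, bil, filt = rhs_elimination(
            ca, cvt[i_liver], self.compartments["liver"],
            self.compartments["kidney"], drug, self.elimination_driving,
        )

        i_gut = self.peripheral.index("gut")
        i_kid = self.peripheral.index("kidney")
        d_blood = (
            float(np.dot(self._flow, cvt - ca))
            + bv.flow * (c_bb - ca)
            - filt
        )
        if self.elimination_driving == "blood":
            d_blood -= met + bil
        else:
            d_per[i_liver] -= met + bil

        dy = np.empty(self.n_state)
        dy[0] = d_blood
        dy[1 : 1 + len(self.peripheral)] = d_per
        dy[self._ix["brain_tissue"]] = d_cns
        dy[self._ix["brain_vascular"]] = d_bb
        dy[self._ix["metabolized"]] = met
        dy[self._ix["feces"]] = bil + efflux[i_gut]
        dy[self._ix["urine"]] = filt + efflux[i_kid]
        return dy

    def concentrations(self, y: np.ndarray) -> dict[str, float]:
        """Per-compartment concentrations (nM) and sink amounts (nmol)."""
        out = {"blood": y[0] / self._v_blood}
        for i, name in enumerate(self.peripheral):
            out[name] = y[1 + i] / self._vol[i]
        out["brain_tissue"] = (
            y[self._ix["brain_tissue"]] / self.compartments["brain_tissue"].volume
        )
        out["brain_vascular"] = (
            y[self._ix["brain_vascular"]]
            / self.compartments["brain_vascular"].volume
        )
        for name in self.SINKS:
            out[name] = y[self._ix[name]]
        return out


# ---------------------------------------------------------------------------
# Parameter-file I/O. Keys mirror the source-table names; concentration-like
# kinetic constants declare units and are converted to the internal nmol/L
# (nM) system at load time.

_CONC_FACTORS = {"pmol/L": 1e-3, "nmol/L": 1.0, "nM": 1.0, "umol/L": 1e3}


def _to_nm(entry, default_unit="nmol/L"):
    if isinstance(entry, dict):
        value, unit = entry["value"], entry.get("unit", default_unit)
    else:
        value, unit = entry, default_unit
    try:
        return float(value) * _CONC_FACTORS[unit]
    except KeyError:
        raise ConfigurationError(
            f"unknown concentration unit {unit!r}; allowed: {list(_CONC_FACTORS)}"
        ) from None


def dump_drug_parameters(drug: DrugParameters, stream=None):
    """Serialize a drug parameter set to YAML (units declared per key)."""
    import yaml

    doc = {
        "molecular_weight_g_per_mol": drug.molecular_weight,
        "Kd_tubulin": {"value": drug.KD_tubulin, "unit": "nM"},
        "binding_capacity_nmol_per_kg": dict(drug.BC),
        "partition_coefficients": dict(drug.PC),
        "ABCB1_expression_scaling": dict(drug.SF_ABCB1),
        "Vm_ABCB1": {"value": drug.Vmax_ABCB1, "unit": "nmol/L"},
        "Km_ABCB1": {"value": drug.Km_ABCB1, "unit": "nmol/L"},
        "Vm_met": {"value": drug.Vmax_met, "unit": "umol/L"},
        "Km_met": {"value": drug.Km_met, "unit": "umol/L"},
        "Vm_bil": {"value": drug.Vmax_bil, "unit": "nmol/L"},
        "Km_bil": {"value": drug.Km_bil, "unit": "nmol/L"},
        "SF_bil": drug.SF_bil,
        "PSA_ml_per_h": drug.PSA_ml_per_h,
        "GFR_fraction": drug.GFR_fraction,
        "fraction_bound_plasma": drug.fraction_bound_plasma,
        "fu": drug.fu,
        "scenario": drug.scenario,
    }
    return yaml.safe_dump(doc, stream, sort_keys=False)


def load_drug_parameters(source) -> DrugParameters:
    """Load a drug parameter file (YAML path, stream, or string).

    ``Vm_met``/``Km_met`` stay in umol/L(/h) internally (they are converted
    in the flux terms); all other kinetic constants are converted to nM.
    """
    import io as _io

    import yaml

    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, (str, bytes)):
        doc = yaml.safe_load(_io.StringIO(source))
    else:
        doc = yaml.safe_load(source)
    return DrugParameters(
        molecular_weight=float(doc["molecular_weight_g_per_mol"]),
        KD_tubulin=_to_nm(doc["Kd_tubulin"]),
        BC={k: float(v) for k, v in doc["binding_capacity_nmol_per_kg"].items()},
        PC={k: float(v) for k, v in doc["partition_coefficients"].items()},
        SF_ABCB1={k: float(v) for k, v in doc["ABCB1_expression_scaling"].items()},
        Vmax_ABCB1=_to_nm(doc["Vm_ABCB1"]),
        Km_ABCB1=_to_nm(doc["Km_ABCB1"]),
        Vmax_met=_to_nm(doc["Vm_met"], "umol/L") / UMOL_TO_NMOL,
        Km_met=_to_nm(doc["Km_met"], "umol/L") / UMOL_TO_NMOL,
        Vmax_bil=_to_nm(doc["Vm_bil"]),
        Km_bil=_to_nm(doc["Km_bil"]),
        SF_bil=float(doc.get("SF_bil", 1.0)),
        PSA_ml_per_h=float(doc.get("PSA_ml_per_h", 0.379)),
        GFR_fraction=float(doc.get("GFR_fraction", 0.11)),
        fraction_bound_plasma=float(doc.get("fraction_bound_plasma", 0.75)),
        fu=float(doc.get("fu", 1.0)),
        scenario=doc.get("scenario", "wild_type"),
    )
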