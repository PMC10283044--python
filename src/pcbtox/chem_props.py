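"""Partition coefficients from solute descriptors and Henry's law constants.

Every chemical in the exposure system is characterised by three
dimensionless, volume-based equilibrium partition coefficients at the
system temperature:

* ``K_lip_w`` — storage lipid / water,
* ``K_pro_w`` — protein / water,
* ``K_air_w`` — air / water.

The condensed-phase coefficients come from polyparameter linear
free-energy relationships (PP-LFERs) over the Abraham solute descriptors
(E, S, A, B, V, L); the air/water coefficient for volatile parent
congeners comes from a Henry's law constant, van't-Hoff-corrected to the
incubation temperature and divided by RT.  Sulfated metabolites carry a
permanent negative charge under assay conditions and are treated as
non-volatile (``K_air_w = 0``) unless explicitly overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ConfigurationError, ValidationError

#: Ideal gas constant, J/(mol K).
R_GAS = 8.314

#: Default internal energy of air–water transfer for PCBs, J/mol, applied
#: when a compound record does not state a congener-specific value.  A
#: single representative value for lower-chlorinated biphenyls; override
#: per compound via ``HenryConstant.delta_u_aw``.
DEFAULT_DELTA_U_AW = 55_000.0

#: Phase-pair labels used throughout the registry.
LIPID_WATER = "lipid/water"
PROTEIN_WATER = "protein/water"
AIR_WATER = "air/water"

COMPOUND_CLASSES = ("parent", "hydroxylated", "sulfated")


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solute descriptors.

    E: excess molar refraction (cm^3/10); S: dipolarity/polarizability;
    A: hydrogen-bond acidity; B: hydrogen-bond basicity; V: McGowan
    characteristic volume (cm^3/mol / 100); L: log10 hexadecane/air
    partition coefficient.
    """

    E: float
    S: float
    A: float
    B: float
    V: float
    L: float

    def __post_init__(self) -> None:
        for name in ("E", "S", "A", "B", "V", "L"):
            _require_finite(name, getattr(self, name))
        if self.V <= 0:
            raise ValidationError(f"McGowan volume V must be > 0, got {self.V}")


@dataclass(frozen=True)
class PPLFERCoefficients:
    """One PP-LFER system: log10 K = c + e*E + s*S + a*A + b*B + (v*V | l*L).

    Exactly one of ``v``/``l`` is set; ``basis`` records whether the
    system yields a dimensionless volume-based coefficient directly
    (``"volume"``) or a mass-based one in L/kg (``"L_per_kg"``), in which
    case ``density`` (kg/L) converts it to the volume basis the mass
    balance needs.
    """

    phase_pair: str
    c: float
    e: float
    s: float
    a: float
    b: float
    v: Optional[float] = None
    l: Optional[float] = None
    basis: str = "volume"
    density: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("c", "e", "s", "a", "b"):
            _require_finite(name, getattr(self, name))
        if (self.v is None) == (self.l is None):
            raise ValidationError(
                f"exactly one of v/l must be set for {self.phase_pair!r}"
            )
        _require_finite("v|l", self.v if self.v is not None else self.l)
        if self.basis not in ("volume", "L_per_kg"):
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.basis == "L_per_kg":
            if self.density is None or self.density <= 0:
                raise ValidationError(
                    f"basis 'L_per_kg' requires a positive density for {self.phase_pair!r}"
                )


@dataclass(frozen=True)
class HenryConstant:
    """Henry's law constant at a reference temperature.

    ``h_ref`` in Pa m^3/mol; ``delta_u_aw`` (J/mol) is the internal
    energy of air–water transfer driving the van't Hoff temperature
    correction, optional.
    """

    h_ref: float
    t_ref: float = 298.15
    delta_u_aw: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite("h_ref", self.h_ref)
        if self.h_ref < 0:
            raise ValidationError(f"h_ref must be >= 0, got {self.h_ref}")
        if self.t_ref <= 0:
            raise ValidationError(f"t_ref must be > 0, got {self.t_ref}")
        if self.delta_u_aw is not None:
            _require_finite("delta_u_aw", self.delta_u_aw)


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical: identity, class, chlorination, descriptors, volatility."""

    id: str
    name: str
    compound_class: str
    n_cl: int
    descriptors: AbrahamDescriptors
    henry: Optional[HenryConstant] = None
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(
                f"compound_class must be one of {COMPOUND_CLASSES}, got {self.compound_class!r}"
            )
        if not (0 <= int(self.n_cl) <= 10):
            raise ValidationError(f"n_cl must be in [0, 10], got {self.n_cl}")


@dataclass(frozen=True)
class PartitionCoefficientSet:
    """Dimensionless volume-based K's at the system temperature."""

    k_lip_w: float
    k_pro_w: float
    k_air_w: float

    def __post_init__(self) -> None:
        for name in ("k_lip_w", "k_pro_w", "k_air_w"):
            value = _require_finite(name, getattr(self, name))
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")


def pplfer_log_k(d: AbrahamDescriptors, coeff: PPLFERCoefficients) -> float:
    """log10 partition coefficient from one PP-LFER system.

    Pure linear combination; the volume term uses V or L depending on
    which coefficient the system defines.
    """
    volume_term = coeff.v * d.V if coeff.v is not None else coeff.l * d.L
    return (
        coeff.c
        + coeff.e * d.E
        + coeff.s * d.S
        + coeff.a * d.A
        + coeff.b * d.B
        + volume_term
    )


def correct_henry_temperature(
    h: HenryConstant,
    t_target: float,
    default_delta_u_aw: float = DEFAULT_DELTA_U_AW,
) -> float:
    """Henry's law constant at ``t_target`` (K) via the van't Hoff relation.

    H(T) = H_ref * exp(-dU_aw/R * (1/T - 1/T_ref)).  When the record
    carries no transfer energy, ``default_delta_u_aw`` is used.
    """
    if t_target <= 0:
        raise ValidationError(f"t_target must be > 0, got {t_target}")
    du = h.delta_u_aw if h.delta_u_aw is not None else default_delta_u_aw
    return h.h_ref * math.exp(-du / R_GAS * (1.0 / t_target - 1.0 / h.t_ref))


def henry_to_kaw(h: float, t: float) -> float:
    """Dimensionless air/water partition coefficient K_aw = H / (R T)."""
    if t <= 0:
        raise ValidationError(f"temperature must be > 0, got {t}")
    if h < 0:
        raise ValidationError(f"Henry constant must be >= 0, got {h}")
    return h / (R_GAS * t)


def _volume_basis_k(log_k: float, coeff: PPLFERCoefficients) -> float:
    """10**log_k converted from the system's basis to dimensionless volume/volume."""
    k = 10.0 ** log_k
    if coeff.basis == "L_per_kg":
        # K [L water / kg phase] * density [kg phase / L phase] -> L/L
        k *= coeff.density
    return k


def build_partition_set(
    compound: CompoundRecord,
    registry: Mapping[str, PPLFERCoefficients],
    t: float,
    default_delta_u_aw: float = DEFAULT_DELTA_U_AW,
) -> PartitionCoefficientSet:
    """Assemble the three partition coefficients for one compound.

    The lipid/water and protein/water coefficients always come from the
    registry's PP-LFER systems.  The air/water route depends on class:
    sulfated metabolites are fixed at K_air_w = 0 (ionised, involatile);
    other compounds use the Henry's law route when a constant is on
    record, otherwise the registry's air/water PP-LFER.
    """
    for pair in (LIPID_WATER, PROTEIN_WATER):
        if pair not in registry:
            raise ConfigurationError(
                f"coefficient registry has no entry for phase pair {pair!r}"
            )
    k_lip = _volume_basis_k(
        pplfer_log_k(compound.descriptors, registry[LIPID_WATER]),
        registry[LIPID_WATER],
    )
    k_pro = _volume_basis_k(
        pplfer_log_k(compound.descriptors, registry[PROTEIN_WATER]),
        registry[PROTEIN_WATER],
    )

    if compound.compound_class == "sulfated":
        k_air = 0.0
    elif compound.henry is not None:
        h_t = correct_henry_temperature(compound.henry, t, default_delta_u_aw)
        k_air = henry_to_kaw(h_t, t)
    elif AIR_WATER in registry:
        k_air = _volume_basis_k(
            pplfer_log_k(compound.descriptors, registry[AIR_WATER]),
            registry[AIR_WATER],
        )
    else:
        raise ConfigurationError(
            f"compound {compound.id!r} has no Henry constant and the registry "
            f"has no entry for phase pair {AIR_WATER!r}"
        )
    return PartitionCoefficientSet(k_lip_w=k_lip, k_pro_w=k_pro, k_air_w=k_air)
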