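"""Equilibrium mass balance of a chemical in a cell-culture exposure well.

At equilibrium the total mass of a chemical splits between the medium
(freely dissolved), cellular protein, cellular storage lipid, and the
air headspace:

    m_tot = C_fre*V_m + K_pro_w*[Pro]*C_fre*V_m + K_lip_w*[Lip]*C_fre*V_m
            + K_air_w*C_fre*V_a

Dividing by ``C_fre * V_m`` gives closed-form phase fractions in terms of
the dimensionless phase loadings.  With

    D = 1 + K_pro_w*pro_frac + K_lip_w*lip_frac + K_air_w*air_ratio

the fractions are ``f_fre = 1/D``, ``f_pro = K_pro_w*pro_frac/D``,
``f_lip = K_lip_w*lip_frac/D`` and ``f_air = K_air_w*air_ratio/D``; they
sum to one by construction.  The cell-associated fraction groups the
protein- and lipid-bound shares with the part of the freely dissolved
chemical that sits in cell water (the cytosol is treated as freely
dissolved, so its concentration equals the medium's C_fre).

Sorption to plastic walls and any saturation cap are deliberately
outside the model: the balance assumes ideal partitioning between the
four phases only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .chem_props import (
    CompoundRecord,
    PartitionCoefficientSet,
    PPLFERCoefficients,
    build_partition_set,
)
from .errors import ValidationError

#: Default incubation temperature, K (37 degrees C).
DEFAULT_TEMPERATURE = 310.15

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class CellComposition:
    """Per-cell phase volumes in uL/cell.

    Defaults are the measured composition of C6 rat glioma cells
    (protein 1.18e-4, lipid 9.57e-5, water 2.84e-6 uL/cell).
    """

    v_pro: float = 1.18e-4
    v_lip: float = 9.57e-5
    v_wat: float = 2.84e-6

    def __post_init__(self) -> None:
        for name in ("v_pro", "v_lip", "v_wat"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SystemGeometry:
    """Abiotic dimensions of one exposure well.

    Defaults describe a 24-well format: 500 uL medium, 2000 uL
    headspace, 2e5 cells, 37 degrees C.
    """

    v_m: float = 500.0
    v_a: float = 2000.0
    n_cells: float = 2.0e5
    t: float = DEFAULT_TEMPERATURE
    composition: CellComposition = CellComposition()

    def __post_init__(self) -> None:
        if self.v_m <= 0:
            raise ValidationError(f"medium volume must be > 0, got {self.v_m}")
        if self.v_a < 0:
            raise ValidationError(f"headspace volume must be >= 0, got {self.v_a}")
        if self.n_cells < 0:
            raise ValidationError(f"cell number must be >= 0, got {self.n_cells}")
        if self.t <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.t}")


@dataclass(frozen=True)
class PhaseLoadings:
    """Dimensionless sorbing-phase loadings relative to the medium volume."""

    pro_frac: float
    lip_frac: float
    wat_frac: float
    air_ratio: float

    def __post_init__(self) -> None:
        for name in ("pro_frac", "lip_frac", "wat_frac", "air_ratio"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SystemFractions:
    """Phase fractions of one chemical across the whole well; sum to one."""

    f_fre: float
    f_pro: float
    f_lip: float
    f_air: float
    f_cell: float
    f_medium: float


@dataclass(frozen=True)
class CellFractions:
    """Distribution of the cell-associated chemical over intracellular phases."""

    g_lip: float
    g_pro: float
    g_wat: float


def phase_loadings(geom: SystemGeometry) -> PhaseLoadings:
    """Turn well geometry and cell composition into dimensionless loadings."""
    c = geom.composition
    return PhaseLoadings(
        pro_frac=geom.n_cells * c.v_pro / geom.v_m,
        lip_frac=geom.n_cells * c.v_lip / geom.v_m,
        wat_frac=geom.n_cells * c.v_wat / geom.v_m,
        air_ratio=geom.v_a / geom.v_m,
    )


def system_fractions(k: PartitionCoefficientSet, loads: PhaseLoadings) -> SystemFractions:
    """Closed-form equilibrium phase fractions for one chemical.

    ``f_cell`` groups protein, lipid and the cell-water share of the
    freely dissolved fraction; ``f_medium`` is the complement of that
    share within ``f_fre``.
    """
    term_pro = k.k_pro_w * loads.pro_frac
    term_lip = k.k_lip_w * loads.lip_frac
    term_air = k.k_air_w * loads.air_ratio
    denom = 1.0 + term_pro + term_lip + term_air
    f_fre = 1.0 / denom
    f_pro = term_pro / denom
    f_lip = term_lip / denom
    f_air = term_air / denom
    f_cell = f_pro + f_lip + f_fre * loads.wat_frac
    f_medium = f_fre * (1.0 - loads.wat_frac)
    total = f_fre + f_pro + f_lip + f_air
    assert abs(total - 1.0) < 1e-9, "mass balance violated"
    return SystemFractions(
        f_fre=f_fre, f_pro=f_pro, f_lip=f_lip, f_air=f_air,
        f_cell=f_cell, f_medium=f_medium,
    )


def intracellular_fractions(
    k: PartitionCoefficientSet, comp: CellComposition
) -> CellFractions:
    """Distribution over the three intracellular phases (lipid, protein, cytosol).

    The cytosol is freely dissolved, so its phase weight is the water
    volume itself; sorbing phases are weighted by K times volume.
    """
    num_lip = k.k_lip_w * comp.v_lip
    num_pro = k.k_pro_w * comp.v_pro
    num_wat = comp.v_wat
    z = num_lip + num_pro + num_wat
    if z <= 0:
        raise ValidationError(
            "all intracellular phase weights are zero; cannot normalise"
        )
    return CellFractions(g_lip=num_lip / z, g_pro=num_pro / z, g_wat=num_wat / z)


def partition_profile(
    compounds: Iterable[CompoundRecord],
    geom: SystemGeometry,
    registry: Mapping[str, PPLFERCoefficients],
) -> pd.DataFrame:
    """Per-compound partitioning table across the well and inside the cells.

    One row per compound: the three K's, the five system fractions plus
    the grouped cell fraction, and the intracellular distribution.
    Raises with the compound id attached if a coefficient set is missing.
    """
    loads = phase_loadings(geom)
    rows = []
    for compound in compounds:
        try:
            k = build_partition_set(compound, registry, geom.t)
            sysf = system_fractions(k, loads)
            cellf = intracellular_fractions(k, geom.composition)
        except Exception as exc:
            raise type(exc)(f"compound {compound.id!r}: {exc}") from exc
        rows.append(
            {
                "id": compound.id,
                "class": compound.compound_class,
                "n_cl": compound.n_cl,
                "K_lip_w": k.k_lip_w,
                "K_pro_w": k.k_pro_w,
                "K_air_w": k.k_air_w,
                "f_fre": sysf.f_fre,
                "f_pro": sysf.f_pro,
                "f_lip": sysf.f_lip,
                "f_air": sysf.f_air,
                "f_cell": sysf.f_cell,
                "f_medium": sysf.f_medium,
                "g_lip": cellf.g_lip,
                "g_pro": cellf.g_pro,
                "g_wat": cellf.g_wat,
            }
        )
    columns = [
        "id", "class", "n_cl", "K_lip_w", "K_pro_w", "K_air_w",
        "f_fre", "f_pro", "f_lip", "f_air", "f_cell", "f_medium",
        "g_lip", "g_pro", "g_wat",
    ]
    return pd.DataFrame(rows, columns=columns)
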