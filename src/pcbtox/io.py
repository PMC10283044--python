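"""Readers and writers for the package's plain-text interchange formats.

* compound table — CSV, one row per chemical (descriptors, chlorination,
  Henry's law data); empty cells mean "not provided", never zero.
* PP-LFER coefficient registry — YAML, phase pair -> coefficient set.
* system geometry — YAML (well volumes, cell number, temperature,
  per-cell composition).
* plate readings — long-format CSV, one row per well.

Packaged defaults live under ``pcbtox/data`` and cover a 15-compound
illustrative library (five parent congener profiles with matched
hydroxylated and sulfated metabolites), a three-system coefficient
registry, and a 24-well exposure geometry.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .chem_props import (
    AbrahamDescriptors,
    CompoundRecord,
    HenryConstant,
    PPLFERCoefficients,
)
from .dose_response import PlateReading
from .errors import ConfigurationError
from .partition_model import CellComposition, SystemGeometry

PathLike = Union[str, Path]

_COMPOUND_COLUMNS = [
    "id", "name", "class", "n_cl", "E", "S", "A", "B", "V", "L",
    "H_ref", "T_ref", "dU_aw", "smiles",
]

_PLATE_COLUMNS = [
    "plate_id", "assay", "row", "col", "treatment", "conc_um",
    "bio_rep", "tech_rep", "signal", "signal_ref",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


# ---------------------------------------------------------------------------
# Compound tables
# ---------------------------------------------------------------------------

def frame_to_compounds(df: pd.DataFrame) -> List[CompoundRecord]:
    records = []
    for _, row in df.iterrows():
        h_ref = _opt_float(row.get("H_ref"))
        henry = None
        if h_ref is not None:
            henry = HenryConstant(
                h_ref=h_ref,
                t_ref=_opt_float(row.get("T_ref")) or 298.15,
                delta_u_aw=_opt_float(row.get("dU_aw")),
            )
        smiles = row.get("smiles")
        if isinstance(smiles, float) and np.isnan(smiles):
            smiles = None
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                name=str(row.get("name", row["id"])),
                compound_class=str(row["class"]),
                n_cl=int(row["n_cl"]),
                descriptors=AbrahamDescriptors(
                    E=float(row["E"]), S=float(row["S"]), A=float(row["A"]),
                    B=float(row["B"]), V=float(row["V"]), L=float(row["L"]),
                ),
                henry=henry,
                smiles=smiles if smiles else None,
            )
        )
    return records


def compounds_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "name": r.name, "class": r.compound_class,
            "n_cl": r.n_cl,
            "E": r.descriptors.E, "S": r.descriptors.S, "A": r.descriptors.A,
            "B": r.descriptors.B, "V": r.descriptors.V, "L": r.descriptors.L,
            "H_ref": r.henry.h_ref if r.henry else None,
            "T_ref": r.henry.t_ref if r.henry else None,
            "dU_aw": r.henry.delta_u_aw if r.henry else None,
            "smiles": r.smiles,
        })
    return pd.DataFrame(rows, columns=_COMPOUND_COLUMNS)


def read_compound_table(path: PathLike) -> List[CompoundRecord]:
    return frame_to_compounds(pd.read_csv(path))


def write_compound_table(records: Sequence[CompoundRecord], path: PathLike) -> None:
    compounds_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coefficient registry and geometry
# ---------------------------------------------------------------------------

def registry_from_mapping(raw: Mapping) -> Dict[str, PPLFERCoefficients]:
    registry: Dict[str, PPLFERCoefficients] = {}
    for pair, entry in raw.items():
        if not isinstance(entry, Mapping):
            raise ConfigurationError(f"registry entry {pair!r} must be a mapping")
        registry[pair] = PPLFERCoefficients(
            phase_pair=pair,
            c=float(entry["c"]), e=float(entry["e"]), s=float(entry["s"]),
            a=float(entry["a"]), b=float(entry["b"]),
            v=_opt_float(entry.get("v")), l=_opt_float(entry.get("l")),
            basis=entry.get("basis", "volume"),
            density=_opt_float(entry.get("density")),
            provenance=entry.get("provenance", ""),
        )
    return registry


def registry_to_mapping(registry: Mapping[str, PPLFERCoefficients]) -> dict:
    out = {}
    for pair, c in registry.items():
        entry = {"c": c.c, "e": c.e, "s": c.s, "a": c.a, "b": c.b,
                 "basis": c.basis, "provenance": c.provenance}
        if c.v is not None:
            entry["v"] = c.v
        if c.l is not None:
            entry["l"] = c.l
        if c.density is not None:
            entry["density"] = c.density
        out[pair] = entry
    return out


def load_registry(path: PathLike) -> Dict[str, PPLFERCoefficients]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"registry file {path} is not a mapping")
    return registry_from_mapping(raw)


def write_registry(registry: Mapping[str, PPLFERCoefficients], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry_to_mapping(registry), fh, sort_keys=True)


def geometry_from_mapping(raw: Mapping) -> SystemGeometry:
    comp = raw.get("composition", {})
    kwargs = {}
    if comp:
        kwargs["composition"] = CellComposition(
            v_pro=float(comp["v_pro"]), v_lip=float(comp["v_lip"]),
            v_wat=float(comp["v_wat"]),
        )
    return SystemGeometry(
        v_m=float(raw.get("v_m", 500.0)),
        v_a=float(raw.get("v_a", 2000.0)),
        n_cells=float(raw.get("n_cells", 2.0e5)),
        t=float(raw.get("t", 310.15)),
        **kwargs,
    )


def geometry_to_mapping(geom: SystemGeometry) -> dict:
    return {
        "v_m": geom.v_m, "v_a": geom.v_a, "n_cells": geom.n_cells, "t": geom.t,
        "composition": {
            "v_pro": geom.composition.v_pro,
            "v_lip": geom.composition.v_lip,
            "v_wat": geom.composition.v_wat,
        },
    }


def load_geometry(path: PathLike) -> SystemGeometry:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"geometry file {path} is not a mapping")
    return geometry_from_mapping(raw)


def write_geometry(geom: SystemGeometry, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(geometry_to_mapping(geom), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Plate readings
# ---------------------------------------------------------------------------

def plates_to_frame(plates: Sequence[PlateReading]) -> pd.DataFrame:
    frames = []
    for p in plates:
        df = p.wells.copy()
        df.insert(0, "plate_id", p.plate_id)
        df.insert(1, "assay", p.assay)
        frames.append(df[_PLATE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=_PLATE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_plates(df: pd.DataFrame) -> List[PlateReading]:
    plates = []
    for (plate_id, assay), grp in df.groupby(["plate_id", "assay"], sort=True):
        wells = grp.drop(columns=["plate_id", "assay"]).reset_index(drop=True)
        plates.append(PlateReading(plate_id=str(plate_id), assay=str(assay), wells=wells))
    return plates


def read_plate_table(path: PathLike) -> List[PlateReading]:
    return frame_to_plates(pd.read_csv(path))


def write_plate_table(plates: Sequence[PlateReading], path: PathLike) -> None:
    plates_to_frame(plates).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("pcbtox.data").joinpath(name)


def default_library() -> List[CompoundRecord]:
    """The shipped 15-compound illustrative library (synthetic descriptors)."""
    with importlib.resources.as_file(_data_path("compounds.csv")) as path:
        return read_compound_table(path)


def default_registry() -> Dict[str, PPLFERCoefficients]:
    with importlib.resources.as_file(_data_path("pplfer_registry.yaml")) as path:
        return load_registry(path)


def default_geometry() -> SystemGeometry:
    with importlib.resources.as_file(_data_path("geometry.yaml")) as path:
        return load_geometry(path)
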