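"""Seeded synthetic study generator.

Everything the analysis consumes can be simulated here with the
statistical structure the workflow assumes: microplates drawn from
Hill-curve ground truth with multiplicative plate-reader noise, and a
compound library whose Abraham descriptors follow plausible
class/chlorination gradients (parents grow more hydrophobic with each
chlorine; hydroxylation adds hydrogen bonding; sulfation adds strong
basicity and polarity, pushing the conjugates toward the aqueous
medium).

Defaults emulate the study design the package targets: a 7-point
concentration series (0, 0.5, 1, 5, 10, 20, 50 uM), DMSO vehicle
controls, three biological by three technical replicates, 10% CV
multiplicative lognormal noise.  Every draw is driven by a single
integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pcb_io
from .chem_props import (
    AbrahamDescriptors,
    CompoundRecord,
    HenryConstant,
)
from .dose_response import (
    CONTROL_TREATMENT,
    LDH_HIGH_CONTROL,
    LDH_LOW_CONTROL,
    PlateReading,
)
from .errors import ValidationError
from .partition_model import SystemGeometry

#: Concentration series of the emulated exposure design, uM.
DEFAULT_CONC_GRID = (0.0, 0.5, 1.0, 5.0, 10.0, 20.0, 50.0)

_PLATE_FORMATS = {"MTT": (4, 6), "LDH": (8, 12)}  # rows x cols


@dataclass(frozen=True)
class CompoundTruth:
    """Ground-truth Hill parameters for one simulated compound."""

    id: str
    compound_class: str = "parent"
    n_cl: int = 0
    top: float = 100.0
    bottom: float = 0.0
    hill: float = -1.0
    ic50_um: float = 10.0


@dataclass(frozen=True)
class SimulationScenario:
    """Full description of one simulated experiment.

    ``noise_model`` is "lognormal" (multiplicative, parameterised by
    ``cv``) or "gaussian" (additive, parameterised by ``sigma_add`` in
    signal units).
    """

    seed: int
    compounds: Tuple[CompoundTruth, ...]
    conc_grid: Tuple[float, ...] = DEFAULT_CONC_GRID
    n_bio: int = 3
    n_tech: int = 3
    noise_model: str = "lognormal"
    cv: float = 0.10
    sigma_add: float = 0.0
    n_controls: int = 3
    assay: str = "MTT"
    control_signal: float = 1.0
    blank: float = 0.05
    ldh_low: float = 0.10
    ldh_high: float = 1.10
    label: str = "study"

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sigma_add < 0:
            raise ValidationError("noise magnitude must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.assay not in _PLATE_FORMATS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.n_bio < 1 or self.n_tech < 1 or self.n_controls < 1:
            raise ValidationError("replicate and control counts must be >= 1")


def hill_viability(conc_um, top: float, bottom: float, hill: float,
                   ic50_um: float):
    """Percent viability on the 4PL curve; concentration 0 maps to the
    no-effect asymptote (top for inhibitory slopes, bottom otherwise)."""
    conc = np.asarray(conc_um, dtype=float)
    out = np.where(
        conc > 0,
        bottom + (top - bottom)
        / (1.0 + 10.0 ** (hill * (np.log10(ic50_um) - np.log10(np.where(conc > 0, conc, 1.0))))),
        top if hill < 0 else bottom,
    )
    return out


def _noise_factor(rng: np.random.Generator, scenario: SimulationScenario) -> float:
    if scenario.noise_model == "lognormal":
        sigma = float(np.sqrt(np.log1p(scenario.cv ** 2)))
        return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
    return 1.0


def _noise_offset(rng: np.random.Generator, scenario: SimulationScenario) -> float:
    if scenario.noise_model == "gaussian":
        return float(rng.normal(0.0, scenario.sigma_add))
    return 0.0


def _well_label(index: int, assay: str) -> Tuple[str, int]:
    n_rows, n_cols = _PLATE_FORMATS[assay]
    if index >= n_rows * n_cols:
        raise ValidationError(
            f"{assay} plate format ({n_rows}x{n_cols}) cannot hold well {index + 1}"
        )
    return "ABCDEFGH"[index // n_cols], index % n_cols + 1


def generate_plate(scenario: SimulationScenario) -> List[PlateReading]:
    """Simulate one plate per (compound, biological replicate).

    MTT plates hold DMSO controls plus the positive concentration
    series, each in ``n_tech`` technical replicates; LDH plates add
    low/high lysis controls.  Expected blank-corrected signal is
    proportional to the true Hill response; noise is applied per well.
    """
    rng = np.random.default_rng(scenario.seed)
    positive = [c for c in scenario.conc_grid if c > 0]
    plates: List[PlateReading] = []
    for truth in scenario.compounds:
        for bio in range(1, scenario.n_bio + 1):
            rows = []
            idx = 0

            def add_well(treatment: str, conc: float, tech: int, expected: float):
                nonlocal idx
                r, c = _well_label(idx, scenario.assay)
                idx += 1
                signal = expected * _noise_factor(rng, scenario) \
                    + _noise_offset(rng, scenario)
                if scenario.assay == "MTT":
                    rows.append({
                        "row": r, "col": c, "treatment": treatment,
                        "conc_um": conc, "bio_rep": bio, "tech_rep": tech,
                        "signal": scenario.blank + signal,
                        "signal_ref": scenario.blank,
                    })
                else:
                    rows.append({
                        "row": r, "col": c, "treatment": treatment,
                        "conc_um": conc, "bio_rep": bio, "tech_rep": tech,
                        "signal": signal, "signal_ref": np.nan,
                    })

            if scenario.assay == "MTT":
                for tech in range(1, scenario.n_controls + 1):
                    add_well(CONTROL_TREATMENT, 0.0, tech, scenario.control_signal)
                for conc in positive:
                    viab = float(hill_viability(conc, truth.top, truth.bottom,
                                                truth.hill, truth.ic50_um))
                    for tech in range(1, scenario.n_tech + 1):
                        add_well(truth.id, conc, tech,
                                 scenario.control_signal * viab / 100.0)
            else:
                span = scenario.ldh_high - scenario.ldh_low
                for tech in range(1, scenario.n_controls + 1):
                    add_well(LDH_LOW_CONTROL, 0.0, tech, scenario.ldh_low)
                for tech in range(1, scenario.n_controls + 1):
                    add_well(LDH_HIGH_CONTROL, 0.0, tech, scenario.ldh_high)
                for conc in positive:
                    viab = float(hill_viability(conc, truth.top, truth.bottom,
                                                truth.hill, truth.ic50_um))
                    cytotox = 100.0 - viab
                    for tech in range(1, scenario.n_tech + 1):
                        add_well(truth.id, conc, tech,
                                 scenario.ldh_low + span * cytotox / 100.0)

            plates.append(PlateReading(
                plate_id=f"{scenario.label}_{truth.id}_b{bio}",
                assay=scenario.assay,
                wells=pd.DataFrame(rows),
            ))
    return plates


# ---------------------------------------------------------------------------
# Compound library
# ---------------------------------------------------------------------------

# Descriptor trends per chlorine and per-class increments; chosen so that
# downstream partitioning reproduces the qualitative structure-activity
# picture (parents cell-bound and mildly volatile, hydroxylated
# intermediates, sulfates aqueous).
_PARENT_BASE = {"E": 1.35, "S": 1.05, "A": 0.0, "B": 0.28, "V": 1.3315, "L": 6.10}
_PARENT_PER_CL = {"E": 0.06, "S": 0.09, "A": 0.0, "B": -0.02, "V": 0.1225, "L": 0.65}
_OH_DELTA = {"E": 0.08, "S": 0.45, "A": 0.65, "B": 0.28, "V": 0.0588, "L": 0.90}
_SULFATE_DELTA = {"E": 0.10, "S": 1.60, "A": 0.35, "B": 1.65, "V": 0.3157, "L": 2.50}

_CLASS_PREFIX = {"parent": "pcb", "hydroxylated": "oh_pcb", "sulfated": "pcb_sulfate"}

#: Chlorination pattern of the emulated five-congener panel (one mono-,
#: one di-, two tri-, one tetra-chlorinated biphenyl).
_NCL_PANEL = (1, 2, 3, 3, 4)


def _descriptor_values(compound_class: str, n_cl: int,
                       jitter: np.ndarray) -> AbrahamDescriptors:
    values = {}
    for i, key in enumerate(("E", "S", "A", "B", "V", "L")):
        base = _PARENT_BASE[key] + _PARENT_PER_CL[key] * n_cl
        if compound_class == "hydroxylated":
            base += _OH_DELTA[key]
        elif compound_class == "sulfated":
            base += _SULFATE_DELTA[key]
        values[key] = base + (jitter[i] if key not in ("A",) else abs(jitter[i]))
    values["A"] = max(values["A"], 0.0)
    return AbrahamDescriptors(**values)


def generate_compound_library(
    seed: int, n_per_class: int = 5, jitter_sd: float = 0.01
) -> List[CompoundRecord]:
    """Seeded library of parent/hydroxylated/sulfated triads.

    Parents carry Henry's law constants that fall slowly with
    chlorination (lower congeners are the more volatile); metabolites
    rely on the air/water PP-LFER (hydroxylated) or are treated as
    involatile (sulfated).  ``jitter_sd`` perturbs descriptors around
    the class trends without breaking their ordering.
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    records: List[CompoundRecord] = []
    for i in range(n_per_class):
        n_cl = _NCL_PANEL[i] if i < len(_NCL_PANEL) else (i % 4) + 1
        parent_jitter = rng.normal(0.0, jitter_sd, size=6)
        for compound_class in ("parent", "hydroxylated", "sulfated"):
            prefix = _CLASS_PREFIX[compound_class]
            henry = None
            if compound_class == "parent":
                henry = HenryConstant(
                    h_ref=float(32.0 - 3.0 * n_cl + rng.normal(0.0, 0.5)),
                    t_ref=298.15,
                    delta_u_aw=55_000.0,
                )
            records.append(CompoundRecord(
                id=f"{prefix}_{n_cl}cl_{i + 1:02d}",
                name=f"{compound_class} ({n_cl} Cl, #{i + 1})",
                compound_class=compound_class,
                n_cl=n_cl,
                descriptors=_descriptor_values(compound_class, n_cl, parent_jitter),
                henry=henry,
            ))
    return records


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one end-to-end run needs, ready to write or analyse."""

    scenario: SimulationScenario
    compounds: List[CompoundRecord]
    plates: List[PlateReading]
    geometry: SystemGeometry


def default_truths(compounds: Sequence[CompoundRecord]) -> Tuple[CompoundTruth, ...]:
    """Plausible ground-truth potencies for a generated library.

    Potency rises with chlorination; hydroxylated metabolites are the
    most potent class and sulfates are essentially non-toxic within the
    tested range (true IC50 far above the top concentration).
    """
    parent_ic50 = {1: 200.0, 2: 150.0, 3: 10.0, 4: 8.8}
    oh_ic50 = {1: 21.4, 2: 13.0, 3: 5.3, 4: 2.2}
    truths = []
    for rec in compounds:
        if rec.compound_class == "parent":
            ic50 = parent_ic50.get(rec.n_cl, 100.0)
        elif rec.compound_class == "hydroxylated":
            ic50 = oh_ic50.get(rec.n_cl, 15.0)
        else:
            ic50 = 200.0 if rec.n_cl < 4 else 8.4
        truths.append(CompoundTruth(
            id=rec.id, compound_class=rec.compound_class, n_cl=rec.n_cl,
            top=100.0, bottom=0.0, hill=-1.2, ic50_um=ic50,
        ))
    return tuple(truths)


def default_scenario(seed: int, assay: str = "MTT") -> SimulationScenario:
    """Study-design scenario over the packaged fixture library."""
    compounds = pcb_io.default_library()
    return SimulationScenario(
        seed=seed, compounds=default_truths(compounds), assay=assay,
    )


def generate_study(
    scenario: SimulationScenario,
    out_dir: Optional[Path] = None,
) -> StudyBundle:
    """Compose library + plates + geometry into a ready-to-run input set.

    When the scenario's compound ids match the packaged fixture library
    those records are used; otherwise a fresh library is generated from
    the scenario seed.  With ``out_dir`` set, the bundle is written in
    the package's interchange formats (compounds.csv, plates.csv,
    geometry.yaml).
    """
    fixture = {rec.id: rec for rec in pcb_io.default_library()}
    if all(t.id in fixture for t in scenario.compounds):
        compounds = [fixture[t.id] for t in scenario.compounds]
    else:
        per_class = max(1, sum(1 for t in scenario.compounds
                               if t.compound_class == "parent"))
        compounds = generate_compound_library(scenario.seed, n_per_class=per_class)
    plates = generate_plate(scenario)
    geometry = pcb_io.default_geometry()
    bundle = StudyBundle(
        scenario=scenario, compounds=compounds, plates=plates, geometry=geometry,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pcb_io.write_compound_table(compounds, out_dir / "compounds.csv")
        pcb_io.write_plate_table(plates, out_dir / "plates.csv")
        pcb_io.write_geometry(geometry, out_dir / "geometry.yaml")
    return bundle
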