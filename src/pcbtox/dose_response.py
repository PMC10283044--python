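"""Plate normalization, four-parameter logistic IC50 fitting, group comparison.

The workflow mirrors a standard in-vitro cytotoxicity screen:

1. MTT viability plates are blank-handled (A570 - A650) and expressed as
   percent of the mean DMSO vehicle-control signal.
2. LDH release plates are expressed as percent cytotoxicity between the
   plate's low (spontaneous release) and high (full lysis) controls.
3. Per compound, a four-parameter logistic (4PL) is fitted on log10
   concentration and the IC50 is reported, censored as ">max" when the
   half-effect lies beyond the tested range.
4. Two cell models (e.g. male vs female primary astrocytes) are compared
   per concentration with an exact two-sided rank-sum test and Holm
   step-down multiplicity adjustment.

Technical replicates are averaged within each biological replicate
before fitting or testing, so the biological replicate is the unit of
analysis throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DataQualityError,
    InsufficientDataError,
    NormalizationError,
    ValidationError,
)

CONTROL_TREATMENT = "DMSO"
LDH_LOW_CONTROL = "low_control"
LDH_HIGH_CONTROL = "high_control"

_WELL_COLUMNS = [
    "row", "col", "treatment", "conc_um", "bio_rep", "tech_rep",
    "signal", "signal_ref",
]


@dataclass
class PlateReading:
    """One plate's raw wells in long format.

    ``wells`` columns: row, col, treatment, conc_um, bio_rep, tech_rep,
    signal, signal_ref (NaN where the assay has no reference
    wavelength).  MTT plates need DMSO vehicle wells; LDH plates need
    designated low- and high-control wells.
    """

    plate_id: str
    assay: str
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in ("MTT", "LDH"):
            raise ValidationError(f"assay must be MTT or LDH, got {self.assay!r}")
        missing = [c for c in _WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"plate {self.plate_id!r} lacks columns {missing}")
        if (self.wells["conc_um"] < 0).any():
            raise ValidationError(f"plate {self.plate_id!r} has negative concentrations")


@dataclass
class DoseResponseDataset:
    """Normalized responses for one compound in one cell model.

    ``points`` columns: conc_um, response_pct, bio_rep — one row per
    biological replicate per concentration (technical replicates already
    averaged).
    """

    compound_id: str
    assay: str
    points: pd.DataFrame
    cell_model: str = ""

    def concentrations(self) -> np.ndarray:
        return np.sort(self.points["conc_um"].unique())


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic with censoring status.

    Model: y = bottom + (top - bottom) / (1 + 10**(hill*(log10_ic50 - log10 x))).
    ``censored`` means the half-effect concentration is not identified
    within the tested range; ``censor_bound`` is the highest tested
    concentration.
    """

    top: float
    bottom: float
    hill: float
    log10_ic50: float
    ic50: float
    converged: bool
    censored: bool
    censor_bound: float
    rss: float
    n_points: int


@dataclass
class IC50Report:
    """Display form of an IC50: numeric, or '>bound' when censored."""

    display: str
    comparator: str  # "=" or ">"
    value: float
    approximate: bool


@dataclass
class GroupComparisonResult:
    """Per-concentration exact-test table for a two-group comparison.

    ``table`` columns: conc_um, statistic, p_raw, p_adj, n_a, n_b,
    significant.
    """

    table: pd.DataFrame
    method: str
    adjustment: str
    alpha: float


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _aggregate(points: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within biological replicate."""
    out = (
        points.groupby(["conc_um", "bio_rep"], as_index=False)["response_pct"]
        .mean()
        .sort_values(["conc_um", "bio_rep"], kind="stable")
        .reset_index(drop=True)
    )
    return out[["conc_um", "response_pct", "bio_rep"]]


def mtt_percent_viability(
    plate: PlateReading, cell_model: str = ""
) -> Dict[str, DoseResponseDataset]:
    """Percent viability relative to the DMSO vehicle controls.

    Blank handling subtracts the reference absorbance (650 nm) from the
    primary one (570 nm) per well; each treated well is then 100 times
    its corrected signal over the mean corrected control signal.
    Returns one dataset per treated compound on the plate.
    """
    if plate.assay != "MTT":
        raise ValidationError(f"expected an MTT plate, got {plate.assay}")
    wells = plate.wells.copy()
    ref = wells["signal_ref"].fillna(0.0)
    wells["corrected"] = wells["signal"] - ref

    controls = wells[wells["treatment"] == CONTROL_TREATMENT]
    if controls.empty:
        raise NormalizationError(
            f"plate {plate.plate_id!r} has no {CONTROL_TREATMENT} control wells"
        )
    control_mean = float(controls["corrected"].mean())
    if control_mean <= 0:
        raise DataQualityError(
            f"plate {plate.plate_id!r}: control mean {control_mean:.4g} is not positive"
        )

    treated = wells[wells["treatment"] != CONTROL_TREATMENT].copy()
    treated["response_pct"] = 100.0 * treated["corrected"] / control_mean
    out: Dict[str, DoseResponseDataset] = {}
    for treatment, grp in treated.groupby("treatment", sort=True):
        out[str(treatment)] = DoseResponseDataset(
            compound_id=str(treatment),
            assay="MTT",
            points=_aggregate(grp),
            cell_model=cell_model,
        )
    return out


def ldh_percent_cytotoxicity(
    plate: PlateReading, cell_model: str = ""
) -> Dict[str, DoseResponseDataset]:
    """Percent cytotoxicity between the plate's low and high controls."""
    if plate.assay != "LDH":
        raise ValidationError(f"expected an LDH plate, got {plate.assay}")
    wells = plate.wells
    low = wells[wells["treatment"] == LDH_LOW_CONTROL]["signal"]
    high = wells[wells["treatment"] == LDH_HIGH_CONTROL]["signal"]
    if low.empty or high.empty:
        raise NormalizationError(
            f"plate {plate.plate_id!r} lacks low/high LDH control wells"
        )
    low_mean, high_mean = float(low.mean()), float(high.mean())
    if high_mean <= low_mean:
        raise DataQualityError(
            f"plate {plate.plate_id!r}: high control ({high_mean:.4g}) must exceed "
            f"low control ({low_mean:.4g})"
        )
    treated = wells[
        ~wells["treatment"].isin([LDH_LOW_CONTROL, LDH_HIGH_CONTROL, CONTROL_TREATMENT])
    ].copy()
    treated["response_pct"] = (
        100.0 * (treated["signal"] - low_mean) / (high_mean - low_mean)
    )
    out: Dict[str, DoseResponseDataset] = {}
    for treatment, grp in treated.groupby("treatment", sort=True):
        out[str(treatment)] = DoseResponseDataset(
            compound_id=str(treatment),
            assay="LDH",
            points=_aggregate(grp),
            cell_model=cell_model,
        )
    return out


# ---------------------------------------------------------------------------
# Four-parameter logistic fitting
# ---------------------------------------------------------------------------

def four_pl(logx: np.ndarray, top: float, bottom: float, hill: float,
            log10_ic50: float) -> np.ndarray:
    """4PL response at log10 concentration ``logx``."""
    z = np.clip(hill * (log10_ic50 - np.asarray(logx, dtype=float)), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** z)


def _fit_starts(logx: np.ndarray) -> list:
    """Deterministic multi-start grid over (log10_ic50, hill)."""
    centers = np.linspace(logx.min() - 0.5, logx.max() + 0.5, 7)
    hills = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)
    return [(c, h) for c in centers for h in hills]


def fit_four_pl(
    data: DoseResponseDataset,
    bottom_min: float = 0.0,
    top_init: float = 100.0,
) -> FourPLFit:
    """Least-squares 4PL fit on log10 concentration with multi-start.

    The vehicle control (concentration 0) is excluded — it anchors the
    normalization, not the curve.  ``bottom`` is constrained to be
    non-negative; the hill slope is unconstrained.  A fit that cannot
    place the half-effect inside the tested range (or shows no response
    at all) is flagged censored rather than raising.
    """
    pts = data.points[data.points["conc_um"] > 0]
    x = pts["conc_um"].to_numpy(dtype=float)
    y = pts["response_pct"].to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise InsufficientDataError(
            f"{data.compound_id!r}: need >= 4 distinct positive concentrations, "
            f"got {np.unique(x).size}"
        )
    logx = np.log10(x)
    bound = float(x.max())
    # both plateaus are bounded below (a viability/cytotoxicity percent
    # cannot be negative); the hill slope and midpoint are free.
    lo = np.array([bottom_min, bottom_min, -np.inf, logx.min() - 3.0])
    hi = np.array([np.inf, np.inf, np.inf, logx.max() + 3.0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return four_pl(logx, *p) - y

    best = None
    for lc, h in _fit_starts(logx):
        p0 = np.array([top_init, max(bottom_min, float(y.min())), h, lc])
        p0[3] = np.clip(p0[3], lo[3], hi[3])
        try:
            res = optimize.least_squares(
                residuals, p0, bounds=(lo, hi), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.all(np.isfinite(best.x)):
        return FourPLFit(
            top=math.nan, bottom=math.nan, hill=math.nan, log10_ic50=math.nan,
            ic50=math.nan, converged=False, censored=True, censor_bound=bound,
            rss=math.nan, n_points=len(y),
        )
    top, bottom, hill, log_ic50 = (float(v) for v in best.x)
    if top < bottom:
        # the 4PL is invariant under (top, bottom, hill) -> (bottom, top,
        # -hill); report the canonical orientation.
        top, bottom, hill = bottom, top, -hill
    ic50 = 10.0 ** log_ic50
    rss = float(2.0 * best.cost)
    converged = bool(best.success)

    # Censor when the half-effect concentration is not resolved inside
    # the tested range: either the fitted midpoint lies beyond the top
    # concentration, or the curve never crosses the absolute 50% level
    # within the range (the ">max" convention for compounds whose
    # response never reaches half-effect).
    ends = four_pl(np.array([logx.min(), logx.max()]), top, bottom, hill, log_ic50)
    crosses_half = float(ends.min()) <= 50.0 <= float(ends.max())
    censored = (not converged) or (ic50 > bound) or (not crosses_half)
    return FourPLFit(
        top=top, bottom=bottom, hill=hill, log10_ic50=log_ic50, ic50=ic50,
        converged=converged, censored=censored, censor_bound=bound,
        rss=rss, n_points=len(y),
    )


def report_ic50(fit: FourPLFit, max_tested: float) -> IC50Report:
    """Display value for an IC50: numeric when resolved, '>max' when not.

    Convergence is 'marginal' (approximate) when the residual spread is
    large relative to the fitted dynamic range.
    """
    censored = fit.censored or (not fit.converged) or not math.isfinite(fit.ic50) \
        or fit.ic50 > max_tested
    if censored:
        return IC50Report(
            display=f">{max_tested:g}", comparator=">", value=float(max_tested),
            approximate=not fit.converged,
        )
    effect = abs(fit.top - fit.bottom)
    rms = math.sqrt(fit.rss / max(fit.n_points, 1))
    approximate = effect > 0 and (rms / effect) > 0.25
    return IC50Report(
        display=f"{fit.ic50:.3g}", comparator="=", value=float(fit.ic50),
        approximate=approximate,
    )


# ---------------------------------------------------------------------------
# Exact rank-sum comparison
# ---------------------------------------------------------------------------

_MAX_EXACT_N = 9  # per group; C(18, 9) = 48620 assignments


def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Exact two-sided rank-sum p-value via complete enumeration.

    Ties get mid-ranks; the null distribution enumerates every
    assignment of the pooled mid-ranks to group A.  Two-sided p is the
    fraction of assignments whose rank sum deviates from its null mean
    at least as much as the observed one.  Falls back to the normal
    approximation beyond 9 per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0

    if max(n1, n2) > _MAX_EXACT_N:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return w_obs, float(p)

    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return w_obs, count / total


def compare_groups(
    a: DoseResponseDataset,
    b: DoseResponseDataset,
    alpha: float = 0.05,
    adjustment: str = "holm",
    min_replicates: int = 3,
) -> GroupComparisonResult:
    """Per-concentration exact rank-sum comparison of two cell models.

    Both datasets must share the positive concentration grid; each
    concentration needs at least ``min_replicates`` biological
    replicates per group.  Raw p-values are adjusted across the grid
    (Holm step-down by default).
    """
    grid_a = a.concentrations()
    grid_b = b.concentrations()
    grid_a = grid_a[grid_a > 0]
    grid_b = grid_b[grid_b > 0]
    if not np.array_equal(grid_a, grid_b):
        raise ValidationError(
            f"concentration grids differ: {grid_a.tolist()} vs {grid_b.tolist()}"
        )
    rows = []
    for conc in grid_a:
        va = a.points.loc[a.points["conc_um"] == conc, "response_pct"].to_numpy()
        vb = b.points.loc[b.points["conc_um"] == conc, "response_pct"].to_numpy()
        if len(va) < min_replicates or len(vb) < min_replicates:
            raise ValidationError(
                f"concentration {conc}: need >= {min_replicates} biological "
                f"replicates per group, got {len(va)} and {len(vb)}"
            )
        statistic, p = exact_rank_sum_p(va, vb)
        rows.append({
            "conc_um": float(conc), "statistic": statistic, "p_raw": p,
            "n_a": len(va), "n_b": len(vb),
        })
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method=adjustment)
    table["p_adj"] = p_adj
    table["significant"] = reject
    table = table[["conc_um", "statistic", "p_raw", "p_adj", "n_a", "n_b", "significant"]]
    return GroupComparisonResult(
        table=table, method="exact rank-sum (enumeration)",
        adjustment=adjustment, alpha=alpha,
    )
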