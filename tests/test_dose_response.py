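"""Plate normalization, 4PL fitting with censoring, exact group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls

from pcbtox.dose_response import (
    CONTROL_TREATMENT,
    LDH_HIGH_CONTROL,
    LDH_LOW_CONTROL,
    DoseResponseDataset,
    FourPLFit,
    PlateReading,
    compare_groups,
    exact_rank_sum_p,
    fit_four_pl,
    four_pl,
    ldh_percent_cytotoxicity,
    mtt_percent_viability,
    report_ic50,
)
from pcbtox.errors import (
    DataQualityError,
    InsufficientDataError,
    NormalizationError,
    ValidationError,
)

STUDY_CONCS = (0.5, 1.0, 5.0, 10.0, 20.0, 50.0)


def make_mtt_plate(control_signals, treated, blank=0.05, plate_id="p1"):
    """treated: list of (treatment, conc, bio, tech, corrected_signal)."""
    rows = []
    for i, s in enumerate(control_signals):
        rows.append(dict(row="A", col=i + 1, treatment=CONTROL_TREATMENT,
                         conc_um=0.0, bio_rep=1, tech_rep=i + 1,
                         signal=s + blank, signal_ref=blank))
    for j, (treatment, conc, bio, tech, s) in enumerate(treated):
        rows.append(dict(row="B", col=j + 1, treatment=treatment, conc_um=conc,
                         bio_rep=bio, tech_rep=tech, signal=s + blank,
                         signal_ref=blank))
    return PlateReading(plate_id=plate_id, assay="MTT", wells=pd.DataFrame(rows))


def dataset_from_curve(top, bottom, hill, ic50, concs=STUDY_CONCS, n_bio=3):
    rows = []
    for conc in concs:
        y = float(four_pl(np.log10(conc), top, bottom, hill, np.log10(ic50)))
        for bio in range(1, n_bio + 1):
            rows.append({"conc_um": conc, "response_pct": y, "bio_rep": bio})
    return DoseResponseDataset(compound_id="c", assay="MTT",
                               points=pd.DataFrame(rows))


class TestMTTNormalization:
    def test_treated_equals_control_mean_gives_100(self):
        plate = make_mtt_plate([0.5, 0.5], [("cmp", 1.0, 1, 1, 0.5)])
        ds = mtt_percent_viability(plate)["cmp"]
        assert ds.points["response_pct"].iloc[0] == pytest.approx(100.0)

    def test_dead_well_gives_zero(self):
        plate = make_mtt_plate([0.5], [("cmp", 1.0, 1, 1, 0.0)])
        ds = mtt_percent_viability(plate)["cmp"]
        assert ds.points["response_pct"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_half_signal(self):
        # controls 0.50/0.55/0.45 AU -> mean 0.50; treated 0.25 -> 50%
        plate = make_mtt_plate([0.50, 0.55, 0.45], [("cmp", 5.0, 1, 1, 0.25)])
        ds = mtt_percent_viability(plate)["cmp"]
        assert ds.points["response_pct"].iloc[0] == pytest.approx(50.0)

    def test_technical_replicates_averaged_within_biological(self):
        plate = make_mtt_plate(
            [0.5],
            [("cmp", 1.0, 1, 1, 0.2), ("cmp", 1.0, 1, 2, 0.3),
             ("cmp", 1.0, 2, 1, 0.5)],
        )
        pts = mtt_percent_viability(plate)["cmp"].points
        assert len(pts) == 2  # one row per biological replicate
        assert pts.loc[pts["bio_rep"] == 1, "response_pct"].iloc[0] == pytest.approx(50.0)
        assert pts.loc[pts["bio_rep"] == 2, "response_pct"].iloc[0] == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 100))
    def test_scaling_all_signals_leaves_percentages_unchanged(self, scale):
        treated = [("cmp", c, 1, 1, 0.1 * i + 0.05) for i, c in enumerate(STUDY_CONCS, 1)]
        p1 = make_mtt_plate([0.5, 0.6], treated, blank=0.0)
        scaled = [(t, c, b, k, s * scale) for t, c, b, k, s in treated]
        p2 = make_mtt_plate([0.5 * scale, 0.6 * scale], scaled, blank=0.0)
        r1 = mtt_percent_viability(p1)["cmp"].points["response_pct"]
        r2 = mtt_percent_viability(p2)["cmp"].points["response_pct"]
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_missing_controls_raise_normalization_error(self):
        plate = make_mtt_plate([], [("cmp", 1.0, 1, 1, 0.3)])
        with pytest.raises(NormalizationError):
            mtt_percent_viability(plate)

    def test_negative_control_mean_is_data_quality_error(self):
        plate = make_mtt_plate([-0.5], [("cmp", 1.0, 1, 1, 0.3)])
        with pytest.raises(DataQualityError):
            mtt_percent_viability(plate)


class TestLDHNormalization:
    def _plate(self, signals):
        rows = []
        for i, s in enumerate([0.1, 0.1]):
            rows.append(dict(row="A", col=i + 1, treatment=LDH_LOW_CONTROL,
                             conc_um=0.0, bio_rep=1, tech_rep=i + 1,
                             signal=s, signal_ref=np.nan))
        for i, s in enumerate([1.1, 1.1]):
            rows.append(dict(row="B", col=i + 1, treatment=LDH_HIGH_CONTROL,
                             conc_um=0.0, bio_rep=1, tech_rep=i + 1,
                             signal=s, signal_ref=np.nan))
        for i, s in enumerate(signals):
            rows.append(dict(row="C", col=i + 1, treatment="cmp", conc_um=1.0,
                             bio_rep=i + 1, tech_rep=1, signal=s,
                             signal_ref=np.nan))
        return PlateReading(plate_id="L1", assay="LDH", wells=pd.DataFrame(rows))

    def test_low_high_and_midpoint(self):
        ds = ldh_percent_cytotoxicity(self._plate([0.1, 1.1, 0.6]))["cmp"]
        assert np.allclose(sorted(ds.points["response_pct"]), [0.0, 50.0, 100.0])

    def test_inverted_controls_rejected(self):
        plate = self._plate([0.5])
        wells = plate.wells.copy()
        wells.loc[wells["treatment"] == LDH_HIGH_CONTROL, "signal"] = 0.05
        with pytest.raises(DataQualityError):
            ldh_percent_cytotoxicity(PlateReading("L1", "LDH", wells))


class TestFourPLFit:
    def test_noiseless_parameters_recovered_exactly(self):
        ds = dataset_from_curve(top=100.0, bottom=0.0, hill=-1.0, ic50=10.0)
        fit = fit_four_pl(ds)
        assert fit.converged and not fit.censored
        assert fit.top == pytest.approx(100.0, rel=1e-6, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.hill == pytest.approx(-1.0, rel=1e-6)
        assert fit.ic50 == pytest.approx(10.0, rel=1e-6)

    def test_flat_response_is_censored(self):
        rows = [{"conc_um": c, "response_pct": 100.0, "bio_rep": b}
                for c in STUDY_CONCS for b in (1, 2, 3)]
        ds = DoseResponseDataset("flat", "MTT", pd.DataFrame(rows))
        fit = fit_four_pl(ds)
        assert fit.censored
        assert fit.censor_bound == pytest.approx(50.0)

    def test_half_effect_beyond_range_is_censored(self):
        ds = dataset_from_curve(top=100.0, bottom=0.0, hill=-1.0, ic50=200.0)
        fit = fit_four_pl(ds)
        assert fit.censored

    def test_too_few_concentrations_rejected(self):
        ds = dataset_from_curve(100, 0, -1, 10, concs=(1.0, 10.0, 50.0))
        with pytest.raises(InsufficientDataError):
            fit_four_pl(ds)

    def test_noisy_fit_agrees_with_grid_search_oracle(self):
        """Multi-start least squares lands within one grid step of an
        exhaustive (log10 IC50, hill) search with profiled plateaus."""
        rng = np.random.default_rng(42)
        true = dict(top=100.0, bottom=0.0, hill=-1.2, ic50=8.8)
        rows = []
        for conc in STUDY_CONCS:
            y = float(four_pl(np.log10(conc), true["top"], true["bottom"],
                              true["hill"], np.log10(true["ic50"])))
            for bio in range(1, 4):
                rows.append({"conc_um": conc,
                             "response_pct": y * rng.lognormal(0, 0.1),
                             "bio_rep": bio})
        ds = DoseResponseDataset("c", "MTT", pd.DataFrame(rows))
        fit = fit_four_pl(ds)

        # independent oracle: dense grid, plateaus profiled linearly
        x = ds.points["conc_um"].to_numpy()
        y = ds.points["response_pct"].to_numpy()
        logx = np.log10(x)
        centers = np.arange(np.log10(0.5) - 1, np.log10(50.0) + 1, 0.02)
        hills = np.arange(-3.0, 3.01, 0.05)
        best = (np.inf, None)
        for lc in centers:
            for h in hills:
                if abs(h) < 1e-9:
                    continue
                theta = 1.0 / (1.0 + 10.0 ** (h * (lc - logx)))
                design = np.column_stack([theta, 1.0 - theta])
                # profile the plateaus under the same non-negativity floor
                # the fitter imposes
                coef, _ = nnls(design, y)
                sse = float(((design @ coef - y) ** 2).sum())
                if sse < best[0]:
                    best = (sse, lc)
        assert fit.log10_ic50 == pytest.approx(best[1], abs=0.02 + 1e-9)


class TestReportIC50:
    def _fit(self, ic50, censored=False, converged=True):
        return FourPLFit(top=100.0, bottom=0.0, hill=-1.0,
                         log10_ic50=np.log10(ic50), ic50=ic50,
                         converged=converged, censored=censored,
                         censor_bound=50.0, rss=1.0, n_points=18)

    def test_resolved_value_is_numeric(self):
        rep = report_ic50(self._fit(8.8), max_tested=50.0)
        assert rep.comparator == "="
        assert rep.display == "8.8"
        assert rep.value == pytest.approx(8.8)

    def test_value_beyond_range_reports_greater_than(self):
        rep = report_ic50(self._fit(72.0), max_tested=50.0)
        assert rep.comparator == ">"
        assert rep.display == ">50"
        assert rep.value == 50.0

    def test_non_converged_fit_is_censored_and_approximate(self):
        rep = report_ic50(self._fit(8.8, converged=False), max_tested=50.0)
        assert rep.display == ">50"
        assert rep.approximate


class TestExactRankSum:
    def test_identical_samples_give_p_one(self):
        _, p = exact_rank_sum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        # only 2 of the C(6,3)=20 assignments are as extreme -> p = 0.1
        _, p = exact_rank_sum_p([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)

    def test_matches_brute_force_enumeration_with_ties(self):
        """Mid-rank enumeration agrees with a from-scratch permutation count."""
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 4.0])
        _, p = exact_rank_sum_p(x, y)
        from scipy.stats import rankdata
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        mu = len(x) * (len(pooled) + 1) / 2
        obs = abs(ranks[: len(x)].sum() - mu)
        count = sum(
            1 for idx in itertools.combinations(range(len(pooled)), len(x))
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9
        )
        assert p == pytest.approx(count / 70)


class TestCompareGroups:
    def _dataset(self, values_by_conc, label):
        rows = [{"conc_um": c, "response_pct": v, "bio_rep": i + 1}
                for c, values in values_by_conc.items()
                for i, v in enumerate(values)]
        return DoseResponseDataset("cmp", "MTT", pd.DataFrame(rows),
                                   cell_model=label)

    def test_identical_groups_are_never_significant(self):
        data = {c: [90.0, 95.0, 100.0] for c in STUDY_CONCS}
        result = compare_groups(self._dataset(data, "m"), self._dataset(data, "f"))
        assert (result.table["p_adj"] == 1.0).all()
        assert not result.table["significant"].any()

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(3)
        a = {c: list(rng.normal(100, 5, 3)) for c in STUDY_CONCS}
        b = {c: list(rng.normal(80, 5, 3)) for c in STUDY_CONCS}
        result = compare_groups(self._dataset(a, "m"), self._dataset(b, "f"))
        assert (result.table["p_adj"] >= result.table["p_raw"] - 1e-12).all()

    def test_single_extreme_concentration_survives_adjustment_as_nonsignificant(self):
        """One separated concentration among six: raw p = 0.1 is already
        above alpha, and Holm adjustment only raises it."""
        a = {c: [90.0, 95.0, 100.0] for c in STUDY_CONCS}
        b = {c: [90.0, 95.0, 100.0] for c in STUDY_CONCS}
        b[50.0] = [10.0, 12.0, 14.0]
        a[50.0] = [90.0, 95.0, 100.0]
        result = compare_groups(self._dataset(a, "m"), self._dataset(b, "f"))
        row = result.table[result.table["conc_um"] == 50.0].iloc[0]
        assert row["p_raw"] == pytest.approx(0.1)
        assert row["p_adj"] >= row["p_raw"]
        assert not row["significant"]

    def test_mismatched_grids_rejected(self):
        a = self._dataset({c: [1.0, 2.0, 3.0] for c in (1.0, 5.0)}, "m")
        b = self._dataset({c: [1.0, 2.0, 3.0] for c in (1.0, 10.0)}, "f")
        with pytest.raises(ValidationError):
            compare_groups(a, b)
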