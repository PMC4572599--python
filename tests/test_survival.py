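"""Survival analytics: SF, ratios, LQ fits, loading arithmetic, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexdef import survival
from lexdef.errors import (AlignmentError, DegenerateInputError, FitError,
                           ValidationError)
from lexdef.survival import (SurvivalCurve, atoms_per_cell, compare_groups,
                             fit_lq, holm_adjust, sf_ratio,
                             surviving_fraction)


def records_from_counts(doses, colonies_by_rep, cells=500):
    rows = []
    for d, reps in zip(doses, colonies_by_rep):
        for i, c in enumerate(reps):
            rows.append(("F98", "typ_pt", 0.0, "160kV", d, cells, c, i))
    return pd.DataFrame(rows, columns=list(survival.RECORD_COLUMNS))


def lq_curve(alpha, beta, doses=(0.0, 1.0, 2.5, 5.0, 10.0, 15.0)):
    d = np.array(doses)
    sf = np.exp(-(alpha * d + beta * d**2))
    return SurvivalCurve(index_name="dose_gy", index=d, sf=sf,
                         sd=np.zeros_like(d), n=np.full(len(d), 3))


class TestSurvivingFraction:
    def test_reference_condition_is_unity(self):
        rec = records_from_counts([0.0, 2.0], [(100, 110, 90), (50, 55, 45)])
        curve = surviving_fraction(rec, reference={"dose_gy": 0.0})
        assert curve.sf[0] == pytest.approx(1.0)

    def test_condition_identical_to_reference_gives_unity(self):
        rec = records_from_counts([0.0, 2.0], [(100, 100, 100),
                                               (100, 100, 100)])
        curve = surviving_fraction(rec, reference={"dose_gy": 0.0})
        assert curve.sf[1] == pytest.approx(1.0)

    def test_zero_reference_colonies_raise(self):
        rec = records_from_counts([0.0, 2.0], [(0, 0, 0), (10, 12, 8)])
        with pytest.raises(DegenerateInputError):
            surviving_fraction(rec, reference={"dose_gy": 0.0})

    def test_known_sf_recovered_within_sampling_error(self):
        rng = np.random.default_rng(1)
        ref = rng.poisson(200.0, 3)
        treated = rng.poisson(50.0, 3)     # true SF 0.25
        rec = records_from_counts([0.0, 5.0], [tuple(ref), tuple(treated)])
        curve = surviving_fraction(rec, reference={"dose_gy": 0.0})
        sd = max(curve.sd[1], 0.02)
        assert abs(curve.sf[1] - 0.25) < 3 * sd


class TestSFRatio:
    def test_identical_curves_ratio_one(self):
        c = lq_curve(0.2, 0.02)
        series = sf_ratio(c, c)
        np.testing.assert_allclose(series.ratio, 1.0)

    def test_one_log_unit_gives_ratio_ten(self):
        a = lq_curve(0.2, 0.02)
        b = SurvivalCurve(index_name="dose_gy", index=a.index,
                          sf=a.sf / 10.0, sd=np.zeros_like(a.sf),
                          n=np.full(len(a.sf), 3))
        np.testing.assert_allclose(sf_ratio(a, b).ratio, 10.0)

    def test_dose_grid_mismatch_raises(self):
        a = lq_curve(0.2, 0.02, doses=(0.0, 1.0, 2.0))
        b = lq_curve(0.2, 0.02, doses=(0.0, 1.0, 3.0))
        with pytest.raises(AlignmentError):
            sf_ratio(a, b)

    def test_log_ratio_matches_lq_parameter_difference(self):
        # consistency of the enhancement series with the generating LQ pair
        a1, b1, a2, b2 = 0.15, 0.01, 0.30, 0.025
        series = sf_ratio(lq_curve(a1, b1), lq_curve(a2, b2))
        d = series.doses
        expect = (a2 - a1) * d + (b2 - b1) * d**2
        np.testing.assert_allclose(np.log(series.ratio), expect, atol=1e-10)


class TestLQFit:
    def test_noise_free_exact_recovery(self):
        fit = fit_lq(lq_curve(0.2, 0.02))
        assert fit.alpha == pytest.approx(0.2, abs=1e-9)
        assert fit.beta == pytest.approx(0.02, abs=1e-9)

    def test_pure_exponential_hits_beta_boundary(self):
        fit = fit_lq(lq_curve(0.3, 0.0))
        assert fit.beta == pytest.approx(0.0, abs=1e-9)
        assert fit.alpha == pytest.approx(0.3, abs=1e-9)

    def test_singular_design_raises(self):
        with pytest.raises(FitError):
            fit_lq(lq_curve(0.2, 0.02, doses=(0.0, 5.0)))

    def test_prediction_at_zero_dose_is_one(self):
        fit = fit_lq(lq_curve(0.2, 0.02))
        assert fit.predict_sf(0.0) == pytest.approx(1.0)


class TestAtomsPerCell:
    @pytest.mark.parametrize("conc,mw,expected", [
        (2.0, 631.4, "1.91e+06"),     # Typ-Pt at 2 ug/ml
        (1.0, 371.2, "1.62e+06"),     # carboplatin at 1 ug/ml
        (2.5, 371.2, "4.05e+06"),     # carboplatin at 2.5 ug/ml
    ])
    def test_worked_examples_to_three_significant_figures(self, conc, mw,
                                                          expected):
        loading = atoms_per_cell(conc, mw)
        assert f"{loading.atoms_per_cell:.3g}" == expected

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           mw=st.floats(min_value=10.0, max_value=1e4),
           scale=st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_concentration_and_inverse_mw(self, c, mw, scale):
        base = atoms_per_cell(c, mw).atoms_per_cell
        assert atoms_per_cell(scale * c, mw).atoms_per_cell == pytest.approx(
            scale * base, rel=1e-12)
        assert atoms_per_cell(c, scale * mw).atoms_per_cell == pytest.approx(
            base / scale, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            atoms_per_cell(0.0, 631.4)


class TestGroupComparisons:
    def test_holm_hand_oracle(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.04, 0.04])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=8))
    def test_holm_adjustment_is_monotone(self, pvals):
        p = np.array(pvals)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0 + 1e-12)

    def test_identical_groups_not_rejected(self):
        groups = {"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5],
                  "c": [0.4, 0.5, 0.6]}
        res = compare_groups(groups)
        for comp in res:
            if comp.label == "a vs b":
                assert comp.p_adjusted == pytest.approx(1.0)
                assert not comp.reject

    def test_three_group_family_uses_anova(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.lognormal(0.0, 0.1, 5) for k in "abc"}
        res = compare_groups(groups, comparisons=[("a", "b", "c")])
        assert len(res) == 1
        assert 0.0 <= res[0].p_raw <= 1.0

    def test_family_wise_error_controlled_under_null(self):
        # 400 simulated null families of 5 two-group comparisons
        rng = np.random.default_rng(3)
        fw_errors = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {k: rng.lognormal(0.0, 0.2, 3) for k in "abcde"}
            res = compare_groups(groups, comparisons=[
                ("a", "b"), ("a", "c"), ("a", "d"), ("a", "e"), ("b", "c")])
            fw_errors += any(c.reject for c in res)
        # binomial slack: 0.05 + 3 sigma at n = 400
        assert fw_errors / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)
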