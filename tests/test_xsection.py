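"""Cross-section tables: parsing, interpolation, mixtures, critical energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexdef import xsection
from lexdef.errors import (CrossoverNotFoundError, EnergyRangeError,
                           TableParseError, ValidationError)
from lexdef.xsection import (CrossSectionTable, critical_energy, load_material,
                             load_table, make_mixture, mu)


class TestLoading:
    def test_pt_edges_include_k_at_78_4(self, pt):
        edges = dict(pt.edges)
        assert edges["K"] == pytest.approx(78.4)

    def test_pt_has_an_l_edge_near_14_kev(self, pt):
        l_edges = [e for label, e in pt.edges if label.startswith("L")]
        assert any(abs(e - 14.0) < 1.5 for e in l_edges)

    def test_water_pair_component_zero_below_threshold(self, water):
        assert mu(water, 500.0, "pair") == 0.0

    def test_malformed_rows_raise_named_parse_errors(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("energy_keV\tpe\tcoherent\tincoherent\tpair\ttotal\n"
                       "10\t1\t0.1\t0.1\t0\t1.2\n"
                       "9\t1\t0.1\t0.1\t0\t1.2\n")
        with pytest.raises(TableParseError, match="decrease"):
            load_table(bad)
        bad.write_text("energy_keV\tpe\tcoherent\tincoherent\tpair\ttotal\n"
                       "10\t-1\t0.1\t0.1\t0\t1.2\n"
                       "20\t1\t0.1\t0.1\t0\t1.2\n")
        with pytest.raises(TableParseError, match="negative"):
            load_table(bad)


class TestMu:
    def test_tabulated_energy_returns_tabulated_value(self, water):
        # 60 keV is a grid row of the packaged water table
        row = np.where(water.energy == 60.0)[0][0]
        assert mu(water, 60.0, "total") == pytest.approx(
            water.total[row], rel=1e-12)

    def test_l_edge_total_near_190(self, pt):
        l1 = dict(pt.edges)["L1"]
        assert mu(pt, l1, "total") == pytest.approx(190.0, rel=0.10)

    def test_edge_query_returns_above_edge_branch(self, pt):
        above = mu(pt, 78.4, "pe")
        below = mu(pt, 78.4 * (1 - 1e-9), "pe")
        assert above > 2.0 * below          # K-edge jump factor > 2

    def test_out_of_range_raises(self, water):
        with pytest.raises(EnergyRangeError):
            mu(water, 7000.0)
        with pytest.raises(EnergyRangeError):
            mu(water, 5.0)

    def test_zero_concentration_mixture_equals_water(self, water):
        mix = make_mixture(0.0)
        for e in (15.0, 60.0, 500.0, 3000.0):
            assert mu(mix, e, "total") == pytest.approx(
                mu(water, e, "total"), rel=1e-12)

    def test_midpoint_interpolation_brackets_tabulated_values(self, water):
        for comp in ("pe", "coherent", "incoherent", "total"):
            vals = water.component(comp)
            for i in range(len(water.energy) - 1):
                e0, e1 = water.energy[i], water.energy[i + 1]
                if e0 == e1 or min(vals[i], vals[i + 1]) <= 0:
                    continue
                mid = mu(water, np.sqrt(e0 * e1), comp)
                lo, hi = sorted((vals[i], vals[i + 1]))
                assert lo <= mid * (1 + 1e-12) and mid <= hi * (1 + 1e-12)


class TestMixture:
    def test_weight_fractions_and_density(self):
        mix = make_mixture(7.0)
        w = dict((t.material_id, wf) for t, wf in mix.components)
        assert w["pt"] == pytest.approx(7.0 / 1007.0)
        assert mix.density == pytest.approx(1.007)
        assert make_mixture(1000.0).components[1][1] == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            make_mixture(-1.0)

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(min_value=0.0, max_value=500.0),
           e=st.floats(min_value=11.0, max_value=5000.0))
    def test_mixture_rule_linearity(self, c, e):
        water = load_material("water")
        pt = load_material("pt")
        mix = make_mixture(c, water=water, pt=pt)
        w_pt = c / (1000.0 + c)
        for comp in ("pe", "coherent", "incoherent", "pair", "total"):
            expect = (1 - w_pt) * mu(water, e, comp) + w_pt * mu(pt, e, comp)
            assert mu(mix, e, comp) == pytest.approx(expect, rel=1e-12,
                                                     abs=1e-300)


class TestCriticalEnergy:
    def test_pt_crossover_near_400_kev(self, pt):
        res = critical_energy(pt)
        assert res.e_c == pytest.approx(400.0, abs=50.0)
        assert res.pe_at_ec == pytest.approx(res.scatter_at_ec, rel=1e-3)

    def test_water_crossover_below_40_kev(self, water):
        assert critical_energy(water).e_c < 40.0

    def test_degenerate_tie_returns_first_grid_energy(self):
        e = np.array([10.0, 100.0, 1000.0])
        ones = np.ones(3)
        tab = CrossSectionTable(material_id="tie", energy=e, pe=ones,
                                coherent=0.5 * ones, incoherent=0.5 * ones,
                                pair=np.zeros(3), total=2.0 * ones)
        assert critical_energy(tab).e_c == pytest.approx(10.0)

    def test_no_crossover_raises(self):
        e = np.array([10.0, 100.0, 1000.0])
        ones = np.ones(3)
        tab = CrossSectionTable(material_id="pe_only", energy=e, pe=ones,
                                coherent=0.1 * ones, incoherent=0.1 * ones,
                                pair=np.zeros(3), total=1.2 * ones)
        with pytest.raises(CrossoverNotFoundError):
            critical_energy(tab)

    def test_pt_pe_share_of_total_decreases_above_k_edge(self, pt):
        grid = np.exp(np.linspace(np.log(80.0), np.log(5000.0), 60))
        share = mu(pt, grid, "pe") / mu(pt, grid, "total")
        assert np.all(np.diff(share) < 0)
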