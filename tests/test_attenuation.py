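"""Narrow-beam depth attenuation: oracles, channel bookkeeping, diagnostics."""

import numpy as np
import pytest

from lexdef import attenuation, spectra, xsection
from lexdef.attenuation import (PhantomSpec, integrated_attenuation,
                                pe_absorption_in_tumor, pe_enhancement_ratio,
                                water_transmission)
from lexdef.errors import DegenerateInputError, ValidationError


@pytest.fixture(scope="module")
def diagnostic_phantom():
    return PhantomSpec(tumor_interval=(10.0, 11.0), pt_mg_per_ml=7.0)


class TestPhantomSpec:
    def test_invalid_tumor_interval_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(tumor_interval=(12.0, 10.0))
        with pytest.raises(ValidationError):
            PhantomSpec(tumor_interval=(10.0, 16.0))

    def test_depth_bin_must_divide_depth(self):
        with pytest.raises(ValidationError):
            PhantomSpec(depth_bin=0.4)


class TestBeerLambertOracle:
    def test_monochromatic_profile_matches_closed_form(self, water):
        phantom = PhantomSpec(pt_mg_per_ml=0.0)
        for e in (40.0, 80.0, 500.0, 2000.0):
            prof = integrated_attenuation(spectra.monochromatic(e), phantom)
            mu_tot = xsection.mu(water, e, "total")
            expect = np.exp(-mu_tot * phantom.bin_edges()[1:])
            np.testing.assert_allclose(prof.transmitted_fraction, expect,
                                       rtol=1e-12)

    def test_depth_zero_transmission_is_one(self, spectrum_160kv):
        prof = integrated_attenuation(spectrum_160kv, PhantomSpec())
        assert prof.transmitted_at(0.0) == 1.0


class TestChannelBookkeeping:
    def test_channel_conservation_total_mode(self, spectrum_160kv,
                                             diagnostic_phantom):
        prof = integrated_attenuation(spectrum_160kv, diagnostic_phantom)
        removed = (prof.pe_water + prof.pe_pt + prof.scatter_removed).sum()
        assert removed + prof.transmitted_fraction[-1] == pytest.approx(
            1.0, abs=1e-9)

    def test_pe_only_removal_below_total(self, spectrum_160kv,
                                         diagnostic_phantom):
        tot = integrated_attenuation(spectrum_160kv, diagnostic_phantom,
                                     mode="total")
        pe = integrated_attenuation(spectrum_160kv, diagnostic_phantom,
                                    mode="pe_only")
        assert np.all(pe.transmitted_fraction
                      >= tot.transmitted_fraction - 1e-12)

    def test_transmission_monotone_nonincreasing(self, spectrum_6mv):
        prof = integrated_attenuation(spectrum_6mv, PhantomSpec())
        assert np.all(np.diff(prof.transmitted_fraction) <= 1e-15)

    def test_beam_hardening_with_depth(self, spectrum_160kv):
        prof = integrated_attenuation(spectrum_160kv, PhantomSpec())
        means = [prof.mean_transmitted_energy(i) for i in (0, 50, 100, 149)]
        assert np.all(np.diff(means) > 0)


class TestPenetrationFractions:
    def test_6mv_half_transmitted_at_10cm(self, spectrum_6mv):
        t = 100.0 * water_transmission(spectrum_6mv, 10.0)
        assert t == pytest.approx(50.0, abs=5.0)

    def test_160kv_about_18_percent_at_10cm(self, spectrum_160kv):
        t = 100.0 * water_transmission(spectrum_160kv, 10.0)
        assert t == pytest.approx(18.0, abs=4.0)


class TestPtPhotoabsorption:
    def test_zero_concentration_gives_zero(self, spectrum_160kv):
        phantom = PhantomSpec(tumor_interval=(10.0, 11.0), pt_mg_per_ml=0.0)
        assert pe_absorption_in_tumor(spectrum_160kv, phantom) == 0.0

    def test_monotone_in_concentration(self, spectrum_160kv):
        vals = [pe_absorption_in_tumor(
            spectrum_160kv,
            PhantomSpec(tumor_interval=(10.0, 11.0), pt_mg_per_ml=c))
            for c in (1.0, 7.0)]
        assert vals[1] > vals[0]

    def test_6mv_concentrations_nearly_indistinguishable(self, spectrum_6mv):
        # high-energy photons barely notice the Pt load
        v1, v7 = [pe_absorption_in_tumor(
            spectrum_6mv,
            PhantomSpec(tumor_interval=(10.0, 11.0), pt_mg_per_ml=c))
            for c in (1.0, 7.0)]
        assert abs(v7 - v1) < 0.002

    def test_identical_spectra_ratio_is_one(self, spectrum_160kv,
                                            diagnostic_phantom):
        r = pe_enhancement_ratio(spectrum_160kv, spectrum_160kv,
                                 diagnostic_phantom, 1.0, 7.0)
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_concentrations_raise(self, spectrum_160kv,
                                             spectrum_6mv,
                                             diagnostic_phantom):
        with pytest.raises(DegenerateInputError):
            pe_enhancement_ratio(spectrum_160kv, spectrum_6mv,
                                 diagnostic_phantom, 7.0, 7.0)

    def test_lex_pe_advantage_an_order_of_magnitude(self, spectrum_160kv,
                                                    spectrum_6mv,
                                                    diagnostic_phantom):
        r = pe_enhancement_ratio(spectrum_160kv, spectrum_6mv,
                                 diagnostic_phantom, 1.0, 7.0)
        assert r > 10.0
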