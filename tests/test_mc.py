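"""Monte Carlo transport: conservation, samplers, DEF behaviour."""

import numpy as np
import pytest
from scipy import integrate, stats

from lexdef import mc, spectra, xsection
from lexdef.attenuation import PhantomSpec
from lexdef.mc import TransportConfig, sample_klein_nishina


def kn_mean_scattered_fraction(energy_kev: float) -> float:
    """Quadrature oracle: fluence-weighted mean eps of the KN distribution."""
    k = energy_kev / 511.0
    eps0 = 1.0 / (1.0 + 2.0 * k)

    def pdf(eps):
        cos_t = 1.0 - (1.0 - eps) / (k * eps)
        sin2 = 1.0 - cos_t**2
        return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))

    norm, _ = integrate.quad(pdf, eps0, 1.0)
    first, _ = integrate.quad(lambda e: e * pdf(e), eps0, 1.0)
    return first / norm


class TestSamplers:
    def test_klein_nishina_mean_matches_quadrature_at_511(self):
        rng = np.random.default_rng(7)
        eps = sample_klein_nishina(rng, np.full(200_000, 511.0))
        assert eps.mean() == pytest.approx(
            kn_mean_scattered_fraction(511.0), rel=0.005)

    @pytest.mark.parametrize("energy", [60.0, 2000.0])
    def test_klein_nishina_mean_other_energies(self, energy):
        rng = np.random.default_rng(11)
        eps = sample_klein_nishina(rng, np.full(100_000, energy))
        assert eps.mean() == pytest.approx(
            kn_mean_scattered_fraction(energy), rel=0.01)

    def test_scattered_fraction_within_kinematic_limits(self):
        rng = np.random.default_rng(3)
        e = np.full(10_000, 300.0)
        eps = sample_klein_nishina(rng, e)
        eps0 = 1.0 / (1.0 + 2.0 * 300.0 / 511.0)
        assert np.all((eps >= eps0) & (eps <= 1.0))


class TestTransport:
    def test_energy_conservation(self, phantom_7mg):
        for label, spec in (("80keV", spectra.monochromatic(80.0)),
                            ("6MV", spectra.linac_spectrum(6))):
            prof = mc.transport(spec, phantom_7mg,
                                TransportConfig(n_photons=30_000, seed=5))
            total = prof.energy_per_photon.sum() + prof.escaped_energy
            assert total == pytest.approx(prof.incident_energy, rel=1e-6), label

    def test_reproducibility_bit_identical(self, phantom_7mg):
        cfg = TransportConfig(n_photons=20_000, seed=42)
        spec = spectra.monochromatic(100.0)
        p1 = mc.transport(spec, phantom_7mg, cfg)
        p2 = mc.transport(spec, phantom_7mg, cfg)
        np.testing.assert_array_equal(p1.energy_per_photon,
                                      p2.energy_per_photon)
        np.testing.assert_array_equal(p1.stderr, p2.stderr)

    def test_first_interaction_depths_follow_exponential_law(self, water):
        phantom = PhantomSpec(pt_mg_per_ml=0.0)
        e = 100.0
        prof = mc.transport(spectra.monochromatic(e), phantom,
                            TransportConfig(n_photons=300_000, seed=9))
        counts = prof.first_collision_counts
        mu_lin = xsection.mu(water, e, "total")  # rho = 1
        # exponential law: fit the log-slope of the first-collision histogram
        zmax = 8.0
        sel = (phantom.depths < zmax) & (counts > 50)
        slope = np.polyfit(phantom.depths[sel], np.log(counts[sel]), 1)[0]
        assert -slope == pytest.approx(mu_lin, rel=0.03)
        # and the total first-collision fraction matches 1 - exp(-mu L)
        frac = counts.sum() / prof.n_photons
        assert frac == pytest.approx(
            1.0 - np.exp(-mu_lin * phantom.total_depth), rel=0.01)

    def test_stderr_scales_as_inverse_sqrt_n(self, phantom_7mg):
        spec = spectra.monochromatic(80.0)
        v = []
        for n in (20_000, 200_000):
            prof = mc.transport(spec, phantom_7mg,
                                TransportConfig(n_photons=n, seed=13))
            sel = prof.energy_per_photon > 0
            v.append(float((prof.stderr[sel] ** 2).sum()))
        assert v[0] / v[1] == pytest.approx(10.0, rel=0.2)


class TestDEF:
    def test_def_unity_without_platinum(self):
        phantom = PhantomSpec(pt_mg_per_ml=0.0)
        res = mc.def_per_energy(80.0, phantom,
                                TransportConfig(n_photons=30_000, seed=21))
        # paired arms share the random stream, so the ratio is exactly 1
        assert res.def_tumor == pytest.approx(1.0, abs=3 * max(
            res.mc_stderr, 1e-12))

    def test_def_monotone_in_concentration_at_80_kev(self):
        defs = []
        for c in (0.0, 1.0, 7.0):
            phantom = PhantomSpec(pt_mg_per_ml=c)
            res = mc.def_per_energy(80.0, phantom,
                                    TransportConfig(n_photons=60_000, seed=17))
            defs.append(res.def_tumor)
        assert defs[0] < defs[1] < defs[2]

    def test_def_approaches_unity_at_high_energy(self, phantom_7mg):
        res = mc.def_per_energy(2000.0, phantom_7mg,
                                TransportConfig(n_photons=100_000, seed=19))
        assert 0.97 <= res.def_tumor <= 1.2

    def test_6mv_flux_beyond_tumor_unchanged_by_pt(self, phantom_7mg,
                                                   spectrum_6mv):
        res = mc.broadband_def(spectrum_6mv, phantom_7mg,
                               TransportConfig(n_photons=150_000, seed=23))
        beyond = phantom_7mg.depths > 12.0
        d_pt = res.profile_pt.energy_per_photon[beyond].sum()
        d_w = res.profile_water.energy_per_photon[beyond].sum()
        assert d_pt == pytest.approx(d_w, rel=0.02)
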