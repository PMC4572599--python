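"""Spectrum-convolved narrow-beam attenuation through a slab phantom.

For each spectral line the primary fluence decays as ``exp(-mu(E) rho x)``
through a water phantom that may contain a platinum-loaded tumor slab.  The
per-depth-bin removal is attributed to interaction channels in proportion to
the local attenuation components, which isolates the photoelectric (PE)
absorption -- and, inside the tumor, the share of PE carried by the dissolved
platinum.  Scattered photons are counted as removed, not re-deposited: this
is a transmission diagnostic, and in-scatter belongs to the Monte Carlo
module (:mod:`lexdef.mc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import xsection
from .errors import DegenerateInputError, EnergyRangeError, ValidationError
from .spectra import SourceSpectrum

DEFAULT_TOTAL_DEPTH_CM = 15.0
#: tumor slab used for the PE diagnostics (a 1-cm slab 10 cm deep)
DIAGNOSTIC_TUMOR_CM = (10.0, 11.0)
#: tumor slab used for Monte Carlo comparisons (a 2-cm slab 10 cm deep)
MC_TUMOR_CM = (10.0, 12.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Water slab phantom with an optional Pt-loaded tumor interval."""

    total_depth: float = DEFAULT_TOTAL_DEPTH_CM           # cm
    tumor_interval: tuple = MC_TUMOR_CM                   # (start, end) cm
    pt_mg_per_ml: float = 7.0
    depth_bin: float = 0.1                                # cm
    lateral_width: float = 5.0                            # cm, square section

    def __post_init__(self):
        if self.lateral_width <= 0:
            raise ValidationError("lateral_width must be positive")
        lo, hi = self.tumor_interval
        if not (0.0 <= lo < hi <= self.total_depth):
            raise ValidationError(
                f"tumor interval {self.tumor_interval} must lie inside "
                f"[0, {self.total_depth:g}] cm")
        if self.depth_bin <= 0:
            raise ValidationError("depth_bin must be positive")
        n = self.total_depth / self.depth_bin
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("depth_bin must divide total_depth")
        if self.pt_mg_per_ml < 0:
            raise ValidationError("pt_mg_per_ml must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.total_depth / self.depth_bin))

    @property
    def depths(self) -> np.ndarray:
        """Depth-bin centers, cm."""
        return (np.arange(self.n_bins) + 0.5) * self.depth_bin

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.depth_bin

    def tumor_bin_mask(self) -> np.ndarray:
        lo, hi = self.tumor_interval
        d = self.depths
        return (d > lo) & (d < hi)

    def materials(self):
        """(water, tumor mixture) pair used through the phantom."""
        water = xsection.load_material("water")
        tumor = xsection.make_mixture(self.pt_mg_per_ml, water=water)
        return water, tumor

    def in_tumor(self, depth_cm) -> np.ndarray:
        lo, hi = self.tumor_interval
        d = np.asarray(depth_cm)
        return (d >= lo) & (d < hi)


@dataclass(frozen=True)
class DepthFluxProfile:
    """Spectrum-integrated primary fluence bookkeeping per depth bin."""

    depths: np.ndarray             # bin centers, cm
    transmitted_fraction: np.ndarray  # fluence surviving to each bin exit
    pe_water: np.ndarray           # per-bin fraction absorbed by water PE
    pe_pt: np.ndarray              # per-bin fraction absorbed by Pt PE
    scatter_removed: np.ndarray    # per-bin fraction removed by non-PE channels
    mode: str = "total"
    transmitted_by_energy: np.ndarray = field(default=None, repr=False)
    energies: np.ndarray = field(default=None, repr=False)
    fluence: np.ndarray = field(default=None, repr=False)

    def transmitted_at(self, depth_cm: float) -> float:
        """Fluence fraction surviving past ``depth_cm``."""
        edges_exit = self.depths + (self.depths[1] - self.depths[0]) / 2.0
        i = np.searchsorted(edges_exit, depth_cm - 1e-12)
        if i == 0 and depth_cm <= 1e-12:
            return 1.0
        return float(self.transmitted_fraction[min(i, len(edges_exit) - 1)])

    def mean_transmitted_energy(self, depth_index: int) -> float:
        """Mean energy of the surviving primary fluence after a given bin."""
        t = self.transmitted_by_energy[:, depth_index]
        w = self.fluence * t
        return float((w * self.energies).sum() / w.sum())


def _attenuation_lattice(spectrum: SourceSpectrum, phantom: PhantomSpec,
                         mode: str):
    """Per-energy, per-bin linear attenuation and channel coefficients."""
    water, tumor = phantom.materials()
    e = spectrum.energies
    lo = max(water.energy_min, tumor.energy_min)
    hi = min(water.energy_max, tumor.energy_max)
    if np.any(e < lo) or np.any(e > hi):
        raise EnergyRangeError(
            f"spectrum support outside fixture range [{lo:g}, {hi:g}] keV")

    def lin(mat, comp, rho):
        return xsection.mu(mat, e, comp) * rho     # 1/cm

    rho_w, rho_t = 1.0, tumor.density
    w_pt = dict(
        (t.material_id, w) for t, w in tumor.components).get("pt", 0.0)
    pt_tab = [t for t, _ in tumor.components if t.material_id == "pt"]
    pe_pt_mass = w_pt * (xsection.mu(pt_tab[0], e, "pe") if pt_tab else 0.0)

    per_mat = {}
    for key, mat, rho in (("water", water, rho_w), ("tumor", tumor, rho_t)):
        tot = lin(mat, "total", rho)
        pe = lin(mat, "pe", rho)
        pe_pt = (pe_pt_mass * rho if key == "tumor" else np.zeros_like(e))
        if mode == "pe_only":
            removal = pe
        elif mode == "total":
            removal = tot
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        per_mat[key] = dict(removal=removal, pe=pe, pe_pt=pe_pt, tot=tot)
    return per_mat


def integrated_attenuation(spectrum: SourceSpectrum, phantom: PhantomSpec,
                           mode: str = "total") -> DepthFluxProfile:
    """Primary-fluence depth profile convolved over the source spectrum.

    ``mode="total"`` removes fluence with the total attenuation coefficient
    and splits each bin's removal into PE (water / Pt) and scattering
    channels; ``mode="pe_only"`` attenuates with the PE coefficient alone,
    the single-channel transmission diagnostic.
    """
    per_mat = _attenuation_lattice(spectrum, phantom, mode)
    nb = phantom.n_bins
    d = phantom.depths
    tumor_bin = phantom.in_tumor(d)
    ne = len(spectrum.energies)

    removal = np.where(tumor_bin[None, :], per_mat["tumor"]["removal"][:, None],
                       per_mat["water"]["removal"][:, None])
    pe = np.where(tumor_bin[None, :], per_mat["tumor"]["pe"][:, None],
                  per_mat["water"]["pe"][:, None])
    pe_pt = np.where(tumor_bin[None, :], per_mat["tumor"]["pe_pt"][:, None],
                     np.zeros((ne, nb)))

    db = phantom.depth_bin
    trans = np.exp(-np.cumsum(removal * db, axis=1))       # at bin exits
    trans_in = np.hstack([np.ones((ne, 1)), trans[:, :-1]])
    removed = trans_in - trans                             # per bin, per E
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_pe = np.where(removal > 0, pe / removal, 0.0)
        frac_pe_pt = np.where(removal > 0, pe_pt / removal, 0.0)
    pe_abs = removed * frac_pe
    pe_abs_pt = removed * frac_pe_pt
    scatter = removed - pe_abs

    f = spectrum.fluence
    return DepthFluxProfile(
        depths=d,
        transmitted_fraction=f @ trans,
        pe_water=f @ (pe_abs - pe_abs_pt),
        pe_pt=f @ pe_abs_pt,
        scatter_removed=f @ scatter,
        mode=mode,
        transmitted_by_energy=trans,
        energies=spectrum.energies,
        fluence=f)


def water_transmission(spectrum: SourceSpectrum, depth_cm: float) -> float:
    """Spectrum-integrated narrow-beam transmission through pure water."""
    water = xsection.load_material("water")
    mu_tot = xsection.mu(water, spectrum.energies, "total")
    return float(np.sum(spectrum.fluence * np.exp(-mu_tot * depth_cm)))


def pe_absorption_in_tumor(spectrum: SourceSpectrum,
                           phantom: PhantomSpec) -> float:
    """Fraction of incident fluence photoelectrically absorbed by tumor Pt."""
    if phantom.pt_mg_per_ml <= 0:
        return 0.0
    prof = integrated_attenuation(spectrum, phantom, mode="total")
    mask = phantom.tumor_bin_mask()
    return float(prof.pe_pt[mask].sum())


def pe_enhancement_ratio(spec_low: SourceSpectrum, spec_high: SourceSpectrum,
                         phantom: PhantomSpec, c_low: float = 1.0,
                         c_high: float = 7.0) -> float:
    """Concentration-differential Pt PE absorption, low vs high energy source.

    Computes the increase in Pt-attributed tumor PE absorption when the Pt
    concentration rises from ``c_low`` to ``c_high`` mg/ml, for each source,
    and returns the low-energy : high-energy ratio of those increases.
    """
    if not c_high > c_low >= 0:
        raise DegenerateInputError(
            f"need c_high > c_low >= 0, got {c_low} -> {c_high} mg/ml")

    def delta(spec):
        lo = pe_absorption_in_tumor(
            spec, _with_concentration(phantom, c_low))
        hi = pe_absorption_in_tumor(
            spec, _with_concentration(phantom, c_high))
        return hi - lo

    num = delta(spec_low)
    den = delta(spec_high)
    if den == 0.0:
        raise DegenerateInputError("high-energy PE increment is zero")
    return num / den


def _with_concentration(phantom: PhantomSpec, c: float) -> PhantomSpec:
    return PhantomSpec(total_depth=phantom.total_depth,
                       tumor_interval=phantom.tumor_interval,
                       pt_mg_per_ml=c, depth_bin=phantom.depth_bin,
                       lateral_width=phantom.lateral_width)
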