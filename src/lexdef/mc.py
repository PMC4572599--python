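"""Analog Monte Carlo photon transport through the slab phantom.

Photons sampled from a source spectrum enter the phantom as a pencil beam on
the central axis at depth zero and are tracked in full 3-D through a right
rectangular water prism (default 15 cm deep with a square 5 x 5 cm cross
section) containing a Pt-loaded tumor slab.  Photons escape through any
face; energy deposits are scored per depth bin.  Heterogeneity is handled by
Woodcock delta-tracking against an energy-dependent majorant attenuation.

Interaction channels are sampled in proportion to the local attenuation
components:

* photoelectric -- the photon energy is deposited in the current depth bin
  (kerma approximation: secondary-electron and Auger-cascade ranges are below
  the 1-mm bin width at kV energies);
* incoherent (Compton) -- the scattered-photon fraction is drawn from the
  Klein-Nishina distribution, the energy difference is deposited locally and
  the scattered photon is tracked onward;
* coherent (Rayleigh) -- the direction is resampled from a Thomson-like
  angular law, nothing is deposited;
* pair production -- ``E - 1022`` keV is deposited locally and two 511-keV
  annihilation photons are emitted isotropically and tracked.

Energy is conserved exactly: per run, deposits plus escaped energy equal the
energy carried in by the sampled photons.

The dose enhancement factor (DEF) of a source is the ratio of the total
energy deposited in the tumor slab with platinum present to that deposited
in the same slab without platinum, computed from paired transports driven by
common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import xsection
from .attenuation import PhantomSpec
from .errors import ValidationError
from .spectra import SourceSpectrum, monochromatic

ELECTRON_REST_KEV = 511.0
PAIR_THRESHOLD_KEV = 1022.0
_GRID_POINTS = 2048
_COMPONENTS = ("pe", "incoherent", "coherent", "pair")
#: platinum K-fluorescence: Kalpha photon energy and fluorescence yield,
#: used only when TransportConfig.pt_k_fluorescence is enabled
PT_K_FLUORESCENCE_KEV = 66.8
PT_K_FLUORESCENCE_YIELD = 0.95


@dataclass(frozen=True)
class TransportConfig:
    """Knobs of the analog transport run."""

    n_photons: int = 200_000
    seed: int = 0
    depth_bin: float = 0.1          # cm
    energy_cutoff: float = 1.0      # keV; photons below deposit locally
    range_cutoff_mm: float = 0.001  # metadata under the kerma approximation
    max_scatters: int = 1000
    n_batches: int = 20
    pt_k_fluorescence: bool = False

    def __post_init__(self):
        if self.n_photons <= 0:
            raise ValidationError("n_photons must be positive")
        if self.energy_cutoff <= 0:
            raise ValidationError("energy_cutoff must be positive")
        if self.n_batches < 2 or self.n_photons < self.n_batches:
            raise ValidationError("need >= 2 batches and photons >= batches")


@dataclass(frozen=True)
class DepthDoseProfile:
    """Mean energy deposited per incident photon, per depth bin."""

    depths: np.ndarray             # bin centers, cm
    energy_per_photon: np.ndarray  # keV per incident photon per bin
    stderr: np.ndarray             # keV, batch-based standard error
    n_photons: int
    seed: int
    incident_energy: float         # mean keV carried in per photon
    escaped_energy: float          # mean keV carried out per photon
    first_collision_counts: np.ndarray = field(repr=False, default=None)
    batch_deposit: np.ndarray = field(repr=False, default=None)  # (B, nbins)

    def total_in(self, mask: np.ndarray) -> float:
        return float(self.energy_per_photon[mask].sum())


@dataclass(frozen=True)
class DEFResult:
    """Dose enhancement factor for one source and phantom."""

    label: str
    def_tumor: float
    def_by_depth: np.ndarray       # per tumor depth bin
    mc_stderr: float
    tumor_depths: np.ndarray
    profile_pt: DepthDoseProfile = field(repr=False, default=None)
    profile_water: DepthDoseProfile = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# cross-section machinery

class _MaterialGrids:
    """Linear attenuation components on a fine log-energy lattice."""

    def __init__(self, phantom: PhantomSpec):
        water, tumor = phantom.materials()
        self.e_floor = max(water.energy_min, tumor.energy_min)
        self.e_ceil = min(water.energy_max, tumor.energy_max)
        self.ln_e = np.linspace(np.log(self.e_floor), np.log(self.e_ceil),
                                _GRID_POINTS)
        e = np.exp(self.ln_e)
        self.lin = np.empty((2, len(_COMPONENTS), _GRID_POINTS))
        for mi, (mat, rho) in enumerate(((water, 1.0),
                                         (tumor, tumor.density))):
            for ci, comp in enumerate(_COMPONENTS):
                self.lin[mi, ci] = xsection.mu(mat, e, comp) * rho
        self.tot = self.lin.sum(axis=1)                  # (2, N)
        self.majorant = self.tot.max(axis=0)             # (N,)
        # Pt share of the tumor PE coefficient (for optional fluorescence)
        w_pt = phantom.pt_mg_per_ml / (1000.0 + phantom.pt_mg_per_ml)
        pt_tab = [t for t, _ in tumor.components if t.material_id == "pt"]
        if pt_tab and w_pt > 0:
            pt_pe = xsection.mu(pt_tab[0], e, "pe") * w_pt * tumor.density
            with np.errstate(invalid="ignore", divide="ignore"):
                self.pt_pe_share = np.where(self.lin[1, 0] > 0,
                                            pt_pe / self.lin[1, 0], 0.0)
        else:
            self.pt_pe_share = np.zeros(_GRID_POINTS)

    def interp(self, table: np.ndarray, energy: np.ndarray) -> np.ndarray:
        return np.interp(np.log(energy), self.ln_e, table)


# ---------------------------------------------------------------------------
# samplers

def sample_klein_nishina(rng: np.random.Generator,
                         energy_kev: np.ndarray) -> np.ndarray:
    """Scattered-to-incident energy ratio eps from the Klein-Nishina law.

    Vectorized composition-rejection sampling (the standard 1/eps + eps
    mixture with the angular rejection factor).
    """
    e = np.asarray(energy_kev, dtype=float)
    k = e / ELECTRON_REST_KEV
    eps0 = 1.0 / (1.0 + 2.0 * k)
    alpha1 = -np.log(eps0)
    alpha2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty_like(e)
    todo = np.ones(e.shape, dtype=bool)
    while np.any(todo):
        n = int(todo.sum())
        u = rng.random((3, n))
        k_t, eps0_t = k[todo], eps0[todo]
        a1, a2 = alpha1[todo], alpha2[todo]
        cand = np.where(u[0] < a1 / (a1 + a2),
                        eps0_t * np.exp(a1 * u[1]),
                        np.sqrt(eps0_t**2 + (1.0 - eps0_t**2) * u[1]))
        t = (1.0 - cand) / (k_t * cand)
        sin2 = t * (2.0 - t)
        g = 1.0 - cand * sin2 / (1.0 + cand**2)
        acc = u[2] <= g
        idx = np.where(todo)[0]
        eps[idx[acc]] = cand[acc]
        todo[idx[acc]] = False
    return eps


def compton_cos_theta(energy_kev, eps):
    """Scattering-angle cosine fixed by Compton kinematics."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    return np.clip(1.0 - (1.0 - eps) / (k * eps), -1.0, 1.0)


def _thomson_cos(rng, n):
    """Cosine from the Thomson angular law, pdf ~ (1 + mu^2)."""
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        m = int(todo.sum())
        c = rng.uniform(-1.0, 1.0, m)
        acc = rng.random(m) <= 0.5 * (1.0 + c**2)
        idx = np.where(todo)[0]
        out[idx[acc]] = c[acc]
        todo[idx[acc]] = False
    return out


def _rotate_direction(rng, u, v, w, cos_scatter):
    """Rotate unit direction (u, v, w) by polar angle acos(cos_scatter)."""
    n = len(w)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_scatter**2))
    cphi, sphi = np.cos(phi), np.sin(phi)
    denom = np.sqrt(np.maximum(1e-30, 1.0 - w**2))
    polar = denom < 1e-10            # travelling along +-z
    u2 = u * cos_scatter + sin_t * (u * w * cphi - v * sphi) / denom
    v2 = v * cos_scatter + sin_t * (v * w * cphi + u * sphi) / denom
    w2 = w * cos_scatter - denom * sin_t * cphi
    if np.any(polar):
        sign = np.sign(w[polar])
        u2[polar] = sin_t[polar] * cphi[polar]
        v2[polar] = sin_t[polar] * sphi[polar]
        w2[polar] = cos_scatter[polar] * sign
    norm = np.sqrt(u2**2 + v2**2 + w2**2)
    return u2 / norm, v2 / norm, w2 / norm


def _isotropic_direction(rng, n):
    w = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - w**2)
    return s * np.cos(phi), s * np.sin(phi), w


# ---------------------------------------------------------------------------
# transport

def transport(spectrum: SourceSpectrum, phantom: PhantomSpec,
              config: TransportConfig,
              majorant_phantom: PhantomSpec | None = None) -> DepthDoseProfile:
    """Run the analog transport and tally energy deposits per depth bin.

    ``majorant_phantom`` optionally supplies the phantom whose cross-sections
    define the Woodcock majorant; paired runs (with and without Pt) pass the
    Pt-loaded phantom for both arms so that common random numbers keep the
    two trajectories synchronized outside the tumor.
    """
    if abs(phantom.depth_bin - config.depth_bin) > 1e-12:
        raise ValidationError("config.depth_bin must match phantom.depth_bin")
    grids = _MaterialGrids(phantom)
    maj_grids = grids if majorant_phantom is None else _MaterialGrids(
        majorant_phantom)
    if np.any(spectrum.energies > grids.e_ceil + 1e-9) or np.any(
            spectrum.energies < grids.e_floor - 1e-9):
        raise ValidationError("spectrum support outside cross-section range")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    n = config.n_photons
    nb = phantom.n_bins
    B = config.n_batches
    depth = phantom.total_depth
    db = phantom.depth_bin
    half = phantom.lateral_width / 2.0
    lo_t, hi_t = phantom.tumor_interval
    cut = max(config.energy_cutoff, grids.e_floor)

    edep = np.zeros(B * nb)
    escaped = np.zeros(B)
    first_coll = np.zeros(nb)

    # initial state: pencil beam along the axis
    cdf = np.cumsum(spectrum.fluence)
    e0 = spectrum.energies[np.searchsorted(cdf, rng.random(n) * cdf[-1])]
    incident = float(e0.sum())
    zeros = np.zeros(n)
    state = dict(x=zeros.copy(), y=zeros.copy(), z=zeros.copy(),
                 u=zeros.copy(), v=zeros.copy(), w=np.ones(n),
                 e=e0.copy(), batch=np.arange(n) % B,
                 nsc=np.zeros(n, dtype=np.int32),
                 virgin=np.ones(n, dtype=bool))
    bank: list[dict] = [state]

    def deposit(batch, z, amount):
        idx = batch * nb + np.minimum((z / db).astype(np.int64), nb - 1)
        np.add.at(edep, idx, amount)

    def push_secondaries(x, y, z, e_new, batch):
        m = len(z)
        su, sv, sw = _isotropic_direction(rng, m)
        bank.append(dict(x=x.copy(), y=y.copy(), z=z.copy(),
                         u=su, v=sv, w=sw, e=e_new,
                         batch=batch.copy(),
                         nsc=np.zeros(m, dtype=np.int32),
                         virgin=np.zeros(m, dtype=bool)))

    while bank:
        s = bank.pop()
        x, y, z = s["x"], s["y"], s["z"]
        u, v, w, e = s["u"], s["v"], s["w"], s["e"]
        batch, nsc, virgin = s["batch"], s["nsc"], s["virgin"]
        while len(e):
            mumaj = maj_grids.interp(maj_grids.majorant, e)
            step = rng.exponential(1.0, len(e)) / mumaj
            x = x + u * step
            y = y + v * step
            z = z + w * step
            inside = ((z >= 0.0) & (z < depth)
                      & (np.abs(x) < half) & (np.abs(y) < half))
            if not np.all(inside):
                out = ~inside
                np.add.at(escaped, batch[out], e[out])
                x, y, z = x[inside], y[inside], z[inside]
                u, v, w, e = u[inside], v[inside], w[inside], e[inside]
                batch, nsc, virgin = batch[inside], nsc[inside], virgin[inside]
                mumaj = mumaj[inside]
                if not len(e):
                    break
            in_tumor = (z >= lo_t) & (z < hi_t)
            mat = in_tumor.astype(np.int64)
            mutot = np.where(in_tumor,
                             grids.interp(grids.tot[1], e),
                             grids.interp(grids.tot[0], e))
            real = rng.random(len(e)) <= mutot / mumaj
            if np.any(real & virgin):
                fv = real & virgin
                np.add.at(first_coll,
                          np.minimum((z[fv] / db).astype(np.int64), nb - 1),
                          1.0)
            virgin = virgin & ~real

            if np.any(real):
                r = np.where(real)[0]
                er, mr = e[r], mat[r]
                comp = np.stack([
                    np.where(mr == 1,
                             grids.interp(grids.lin[1, ci], er),
                             grids.interp(grids.lin[0, ci], er))
                    for ci in range(len(_COMPONENTS))])
                pick = rng.random(len(r)) * comp.sum(axis=0)
                c_cum = np.cumsum(comp, axis=0)
                channel = (pick[None, :] > c_cum).sum(axis=0)
                # 0 pe, 1 incoherent, 2 coherent, 3 pair

                kill = np.zeros(len(e), dtype=bool)

                # photoelectric: local deposit (kerma approximation)
                pe_m = channel == 0
                if np.any(pe_m):
                    pe_idx = r[pe_m]
                    dep = e[pe_idx].copy()
                    if config.pt_k_fluorescence and phantom.pt_mg_per_ml > 0:
                        share = grids.interp(grids.pt_pe_share, e[pe_idx])
                        fluo = ((mat[pe_idx] == 1)
                                & (rng.random(len(pe_idx)) < share)
                                & (e[pe_idx] > 78.4)
                                & (rng.random(len(pe_idx))
                                   < PT_K_FLUORESCENCE_YIELD))
                        if np.any(fluo):
                            dep[fluo] -= PT_K_FLUORESCENCE_KEV
                            push_secondaries(
                                x[pe_idx][fluo], y[pe_idx][fluo],
                                z[pe_idx][fluo],
                                np.full(int(fluo.sum()),
                                        PT_K_FLUORESCENCE_KEV),
                                batch[pe_idx][fluo])
                    deposit(batch[pe_idx], z[pe_idx], dep)
                    kill[pe_idx] = True

                # incoherent: Klein-Nishina energy loss, photon scatters on
                inc_m = channel == 1
                if np.any(inc_m):
                    ii = r[inc_m]
                    eps = sample_klein_nishina(rng, e[ii])
                    cth = compton_cos_theta(e[ii], eps)
                    deposit(batch[ii], z[ii], e[ii] * (1.0 - eps))
                    e[ii] = e[ii] * eps
                    u[ii], v[ii], w[ii] = _rotate_direction(
                        rng, u[ii], v[ii], w[ii], cth)
                    low = np.zeros(len(e), dtype=bool)
                    low[ii] = e[ii] < cut
                    if np.any(low):
                        deposit(batch[low], z[low], e[low])
                        kill |= low

                # coherent: direction resampled, no deposit
                coh_m = channel == 2
                if np.any(coh_m):
                    ci_ = r[coh_m]
                    cth = _thomson_cos(rng, len(ci_))
                    u[ci_], v[ci_], w[ci_] = _rotate_direction(
                        rng, u[ci_], v[ci_], w[ci_], cth)

                # pair production: local deposit + two annihilation photons
                pair_m = channel == 3
                if np.any(pair_m):
                    pi = r[pair_m]
                    deposit(batch[pi], z[pi], e[pi] - PAIR_THRESHOLD_KEV)
                    e[pi] = ELECTRON_REST_KEV
                    u[pi], v[pi], w[pi] = _isotropic_direction(rng, len(pi))
                    push_secondaries(x[pi], y[pi], z[pi],
                                     np.full(len(pi), ELECTRON_REST_KEV),
                                     batch[pi])

                nsc[r] += 1
                tired = nsc > config.max_scatters
                if np.any(tired & ~kill):
                    tk = tired & ~kill
                    deposit(batch[tk], z[tk], e[tk])
                    kill |= tk
                if np.any(kill):
                    keep = ~kill
                    x, y, z = x[keep], y[keep], z[keep]
                    u, v, w, e = u[keep], v[keep], w[keep], e[keep]
                    batch, nsc, virgin = batch[keep], nsc[keep], virgin[keep]

    edep = edep.reshape(B, nb)
    per_batch_n = np.bincount(np.arange(n) % B, minlength=B).astype(float)
    batch_means = edep / per_batch_n[:, None]
    mean = edep.sum(axis=0) / n
    stderr = batch_means.std(axis=0, ddof=1) / np.sqrt(B)
    return DepthDoseProfile(
        depths=phantom.depths,
        energy_per_photon=mean,
        stderr=stderr,
        n_photons=n,
        seed=config.seed,
        incident_energy=incident / n,
        escaped_energy=float(escaped.sum()) / n,
        first_collision_counts=first_coll,
        batch_deposit=edep)


# ---------------------------------------------------------------------------
# dose enhancement factors

def _paired_def(label: str, spectrum: SourceSpectrum, phantom: PhantomSpec,
                config: TransportConfig) -> DEFResult:
    water_arm = PhantomSpec(total_depth=phantom.total_depth,
                            tumor_interval=phantom.tumor_interval,
                            pt_mg_per_ml=0.0, depth_bin=phantom.depth_bin,
                            lateral_width=phantom.lateral_width)
    prof_pt = transport(spectrum, phantom, config, majorant_phantom=phantom)
    prof_w = transport(spectrum, water_arm, config, majorant_phantom=phantom)
    mask = phantom.tumor_bin_mask()
    tot_pt = prof_pt.total_in(mask)
    tot_w = prof_w.total_in(mask)
    if tot_w <= 0:
        raise ValidationError("no tumor deposit in the reference arm")
    batch_pt = prof_pt.batch_deposit[:, mask].sum(axis=1)
    batch_w = prof_w.batch_deposit[:, mask].sum(axis=1)
    ratios = batch_pt / batch_w
    stderr = float(ratios.std(ddof=1) / np.sqrt(len(ratios)))
    with np.errstate(invalid="ignore", divide="ignore"):
        by_depth = np.where(prof_w.energy_per_photon[mask] > 0,
                            prof_pt.energy_per_photon[mask]
                            / prof_w.energy_per_photon[mask], np.nan)
    return DEFResult(label=label,
                     def_tumor=tot_pt / tot_w,
                     def_by_depth=by_depth,
                     mc_stderr=stderr,
                     tumor_depths=phantom.depths[mask],
                     profile_pt=prof_pt,
                     profile_water=prof_w)


def def_per_energy(energy_kev: float, phantom: PhantomSpec,
                   config: TransportConfig) -> DEFResult:
    """DEF for a monoenergetic beam (20 keV to 6 MeV)."""
    if not 20.0 <= energy_kev <= 6000.0:
        raise ValidationError("per-energy DEF supported for 20-6000 keV")
    return _paired_def(f"{energy_kev:g}keV", monochromatic(energy_kev),
                       phantom, config)


def broadband_def(spectrum: SourceSpectrum, phantom: PhantomSpec,
                  config: TransportConfig) -> DEFResult:
    """Tumor-averaged DEF for a broadband source spectrum."""
    return _paired_def(spectrum.label, spectrum, phantom, config)
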