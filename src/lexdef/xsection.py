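"""Mass-attenuation tables for water, platinum and filter metals.

Tables are packaged as TSV fixtures with one row per grid energy and columns
for the photoelectric (pe), coherent, incoherent and pair-production
components (cm^2/g).  Absorption edges are represented by duplicated energy
rows: the first row carries the below-edge coefficients, the second the
above-edge ones.  Queries use log-log interpolation between grid points; a
query at an exact edge energy resolves to the above-edge branch.

Mixtures (water loaded with dissolved platinum at some mg/ml) obey the
weight-fraction mixture rule component by component.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import (CrossoverNotFoundError, EnergyRangeError, TableParseError,
                     ValidationError)

COMPONENTS = ("pe", "coherent", "incoherent", "pair", "total")
PAIR_THRESHOLD_KEV = 1022.0
_LOG_FLOOR = 1e-300
# relative offset applied to the below-edge duplicate so the internal grid is
# strictly increasing; queries at the exact edge then hit the above-edge row
_EDGE_SHIFT = 1e-9

_DATA_SUBDIR = "data/xcom_synthetic"

#: density of liquid water, g/cm^3
WATER_DENSITY = 1.0


@dataclass(frozen=True)
class CrossSectionTable:
    """Mass-attenuation components versus energy for one material."""

    material_id: str
    energy: np.ndarray          # keV, non-decreasing; duplicates at edges
    pe: np.ndarray              # cm^2/g
    coherent: np.ndarray
    incoherent: np.ndarray
    pair: np.ndarray
    total: np.ndarray
    edges: tuple = ()           # ((shell_label, energy_keV), ...)

    def __post_init__(self):
        _validate_table(self)

    @property
    def energy_min(self) -> float:
        return float(self.energy[0])

    @property
    def energy_max(self) -> float:
        return float(self.energy[-1])

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise ValidationError(f"unknown component {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class Mixture:
    """A homogeneous mixture of tabulated materials by weight fraction."""

    components: tuple           # ((CrossSectionTable, weight_fraction), ...)
    density: float              # g/cm^3
    pt_concentration: float = 0.0  # mg elemental Pt per ml

    def __post_init__(self):
        wsum = sum(w for _, w in self.components)
        if abs(wsum - 1.0) > 1e-12:
            raise ValidationError(f"weight fractions sum to {wsum}, not 1")
        if self.density <= 0:
            raise ValidationError("density must be positive")
        if self.pt_concentration < 0:
            raise ValidationError("pt_concentration must be >= 0")

    @property
    def energy_min(self) -> float:
        return max(t.energy_min for t, _ in self.components)

    @property
    def energy_max(self) -> float:
        return min(t.energy_max for t, _ in self.components)


Material = Union[CrossSectionTable, Mixture]


@dataclass(frozen=True)
class CriticalEnergyResult:
    """Where photon scattering overtakes photoelectric absorption."""

    material_id: str
    e_c: float                  # keV
    pe_at_ec: float             # cm^2/g
    scatter_at_ec: float        # cm^2/g


# ---------------------------------------------------------------------------
# loading

def _validate_table(tab: CrossSectionTable) -> None:
    e = tab.energy
    if e.ndim != 1 or len(e) < 2:
        raise TableParseError(f"{tab.material_id}: need at least two rows")
    if np.any(np.diff(e) < 0):
        i = int(np.argmax(np.diff(e) < 0))
        raise TableParseError(
            f"{tab.material_id}: energies decrease at row {i + 1} "
            f"({e[i]:g} -> {e[i + 1]:g} keV)")
    dup = np.where(np.diff(e) == 0)[0]
    edge_energies = {en for _, en in tab.edges}
    for i in dup:
        if not any(abs(e[i] - ee) < 1e-6 for ee in edge_energies):
            raise TableParseError(
                f"{tab.material_id}: duplicated energy {e[i]:g} keV at row "
                f"{i} is not a declared edge")
    for name in COMPONENTS:
        v = tab.component(name)
        if v.shape != e.shape:
            raise TableParseError(f"{tab.material_id}: ragged column {name}")
        if np.any(v < 0):
            i = int(np.argmax(v < 0))
            raise TableParseError(
                f"{tab.material_id}: negative {name} at row {i} "
                f"({e[i]:g} keV)")
    comp_sum = tab.pe + tab.coherent + tab.incoherent + tab.pair
    bad = np.abs(comp_sum - tab.total) > 0.01 * np.maximum(tab.total, 1e-300)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise TableParseError(
            f"{tab.material_id}: total differs from component sum by >1% "
            f"at row {i} ({e[i]:g} keV)")
    if np.any(tab.pair[e < PAIR_THRESHOLD_KEV] != 0):
        raise TableParseError(
            f"{tab.material_id}: nonzero pair component below "
            f"{PAIR_THRESHOLD_KEV:g} keV")


def load_table(path, material_id: str | None = None) -> CrossSectionTable:
    """Parse a TSV fixture into a validated :class:`CrossSectionTable`."""
    edges = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("edge:"):
                    _, label, en = line[1:].strip().split()
                    edges.append((label, float(en)))
                continue
            if line.startswith("energy"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise TableParseError(f"{path}: line {lineno}: expected 6 "
                                      f"columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise TableParseError(
                    f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise TableParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    name = material_id or str(path).rsplit("/", 1)[-1].split(".")[0]
    return CrossSectionTable(
        material_id=name, energy=arr[:, 0], pe=arr[:, 1], coherent=arr[:, 2],
        incoherent=arr[:, 3], pair=arr[:, 4], total=arr[:, 5],
        edges=tuple(edges))


@functools.lru_cache(maxsize=None)
def load_material(name: str) -> CrossSectionTable:
    """Load one of the packaged materials: ``water``, ``pt``, ``al``, ``cu``."""
    ref = importlib.resources.files("lexdef").joinpath(
        f"{_DATA_SUBDIR}/{name}.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_table(path, material_id=name)


# ---------------------------------------------------------------------------
# interpolation

def _interp_grid(tab: CrossSectionTable):
    """Strictly-increasing log-energy grid (below-edge rows nudged down)."""
    e = tab.energy.astype(float).copy()
    for i in range(len(e) - 1):
        if e[i] == e[i + 1]:
            e[i] = e[i] * (1.0 - _EDGE_SHIFT)
    return np.log(e)


def mu(material: Material, energy, component: str = "total"):
    """Mass attenuation coefficient (cm^2/g) by log-log interpolation.

    ``energy`` may be a scalar or array (keV).  Energies outside the table
    range raise :class:`EnergyRangeError`; at an exact edge energy the
    above-edge value is returned.  Mixtures combine their components by
    weight-fraction-weighted sums.
    """
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if isinstance(material, Mixture):
        lo, hi = material.energy_min, material.energy_max
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy outside mixture range [{lo:g}, {hi:g}] keV")
        out = np.zeros_like(e)
        for tab, w in material.components:
            out += w * mu(tab, e, component)
        return float(out[0]) if scalar else out
    tab = material
    if np.any(e < tab.energy_min) or np.any(e > tab.energy_max):
        raise EnergyRangeError(
            f"energy outside {tab.material_id} table range "
            f"[{tab.energy_min:g}, {tab.energy_max:g}] keV")
    loge = _interp_grid(tab)
    vals = np.log(np.maximum(tab.component(component), _LOG_FLOOR))
    with np.errstate(under="ignore"):
        out = np.exp(np.interp(np.log(e), loge, vals))
    out[out < 1e-290] = 0.0
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# mixtures

def make_mixture(pt_mg_per_ml: float,
                 water: CrossSectionTable | None = None,
                 pt: CrossSectionTable | None = None) -> Mixture:
    """Water loaded with ``pt_mg_per_ml`` mg of elemental Pt per ml.

    The dissolved metal adds its mass to a millilitre of water, so the density
    is ``1 + c/1000`` g/cm^3 and the Pt weight fraction ``c / (1000 + c)``.
    """
    c = float(pt_mg_per_ml)
    if c < 0:
        raise ValidationError("Pt concentration must be >= 0 mg/ml")
    water = water if water is not None else load_material("water")
    pt = pt if pt is not None else load_material("pt")
    w_pt = c / (1000.0 + c)
    return Mixture(components=((water, 1.0 - w_pt), (pt, w_pt)),
                   density=WATER_DENSITY + c / 1000.0,
                   pt_concentration=c)


# ---------------------------------------------------------------------------
# critical energy

def _material_id(material: Material) -> str:
    if isinstance(material, Mixture):
        return "+".join(t.material_id for t, _ in material.components)
    return material.material_id


def _scan_start(material: Material) -> float:
    """Lowest scan energy: just above the highest absorption edge, if any."""
    edges = []
    tabs = ([t for t, _ in material.components]
            if isinstance(material, Mixture) else [material])
    for t in tabs:
        edges.extend(en for _, en in t.edges)
    lo = max(t.energy_min for t in tabs) if isinstance(material, Mixture) \
        else material.energy_min
    if edges:
        lo = max(lo, max(edges))
    return lo


def critical_energy(material: Material,
                    n_scan: int = 600) -> CriticalEnergyResult:
    """Lowest energy above the highest edge where scattering >= photoelectric.

    Scattering is the sum of the coherent and incoherent components.  The
    crossing is bracketed on a log grid and refined by bisection on the
    interpolated curves.
    """
    lo = _scan_start(material)
    hi = material.energy_max if not isinstance(material, Mixture) \
        else material.energy_max
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_scan))

    def gap(e):
        return (mu(material, e, "coherent") + mu(material, e, "incoherent")
                - mu(material, e, "pe"))

    g = gap(grid)
    if g[0] >= 0:
        e_c = float(grid[0])
    else:
        idx = np.where(g >= 0)[0]
        if len(idx) == 0:
            raise CrossoverNotFoundError(
                f"{_material_id(material)}: scattering never overtakes "
                f"photoelectric absorption in [{lo:g}, {hi:g}] keV")
        a, b = grid[idx[0] - 1], grid[idx[0]]
        for _ in range(80):  # bisection to interpolation tolerance
            m = 0.5 * (a + b)
            if gap(m) >= 0:
                b = m
            else:
                a = m
        e_c = float(b)
    return CriticalEnergyResult(
        material_id=_material_id(material),
        e_c=e_c,
        pe_at_ec=float(mu(material, e_c, "pe")),
        scatter_at_ec=float(mu(material, e_c, "coherent")
                            + mu(material, e_c, "incoherent")))
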