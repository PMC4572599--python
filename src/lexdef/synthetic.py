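"""Synthetic clonogenic-assay generator and parameter-recovery harness.

The generator emulates the triplicate-plate clonogenic experiments the
survival analytics expect: cells pre-treated with a platinum sensitizer for
a few hours, irradiated from one of several sources, plated, and scored for
colonies of more than 50 cells.  The underlying truth model is

    SF(c, D, source) = S_chem(c) * exp(-(alpha e D) - beta (e D)^2)

with ``S_chem`` a log-logistic intrinsic-cytotoxicity curve parametrized by
an IC50 and Hill slope, and ``e = 1 + (e_src - 1) c / c_ref`` a
source-dependent dose-modifying enhancement that grows linearly with the
sensitizer concentration (it equals 1 for unsensitized cells and ``e_src``
at the reference concentration).  Colony counts are Poisson with mean
``cells_seeded * plating_efficiency * SF``.

Defaults mirror the studied compounds: a Pt(II) terpyridine complex
(Typ-Pt, MW 631.4 Da, 4-h IC50 3.5 ug/ml) and carboplatin (MW 371.2 Da,
IC50 0.437 ug/ml), dose grid {0, 1, 2.5, 5, 10, 15} Gy, three replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .errors import IdentifiabilityError, ValidationError
from .survival import (RECORD_COLUMNS, fit_lq, surviving_fraction)

DEFAULT_DOSES_GY = (0.0, 1.0, 2.5, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class Sensitizer:
    name: str = "typ_pt"
    molecular_weight: float = 631.4    # Da
    ic50: float = 3.5                  # ug/ml
    hill: float = 1.5                  # log-logistic slope

    def chem_survival(self, concentration):
        c = np.asarray(concentration, dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + (c / self.ic50) ** self.hill)


@dataclass(frozen=True)
class AssayDesign:
    """Design of one synthetic clonogenic experiment."""

    cell_line: str = "F98"
    sensitizer: Sensitizer = field(default_factory=Sensitizer)
    concentrations: tuple = (0.0, 2.0)          # ug/ml
    doses: tuple = DEFAULT_DOSES_GY             # Gy
    sources: dict = field(default_factory=lambda: {"160kV": 1.6, "6MV": 1.0})
    enhancement_ref_concentration: float = 2.0  # ug/ml where e_src applies
    alpha: float = 0.25                         # 1/Gy
    beta: float = 0.025                         # 1/Gy^2
    plating_efficiency: float = 0.35
    cells_seeded: int = 600
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(e < 1.0 for e in self.sources.values()):
            raise ValidationError("source enhancement factors must be >= 1")
        if not 0.0 < self.plating_efficiency <= 1.0:
            raise ValidationError("plating efficiency must be in (0, 1]")
        if self.replicates < 1 or self.cells_seeded < 1:
            raise ValidationError("need >= 1 replicate and seeded cell")
        if self.enhancement_ref_concentration <= 0:
            raise ValidationError("enhancement reference concentration > 0")

    def enhancement(self, source: str, concentration: float) -> float:
        e_src = self.sources[source]
        return 1.0 + (e_src - 1.0) * (concentration
                                      / self.enhancement_ref_concentration)

    def true_sf(self, concentration, dose, source):
        c = np.asarray(concentration, dtype=float)
        d = np.asarray(dose, dtype=float)
        e = 1.0 + (self.sources[source] - 1.0) * (
            c / self.enhancement_ref_concentration)
        ed = e * d
        return (self.sensitizer.chem_survival(c)
                * np.exp(-(self.alpha * ed + self.beta * ed**2)))

    def expected_colonies(self, concentration, dose, source):
        return (self.cells_seeded * self.plating_efficiency
                * self.true_sf(concentration, dose, source))


def generate_assay(design: AssayDesign,
                   poisson_noise: bool = True) -> pd.DataFrame:
    """Simulate plates for every (source, concentration, dose, replicate).

    With ``poisson_noise=False`` the expected (rounded) colony counts are
    returned, which makes noise-free round-trip tests exact.  Reproducible:
    identical design and seed give identical records.
    """
    rng = np.random.Generator(np.random.PCG64(design.seed))
    rows = []
    for source in design.sources:
        for c in design.concentrations:
            for d in design.doses:
                mean = design.expected_colonies(c, d, source)
                for rep in range(design.replicates):
                    if poisson_noise:
                        colonies = int(rng.poisson(mean))
                    else:
                        colonies = int(round(mean))
                    rows.append((design.cell_line, design.sensitizer.name,
                                 c, source, d, design.cells_seeded,
                                 min(colonies, design.cells_seeded), rep))
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


# ---------------------------------------------------------------------------
# recovery

@dataclass(frozen=True)
class RecoveredParameters:
    alpha: dict                 # per source: estimate
    beta: dict
    alpha_ci: dict              # per source: (lo, hi)
    beta_ci: dict
    enhancement: dict           # per (source, concentration): estimate
    enhancement_ci: dict
    ic50: float = np.nan
    hill: float = np.nan


def _fit_chem(records: pd.DataFrame, design: AssayDesign):
    """IC50/Hill from the unirradiated plates across concentrations."""
    sub = records[records["dose_gy"] == 0.0]
    concs = np.sort(sub["concentration_ug_ml"].unique())
    if len(concs[concs > 0]) < 2:
        return np.nan, np.nan
    pe0 = sub[sub["concentration_ug_ml"] == 0.0]
    if pe0.empty:
        raise IdentifiabilityError("need an unsensitized, unirradiated arm")
    ref = (pe0["colonies"] / pe0["cells_seeded"]).mean()
    sf = np.array([
        ((sub[sub["concentration_ug_ml"] == c]["colonies"]
          / sub[sub["concentration_ug_ml"] == c]["cells_seeded"]).mean()
         / ref) for c in concs])
    ok = sf > 0

    def model(c, ic50, hill):
        return 1.0 / (1.0 + (c / ic50) ** hill)

    p0 = (design.sensitizer.ic50, design.sensitizer.hill)
    try:
        popt, _ = curve_fit(model, concs[ok], sf[ok], p0=p0,
                            bounds=([1e-6, 0.1], [1e3, 10.0]), maxfev=5000)
    except RuntimeError:
        return np.nan, np.nan
    return float(popt[0]), float(popt[1])


def _curves_by_arm(records: pd.DataFrame):
    for (source, conc), _ in records.groupby(["source",
                                              "concentration_ug_ml"]):
        yield source, conc


def _fit_enhancement(curve, alpha, beta):
    """Dose-modifying factor that best maps the c=0 LQ fit onto a curve."""
    d = curve.index
    ok = curve.sf > 0
    y = -np.log(curve.sf[ok] / curve.sf[np.isclose(d, 0.0)][0])
    dd = d[ok]

    def loss(e):
        return float(np.sum((y - (alpha * e * dd + beta * (e * dd) ** 2))**2))

    res = minimize_scalar(loss, bounds=(0.1, 10.0), method="bounded")
    return float(res.x)


def recover_parameters(records: pd.DataFrame, design: AssayDesign,
                       n_boot: int = 200,
                       ci_level: float = 0.95,
                       seed: int = 1234) -> RecoveredParameters:
    """Staged recovery of the generator's parameters from assay records.

    Stage 1 fits the intrinsic-cytotoxicity curve on the unirradiated
    plates; stage 2 fits per-source LQ parameters on the unsensitized arms;
    stage 3 estimates each sensitized arm's dose-modifying enhancement given
    the stage-2 LQ fit.  Enhancement confidence intervals come from a
    nonparametric bootstrap over replicate plates.
    """
    if 0.0 not in records["concentration_ug_ml"].values:
        raise IdentifiabilityError("need unsensitized (c = 0) arms")
    ic50, hill = _fit_chem(records, design)

    alpha, beta, alpha_ci, beta_ci = {}, {}, {}, {}
    enhancement, enhancement_ci = {}, {}
    rng = np.random.Generator(np.random.PCG64(seed))
    for source in records["source"].unique():
        base = surviving_fraction(
            records, reference={"dose_gy": 0.0},
            group={"source": source, "concentration_ug_ml": 0.0})
        fit = fit_lq(base)
        alpha[source], beta[source] = fit.alpha, fit.beta
        ci = fit.confint(ci_level)
        alpha_ci[source] = tuple(ci[0])
        beta_ci[source] = tuple(ci[1])
        for src, conc in set(_curves_by_arm(records)):
            if src != source or conc == 0.0:
                continue
            curve = surviving_fraction(
                records, reference={"dose_gy": 0.0},
                group={"source": source, "concentration_ug_ml": conc})
            e_hat = _fit_enhancement(curve, fit.alpha, fit.beta)
            enhancement[(source, conc)] = e_hat
            boots = []
            sub = records[(records["source"] == source)
                          & (records["concentration_ug_ml"].isin([0.0, conc]))]
            grouped = [g for _, g in sub.groupby(
                ["concentration_ug_ml", "dose_gy"], group_keys=False)]
            for _ in range(n_boot):
                resampled = pd.concat([
                    g.iloc[rng.integers(0, len(g), len(g))] for g in grouped],
                    ignore_index=True)
                try:
                    b0 = surviving_fraction(
                        resampled, reference={"dose_gy": 0.0},
                        group={"source": source,
                               "concentration_ug_ml": 0.0})
                    bfit = fit_lq(b0)
                    bc = surviving_fraction(
                        resampled, reference={"dose_gy": 0.0},
                        group={"source": source,
                               "concentration_ug_ml": conc})
                    boots.append(_fit_enhancement(bc, bfit.alpha, bfit.beta))
                except Exception:
                    continue
            if boots:
                lo, hi = np.quantile(boots, [(1 - ci_level) / 2,
                                             0.5 + ci_level / 2])
                enhancement_ci[(source, conc)] = (float(lo), float(hi))
            else:
                enhancement_ci[(source, conc)] = (np.nan, np.nan)
    return RecoveredParameters(alpha=alpha, beta=beta, alpha_ci=alpha_ci,
                               beta_ci=beta_ci, enhancement=enhancement,
                               enhancement_ci=enhancement_ci,
                               ic50=ic50, hill=hill)


def design_with(design: AssayDesign, **kwargs) -> AssayDesign:
    """Convenience: a copy of ``design`` with fields replaced."""
    return replace(design, **kwargs)
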