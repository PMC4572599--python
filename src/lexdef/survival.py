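"""Clonogenic-survival analytics.

Surviving fractions (SF) from colony counts, SF-ratio enhancement series,
linear-quadratic (LQ) fits on log-transformed data, group comparisons with
Holm multiplicity adjustment, and the sensitizer atoms-per-cell loading
arithmetic.

An assay record is one plate: a cell line exposed to a sensitizer
concentration, irradiated from one source with one dose, seeded with a known
number of cells, and scored for colonies of more than 50 cells.  Records
arrive as a tidy :class:`pandas.DataFrame` with the columns

``cell_line, sensitizer, concentration_ug_ml, source, dose_gy,
cells_seeded, colonies, replicate``

(the same dialect the synthetic generator emits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear
from statsmodels.stats.multitest import multipletests

from .errors import (AlignmentError, DegenerateInputError, FitError,
                     ValidationError)

RECORD_COLUMNS = ("cell_line", "sensitizer", "concentration_ug_ml", "source",
                  "dose_gy", "cells_seeded", "colonies", "replicate")

#: Avogadro constant at the 3-significant-figure precision used in the
#: original loading arithmetic; the full-precision value is available via
#: the ``avogadro`` argument of :func:`atoms_per_cell`.
AVOGADRO_3SF = 6.02e23
AVOGADRO_FULL = 6.02214076e23

MW_TYP_PT_DA = 631.4
MW_CARBOPLATIN_DA = 371.2
DEFAULT_CELL_DENSITY_PER_ML = 1e9


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records missing columns {missing}")
    if (records["colonies"] > records["cells_seeded"]).any():
        raise ValidationError("colonies exceed cells seeded")
    if (records["dose_gy"] < 0).any() or (records["concentration_ug_ml"] < 0).any():
        raise ValidationError("dose and concentration must be >= 0")
    return records


@dataclass(frozen=True)
class SurvivalCurve:
    """Surviving fraction versus an index variable (dose or concentration)."""

    index_name: str            # e.g. "dose_gy"
    index: np.ndarray
    sf: np.ndarray             # mean surviving fraction
    sd: np.ndarray             # replicate standard deviation
    n: np.ndarray              # replicates per condition
    normalization: str = "to_reference"
    # colony bookkeeping (populated when built from records); lets the LQ
    # fit use Poisson counting weights instead of noisy 3-replicate spreads
    colonies_total: np.ndarray | None = None
    ref_colonies_total: float | None = None


@dataclass(frozen=True)
class LQFit:
    """Linear-quadratic survival fit: SF = exp(-(alpha D + beta D^2))."""

    alpha: float               # 1/Gy
    beta: float                # 1/Gy^2
    covariance: np.ndarray     # 2x2, (alpha, beta)
    doses: np.ndarray
    dof: int

    def predict_sf(self, dose):
        d = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d**2))

    def confint(self, level: float = 0.95):
        """(alpha, beta) confidence intervals from the fit covariance."""
        se = np.sqrt(np.diag(self.covariance))
        tq = stats.t.ppf(0.5 + level / 2.0, max(self.dof, 1))
        est = np.array([self.alpha, self.beta])
        return np.column_stack([est - tq * se, est + tq * se])


@dataclass(frozen=True)
class SFRatioSeries:
    """SF(radiation alone) / SF(radiation + sensitizer) per dose."""

    doses: np.ndarray
    ratio: np.ndarray
    log_se: np.ndarray         # delta-method standard error of ln(ratio)

    @property
    def uncertainty(self) -> np.ndarray:
        """Approximate standard error of the ratio itself."""
        return self.ratio * self.log_se


@dataclass(frozen=True)
class CellLoading:
    """Sensitizer atoms per cell under the equal-uptake assumption."""

    concentration: float       # ug/ml
    molecular_weight: float    # Da
    cell_density: float        # cells/ml
    atoms_per_cell: float


# ---------------------------------------------------------------------------
# surviving fractions

def surviving_fraction(records: pd.DataFrame, reference: dict,
                       index_col: str = "dose_gy",
                       group: dict | None = None) -> SurvivalCurve:
    """Per-condition surviving fractions relative to a reference condition.

    ``reference`` selects the reference plates by column values (e.g.
    ``{"dose_gy": 0.0}``); ``group`` optionally restricts the records (e.g.
    to one source and concentration) before the SF is computed.  Plating
    efficiency is colonies/cells_seeded; SF is each replicate's plating
    efficiency divided by the mean reference plating efficiency, then
    averaged over replicates.
    """
    df = validate_records(records)
    if group:
        for k, val in group.items():
            df = df[df[k] == val]
    if df.empty:
        raise ValidationError("no records after filtering")
    ref = df
    for k, val in reference.items():
        ref = ref[ref[k] == val]
    if ref.empty:
        raise DegenerateInputError(f"reference condition {reference} absent")
    pe_ref = (ref["colonies"] / ref["cells_seeded"]).mean()
    if pe_ref <= 0:
        raise DegenerateInputError("reference condition has zero colonies")
    idx_vals, sf_mean, sf_sd, n_rep, col_tot = [], [], [], [], []
    for val, sub in df.groupby(index_col, sort=True):
        sf = (sub["colonies"] / sub["cells_seeded"]) / pe_ref
        idx_vals.append(val)
        sf_mean.append(sf.mean())
        sf_sd.append(sf.std(ddof=1) if len(sf) > 1 else 0.0)
        n_rep.append(len(sf))
        col_tot.append(float(sub["colonies"].sum()))
    return SurvivalCurve(index_name=index_col,
                         index=np.array(idx_vals, dtype=float),
                         sf=np.array(sf_mean), sd=np.array(sf_sd),
                         n=np.array(n_rep),
                         colonies_total=np.array(col_tot),
                         ref_colonies_total=float(ref["colonies"].sum()))


def sf_ratio(curve_unsensitized: SurvivalCurve,
             curve_sensitized: SurvivalCurve) -> SFRatioSeries:
    """Element-wise enhancement ratio with log-scale error propagation."""
    a, b = curve_unsensitized, curve_sensitized
    if len(a.index) != len(b.index) or np.any(np.abs(a.index - b.index) > 1e-9):
        raise AlignmentError(
            f"dose grids differ: {a.index.tolist()} vs {b.index.tolist()}")
    ok = (a.sf > 0) & (b.sf > 0)
    if not np.any(ok):
        raise DegenerateInputError("no dose with positive SF in both curves")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, a.sf / np.where(ok, b.sf, 1.0), np.nan)
        # delta method on the log scale: var(ln SF) ~ (sd/sf)^2 / n
        var_log = np.where(
            ok,
            (a.sd / np.where(ok, a.sf, 1.0)) ** 2 / np.maximum(a.n, 1)
            + (b.sd / np.where(ok, b.sf, 1.0)) ** 2 / np.maximum(b.n, 1),
            np.nan)
    return SFRatioSeries(doses=a.index.copy(), ratio=ratio,
                         log_se=np.sqrt(var_log))


# ---------------------------------------------------------------------------
# LQ fitting

def fit_lq(curve: SurvivalCurve) -> LQFit:
    """Weighted least squares of ``-ln SF = alpha D + beta D^2``.

    Conditions with zero colonies carry no log-SF information and are
    dropped.  When the curve carries colony totals (curves built from
    records do), weights follow the Poisson delta-method variance of ln SF,
    ``1/colonies + 1/colonies_ref``; otherwise the replicate-spread
    delta-method variance is used.  The residual scale is never deflated
    below the counting expectation, so confidence intervals stay honest for
    well-specified data and widen under over-dispersion.  ``alpha`` is
    unconstrained, ``beta`` is bounded at zero.
    """
    pos = curve.sf > 0
    d = np.asarray(curve.index, dtype=float)[pos]
    if len(np.unique(d)) < 3 or 0.0 not in np.round(d, 9):
        raise FitError("need >= 3 distinct doses with colonies, including 0 Gy")
    sf, sd, n = curve.sf[pos], curve.sd[pos], curve.n[pos]
    y = -np.log(sf)
    if curve.colonies_total is not None and curve.ref_colonies_total:
        var_log = (1.0 / np.maximum(curve.colonies_total[pos], 1.0)
                   + 1.0 / curve.ref_colonies_total)
    else:
        var_log = (sd / sf) ** 2 / np.maximum(n, 1)
        has_var = var_log > 0
        fill = np.median(var_log[has_var]) if np.any(has_var) else 1.0
        var_log = np.where(has_var, var_log, fill)
    wgt = 1.0 / var_log
    A = np.column_stack([d, d**2])
    Aw = A * np.sqrt(wgt)[:, None]
    yw = y * np.sqrt(wgt)
    if np.linalg.matrix_rank(Aw) < 2:
        raise FitError("singular design: doses do not span a quadratic")
    res = lsq_linear(Aw, yw, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    alpha, beta = res.x
    dof = max(len(d) - 2, 1)
    resid = yw - Aw @ res.x
    sigma2 = max(float(resid @ resid) / dof, 1.0)
    cov = sigma2 * np.linalg.inv(Aw.T @ Aw)
    return LQFit(alpha=float(alpha), beta=float(beta), covariance=cov,
                 doses=d.copy(), dof=dof)


# ---------------------------------------------------------------------------
# loading arithmetic

def atoms_per_cell(concentration_ug_ml: float, molecular_weight_da: float,
                   cell_density_per_ml: float = DEFAULT_CELL_DENSITY_PER_ML,
                   avogadro: float = AVOGADRO_3SF) -> CellLoading:
    """Sensitizer atoms per cell assuming uptake equal to the medium.

    atoms/cell = c[g/ml] / MW * N_A / (cells/ml).
    """
    if concentration_ug_ml <= 0 or molecular_weight_da <= 0 \
            or cell_density_per_ml <= 0:
        raise ValidationError("all loading inputs must be positive")
    atoms = (concentration_ug_ml * 1e-6 / molecular_weight_da * avogadro
             / cell_density_per_ml)
    return CellLoading(concentration=concentration_ug_ml,
                       molecular_weight=molecular_weight_da,
                       cell_density=cell_density_per_ml,
                       atoms_per_cell=atoms)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass(frozen=True)
class GroupComparison:
    label: str
    statistic: float
    p_raw: float
    p_adjusted: float = field(default=np.nan)
    reject: bool = field(default=False)


def compare_groups(groups: dict, comparisons: list | None = None,
                   alpha: float = 0.05,
                   log_transform: bool = True) -> list[GroupComparison]:
    """t / ANOVA tests across SF groups with Holm step-down adjustment.

    ``groups`` maps labels to arrays of (positive) surviving fractions;
    ``comparisons`` lists the family as label pairs (Welch t-test each) or
    label tuples of length > 2 (one-way ANOVA).  By default every pairwise
    comparison of the supplied groups forms the family.
    """
    prepared = {}
    for k, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            raise ValidationError(f"group {k!r} needs >= 2 observations")
        prepared[k] = np.log(arr) if log_transform else arr
    if comparisons is None:
        keys = sorted(prepared)
        comparisons = [(a, b) for i, a in enumerate(keys)
                       for b in keys[i + 1:]]
    if all(np.allclose(v, v[0]) for v in prepared.values()):
        raise ValidationError("zero variance in every group")

    out = []
    for comp in comparisons:
        if len(comp) == 2:
            a, b = prepared[comp[0]], prepared[comp[1]]
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) \
                    and np.isclose(a[0], b[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            arrays = [prepared[k] for k in comp]
            stat, p = stats.f_oneway(*arrays)
        label = " vs ".join(str(c) for c in comp)
        out.append(GroupComparison(label=label, statistic=float(stat),
                                   p_raw=float(p)))
    reject, p_adj, _, _ = multipletests([c.p_raw for c in out],
                                        alpha=alpha, method="holm")
    return [GroupComparison(label=c.label, statistic=c.statistic,
                            p_raw=c.p_raw, p_adjusted=float(pa),
                            reject=bool(rj))
            for c, pa, rj in zip(out, p_adj, reject)]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                   method="holm")
    return p_adj
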