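# Methods

`lexdef` models why kilovoltage (LEX) X-rays activate a dissolved platinum
radiosensitizer far more effectively than megavoltage (HEX) photons, and
provides the survival-assay statistics used to test that prediction in
clonogenic experiments.  This note records the models, the defaults, the
numerical choices, and what the synthetic data do and do not establish.

## Cross-section tables

Photon interaction data are packaged as TSV tables
(`lexdef/data/xcom_synthetic/`) holding the photoelectric (PE), coherent,
incoherent and pair-production mass attenuation components (cm²/g) on a
~55-point grid from 10 keV to 6 MeV.  They are a **synthetic
reconstruction** generated by `scripts/build_attenuation_tables.py`, not a
verbatim database export:

* PE follows piecewise power laws between shell edges.  For Pt the edges sit
  at the published energies (L3 11.564, L2 13.273, L1 13.880, K 78.4 keV)
  with conventional jump ratios (K 4.3; L1/L2/L3 1.16/1.40/2.20); the local
  exponents (2.41 below 30 keV, 2.85 from 30 keV to the K edge, 2.79 above,
  flattening to 1.35 beyond 1 MeV) were set so the table matches widely
  tabulated Pt coefficients at 40–70 keV, ≈8.5 cm²/g just above the K edge,
  ≈190 cm²/g just above the L1 edge, and a PE/scattering crossover near
  400 keV.
* Incoherent scattering is the Klein–Nishina cross-section per electron
  times Z/A, damped at low energy by `exp(-(E₀/E)^1.5)` standing in for the
  incoherent scattering function (E₀ = 40 keV for Pt).
* For water, aluminium and copper the *total* coefficient is pinned to the
  standard tabulated grid (the values a dosimetrist would look up) and the
  incoherent column absorbs the residual, so spectrum-integrated
  transmissions computed from the tables are accurate at the few-percent
  level.  The residual agrees with free-electron Klein–Nishina to <1% from
  0.2–6 MeV, which is a useful internal consistency check.

Interpolation is log–log linear.  Absorption edges are duplicated rows; a
query at the exact edge energy returns the above-edge value, and the
below-edge branch is reachable at `edge·(1−ε)`.  Mixtures (water + dissolved
Pt at c mg/ml) use the weight-fraction mixture rule with density
`1 + c/1000` g/cm³ and Pt weight fraction `c/(1000+c)`; "7 mg/ml" means
elemental platinum mass, not compound mass.

The *critical energy* `E_c` of a material is the lowest energy above its
highest absorption edge at which coherent+incoherent scattering overtakes
PE absorption, located by log-grid bracketing plus bisection.  For the
packaged Pt table `E_c ≈ 408 keV`; for water, ≈25 keV.

## Source spectra

Spectra are photon fluence (counts, not energy fluence), normalized to one,
on uniform 10-keV bins; each occupied bin is represented by its
fluence-weighted mean energy.  Tube spectra use the Kramers thin-target
shape `(kVp−E)/E`, cut below 10 keV, hardened through added filtration with
the packaged Al/Cu tables.  The irradiator's true filtration is not public;
the default (2 mm Al + 0.9 mm Cu) was chosen so the 250-kV spectrum shows
its broad fluence peak near 80 keV, the documented property of these
sources; users can override both thicknesses or load a measured spectrum
from CSV.  The megavoltage beam is a parametric thick-target shape
`exp(−aE)(E_max−E)` with `a` solved so the mean energy is 1.8 MeV (a typical
6-MV beam lies at 1.7–2.0 MeV); the resulting spectrum holds <4% of its
fluence below 100 keV.  No characteristic anode lines and no
target/anode-angle physics are modelled.

## Narrow-beam attenuation diagnostic

`attenuation.integrated_attenuation` convolves the source spectrum with
`exp(−μ(E)ρx)` through the slab phantom, accumulating per-depth-bin removal
and attributing it to channels in proportion to the local attenuation
components.  Scattered photons count as removed (narrow-beam geometry, no
build-up): this is a transmission diagnostic, and in-scatter belongs to the
Monte Carlo module.  Inside the tumor slab the PE removal is split into
water and platinum shares, giving the Pt-attributed photoionization per
incident photon.  The *PE enhancement ratio* compares, between two sources,
the increase in Pt photoionization when the concentration rises from 1 to
7 mg/ml; the differential form is used because the absolute Pt PE at fixed
concentration also scales trivially with concentration.  For a single-line
spectrum the profile reduces to Beer–Lambert exactly, which the tests use
as an oracle.

## Monte Carlo dose enhancement

`mc.transport` is an analog photon Monte Carlo through the
(15 × 5 × 5)-cm right rectangular water prism with a tumor slab (default
10–12 cm, 7 mg/ml Pt) and a central pencil beam.  Heterogeneity is handled
by Woodcock delta-tracking against the energy-dependent majorant of the two
materials.  Channels: PE deposits the full photon energy in the local 1-mm
depth bin (kerma approximation); incoherent scattering samples the
scattered fraction from Klein–Nishina (composition–rejection, validated
against quadrature to 0.5%), deposits the difference, and continues the
photon; coherent scattering resamples the direction from a Thomson-like
law; pair production deposits `E−1022` keV and emits two isotropic 511-keV
photons.  Photons terminate below the energy cutoff (or the 10-keV table
floor, whose residual is deposited locally — at 10 keV the mean free path
in water is under 2 mm) or on leaving the prism through any face.  Energy
is conserved to machine precision by construction, and identical
seeds/configs give bit-identical tallies.

Geometry matters here: in a laterally infinite (1-D) slab the
multiply-scattered photon fluence at 10–12 cm depth dominates the tumor
dose and dilutes the enhancement; with the real 5 × 5 cm cross-section and
a pencil beam most scattered photons escape laterally, and the tumor dose
stays primary-dominated.  The package therefore tracks the full 3-D prism.

The DEF of a source is the ratio of total tumor-slab energy deposits in
paired transports with and without platinum, run with common random
numbers (the Pt-arm majorant is used in both arms so trajectories stay
synchronized outside the tumor).  Uncertainties come from 20 photon
batches.  Defaults: 2×10⁵ photons/arm for monoenergetic DEFs, 10⁶ for
broadband runs (≈4 s and ≈15 s respectively on one core).

Known fidelity limits, in decreasing order of importance:

* **Kerma approximation.**  No electron transport and no explicit Auger
  cascade: all transferred energy deposits in the interaction bin.  This is
  faithful at kV energies (secondary-electron ranges ≲50 µm, far below the
  1-mm bin) but at 6 MV the ~1 cm electron paths would smear deposits over
  several bins.  One consequence is statistical: with pointwise deposits
  the per-bin standard error at 10⁶ photons is 1–3%, whereas a
  condensed-history code that spreads each history's energy over many bins
  reports sub-1% bin errors at comparable statistics.
* **Megavoltage enhancement.**  At MeV energies the Pt admixture changes
  the tumor's energy absorption by well under 1% (PE ≈ 3×10⁻³ cm²/g at
  1.8 MeV and the pair excess ≈ 2.4×10⁻³ cm²/g, each weighted by the
  7×10⁻³ weight fraction), and the sub-100-keV fluence of the parametric
  6-MV spectrum contributes ~0.1% of tumor dose.  The simulation
  accordingly yields a 6-MV broadband DEF of ≈1.00–1.01; reported
  megavoltage DEFs well above that level would require either a much softer
  spectrum or non-kerma mechanisms outside this model.
* **Monoenergetic DEF band.**  In the 40–80 keV band the simulated DEF at
  7 mg/ml runs ≈1.9–2.5 with its peak just above the K edge.  An
  interaction-kerma estimate with tabulated coefficients gives ≈1.9 at
  60 keV, so claims that the whole band exceeds 2.0 are not reproducible
  under local-deposition physics; the band's upper half is.
* Pt K-fluorescence is off by default (the vacancy's energy deposits
  locally); an option emits one 66.8-keV K photon with yield 0.95 instead.

## Clonogenic survival analytics

Surviving fractions are plating efficiencies (colonies/cells seeded)
normalized to a reference condition, averaged over (triplicate) plates,
with replicate SDs.  SF-*ratio* series — SF(radiation alone)/SF(radiation +
sensitizer) at matched dose — carry delta-method log-scale errors; doses at
which either arm has zero colonies are reported as NaN rather than
invented.

LQ fits minimize weighted squared error of `−ln SF = αD + βD²` (no
intercept; α free, β ≥ 0 via bounded least squares).  When the curve was
built from records the weights are Poisson counting variances of the
pooled per-condition colony totals, `1/T_i + 1/T_ref`; the residual scale
is never deflated below the counting expectation, and intervals use t
quantiles.  A 200-simulation calibration at α = 0.25 Gy⁻¹, β = 0.025 Gy⁻²
(triplicate plates, 600 cells seeded) puts the 95% CI coverage for both
parameters near 99% — conservative, by design, for 3-replicate data.
Zero-colony conditions are dropped from the fit.

Group tests follow the field's convention: Welch's t for two groups (the
conservative choice; the flavor is otherwise unspecified), one-way ANOVA
for more, Holm step-down adjustment controlling the family-wise error rate
at 0.05 (verified against a hand-computed oracle and a simulated null).

Atoms-per-cell loading uses `c·10⁻⁶/MW · N_A / (cells/ml)` with cell
density 10⁹ cells/ml and N_A fixed at 6.02×10²³ (3 s.f.) — the
full-precision constant changes the third significant figure of the
2.5 µg/ml carboplatin case (4.06 vs 4.05 ×10⁶), so the 3-s.f. convention is
the default and the full constant is an option.

## Synthetic assays

The generator draws colony counts as Poisson with mean
`cells_seeded · PE · SF_true`, where
`SF_true = S_chem(c) · exp(−α(eD) − β(eD)²)`,
`S_chem` is log-logistic with the sensitizer's IC50 (3.5 µg/ml for the
terpyridine Pt complex, 0.437 µg/ml for carboplatin) and Hill slope, and
the enhancement `e = 1 + (e_src−1)·c/c_ref` acts as a dose-modifying
factor that is 1 at c = 0 and e_src at the reference concentration — the
way a physical DEF would rescale absorbed dose.  A multiplicative
enhancement entering additively in log-survival was deliberately not
implemented.  Defaults: doses {0, 1, 2.5, 5, 10, 15} Gy, plating
efficiency 0.35, 600 cells/plate, 3 replicates, kV-arm enhancement 1.6,
MV-arm 1.0.

Parameter recovery is staged — chemistry from the unirradiated plates, LQ
from the unsensitized arms, enhancement per sensitized arm by 1-D
optimization given the LQ fit — with bootstrap CIs over replicate plates.

What the synthetic data do **not** emulate: over-dispersion beyond Poisson
(a knob exists but defaults off), plating-density effects, cell-cycle or
DNA-repair mechanisms, and any difference between sensitizer uptake and
medium concentration.  Green round-trip tests therefore show the analytics
are self-consistent and calibrated under the stated noise model — not that
real assays satisfy that model.

## Numerical conventions

Seeds: every stochastic component takes an explicit integer seed (PCG64);
identical seed + config is bit-reproducible.  Spectrum bins: 10 keV.
Depth bins: 0.1 cm.  Monte Carlo photon guards: max 1000 scatters
(residual energy then deposits locally, preserving conservation).
Interpolation for transport uses a 2048-point log-energy lattice sampled
from the tables; exact-edge semantics live in the table layer.  Degenerate
inputs (zero reference colonies, equal concentrations in the enhancement
ratio, no PE/scatter crossover) raise typed errors rather than NaNs.
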