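"""End-to-end orchestration: validated configs, staged runs, manifests.

A run config (dict or YAML) names the stages to execute and their
parameters.  Stages run in dependency order -- spectra first, then the
attenuation diagnostic and the Monte Carlo DEF simulation, then the
synthetic assay and its survival analysis -- and every artifact lands in
the output directory together with a manifest recording inputs, seeds,
package version and SHA-256 checksums, so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import pandas as pd
import yaml

from . import __version__, attenuation, mc, spectra, survival, synthetic
from .errors import ValidationError

log = logging.getLogger("lexdef")

STAGE_ORDER = ("spectrum", "attenuate", "defsim", "simulate_assay", "survival")


def resolve_source(name, bin_width: float = 10.0) -> spectra.SourceSpectrum:
    """Map a source label to a spectrum.

    Accepts ``"<kvp>kV"`` (filtered tube), ``"<mv>MV"`` (parametric LINAC),
    a bare number in keV (monochromatic), or a path to a spectrum CSV.
    """
    if isinstance(name, (int, float)):
        return spectra.monochromatic(float(name), bin_width)
    s = str(name)
    try:
        return spectra.monochromatic(float(s), bin_width)
    except ValueError:
        pass
    if s.endswith("kV"):
        return spectra.tube_spectrum(float(s[:-2]), bin_width=bin_width)
    if s.endswith("MV"):
        return spectra.linac_spectrum(float(s[:-2]), bin_width=bin_width)
    if os.path.exists(s):
        return spectra.from_csv(s, bin_width=bin_width)
    raise ValidationError(f"cannot resolve source {name!r}")


def _phantom(cfg: dict) -> attenuation.PhantomSpec:
    tumor = tuple(cfg.get("tumor", attenuation.MC_TUMOR_CM))
    return attenuation.PhantomSpec(
        total_depth=cfg.get("total_depth", attenuation.DEFAULT_TOTAL_DEPTH_CM),
        tumor_interval=tumor,
        pt_mg_per_ml=cfg.get("pt_mg_per_ml", 7.0),
        depth_bin=cfg.get("depth_bin", 0.1))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages

def stage_spectrum(cfg: dict, out_dir: str, seed: int) -> list[str]:
    spec = resolve_source(cfg.get("source", f"{cfg.get('kvp', 160)}kV"))
    path = os.path.join(out_dir, f"spectrum_{spec.label}.csv")
    pd.DataFrame({"energy_keV": spec.energies,
                  "fluence": spec.fluence}).to_csv(path, index=False)
    return [path]


def stage_attenuate(cfg: dict, out_dir: str, seed: int) -> list[str]:
    spec = resolve_source(cfg.get("source", "160kV"))
    phantom = _phantom(cfg)
    prof = attenuation.integrated_attenuation(spec, phantom,
                                              mode=cfg.get("mode", "total"))
    path = os.path.join(out_dir, f"attenuation_{spec.label}.csv")
    pd.DataFrame({"depth_cm": prof.depths,
                  "transmitted": prof.transmitted_fraction,
                  "pe_water": prof.pe_water,
                  "pe_pt": prof.pe_pt,
                  "scatter_removed": prof.scatter_removed}).to_csv(
        path, index=False)
    summary = {
        "source": spec.label,
        "transmitted_at_10cm": prof.transmitted_at(10.0),
        "pe_pt_tumor": float(prof.pe_pt[phantom.tumor_bin_mask()].sum()),
    }
    jpath = os.path.join(out_dir, f"attenuation_{spec.label}.json")
    with open(jpath, "w") as fh:
        json.dump(summary, fh, indent=1)
    return [path, jpath]


def stage_defsim(cfg: dict, out_dir: str, seed: int) -> list[str]:
    spec = resolve_source(cfg.get("source", "160kV"))
    phantom = _phantom(cfg)
    config = mc.TransportConfig(
        n_photons=int(cfg.get("n_photons", 200_000)),
        seed=int(cfg.get("seed", seed)),
        depth_bin=phantom.depth_bin,
        n_batches=int(cfg.get("n_batches", 20)))
    res = mc.broadband_def(spec, phantom, config)
    path = os.path.join(out_dir, f"def_{spec.label}.csv")
    mask = phantom.tumor_bin_mask()
    pd.DataFrame({
        "depth_cm": phantom.depths,
        "dose_water": res.profile_water.energy_per_photon,
        "dose_pt": res.profile_pt.energy_per_photon,
        "stderr_water": res.profile_water.stderr,
        "stderr_pt": res.profile_pt.stderr}).to_csv(path, index=False)
    summary = {"source": spec.label, "def_tumor": res.def_tumor,
               "mc_stderr": res.mc_stderr, "n_photons": config.n_photons,
               "seed": config.seed,
               "tumor_interval_cm": list(phantom.tumor_interval)}
    jpath = os.path.join(out_dir, f"def_{spec.label}.json")
    with open(jpath, "w") as fh:
        json.dump(summary, fh, indent=1)
    return [path, jpath]


def design_from_config(cfg: dict, default_seed: int = 0
                       ) -> synthetic.AssayDesign:
    """Build an :class:`AssayDesign` from a (YAML-derived) mapping."""
    sens = synthetic.Sensitizer(**cfg.get("sensitizer", {}))
    return synthetic.AssayDesign(
        cell_line=cfg.get("cell_line", "F98"),
        sensitizer=sens,
        concentrations=tuple(cfg.get("concentrations", (0.0, 2.0))),
        doses=tuple(cfg.get("doses", synthetic.DEFAULT_DOSES_GY)),
        sources=dict(cfg.get("sources", {"160kV": 1.6, "6MV": 1.0})),
        alpha=cfg.get("alpha", 0.25), beta=cfg.get("beta", 0.025),
        plating_efficiency=cfg.get("plating_efficiency", 0.35),
        cells_seeded=int(cfg.get("cells_seeded", 600)),
        replicates=int(cfg.get("replicates", 3)),
        seed=int(cfg.get("seed", default_seed)))


def stage_simulate_assay(cfg: dict, out_dir: str, seed: int) -> list[str]:
    design = design_from_config(cfg, default_seed=seed)
    records = synthetic.generate_assay(design)
    path = os.path.join(out_dir, "assay.csv")
    records.to_csv(path, index=False)
    return [path]


def stage_survival(cfg: dict, out_dir: str, seed: int) -> list[str]:
    path_in = cfg.get("input", os.path.join(out_dir, "assay.csv"))
    if not os.path.exists(path_in):
        raise ValidationError(f"survival stage: missing input {path_in}")
    records = pd.read_csv(path_in)
    ratio_by = cfg.get("ratio_by", "source")
    out_paths = []
    curves, ratios, fits = [], [], []
    for source in records["source"].unique():
        concs = sorted(records["concentration_ug_ml"].unique())
        base = survival.surviving_fraction(
            records, reference={"dose_gy": 0.0},
            group={"source": source, "concentration_ug_ml": 0.0})
        for c in concs:
            curve = survival.surviving_fraction(
                records, reference={"dose_gy": 0.0},
                group={"source": source, "concentration_ug_ml": c})
            fit = survival.fit_lq(curve)
            for d, sf, sd, n in zip(curve.index, curve.sf, curve.sd, curve.n):
                curves.append((source, c, d, sf, sd, n))
            fits.append((source, c, fit.alpha, fit.beta))
            if c > 0:
                rs = survival.sf_ratio(base, curve)
                for d, r, se in zip(rs.doses, rs.ratio, rs.log_se):
                    ratios.append((source, c, d, r, se))
    p = os.path.join(out_dir, "sf_curves.csv")
    pd.DataFrame(curves, columns=["source", "concentration_ug_ml", "dose_gy",
                                  "sf", "sd", "n"]).to_csv(p, index=False)
    out_paths.append(p)
    p = os.path.join(out_dir, "sf_ratios.csv")
    pd.DataFrame(ratios, columns=["source", "concentration_ug_ml", "dose_gy",
                                  "sf_ratio", "log_se"]).to_csv(p, index=False)
    out_paths.append(p)
    p = os.path.join(out_dir, "lq_fits.csv")
    pd.DataFrame(fits, columns=["source", "concentration_ug_ml", "alpha_per_gy",
                                "beta_per_gy2"]).to_csv(p, index=False)
    out_paths.append(p)
    return out_paths


_STAGES = {"spectrum": stage_spectrum, "attenuate": stage_attenuate,
           "defsim": stage_defsim, "simulate_assay": stage_simulate_assay,
           "survival": stage_survival}


# ---------------------------------------------------------------------------
# driver

def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ValidationError("config.stages must name at least one stage")
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    for name, cfg in stages.items():
        if cfg is not None and not isinstance(cfg, dict):
            raise ValidationError(f"stage {name!r} config must be a mapping")
    return config


def run_pipeline(config: dict, out_dir: str | None = None,
                 seed: int | None = None) -> dict:
    """Execute the configured stages and write a manifest; returns it."""
    config = validate_config(config)
    out_dir = out_dir or config.get("output_dir", "lexdef_out")
    seed = int(seed if seed is not None else config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    produced = []
    for name in STAGE_ORDER:
        if name not in config["stages"]:
            continue
        cfg = config["stages"][name] or {}
        log.info("stage %s: %s", name, cfg)
        produced.extend(_STAGES[name](cfg, out_dir, seed))
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "lexdef_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "outputs": [{"path": os.path.relpath(p, out_dir),
                     "sha256": _sha256(p)} for p in produced],
    }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def load_config(path: str) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))
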