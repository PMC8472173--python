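"""End-to-end pipeline: simulate -> fit creep -> descriptors -> kinetics ->
extractability, with flat-file handoff so each stage is independently
runnable and testable.  Outputs are deterministic (byte-identical) under a
fixed configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import descriptors as desc_mod
from . import extractability as extr_mod
from . import io as io_mod
from . import softening_kinetics as kin_mod
from . import synthetic_data as syn_mod
from .creep_model import select_model_order, monte_carlo_ci

log = logging.getLogger("caulirheo")

__all__ = [
    "PipelineConfig",
    "CreepOptions",
    "KineticsOptions",
    "RegressionOptions",
    "run_pipeline",
    "load_config",
]


class CreepOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    max_m: int = 3
    loss: str = "squared"
    n_sims: int = 0  # Monte Carlo CI simulations per fit; 0 skips CIs
    hold_s: float = 600.0
    recovery_s: float = 600.0
    step_s: float = 1.0


class KineticsOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    fix_n: float | None = None  # None: free when >= 4 distinct times, else 1


class RegressionOptions(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    split_seed: int = 0
    responses: tuple[str, ...] = ("TotSte", "TotToc", "water_pct")


class PipelineConfig(BaseModel):
    """Validated before any stage runs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)
    output_dir: str = "caulirheo_out"
    generator: syn_mod.GeneratorConfig = syn_mod.GeneratorConfig()
    creep: CreepOptions = CreepOptions()
    kinetics: KineticsOptions = KineticsOptions()
    regression: RegressionOptions = RegressionOptions()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})


def _curves_dir(out: Path) -> Path:
    return out / "curves"


def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    """Generate study tables, creep curves and cooking profiles."""
    gen = config.generator
    out.mkdir(parents=True, exist_ok=True)
    study = syn_mod.gen_study_dataset(gen)
    study.descriptors.to_csv(out / "study_descriptors.csv", index=False)
    study.specimens.to_csv(out / "study_specimens.csv", index=False)

    cdir = _curves_dir(out)
    cdir.mkdir(exist_ok=True)
    schedule = syn_mod.LoadSchedule(
        hold_s=config.creep.hold_s, recovery_s=config.creep.recovery_s, step_s=config.creep.step_s
    )
    n_curves = 0
    seeds = np.random.SeedSequence(gen.seed).generate_state(
        len(gen.varieties) * len(gen.methods) * len(gen.times_min) * gen.replicates_rheology
    )
    i = 0
    for v in gen.varieties:
        for m in gen.methods:
            for t in gen.times_min:
                params = syn_mod.burgers_for_condition(v, m, t, hold_s=schedule.hold_s)
                for rep in range(1, gen.replicates_rheology + 1):
                    curve = syn_mod.gen_creep_curve(
                        params, schedule, noise_cv=gen.noise_cv_creep, seed=int(seeds[i] % 2**31)
                    )
                    i += 1
                    io_mod.write_creep_curve(curve, cdir / io_mod.curve_filename(v, m, t, rep))
                    n_curves += 1
            profile = syn_mod.gen_temperature_profile(m, duration_min=max(gen.times_min) or 25.0)
            io_mod.write_profile(profile, out / f"profile_{m}.csv")
    log.info("simulate: %d curves, %d descriptor rows, %d specimen rows",
             n_curves, len(study.descriptors), len(study.specimens))
    return {
        "curves": n_curves,
        "descriptor_rows": len(study.descriptors),
        "specimen_rows": len(study.specimens),
    }


def _parse_curve_name(name: str) -> dict:
    stem = name.removesuffix(".csv")
    variety, method, t_part, rep_part = stem.split("_")
    return {
        "variety": variety,
        "method": method,
        "time_min": float(t_part.removesuffix("min")),
        "replicate": int(rep_part.removesuffix(".csv").removeprefix("rep")),
    }


def stage_fit_creep(config: PipelineConfig, out: Path) -> dict:
    """Fit every stored creep curve with Durbin-Watson order selection."""
    cdir = _curves_dir(out)
    reports = {}
    n_fail = 0
    for path in sorted(cdir.glob("*.csv")):
        curve = io_mod.read_creep_curve(path)
        try:
            fit = select_model_order(curve, max_m=config.creep.max_m, loss=config.creep.loss)
        except Exception as exc:
            n_fail += 1
            log.error("fit-creep failed for %s: %s", path.name, exc)
            raise RuntimeError(f"creep fit failed for specimen {path.name}") from exc
        if config.creep.n_sims > 0:
            name_key = int.from_bytes(hashlib.sha256(path.name.encode()).digest()[:4], "big")
            seed = int(
                np.random.SeedSequence([config.generator.seed, name_key]).generate_state(1)[0]
                % 2**31
            )
            fit = fit.with_ci(monte_carlo_ci(fit, curve, n_sims=config.creep.n_sims, seed=seed))
        reports[path.name] = io_mod.fit_to_dict(fit)
    io_mod.write_json(reports, out / "creep_fits.json")
    log.info("fit-creep: %d fits, %d failures", len(reports), n_fail)
    return {"fits": len(reports)}


def stage_descriptors(config: PipelineConfig, out: Path) -> dict:
    """Compute descriptor rows from the stored curves and their fits."""
    from .creep_model import BurgersParams

    fits = json.loads((out / "creep_fits.json").read_text())
    rows = []
    for name, rec in sorted(fits.items()):
        curve = io_mod.read_creep_curve(_curves_dir(out) / name)
        params = BurgersParams(
            J0=rec["J0"],
            elements=tuple((e["Ji"], e["RTi"]) for e in rec["elements"]),
            JN=rec["JN"],
        )
        ds = desc_mod.compute_descriptors(curve, _FitView(params))
        rows.append({**_parse_curve_name(name), **_descriptor_row(ds)})
    df = pd.DataFrame(rows).sort_values(["variety", "method", "time_min", "replicate"])
    df.to_csv(out / "curve_descriptors.csv", index=False)
    log.info("descriptors: %d rows", len(df))
    return {"rows": len(df)}


class _FitView:
    """Minimal stand-in exposing ``params`` to the descriptor computation."""

    def __init__(self, params):
        self.params = params


def _descriptor_row(ds: desc_mod.DescriptorSet) -> dict:
    f0, fi, fn = ds.fractions
    return {
        "Ur": ds.Ur, "JR": ds.JR, "J0_over_Ur": f0, "sumJi_over_Ur": fi,
        "JN_over_Ur": fn, "Jmax": ds.Jmax, "Jeq": ds.Jeq, "ERA": ds.ERA,
        "EPR": ds.EPR, "E0": ds.E0, "EtaN": ds.EtaN,
    }


def stage_kinetics(config: PipelineConfig, out: Path) -> dict:
    """Fit the ERA decay model per variety x method on the study descriptors."""
    df = pd.read_csv(out / "study_descriptors.csv")
    rows = []
    for (v, m), grp in df.groupby(["variety", "method"]):
        n_times = grp["time_min"].nunique()
        fix_n = config.kinetics.fix_n
        if fix_n is None and n_times < 4:
            fix_n = 1.0  # sparse series: fixed first order
        fit = kin_mod.fit_decay(
            grp["time_min"].to_numpy(float), grp["ERA"].to_numpy(float), fix_n=fix_n
        )
        rows.append(
            {
                "variety": v, "method": m, "ERA0": fit.ERA0, "ERAinf": fit.ERAinf,
                "k": fit.k, "n": fit.n, "t50_min": fit.t50, "E_pct": fit.E_pct, "r2": fit.r2,
            }
        )
    pd.DataFrame(rows).to_csv(out / "kinetics.csv", index=False)
    log.info("kinetics: %d condition fits", len(rows))
    return {"condition_fits": len(rows)}


def stage_extractability(config: PipelineConfig, out: Path) -> dict:
    """Join tables, fit the regression models and run the PCA."""
    specimens = pd.read_csv(out / "study_specimens.csv")
    descriptors = pd.read_csv(out / "study_descriptors.csv")
    joined = extr_mod.join_tables(specimens, descriptors)
    joined.to_csv(out / "joined_table.csv", index=False)

    mra = {}
    for resp in config.regression.responses:
        model = extr_mod.fit_mra(joined, resp, split_seed=config.regression.split_seed)
        mra[resp] = {
            "predictors": list(model.predictors),
            "coefficients": model.coefficients,
            "standard_errors": model.standard_errors,
            "calibration_mare_pct": model.calibration_mare,
            "validation_mare_pct": model.validation_mare,
            "validation_r2": model.validation_r2,
            "intercept_only": model.intercept_only,
        }
    io_mod.write_json(mra, out / "mra_models.json")

    active = ("ERA", "EPR", "Ur", "TotSte", "TotToc", "water_pct")
    supplementary = tuple(
        c for c in ("campesterol", "stigmasterol", "beta_sitosterol", "gamma_T", "alpha_T", "EtaN", "E0")
        if c in joined.columns
    )
    pca = extr_mod.pca_supplementary(joined, active, supplementary)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pca.supplementary.to_csv(out / "pca_supplementary.csv")
    pca.scores.to_csv(out / "pca_scores.csv", index=False)
    io_mod.write_json(
        {
            "eigenvalues": pca.eigenvalues,
            "percent_variance": pca.percent_variance,
        },
        out / "pca_summary.json",
    )
    log.info("extractability: %d joined rows, %d MRA models", len(joined), len(mra))
    return {"joined_rows": len(joined), "mra_models": len(mra)}


_STAGES = {
    "simulate": stage_simulate,
    "fit-creep": stage_fit_creep,
    "descriptors": stage_descriptors,
    "kinetics": stage_kinetics,
    "extractability": stage_extractability,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the requested stages (all, in dependency order, by default) and
    write a manifest carrying the config hash, seed and per-stage counts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.generator.seed, "stages": {}}
    for name in stages or tuple(_STAGES):
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}; expected one of {tuple(_STAGES)}")
        manifest["stages"][name] = _STAGES[name](config, out)
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest
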