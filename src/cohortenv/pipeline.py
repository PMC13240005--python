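"""End-to-end orchestration: simulate -> cohorts -> envfeatures -> bioenv ->
rda (-> trends), with a machine-readable run manifest.

The manifest records the config hash, seeds, per-stage wall-clock, the SHA-256
of every artifact written, and every decision flag in force, so a run can be
reproduced and audited: identical configs give identical manifests for the
deterministic stages and identical seeded streams for the stochastic ones.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from cohortenv import bioenv as _bioenv
from cohortenv import demography as _demog
from cohortenv import env_features as _env
from cohortenv import io as _io
from cohortenv import rda as _rda
from cohortenv import synthetic as _syn

__all__ = ["RunManifest", "run_pipeline", "default_config"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: dict = field(default_factory=dict)  #: stage -> {seconds, outputs: {path: sha256}}
    flags: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def default_config() -> dict:
    """Default pipeline configuration (all stages on, synthetic inputs)."""
    return {
        "seed": 0,
        "simulate": {"enabled": True},
        "cohorts": {
            "min_birth_year": 1999,
            "min_record_years": 4,
            "min_age": 2,
            "max_age": 10,
            "impute_mode": "observed_plus_imputed",
        },
        "bioenv": {
            "method": "pearson",
            "standardize_env": True,
            "standardize_biotic": False,
            "columns": None,  # optional restriction to a named column panel
        },
        "rda": {"n_perm": 999, "scale_response": False},
        "inputs": {},  # paths to pre-existing CSVs when simulate is disabled
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute the analysis chain, writing artifacts and a manifest to
    ``outdir``.  Stops at the first failing stage; the manifest records the
    failure point and partial artifacts are retained."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(default_config(), config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    canonical = yaml.safe_dump(config, sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=int(config["seed"]),
        package_version=__import__("cohortenv").__version__,
        flags={
            "bioenv": config["bioenv"],
            "cohorts": config["cohorts"],
            "rda": {k: v for k, v in config["rda"].items()},
        },
    )

    def record(stage: str, t0: float, outputs: dict) -> None:
        manifest.stages[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p): _io.sha256_of(p) for p in outputs.values()},
            "records": {k: str(p) for k, p in outputs.items()},
        }

    try:
        # ---- simulate ----------------------------------------------------
        t0 = time.perf_counter()
        if config["simulate"].get("enabled", True):
            sim_cfg = {k: v for k, v in config["simulate"].items() if k != "enabled"}
            sim_cfg.setdefault("seed", config["seed"])
            scfg = _syn.SimulationConfig.from_dict(sim_cfg)
            env = _syn.simulate_environment(scfg)
            truth = _syn.simulate_cohorts(env, scfg)
            samples = _syn.sample_ages(truth, config=scfg)
            annual = _syn.simulate_annual_temperature(scfg)
            biomass = _syn.simulate_biomass_surveys(scfg, annual_temp=annual)
            outputs = {
                "env": _io.write_table(env, outdir / "env_series.csv"),
                "truth": _io.write_table(truth.table, outdir / "cohort_truth.csv", index=True),
                "samples": _io.write_table(samples, outdir / "age_samples.csv"),
                "annual_temp": _io.write_table(annual, outdir / "annual_temperature.csv"),
                "biomass": _io.write_table(biomass, outdir / "biomass_records.csv"),
            }
            record("simulate", t0, outputs)
        else:
            inputs = config["inputs"]
            for key in ("env", "samples"):
                if key not in inputs:
                    raise FileNotFoundError(f"simulation disabled and no input path for {key!r}")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"input file not found: {inputs[key]}")
            env = _io.read_env_series(inputs["env"])
            samples = _io.read_age_samples(inputs["samples"])
            record("simulate", t0, {})

        # ---- cohorts -----------------------------------------------------
        t0 = time.perf_counter()
        ccfg = config["cohorts"]
        gm = _demog.build_generation_matrix(samples)
        gm_f, report = _demog.filter_generations(
            gm,
            min_birth_year=ccfg["min_birth_year"],
            min_record_years=ccfg["min_record_years"],
            min_age=ccfg["min_age"],
            max_age=ccfg["max_age"],
        )
        fits = _demog.fit_all_generations(gm_f)
        dm = _demog.impute_missing(
            gm_f, fits, min_age=ccfg["min_age"], max_age=ccfg["max_age"],
            mode=ccfg["impute_mode"],
        )
        diag = _demog.density_dependence_diagnostics(dm)
        report_path = outdir / "filter_report.json"
        with open(report_path, "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        outputs = {
            "generation_matrix": _io.write_table(gm_f, outdir / "generation_matrix.csv", index=True),
            "demographic_matrix": _io.write_table(dm.data, outdir / "demographic_matrix.csv", index=True),
            "provenance": _io.write_table(dm.provenance, outdir / "demographic_provenance.csv", index=True),
            "diagnostics": _io.write_table(diag, outdir / "density_dependence.csv", index=True),
            "filter_report": report_path,
        }
        record("cohorts", t0, outputs)

        # ---- envfeatures ---------------------------------------------------
        t0 = time.perf_counter()
        last = _demog.last_detection_years(gm_f)
        generations = [(int(b), int(last[b])) for b in gm_f.index]
        env_matrix = _env.build_env_matrix(env, generations)
        outputs = {
            "env_features": _io.write_table(env_matrix, outdir / "env_features.csv", index=True)
        }
        record("envfeatures", t0, outputs)

        # ---- bioenv --------------------------------------------------------
        t0 = time.perf_counter()
        bcfg = config["bioenv"]
        env_used = env_matrix[list(bcfg["columns"])] if bcfg.get("columns") else env_matrix
        biotic = _bioenv.euclidean_distances(dm.data, standardize=bcfg["standardize_biotic"])
        result = _bioenv.exhaustive_bioenv(
            biotic,
            env_used,
            method=bcfg["method"],
            standardize_env=bcfg["standardize_env"],
            standardize_biotic=bcfg["standardize_biotic"],
        )
        bioenv_path = outdir / "bioenv.json"
        result.to_json(bioenv_path)
        outputs = {
            "bioenv": bioenv_path,
            "per_size": _io.write_table(result.per_size, outdir / "bioenv_per_size.csv"),
        }
        record("bioenv", t0, outputs)

        # ---- rda -----------------------------------------------------------
        t0 = time.perf_counter()
        rcfg = config["rda"]
        X = env_matrix[list(result.best_subset)]
        rda_fit = _rda.fit_rda(dm.data, X, scale_response=rcfg["scale_response"])
        seed = int(config["seed"])
        p_model, f_obs, n_used, _ = _rda.permutation_test_model(
            dm.data, X, n_perm=rcfg["n_perm"], seed=seed,
            scale_response=rcfg["scale_response"],
        )
        p_axes = _rda.permutation_test_axes(
            dm.data, X, n_perm=rcfg["n_perm"], seed=seed + 1,
            scale_response=rcfg["scale_response"],
        )
        p_terms = _rda.permutation_test_terms(
            dm.data, X, n_perm=rcfg["n_perm"], seed=seed + 2,
            scale_response=rcfg["scale_response"],
        )
        rda_fit.p_model, rda_fit.pseudo_f = p_model, f_obs
        rda_fit.p_axes, rda_fit.p_terms = p_axes, p_terms
        rda_fit.n_perm, rda_fit.seed = rcfg["n_perm"], seed
        rda_path = outdir / "rda.json"
        with open(rda_path, "w") as fh:
            json.dump(rda_fit.to_dict(), fh, indent=2)
        outputs = {
            "rda": rda_path,
            "site_scores": _io.write_table(rda_fit.site_scores, outdir / "rda_site_scores.csv", index=True),
            "loadings": _io.write_table(rda_fit.response_loadings, outdir / "rda_loadings.csv", index=True),
            "biplot": _io.write_table(rda_fit.biplot_scores, outdir / "rda_biplot_scores.csv", index=True),
        }
        record("rda", t0, outputs)

    except Exception as exc:  # record the failure point, then re-raise
        manifest.failed_stage = _next_stage(manifest)
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.to_json(outdir / "manifest.json")
        raise

    manifest.to_json(outdir / "manifest.json")
    return manifest


_STAGE_ORDER = ["simulate", "cohorts", "envfeatures", "bioenv", "rda"]


def _next_stage(manifest: RunManifest) -> str:
    for stage in _STAGE_ORDER:
        if stage not in manifest.stages:
            return stage
    return "post"
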