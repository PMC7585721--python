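"""End-to-end pipeline runs: simulate, calibrate, fit, contrast, report.

Each step is an importable function; the command-line interface in
:mod:`cricketsize.cli` is a thin wrapper around these. Every output
directory gets a ``provenance.json`` recording the seed and a hash of the
effective configuration, so a rerun with the same configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import calibration as cal
from . import contrasts as ctr
from . import design as dsg
from . import io as dio
from . import simulate as sim
from .model import MCMCSettings, Priors, TraitModel
from .results import TraitModelResults

log = logging.getLogger("cricketsize")

#: default sex handling per trait: genital traits are fitted per sex
DEFAULT_SEX_MODES = {
    "femur": "pooled", "wing": "pooled", "pronotum": "pooled",
    dsg.MALE_GENITAL: "male_only", dsg.FEMALE_GENITAL: "female_only",
}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    morphometry: str | None = None
    calibration: str | None = None
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_SEX_MODES))
    sex_modes: dict[str, str] = field(default_factory=dict)
    chains: int = 2
    burn_in: int = 10_000
    samples: int = 10_000
    thin: int = 1
    seed: int = 0
    out_dir: str = "results"
    year_handling: str = "mix"   # or a reference year as int

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def mcmc(self) -> MCMCSettings:
        return MCMCSettings(chains=self.chains, burn_in=self.burn_in,
                            samples=self.samples, thin=self.thin,
                            seed=self.seed)

    def sex_mode_for(self, trait: str) -> str:
        return self.sex_modes.get(trait, DEFAULT_SEX_MODES.get(trait, "pooled"))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_provenance(out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"seed": config.seed, "config_sha256": config.digest(),
                   "config": asdict(config)}, fh, indent=2)


def cmd_simulate(config: PipelineConfig,
                 effects: dsg.EffectConfig | None = None,
                 design: dsg.StudyDesign | None = None,
                 n_pairs: int = 48) -> dict[str, Path]:
    """Write a seeded synthetic dataset: the morphometry CSV, the paired
    dual-instrument calibration CSV and the generating truth (YAML)."""
    out = Path(config.out_dir)
    _write_provenance(out, config)
    design = design or dsg.default_study_design()
    effects = effects or dsg.default_study_effects()
    records = sim.simulate_individuals(design, effects, seed=config.seed)
    pairs = sim.simulate_dual_measurements(records, effects, n_pairs=n_pairs,
                                           seed=config.seed + 1)
    paths = {"morphometry": out / "morphometry.csv",
             "calibration": out / "calibration_pairs.csv",
             "truth": out / "effects_truth.yaml"}
    dio.write_morphometry_table(records, paths["morphometry"])
    dio.write_calibration_table(pairs, paths["calibration"])
    dsg.effects_to_yaml(effects, paths["truth"])
    log.info("simulated %d individuals, %d calibration rows -> %s",
             len(records), len(pairs), out)
    return paths


def cmd_calibrate(config: PipelineConfig) -> Path:
    """Fit the per-trait calliper-to-digital conversions and write them."""
    if not config.calibration:
        raise ValueError("config.calibration: no paired-measurement CSV given")
    out = Path(config.out_dir)
    _write_provenance(out, config)
    pairs = dio.read_calibration_table(config.calibration)
    ests = cal.fit_all_conversions(pairs)
    path = out / "conversions.json"
    cal.conversions_to_json(ests, path)
    for t, e in ests.items():
        log.info("conversion %s: %.3f +/- %.3f mm (n=%d, r=%.3f)",
                 t, e.offset_mean, e.offset_sd, e.n_pairs, e.pearson_r)
    return path


def fit_all_traits(records: pd.DataFrame,
                   conversions: dict[str, cal.ConversionEstimate] | None,
                   config: PipelineConfig,
                   priors: Priors | None = None
                   ) -> dict[str, TraitModelResults]:
    """Fit every requested trait model; chain seeds are derived per trait
    so traits are independent but the whole run is reproducible."""
    results: dict[str, TraitModelResults] = {}
    base = config.mcmc()
    for k, trait in enumerate(config.traits):
        col = trait if trait in dsg.SHARED_TRAITS else "genital"
        if col not in records.columns or records[col].notna().sum() == 0:
            log.warning("skipping %s: no measurements", trait)
            continue
        conv = (conversions or {}).get(trait)
        model = TraitModel(records, trait,
                           sex_mode=config.sex_mode_for(trait),
                           conversion=conv, priors=priors)
        results[trait] = model.fit(settings=base, seed=base.seed + 1000 * k)
        log.info("fitted %s (n=%d)", trait, model.design.n)
    return results


def cmd_fit(config: PipelineConfig,
            priors: Priors | None = None) -> dict[str, TraitModelResults]:
    """Fit all trait models and write posterior summaries and diagnostics."""
    if not config.morphometry:
        raise ValueError("config.morphometry: no records CSV given")
    out = Path(config.out_dir)
    _write_provenance(out, config)
    records = dio.read_morphometry_table(config.morphometry)
    conversions = None
    if (records["instrument"] == "calliper").any():
        if not config.calibration:
            raise ValueError(
                "records contain calliper measurements: a calibration "
                "paired-measurement CSV (config.calibration) is required")
        pairs = dio.read_calibration_table(config.calibration)
        conversions = cal.fit_all_conversions(pairs)
        cal.conversions_to_json(conversions, out / "conversions.json")
    results = fit_all_traits(records, conversions, config, priors=priors)

    diagnostics = {}
    for trait, res in results.items():
        res.summary().to_csv(out / f"posterior_{trait}.csv")
        report = res.check_convergence()
        ppc_mean = res.posterior_predictive_check("mean", seed=config.seed)
        ppc_cv = res.posterior_predictive_check("cv", seed=config.seed)
        diagnostics[trait] = {
            "rhat_max": float(report.rhat.max()),
            "rhat_flagged": report.flagged,
            "ess_bulk_min": float(report.ess_bulk.min()),
            "bayes_p_mean": ppc_mean.bayes_p,
            "bayes_p_cv": ppc_cv.bayes_p,
            "ppc_passed": ppc_mean.passed and ppc_cv.passed,
            "n_rows": res.model.design.n,
            "seed": config.seed,
        }
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)
    return results


def cmd_contrast(config: PipelineConfig,
                 results: dict[str, TraitModelResults] | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Compute the three result tables and write them as CSV."""
    results = results if results is not None else cmd_fit(config)
    out = Path(config.out_dir)
    year = (config.year_handling if config.year_handling == "mix"
            else int(config.year_handling))
    tables = ctr.make_results_tables(results, year=year)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return tables


def cmd_report(config: PipelineConfig,
               results: dict[str, TraitModelResults] | None = None,
               figure: bool = True) -> dict[str, pd.DataFrame]:
    """Full run: fit, tables and the standardised forest figure."""
    results = results if results is not None else cmd_fit(config)
    tables = cmd_contrast(config, results=results)
    if figure:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = ctr.plot_forest(results)
        ax.figure.tight_layout()
        ax.figure.savefig(Path(config.out_dir) / "forest.png", dpi=150)
        plt.close(ax.figure)
    return tables
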