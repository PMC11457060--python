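"""End-to-end orchestration: simulate -> QC -> traits -> BLUEs -> GRM ->
reaction norm -> CV -> report, with structured JSONL logging.

Every stage is a plain function call into the library; this module only
sequences them, stamps outputs with the package version / config hash /
seed, and makes reruns with an identical config byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cv import run_cv
from .errors import ConfigurationError
from .io import (
    read_markers,
    read_phenotypes,
    write_kernel,
    write_markers,
    write_phenotypes,
    write_table,
)
from .markers import compute_grm, qc_markers
from .mixed import blues_by_environment, fit_across_sites, trait_correlations
from .reaction_norm import build_design, fit_gibbs, predict_gebv
from .simulate import SimulationConfig, simulate_striga_dataset
from .traits import derive_traits

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_TRAITS = ("STR8WAP", "STR10WAP", "STR12WAP", "SDR1", "SDR2",
                  "SDR", "AUSNPC", "GY")


@dataclass
class PipelineConfig:
    output_dir: str = "strigagp_out"
    phenotype_path: str | None = None   # None -> simulate
    marker_path: str | None = None
    traits: tuple = DEFAULT_TRAITS
    prediction_traits: tuple = ("STR10WAP", "GY")
    maf_threshold: float = 0.05
    wap_schedule: tuple = (8, 10, 12)
    sampler: dict = field(default_factory=lambda: dict(
        iterations=30_000, burn_in=15_000, thin=10))
    cv: dict = field(default_factory=lambda: dict(
        schemes=("CV0", "CV1", "CV2"), n_folds=50, test_fraction=0.2))
    simulation: dict = field(default_factory=dict)
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        # identifies the analysis, not its destination
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class _Log:
    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def stage(self, name, t0, **extra):
        rec = {"stage": name, "seconds": round(time.time() - t0, 3), **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of output paths.

    Inputs come either from ``phenotype_path``/``marker_path`` or, when
    those are unset, from the synthetic generator under the pipeline
    seed.  Identical config + seed reproduce identical outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(out_dir / "pipeline_log.jsonl")
    meta = {"config_hash": config.hash(), "seed": config.seed}
    outputs = {}

    # --- inputs -----------------------------------------------------
    t0 = time.time()
    if config.phenotype_path and config.marker_path:
        phenotypes = read_phenotypes(config.phenotype_path)
        markers = read_markers(config.marker_path)
        source = "files"
    else:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
        markers, phenotypes, _ = simulate_striga_dataset(sim)
        write_phenotypes(phenotypes, out_dir / "phenotypes.csv", meta)
        write_markers(markers, out_dir / "markers.csv", meta)
        outputs["phenotypes"] = str(out_dir / "phenotypes.csv")
        outputs["markers"] = str(out_dir / "markers.csv")
        source = "synthetic"
    log.stage("inputs", t0, source=source, n_plots=len(phenotypes),
              n_lines=markers.n_lines, n_markers=markers.n_markers)

    # --- derived traits ---------------------------------------------
    t0 = time.time()
    phenotypes = derive_traits(phenotypes, wap_schedule=config.wap_schedule)
    traits = [t for t in config.traits if t in phenotypes.columns]
    log.stage("traits", t0, traits=traits)

    # --- marker QC and GRM ------------------------------------------
    t0 = time.time()
    clean = qc_markers(markers, config.maf_threshold)
    grm = compute_grm(clean)
    write_kernel(grm, out_dir / "grm.csv", meta)
    outputs["grm"] = str(out_dir / "grm.csv")
    log.stage("grm", t0, markers_before=markers.n_markers,
              markers_after=clean.n_markers)

    # --- mixed models: variance components, H2, BLUPs, BLUEs --------
    t0 = time.time()
    rows, blups = [], {}
    env_blues = {}
    for trait in traits:
        summary = fit_across_sites(phenotypes, trait)
        vc = summary.varcomps
        rows.append(dict(
            trait=trait, sigma2_G=vc.sigma2_G, sigma2_GE=vc.sigma2_GE,
            sigma2_error=vc.sigma2_error, heritability=summary.heritability,
            lsd05=summary.lsd05,
        ))
        blups[trait] = summary.blups
        env_blues[trait] = blues_by_environment(phenotypes, trait)
    varcomp_table = pd.DataFrame(rows)
    write_table(varcomp_table, out_dir / "variance_components.csv", meta)
    blup_table = pd.DataFrame(blups)
    blup_table.index.name = "entry"
    write_table(blup_table, out_dir / "blups.csv", meta, index=True)
    corr = trait_correlations(blup_table)
    write_table(corr.reset_index(), out_dir / "trait_correlations.csv", meta)
    for trait, tbl in env_blues.items():
        tbl.index.name = "entry"
        write_table(tbl, out_dir / f"blues_{trait}.csv", meta, index=True)
    outputs["variance_components"] = str(out_dir / "variance_components.csv")
    outputs["blups"] = str(out_dir / "blups.csv")
    log.stage("mixed_models", t0, n_traits=len(traits))

    # --- reaction norm fit + GEBVs ----------------------------------
    t0 = time.time()
    gebv_frames = []
    for trait in config.prediction_traits:
        if trait not in env_blues:
            continue
        design = build_design(env_blues[trait], grm)
        samples = fit_gibbs(design, seed=config.seed, **config.sampler)
        gebv = predict_gebv(samples, design)
        gebv = gebv.rename(columns={
            c: (f"{trait}" if c == "gebv" else f"{trait}_{c[5:]}")
            for c in gebv.columns if c.startswith("gebv")
        })
        gebv_frames.append(gebv)
    if gebv_frames:
        merged = gebv_frames[0]
        for extra in gebv_frames[1:]:
            merged = merged.join(extra.drop(columns="set"))
        merged.index.name = "line_id"
        write_table(merged, out_dir / "gebv.csv", meta, index=True)
        outputs["gebv"] = str(out_dir / "gebv.csv")
    log.stage("reaction_norm", t0, traits=list(config.prediction_traits))

    # --- cross-validation -------------------------------------------
    t0 = time.time()
    acc_rows = []
    for trait in config.prediction_traits:
        if trait not in env_blues:
            continue
        for scheme in config.cv.get("schemes", ()):
            res = run_cv(
                env_blues[trait], grm, scheme,
                n_folds=config.cv.get("n_folds", 50),
                test_fraction=config.cv.get("test_fraction", 0.2),
                seed=config.seed,
                sampler=config.sampler,
                trait=trait,
            )
            row = dict(trait=trait, scheme=scheme, across=res.across,
                       n_folds=res.n_folds)
            row.update({f"r_{e}": r for e, r in res.per_environment.items()})
            acc_rows.append(row)
    if acc_rows:
        write_table(pd.DataFrame(acc_rows), out_dir / "accuracy.csv", meta)
        outputs["accuracy"] = str(out_dir / "accuracy.csv")
    log.stage("cross_validation", t0, n_rows=len(acc_rows))

    # --- report ------------------------------------------------------
    report = {
        "package": f"strigagp {__version__}",
        "config_hash": config.hash(),
        "seed": config.seed,
        "outputs": outputs,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    outputs["report"] = str(out_dir / "report.json")
    outputs["log"] = str(out_dir / "pipeline_log.jsonl")
    return outputs
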