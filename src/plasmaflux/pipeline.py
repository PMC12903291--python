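"""Workflow orchestration: metabolome, panel and flux pipelines.

Each workflow reads real input files or generates synthetic data from a
config block, runs the stage functions in order, writes every stage
output under an output directory, and records a run manifest (resolved
config, package version, per-file sha256 checksums, stage timings, and
the per-stage seed registry).  A single global seed fans out to
per-stage seeds via a stage-name CRC32 hash, so any stage can be re-run
in isolation and reproduce its output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    IntensityMatrix,
    class_summary,
    compute_vip,
    filter_missing,
    fit_oplsda,
    impute_missing,
    pca,
    permutation_test,
    select_sdms,
)
from .flux import (
    FluxModel,
    compare_conditions,
    export_flux_graph,
    load_default_network,
    parse_network,
)
from .panel import check_assumptions, compare_all
from .simulate import (
    DEFAULT_PANEL_SCENARIO,
    PanelScenario,
    SyntheticMetabolomeConfig,
    generate_flux_scenario,
    generate_intensity_matrix,
    generate_panel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "stage_seed",
    "run_metabolome_workflow",
    "run_panel_workflow",
    "run_flux_workflow",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32(stage) XOR global, below 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: Mapping[str, Any], seed: int) -> None:
        self.outdir = outdir
        self.doc: dict[str, Any] = {
            "package_version": __version__,
            "global_seed": seed,
            "config": json.loads(json.dumps(config, default=str)),
            "stages": [],
        }

    def record(self, stage: str, outputs: list[Path], elapsed: float, seed: int | None = None) -> None:
        self.doc["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "elapsed_s": round(elapsed, 4),
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )
        logger.info("stage %-18s %6.2fs  %s", stage, elapsed, [p.name for p in outputs])

    def write(self) -> Path:
        path = self.outdir / "run_manifest.json"
        path.write_text(json.dumps(self.doc, indent=2))
        return path


def _load_or_generate_matrix(config: Mapping[str, Any], seed: int):
    if "intensity_tsv" in config:
        return IntensityMatrix.from_tsv(config["intensity_tsv"]), None
    synth = dict(config.get("synthetic", {}))
    synth.setdefault("seed", stage_seed(seed, "simulate_metabolome"))
    return generate_intensity_matrix(SyntheticMetabolomeConfig(**synth))


def run_metabolome_workflow(config: Mapping[str, Any], outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """filter -> impute -> PCA -> OPLS-DA -> VIP -> permutation -> SDMs -> classes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config, seed)
    artifacts: dict[str, Path] = {}

    t0 = time.perf_counter()
    matrix, truth = _load_or_generate_matrix(config, seed)
    p_in = outdir / "intensity_matrix.tsv"
    matrix.to_tsv(p_in)
    outputs = [p_in, p_in.with_suffix(".json")]
    if truth is not None:
        p_truth = outdir / "synthetic_truth.json"
        truth.to_json(p_truth)
        outputs.append(p_truth)
    manifest.record("load_or_simulate", outputs, time.perf_counter() - t0)
    artifacts["intensity_matrix"] = p_in

    t0 = time.perf_counter()
    filtered = filter_missing(matrix, config.get("max_missing_frac", 0.5),
                              config.get("missing_filter_mode", "all"))
    complete = impute_missing(filtered, config.get("impute_method", "half_min"))
    p_complete = outdir / "imputed_matrix.tsv"
    complete.to_tsv(p_complete)
    manifest.record("filter_impute", [p_complete], time.perf_counter() - t0)
    artifacts["imputed_matrix"] = p_complete

    t0 = time.perf_counter()
    n_comp = min(config.get("pca_components", 2), complete.n_samples - 1, complete.n_metabolites)
    pca_res = pca(complete, n_comp, config.get("scaling", "uv"))
    p_scores = outdir / "pca_scores.tsv"
    pca_res.scores.assign(group=complete.groups).to_csv(p_scores, sep="\t")
    manifest.record("pca", [p_scores], time.perf_counter() - t0)
    artifacts["pca_scores"] = p_scores

    t0 = time.perf_counter()
    cv_seed = stage_seed(seed, "oplsda_cv")
    model = fit_oplsda(
        complete,
        n_orth=config.get("n_orth", 1),
        scaling=config.get("scaling", "uv"),
        cv_folds=min(config.get("cv_folds", 7), complete.n_samples),
        cv_seed=cv_seed,
    )
    vip = compute_vip(model)
    perm = permutation_test(
        complete,
        n_orth=config.get("n_orth", 1),
        scaling=config.get("scaling", "uv"),
        cv_folds=min(config.get("cv_folds", 7), complete.n_samples),
        cv_seed=cv_seed,
        n_permutations=config.get("n_permutations", 200),
        seed=stage_seed(seed, "permutation"),
    )
    report = {
        "R2X": model.r2x,
        "R2Y": model.r2y,
        "Q2": model.q2,
        "n_orth": model.n_orth,
        "scaling": model.scaling,
        "cv_folds": model.cv_folds,
        "permutation": {
            "n_permutations": perm.n_permutations,
            "p_R2Y": perm.p_r2y,
            "p_Q2": perm.p_q2,
            "null_R2Y_mean": float(perm.permuted_r2y.mean()),
            "null_Q2_mean": float(perm.permuted_q2.mean()),
        },
    }
    p_model = outdir / "oplsda_report.json"
    p_model.write_text(json.dumps(report, indent=2))
    manifest.record("oplsda", [p_model], time.perf_counter() - t0, cv_seed)
    artifacts["oplsda_report"] = p_model

    t0 = time.perf_counter()
    sdm = select_sdms(
        complete, vip,
        vip_threshold=config.get("vip_threshold", 1.0),
        p_threshold=config.get("p_threshold", 0.05),
    )
    p_sdm = outdir / "sdm_table.tsv"
    sdm.to_csv(p_sdm, sep="\t")
    volcano = sdm.assign(neg_log10_p=-np.log10(sdm["p_value"]))
    p_volcano = outdir / "volcano_table.tsv"
    volcano[["log2_fc", "neg_log10_p", "vip", "direction", "selected"]].to_csv(p_volcano, sep="\t")
    counts, z = class_summary(sdm, complete)
    p_counts = outdir / "class_counts.tsv"
    counts.to_csv(p_counts, sep="\t")
    p_heat = outdir / "heatmap_zscores.tsv"
    z.to_csv(p_heat, sep="\t")
    manifest.record("sdm_selection", [p_sdm, p_volcano, p_counts, p_heat], time.perf_counter() - t0)
    artifacts.update(sdm_table=p_sdm, volcano_table=p_volcano,
                     class_counts=p_counts, heatmap=p_heat)

    artifacts["manifest"] = manifest.write()
    return artifacts


def run_panel_workflow(config: Mapping[str, Any], outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Panel comparison: means +/- SEM, pooled t, percent change, checks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config, seed)
    artifacts: dict[str, Path] = {}

    t0 = time.perf_counter()
    if "panel_tsv" in config:
        panel = pd.read_csv(config["panel_tsv"], sep="\t")
    else:
        sc = config.get("scenario")
        scenario = (
            PanelScenario(**{**sc, "seed": sc.get("seed", stage_seed(seed, "simulate_panel"))})
            if sc
            else PanelScenario(
                group_means=DEFAULT_PANEL_SCENARIO.group_means,
                cv=DEFAULT_PANEL_SCENARIO.cv,
                n_per_group=DEFAULT_PANEL_SCENARIO.n_per_group,
                seed=stage_seed(seed, "simulate_panel"),
            )
        )
        panel, _ = generate_panel(scenario)
    p_panel = outdir / "panel_measurements.tsv"
    panel.to_csv(p_panel, sep="\t", index=False)
    manifest.record("load_or_simulate", [p_panel], time.perf_counter() - t0)
    artifacts["panel"] = p_panel

    t0 = time.perf_counter()
    table = compare_all(panel, welch=config.get("welch", False))
    checks = []
    for met in table["metabolite"]:
        sub = panel[panel["metabolite"] == met]
        rep = check_assumptions(
            sub.loc[sub["group"] == "low", "concentration"],
            sub.loc[sub["group"] == "high", "concentration"],
        )
        checks.append({"metabolite": met, **asdict(rep)})
    p_table = outdir / "panel_comparisons.tsv"
    table.to_csv(p_table, sep="\t", index=False)
    p_checks = outdir / "assumption_checks.tsv"
    pd.DataFrame(checks).to_csv(p_checks, sep="\t", index=False)
    manifest.record("compare_groups", [p_table, p_checks], time.perf_counter() - t0)
    artifacts.update(comparisons=p_table, assumption_checks=p_checks)

    artifacts["manifest"] = manifest.write()
    return artifacts


def run_flux_workflow(config: Mapping[str, Any], outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """parse -> stoichiometry -> assemble -> solve -> normalize -> export."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config, seed)
    artifacts: dict[str, Path] = {}

    t0 = time.perf_counter()
    network = (
        parse_network(config["network"]) if "network" in config else load_default_network()
    )
    truth = None
    if "measurements_tsv" in config:
        meas_df = pd.read_csv(config["measurements_tsv"], sep="\t", header=None,
                              names=["metabolite", "concentration"], comment="#")
        measurements = dict(zip(meas_df["metabolite"], meas_df["concentration"]))
    elif "measurements" in config:
        measurements = dict(config["measurements"])
    else:
        truth, measurements = generate_flux_scenario(
            network,
            seed=stage_seed(seed, "simulate_flux"),
            noise_frac=config.get("noise_frac", 0.0),
        )
    p_meas = outdir / "measurements.tsv"
    pd.Series(measurements, name="concentration").rename_axis("metabolite").to_csv(
        p_meas, sep="\t", header=False
    )
    manifest.record("load_or_simulate", [p_meas], time.perf_counter() - t0)
    artifacts["measurements"] = p_meas

    t0 = time.perf_counter()
    model = FluxModel(network, measurements=measurements, scale=config.get("scale", 100.0))
    solution = model.fit(nonnegative=config.get("nonnegative", False)).normalize()
    table = solution.to_frame()
    diagnostics = dict(solution.diagnostics)
    if truth is not None:
        rel_err = (
            (solution.fluxes - truth.fluxes).abs() / truth.fluxes.abs().clip(lower=1e-12)
        )
        table["true_flux"] = truth.fluxes.reindex(table["reaction"]).to_numpy()
        diagnostics["max_relative_error_vs_truth"] = float(rel_err.max())
    p_table = outdir / "flux_table.tsv"
    table.to_csv(p_table, sep="\t", index=False)
    p_diag = outdir / "flux_diagnostics.json"
    p_diag.write_text(json.dumps(diagnostics, indent=2))
    graph_paths = export_flux_graph(network, solution, outdir)
    manifest.record(
        "solve_export",
        [p_table, p_diag, graph_paths["graphml"], graph_paths["dot"]],
        time.perf_counter() - t0,
    )
    artifacts.update(flux_table=p_table, diagnostics=p_diag, **graph_paths)

    if "conditions" in config:  # e.g. a low- and a high-elevation measurement set
        t0 = time.perf_counter()
        comparison = compare_conditions(
            network, config["conditions"], scale=config.get("scale", 100.0),
            nonnegative=config.get("nonnegative", False),
        )
        p_cmp = outdir / "flux_comparison.tsv"
        comparison.to_csv(p_cmp, sep="\t")
        manifest.record("compare_conditions", [p_cmp], time.perf_counter() - t0)
        artifacts["flux_comparison"] = p_cmp

    artifacts["manifest"] = manifest.write()
    return artifacts
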