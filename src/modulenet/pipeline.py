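"""End-to-end module-network inference pipeline.

simulate/load -> ensemble clustering -> consensus modules -> regulatory
programs -> random-regulator null and cutoff -> gene-set enrichment, driven
by one config and one master seed.  All intermediate artifacts are written
as human-readable TSV/JSON so a run can be audited file by file; rerunning
with the same config reproduces every output byte for byte.

Default parameters follow the reference analysis workflow: 30 clustering
runs, 100 condition trees per module, up to 100 regulators per node, a top
2% interaction cutoff and a 0.05 enrichment threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import coclustering_matrix, extract_tight_clusters
from .enrichment import enrich_modules
from .expression import (GeneSetCollection, filter_rows, read_expression_tsv,
                         read_gmt, read_regulator_list, write_expression_tsv,
                         write_regulator_list)
from .gibbs import run_ensemble
from .normal_gamma import NormalGammaPrior
from .programs import learn_programs
from .significance import apply_cutoff, null_scores, score_histogram
from .synthetic import SyntheticConfig, generate_dataset, recovery_metrics


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Flat configuration of the whole pipeline (YAML-loadable)."""

    # input (real mode) -- leave unset to run in synthetic mode
    matrix_path: str | None = None
    regulators_path: str | None = None
    gmt_path: str | None = None
    min_sd: float = 0.0
    # synthetic mode
    synthetic: SyntheticConfig | None = None
    # model prior
    prior_lambda0: float = 0.1
    prior_alpha0: float = 0.1
    prior_beta_scale: float = 0.1
    # ensemble clustering
    n_runs: int = 30
    n_sweeps: int = 100
    # consensus
    membership_threshold: float = 0.7
    min_size: int = 3
    # regulatory programs
    n_trees: int = 100
    top_k: int = 100
    beta: float = 2.0
    tree_sweeps: int = 50
    # significance
    quantile: float = 0.02
    null_draws: int = 1000
    # enrichment
    alpha: float = 0.05
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_yaml_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        flat: dict = {}
        nested_map = {
            "input": {"matrix": "matrix_path", "regulators": "regulators_path",
                      "gmt": "gmt_path", "min_sd": "min_sd"},
            "model": {"lambda0": "prior_lambda0", "alpha0": "prior_alpha0",
                      "beta_scale": "prior_beta_scale"},
            "clustering": {"n_runs": "n_runs", "n_sweeps": "n_sweeps"},
            "consensus": {"membership_threshold": "membership_threshold",
                          "min_size": "min_size"},
            "programs": {"n_trees": "n_trees", "top_k": "top_k", "beta": "beta",
                         "tree_sweeps": "tree_sweeps"},
            "significance": {"quantile": "quantile", "null_draws": "null_draws"},
            "enrichment": {"alpha": "alpha"},
        }
        for section, mapping in nested_map.items():
            for key, val in (raw.pop(section, {}) or {}).items():
                if key not in mapping:
                    raise ValueError(f"unknown config key {section}.{key}")
                flat[mapping[key]] = val
        synth = raw.pop("synthetic", None)
        if synth is not None:
            flat["synthetic"] = SyntheticConfig.from_dict(synth)
        for key, val in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key}")
            flat[key] = val
        return cls(**flat)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns a summary dict and writes all
    artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"mode": "synthetic" if cfg.matrix_path is None else "real"}

    # -- stage: input ---------------------------------------------------
    @_stage("input")
    def load_inputs():
        if cfg.matrix_path is None:
            synth = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
            matrix, candidates, truth = generate_dataset(synth)
            write_expression_tsv(matrix, out / "matrix.tsv")
            write_regulator_list(candidates, out / "regulators.txt")
            truth.save(out / "truth.json")
            gene_sets = GeneSetCollection(
                {f"planted_{m}": list(genes)
                 for m, genes in truth.module_members.items()},
                list(matrix.row_ids))
            return matrix, candidates, truth, gene_sets
        matrix = read_expression_tsv(cfg.matrix_path, strict=False)
        if cfg.min_sd > 0:
            matrix = filter_rows(matrix, min_sd=cfg.min_sd)
        candidates = read_regulator_list(cfg.regulators_path)
        candidates.validate(matrix)
        gene_sets = (read_gmt(cfg.gmt_path, universe=matrix.row_ids)
                     if cfg.gmt_path else None)
        return matrix, candidates, None, gene_sets

    matrix, candidates, truth, gene_sets = load_inputs()
    summary["n_rows"] = matrix.n_rows
    summary["n_cols"] = matrix.n_cols

    prior = NormalGammaPrior.from_matrix(matrix, lambda0=cfg.prior_lambda0,
                                         alpha0=cfg.prior_alpha0,
                                         beta_scale=cfg.prior_beta_scale)

    # -- stage: ensemble clustering ------------------------------------
    @_stage("clustering")
    def cluster():
        solutions = run_ensemble(matrix, prior, n_runs=cfg.n_runs,
                                 n_sweeps=cfg.n_sweeps, base_seed=cfg.seed)
        runs_dir = out / "runs"
        runs_dir.mkdir(exist_ok=True)
        for i, sol in enumerate(solutions):
            sol.save(runs_dir / f"run_{i:03d}.json")
        return solutions

    solutions = cluster()
    summary["n_runs"] = len(solutions)

    # -- stage: consensus ----------------------------------------------
    @_stage("consensus")
    def consensus():
        C = coclustering_matrix(solutions)
        modules = extract_tight_clusters(C, cfg.membership_threshold, cfg.min_size)
        if not modules.clusters:
            raise PipelineError("stage 'consensus' failed: no tight clusters found")
        modules.save(out / "modules.json")
        return modules

    modules = consensus()
    summary["n_modules"] = len(modules.clusters)
    summary["n_module_genes"] = int(sum(len(c) for c in modules.clusters))

    # -- stage: regulatory programs ------------------------------------
    @_stage("programs")
    def programs_stage():
        progs = learn_programs(modules, matrix, candidates, prior,
                               n_trees=cfg.n_trees, top_k=cfg.top_k,
                               beta=cfg.beta, tree_sweeps=cfg.tree_sweeps,
                               base_seed=cfg.seed + 2_000_000)
        progs.table.to_csv(out / "scores.tsv", sep="\t", index=False)
        progs.save(out / "programs.json")
        return progs

    progs = programs_stage()
    summary["n_scored_interactions"] = int(len(progs.table))

    # -- stage: significance -------------------------------------------
    @_stage("significance")
    def significance_stage():
        null = null_scores(progs, matrix, candidates, n_draws=cfg.null_draws,
                           seed=cfg.seed + 1_000_000)
        calls = apply_cutoff(progs.table, null, cfg.quantile)
        calls.table.to_csv(out / "calls.tsv", sep="\t", index=False)
        pd.DataFrame({"null_score": null.scores}).to_csv(
            out / "null_scores.tsv", sep="\t", index=False)
        score_histogram(progs.table, null, out / "histogram.tsv",
                        out / "histogram.png")
        (out / "significance.json").write_text(json.dumps({
            "cutoff_score": calls.cutoff_score,
            "max_null_score": calls.max_null_score,
            "quantile": calls.quantile_used,
            "n_pass": int(calls.table["passes_cutoff"].sum()),
        }), encoding="utf-8")
        return null, calls

    null, calls = significance_stage()
    summary["cutoff_score"] = calls.cutoff_score
    summary["max_null_score"] = calls.max_null_score
    summary["n_pass"] = int(calls.table["passes_cutoff"].sum())

    # -- stage: enrichment ---------------------------------------------
    if gene_sets is not None:
        @_stage("enrichment")
        def enrichment_stage():
            table = enrich_modules(modules, gene_sets, cfg.alpha)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            return table

        enr = enrichment_stage()
        summary["n_enriched_pairs"] = int(enr["enriched"].sum()) if len(enr) else 0

    # -- stage: recovery (synthetic only) ------------------------------
    if truth is not None:
        @_stage("recovery")
        def recovery_stage():
            report = recovery_metrics(truth, modules, progs.table)
            (out / "recovery.json").write_text(json.dumps(report), encoding="utf-8")
            return report

        report = recovery_stage()
        summary["ari"] = report["ari"]
        summary["top1_regulator_recovery"] = report.get("top1_regulator_recovery")

    log = {
        "modulenet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "derived_seeds": {
            "clustering_base": cfg.seed,
            "programs_base": cfg.seed + 2_000_000,
            "null": cfg.seed + 1_000_000,
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    (out / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    return summary
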