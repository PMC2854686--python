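"""Synthetic expression data with planted module-network structure.

The generator emulates the statistical structure a module-network analysis
expects to find in a mixed mRNA/miRNA tumor expression compendium:

* **modules** of tightly co-expressed genes, each with its own partition of
  the samples into condition clusters; within a condition cluster the
  module's genes share one mean,
* **direct regulators** whose (standardized) profile tracks the module mean
  with either sign,
* **indirect regulators** whose influence is routed through a hidden
  intermediate transcription factor: the regulator tracks the module, while
  the intermediate's *measured* row is blurred by divergence noise -- the
  situation where a repressive TF sits between a miRNA and the module genes
  but its own transcript no longer correlates with either,
* **background genes** and **decoy regulators** of i.i.d. noise,
* **miRNA-kind** rows measured on a different absolute scale
  (``mirna_scale``) than mRNA rows; only row shapes, not scales, carry
  signal.

Everything is reproducible from a single seed; per-entity substreams are
spawned deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .expression import (CandidateRegulatorSet, ExpressionMatrix,
                         standardize_row)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the "strong-signal" conditions: three modules of 20 genes
    across 40 samples with condition-cluster means (SD 2.0) well separated
    from the per-gene noise (SD 0.3).
    """

    n_modules: int = 3
    genes_per_module: tuple[int, int] = (20, 20)
    n_background: int = 0
    n_samples: int = 40
    cond_clusters_per_module: tuple[int, int] = (2, 4)
    cluster_mean_sd: float = 2.0
    gene_noise_sd: float = 0.3
    n_direct_regulators_per_module: int = 1
    n_indirect_regulators_per_module: int = 1
    indirect_divergence_sd: float = 2.0
    mirna_fraction: float = 0.5
    mirna_scale: float = 0.25
    n_decoy_regulators: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_modules < 0 or self.n_background < 0 or self.n_decoy_regulators < 0:
            raise ValueError("counts must be >= 0")
        if self.n_modules == 0 and self.n_background == 0:
            raise ValueError("empty dataset: no modules and no background genes")
        lo, hi = self.genes_per_module
        if not (1 <= lo <= hi):
            raise ValueError("invalid genes_per_module range")
        clo, chi = self.cond_clusters_per_module
        if not (2 <= clo <= chi <= self.n_samples):
            raise ValueError("invalid cond_clusters_per_module range")
        if self.cluster_mean_sd < 0 or self.gene_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.mirna_fraction <= 1.0):
            raise ValueError("mirna_fraction must be in [0, 1]")
        if self.mirna_scale <= 0:
            raise ValueError("mirna_scale must be > 0")
        if (self.n_direct_regulators_per_module < 0
                or self.n_indirect_regulators_per_module < 0):
            raise ValueError("regulator counts must be >= 0")

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        d["genes_per_module"] = list(self.genes_per_module)
        d["cond_clusters_per_module"] = list(self.cond_clusters_per_module)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("genes_per_module", "cond_clusters_per_module"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def strong_signal_config(**overrides) -> SyntheticConfig:
    """Strong-signal conditions: condition-cluster means (SD 2.0) dominate
    gene noise (SD 0.3)."""
    return SyntheticConfig(**overrides)


def moderate_signal_config(**overrides) -> SyntheticConfig:
    """Moderate conditions: means SD 1.0 against gene noise SD 0.5."""
    params = dict(cluster_mean_sd=1.0, gene_noise_sd=0.5)
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass(frozen=True)
class RegulatorTruth:
    id: str
    module: str
    mode: str  # "direct" | "indirect"
    sign: int  # +1 / -1 relative to the module mean profile


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    module_members: dict[str, list[str]]
    condition_assignment: dict[str, dict[str, int]]
    cluster_means: dict[str, dict[int, float]]
    regulators: list[RegulatorTruth]
    hidden_intermediates: dict[str, str]  # indirect regulator id -> hidden TF id

    def regulators_of(self, module: str, mode: str | None = None) -> list[RegulatorTruth]:
        return [r for r in self.regulators
                if r.module == module and (mode is None or r.mode == mode)]

    def gene_labels(self) -> dict[str, str]:
        return {g: m for m, genes in self.module_members.items() for g in genes}

    def to_dict(self) -> dict:
        return {
            "module_members": self.module_members,
            "condition_assignment": self.condition_assignment,
            "cluster_means": {m: {str(c): v for c, v in cv.items()}
                              for m, cv in self.cluster_means.items()},
            "regulators": [asdict(r) for r in self.regulators],
            "hidden_intermediates": self.hidden_intermediates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            module_members={m: list(v) for m, v in d["module_members"].items()},
            condition_assignment={m: {s: int(c) for s, c in v.items()}
                                  for m, v in d["condition_assignment"].items()},
            cluster_means={m: {int(c): float(v) for c, v in cv.items()}
                           for m, cv in d["cluster_means"].items()},
            regulators=[RegulatorTruth(**r) for r in d["regulators"]],
            hidden_intermediates=dict(d["hidden_intermediates"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def generate_dataset(cfg: SyntheticConfig):
    """Generate ``(ExpressionMatrix, CandidateRegulatorSet, GroundTruth)``.

    Candidate regulators are the planted direct and indirect regulators plus
    the decoys -- never the hidden intermediates, whose measured rows are in
    the matrix (they could in principle be clustered) but are decorrelated
    from their true profile by ``indirect_divergence_sd``.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    (ss_modules, ss_background, ss_regulators, ss_decoys,
     ss_kinds) = root.spawn(5)

    sample_ids = [f"s{j + 1:03d}" for j in range(cfg.n_samples)]

    row_ids: list[str] = []
    kinds: list[str] = []
    rows: list[np.ndarray] = []

    module_members: dict[str, list[str]] = {}
    condition_assignment: dict[str, dict[str, int]] = {}
    cluster_means: dict[str, dict[int, float]] = {}
    module_profiles: dict[str, np.ndarray] = {}

    mod_streams = ss_modules.spawn(max(cfg.n_modules, 1))
    for i in range(cfg.n_modules):
        rng = np.random.default_rng(mod_streams[i])
        mname = f"m{i + 1:02d}"
        n_genes = int(rng.integers(cfg.genes_per_module[0],
                                   cfg.genes_per_module[1] + 1))
        n_cond = int(rng.integers(cfg.cond_clusters_per_module[0],
                                  cfg.cond_clusters_per_module[1] + 1))
        assign = rng.integers(0, n_cond, size=cfg.n_samples)
        means = rng.normal(0.0, cfg.cluster_mean_sd, size=n_cond)
        profile = means[assign]
        module_profiles[mname] = profile
        condition_assignment[mname] = {s: int(c) for s, c in zip(sample_ids, assign)}
        cluster_means[mname] = {int(c): float(means[c]) for c in range(n_cond)}
        members = []
        for k in range(n_genes):
            gid = f"{mname}_g{k + 1:03d}"
            members.append(gid)
            row_ids.append(gid)
            kinds.append("mrna")
            rows.append(profile + rng.normal(0.0, cfg.gene_noise_sd, cfg.n_samples))
        module_members[mname] = members

    rng_bg = np.random.default_rng(ss_background)
    for k in range(cfg.n_background):
        row_ids.append(f"bg_{k + 1:04d}")
        kinds.append("mrna")
        rows.append(rng_bg.normal(0.0, 1.0, cfg.n_samples))

    regulators: list[RegulatorTruth] = []
    hidden: dict[str, str] = {}
    candidate_ids: list[str] = []
    rng_reg = np.random.default_rng(ss_regulators)
    rng_kind = np.random.default_rng(ss_kinds)

    def emit_regulator(base_id: str, profile: np.ndarray) -> str:
        is_mirna = bool(rng_kind.random() < cfg.mirna_fraction)
        rid = ("mir-" + base_id) if is_mirna else base_id
        row = profile * cfg.mirna_scale if is_mirna else profile
        row_ids.append(rid)
        kinds.append("mirna" if is_mirna else "mrna")
        rows.append(row)
        return rid

    for i in range(cfg.n_modules):
        mname = f"m{i + 1:02d}"
        z = standardize_row(module_profiles[mname])
        for r in range(cfg.n_direct_regulators_per_module):
            sign = int(rng_reg.choice([-1, 1]))
            profile = sign * z + rng_reg.normal(0.0, cfg.gene_noise_sd, cfg.n_samples)
            rid = emit_regulator(f"dreg{r + 1}_{mname}", profile)
            candidate_ids.append(rid)
            regulators.append(RegulatorTruth(rid, mname, "direct", sign))
        for r in range(cfg.n_indirect_regulators_per_module):
            sign = int(rng_reg.choice([-1, 1]))
            # regulator tracks the module through a repressive intermediate:
            # true intermediate profile anti-correlates with both
            profile = sign * z + rng_reg.normal(0.0, cfg.gene_noise_sd, cfg.n_samples)
            rid = emit_regulator(f"ireg{r + 1}_{mname}", profile)
            candidate_ids.append(rid)
            regulators.append(RegulatorTruth(rid, mname, "indirect", sign))
            tf_id = f"tf_hidden_{mname}_{r + 1}"
            tf_row = (-sign * z
                      + rng_reg.normal(0.0, cfg.indirect_divergence_sd, cfg.n_samples))
            row_ids.append(tf_id)
            kinds.append("mrna")
            rows.append(tf_row)
            hidden[rid] = tf_id

    rng_dec = np.random.default_rng(ss_decoys)
    for k in range(cfg.n_decoy_regulators):
        profile = rng_dec.normal(0.0, 1.0, cfg.n_samples)
        rid = emit_regulator(f"decoy_{k + 1:03d}", profile)
        candidate_ids.append(rid)

    matrix = ExpressionMatrix(row_ids, sample_ids,
                              np.vstack(rows) if rows else np.zeros((0, cfg.n_samples)),
                              kinds)
    truth = GroundTruth(module_members, condition_assignment, cluster_means,
                        regulators, hidden)
    return matrix, CandidateRegulatorSet(candidate_ids), truth


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def recovery_metrics(truth: GroundTruth, modules, scores=None) -> dict:
    """Compare inferred tight clusters (and optional regulator scores)
    against the planted structure.

    Returns a dict with per-module best-match Jaccard indices, the adjusted
    Rand index of the gene partition restricted to planted module genes
    (unassigned genes count as singletons), the fraction of matched modules
    whose top-ranked regulator is a planted regulator of that module, and
    the rank of every planted regulator within its matched module's ranking.
    """
    inferred = {f"cluster_{i}": set(cl) for i, cl in enumerate(modules.clusters)}
    gene_to_cluster: dict[str, str] = {}
    for name, members in inferred.items():
        for g in members:
            gene_to_cluster[g] = name

    true_labels: list[str] = []
    pred_labels: list[str] = []
    for mname, members in truth.module_members.items():
        for g in members:
            true_labels.append(mname)
            pred_labels.append(gene_to_cluster.get(g, f"singleton_{g}"))
    ari = float(adjusted_rand_score(true_labels, pred_labels)) if true_labels else 0.0

    jaccard: dict[str, float] = {}
    best_match: dict[str, str | None] = {}
    for mname, members in truth.module_members.items():
        mset = set(members)
        best, best_j = None, 0.0
        for cname, cset in inferred.items():
            inter = len(mset & cset)
            if inter == 0:
                continue
            j = inter / len(mset | cset)
            if j > best_j:
                best, best_j = cname, j
        jaccard[mname] = best_j
        best_match[mname] = best

    result: dict = {"ari": ari, "jaccard": jaccard, "best_match": best_match,
                    "mean_jaccard": float(np.mean(list(jaccard.values()))) if jaccard else 0.0}

    if scores is not None:
        # scores: DataFrame with columns module, regulator, global_score
        cluster_names = {name: i for i, name in enumerate(inferred)}
        planted_by_module = {m: {r.id for r in truth.regulators_of(m)}
                             for m in truth.module_members}
        top_hits = 0
        n_eval = 0
        ranks: dict[str, dict[str, int]] = {}
        # score tables name modules after TightClusterSet.as_dict(): the
        # i-th tight cluster is "module_{i+1:02d}"
        for mname, cname in best_match.items():
            if cname is None:
                continue
            idx = cluster_names[cname]
            module_id = f"module_{idx + 1:02d}"
            sub = scores[scores["module"] == module_id]
            if len(sub) == 0:
                continue
            sub = sub.sort_values(["global_score", "regulator"],
                                  ascending=[False, True]).reset_index(drop=True)
            n_eval += 1
            if sub.loc[0, "regulator"] in planted_by_module[mname]:
                top_hits += 1
            rank_of = {rid: rank + 1 for rank, rid in enumerate(sub["regulator"])}
            ranks[mname] = {rid: rank_of.get(rid, -1)
                            for rid in planted_by_module[mname]}
        result["top1_regulator_recovery"] = top_hits / n_eval if n_eval else 0.0
        result["planted_regulator_ranks"] = ranks
    return result
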