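"""Regulatory programs: condition trees and regulator scoring.

For each module (tight cluster) the samples are repeatedly partitioned into
condition clusters by a columns-only Gibbs run (the module's genes pooled),
and each partition is linked into a hierarchical tree by greedy agglomerative
merging: at every step the pair of condition clusters whose merge gains the
most block log marginal likelihood is joined, and the merge is recorded as an
internal node splitting a low-mean (left) from a high-mean (right) sample
set.

Candidate regulators are scored at every node with a fuzzy split score: the
regulator's standardized profile x is compared against the split through

    score(+) = max_z  sum_{c in L} ln s(b (z - x_c)) + sum_{c in R} ln s(b (x_c - z))

with s the logistic function and b a fixed sharpness.  The opposite
orientation swaps L and R; the better orientation determines the regulator's
sign.  Because x is standardized first, the score sees only the differential
expression of the regulator across the split, never its absolute scale --
the property that lets miRNA and mRNA regulators compete on equal footing.

Per-node top-K lists over many trees are aggregated into one non-negative
global score per (module, regulator): the sample-weighted sum of the
regulator's score above the node's top-K mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CandidateRegulatorSet, ExpressionMatrix, standardize_rows
from .gibbs import sample_solution
from .normal_gamma import BlockStats, NormalGammaPrior, block_logml


@dataclass(frozen=True)
class TreeLeaf:
    """One condition cluster: a sample set with its mean/SD summary."""

    samples: tuple[str, ...]
    mean: float
    sd: float


@dataclass(frozen=True)
class TreeNode:
    """A split between a low-mean (left) and high-mean (right) sample set."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    weight: int  # |left| + |right|


@dataclass
class ConditionTree:
    """Binary hierarchy over one module's condition clusters.

    ``nodes`` are stored in merge order (root last); leaves partition the
    module's samples.  A single-leaf tree has no nodes.
    """

    leaves: list[TreeLeaf]
    nodes: list[TreeNode]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for leaf in self.leaves:
            for s in leaf.samples:
                if s in seen:
                    raise ValueError("leaves do not partition the samples")
                seen.add(s)


def build_condition_trees(module_genes, matrix: ExpressionMatrix,
                          prior: NormalGammaPrior | None = None,
                          n_trees: int = 100, base_seed: int = 0,
                          n_sweeps: int = 50) -> list[ConditionTree]:
    """Sample ``n_trees`` condition hierarchies for one module.

    Each tree starts from an independent columns-only Gibbs clustering of
    the module's samples (seeds ``base_seed + t``) followed by greedy
    log-marginal-likelihood agglomeration of the resulting condition
    clusters.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    sub = matrix.subset_rows(list(module_genes))
    if sub.n_cols < 2:
        raise ValueError("need at least 2 samples to build condition trees")
    if prior is None:
        prior = NormalGammaPrior.from_matrix(sub)
    trees = []
    for t in range(n_trees):
        sol = sample_solution(sub, prior, n_sweeps=n_sweeps, seed=base_seed + t,
                              update_genes=False)
        cond = sol.condition_assignment[0]
        groups: dict[int, list[str]] = {}
        for cid in sub.col_ids:  # deterministic column order
            groups.setdefault(cond[cid], []).append(cid)
        trees.append(_agglomerate(sub, [tuple(g) for g in groups.values()], prior))
    return trees


def _pooled_stats(sub: ExpressionMatrix, samples: tuple[str, ...]) -> BlockStats:
    cols = [sub.col_index(c) for c in samples]
    return BlockStats.from_values(sub.values[:, cols])


def _agglomerate(sub: ExpressionMatrix, groups: list[tuple[str, ...]],
                 prior: NormalGammaPrior) -> ConditionTree:
    leaves = []
    for samples in groups:
        st = _pooled_stats(sub, samples)
        mean = st.s1 / st.n
        var = max(st.s2 / st.n - mean * mean, 0.0)
        leaves.append(TreeLeaf(samples, float(mean), float(np.sqrt(var))))

    clusters = [(samples, _pooled_stats(sub, samples)) for samples in groups]
    logmls = [block_logml(st, prior) for _, st in clusters]
    nodes: list[TreeNode] = []
    while len(clusters) > 1:
        best, best_gain = None, -np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                merged = clusters[a][1] + clusters[b][1]
                gain = block_logml(merged, prior) - logmls[a] - logmls[b]
                if gain > best_gain + 1e-15:
                    best, best_gain = (a, b), gain
        a, b = best
        sa, sta = clusters[a]
        sb, stb = clusters[b]
        mean_a, mean_b = sta.s1 / sta.n, stb.s1 / stb.n
        left, right = (sa, sb) if mean_a <= mean_b else (sb, sa)
        nodes.append(TreeNode(left, right, len(sa) + len(sb)))
        merged_samples = tuple(sa) + tuple(sb)
        merged_stats = sta + stb
        clusters[a] = (merged_samples, merged_stats)
        logmls[a] = block_logml(merged_stats, prior)
        del clusters[b]
        del logmls[b]
    return ConditionTree(leaves, nodes)


# ---------------------------------------------------------------------------
# node split score
# ---------------------------------------------------------------------------

def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def node_split_score(x_r: np.ndarray, left_idx, right_idx,
                     beta: float = 2.0) -> tuple[float, float, int]:
    """Fuzzy split score of one standardized regulator at one node.

    Returns ``(score, z, sign)`` where ``score <= 0`` is the best
    log-likelihood over both orientations, ``z`` the optimal split value
    (searched over midpoints of sorted unique regulator values plus the
    endpoints -- a finite deterministic grid) and ``sign`` +1 when the
    regulator is high on the high-mean side.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    left_idx = np.asarray(left_idx, dtype=int)
    right_idx = np.asarray(right_idx, dtype=int)
    if left_idx.size == 0 or right_idx.size == 0:
        raise ValueError("both sides of a split must be non-empty")
    xL = x_r[left_idx]
    xR = x_r[right_idx]
    u = np.unique(np.concatenate([xL, xR]))
    if u.size == 1:
        grid = u
    else:
        grid = np.concatenate([[u[0]], 0.5 * (u[:-1] + u[1:]), [u[-1]]])
    # orientation +: regulator low on the left, high on the right
    low = _log_sigmoid(beta * (grid[:, None] - xL[None, :])).sum(axis=1)
    high = _log_sigmoid(beta * (xR[None, :] - grid[:, None])).sum(axis=1)
    plus = low + high
    # orientation -: swap sides
    low_m = _log_sigmoid(beta * (grid[:, None] - xR[None, :])).sum(axis=1)
    high_m = _log_sigmoid(beta * (xL[None, :] - grid[:, None])).sum(axis=1)
    minus = low_m + high_m
    ip = int(np.argmax(plus))
    im = int(np.argmax(minus))
    if plus[ip] >= minus[im]:
        return float(plus[ip]), float(grid[ip]), 1
    return float(minus[im]), float(grid[im]), -1


def rank_candidates(scores: dict[str, float], top_k: int) -> list[str]:
    """Rank candidate ids by decreasing score; ties broken lexicographically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    order = sorted(scores, key=lambda rid: (-scores[rid], rid))
    return order[:top_k]


# ---------------------------------------------------------------------------
# module-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class NodeAssignment:
    """Top-K regulator list of one tree node, with the aggregation context
    (sample-fraction weight and top-K mean score) needed to score any extra
    regulator through the identical path."""

    module: str
    tree: int
    node: int
    weight: float  # node weight / total number of samples
    left: tuple[str, ...]
    right: tuple[str, ...]
    top: list[tuple[str, float, int]]  # (regulator, score, sign), ranked
    mean_top_score: float

    def to_dict(self) -> dict:
        return {"module": self.module, "tree": self.tree, "node": self.node,
                "weight": self.weight, "left": list(self.left),
                "right": list(self.right),
                "top": [[r, s, g] for r, s, g in self.top],
                "mean_top_score": self.mean_top_score}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeAssignment":
        return cls(d["module"], int(d["tree"]), int(d["node"]), float(d["weight"]),
                   tuple(d["left"]), tuple(d["right"]),
                   [(str(r), float(s), int(g)) for r, s, g in d["top"]],
                   float(d["mean_top_score"]))


@dataclass
class RegulatoryPrograms:
    """Learned programs for a set of modules: per-node assignments plus the
    aggregated global score table (one row per scored (module, regulator))."""

    assignments: list[NodeAssignment]
    table: pd.DataFrame  # columns: module, regulator, global_score, sign, n_nodes_assigned
    beta: float
    top_k: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "beta": self.beta, "top_k": self.top_k,
            "assignments": [a.to_dict() for a in self.assignments],
            "table": self.table.to_dict(orient="list"),
        }), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RegulatoryPrograms":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls([NodeAssignment.from_dict(a) for a in d["assignments"]],
                   pd.DataFrame(d["table"]), float(d["beta"]), int(d["top_k"]))


def node_regulator_score(assignment: NodeAssignment, x_std: np.ndarray,
                         col_index: dict[str, int], beta: float) -> tuple[float, int]:
    """Score one standardized regulator row at one recorded node.

    This is the single shared scoring path: the true program learning and the
    random-regulator null both go through it.
    """
    left = [col_index[c] for c in assignment.left]
    right = [col_index[c] for c in assignment.right]
    score, _z, sign = node_split_score(x_std, left, right, beta)
    return score, sign


def _aggregate_global(assignments: list[NodeAssignment],
                      module_ids: list[str]) -> pd.DataFrame:
    rows = []
    per_module: dict[str, dict[str, dict]] = {m: {} for m in module_ids}
    for a in assignments:
        for rid, score, sign in a.top:
            acc = per_module[a.module].setdefault(
                rid, {"contrib": 0.0, "signed_w": 0.0, "n_nodes": 0})
            acc["contrib"] += a.weight * (score - a.mean_top_score)
            acc["signed_w"] += a.weight * sign
            acc["n_nodes"] += 1
    for m in module_ids:
        for rid, acc in sorted(per_module[m].items()):
            rows.append({
                "module": m,
                "regulator": rid,
                "global_score": max(acc["contrib"], 0.0),
                "sign": 1 if acc["signed_w"] >= 0 else -1,
                "n_nodes_assigned": acc["n_nodes"],
            })
    table = pd.DataFrame(rows, columns=["module", "regulator", "global_score",
                                        "sign", "n_nodes_assigned"])
    return table.sort_values(["module", "global_score", "regulator"],
                             ascending=[True, False, True]).reset_index(drop=True)


def learn_programs(modules, matrix: ExpressionMatrix,
                   candidates: CandidateRegulatorSet,
                   prior: NormalGammaPrior | None = None,
                   n_trees: int = 100, top_k: int = 100, beta: float = 2.0,
                   tree_sweeps: int = 50, base_seed: int = 0) -> RegulatoryPrograms:
    """Learn the regulatory program of every module.

    ``modules`` is a :class:`~modulenet.consensus.TightClusterSet` or any
    mapping module id -> gene list.  For each module, ``n_trees`` condition
    trees are built (tree seeds are derived from ``base_seed`` and the module
    index) and up to ``top_k`` regulators are assigned per node; node scores
    are aggregated into the global score table.
    """
    candidates.validate(matrix)
    module_map = modules.as_dict() if hasattr(modules, "as_dict") else dict(modules)
    cand_ids = candidates.sorted_ids()
    cand_rows = np.array([matrix.row_index(r) for r in cand_ids])
    x_std = standardize_rows(matrix.values[cand_rows])
    col_index = {c: j for j, c in enumerate(matrix.col_ids)}
    n_total = matrix.n_cols

    assignments: list[NodeAssignment] = []
    for mi, (mid, genes) in enumerate(module_map.items()):
        trees = build_condition_trees(genes, matrix, prior, n_trees=n_trees,
                                      base_seed=base_seed + 10_000 * (mi + 1),
                                      n_sweeps=tree_sweeps)
        for ti, tree in enumerate(trees):
            for ni, node in enumerate(tree.nodes):
                left = [col_index[c] for c in node.left]
                right = [col_index[c] for c in node.right]
                scores: dict[str, float] = {}
                signs: dict[str, int] = {}
                for ci, rid in enumerate(cand_ids):
                    s, _z, sg = node_split_score(x_std[ci], left, right, beta)
                    scores[rid] = s
                    signs[rid] = sg
                top_ids = rank_candidates(scores, top_k)
                top = [(rid, scores[rid], signs[rid]) for rid in top_ids]
                mean_top = float(np.mean([s for _r, s, _g in top]))
                assignments.append(NodeAssignment(
                    mid, ti, ni, node.weight / n_total,
                    node.left, node.right, top, mean_top))
    table = _aggregate_global(assignments, list(module_map))
    return RegulatoryPrograms(assignments, table, beta, top_k)
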