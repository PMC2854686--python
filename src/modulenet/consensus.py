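"""Ensemble averaging and spectral tight-cluster extraction.

The ensemble of clustering runs is averaged into a co-clustering frequency
matrix F, with F[i, j] the fraction of runs in which genes i and j share a
cluster.  Tight clusters -- genes that consistently co-cluster across runs --
are peeled off one at a time: the dominant eigenvector of the remaining
frequency graph localizes on the heaviest consistent subset; genes whose
eigenvector weight is at least ``membership_threshold`` times the maximum
form the candidate, which is accepted if its mean pairwise frequency is at
least 0.5 and it is large enough, then removed from the graph.

The dominant eigenvector is obtained by power iteration started from the
highest-degree gene.  Starting from a localized vector matters: when the
frequency graph decomposes into (nearly) disconnected blocks of equal
weight, the dominant eigenvalue is (nearly) degenerate and a generic
eigensolver returns an arbitrary mixture of blocks, while power iteration
from a single vertex stays inside that vertex's block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gibbs import ClusterSolution


@dataclass
class CoclusterMatrix:
    """Symmetric gene x gene co-clustering frequency matrix (diagonal 1)."""

    ids: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        n = len(self.ids)
        if self.F.shape != (n, n):
            raise ValueError("frequency matrix shape does not match ids")
        if not np.allclose(self.F, self.F.T, atol=1e-12):
            raise ValueError("co-clustering matrix must be symmetric")
        if self.F.min() < -1e-12 or self.F.max() > 1 + 1e-12:
            raise ValueError("co-clustering frequencies must lie in [0, 1]")


@dataclass
class TightClusterSet:
    """Disjoint consensus gene clusters (modules, before regulator
    assignment)."""

    clusters: list[list[str]]
    min_size: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cl in self.clusters:
            if len(cl) < self.min_size:
                raise ValueError("cluster below min_size")
            for g in cl:
                if g in seen:
                    raise ValueError(f"gene {g} appears in two tight clusters")
                seen.add(g)

    def as_dict(self) -> dict[str, list[str]]:
        return {f"module_{i + 1:02d}": list(cl) for i, cl in enumerate(self.clusters)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"min_size": self.min_size, "clusters": self.clusters}),
            encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TightClusterSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls([list(map(str, cl)) for cl in d["clusters"]], int(d["min_size"]))


def coclustering_matrix(solutions: list[ClusterSolution]) -> CoclusterMatrix:
    """Average an ensemble into co-membership frequencies."""
    if not solutions:
        raise ValueError("need at least one clustering solution")
    ids = list(solutions[0].gene_assignment.keys())
    universe = set(ids)
    F = np.zeros((len(ids), len(ids)))
    for sol in solutions:
        if set(sol.gene_assignment) != universe:
            raise ValueError("solutions have mismatched gene universes")
        labels = np.array([sol.gene_assignment[g] for g in ids])
        F += (labels[:, None] == labels[None, :]).astype(float)
    F /= len(solutions)
    np.fill_diagonal(F, 1.0)
    return CoclusterMatrix(ids, F)


def _dominant_eigenvector(A: np.ndarray, tol: float = 1e-12,
                          max_iter: int = 10000) -> np.ndarray:
    """Power iteration from the highest-degree vertex (ties: lowest index)."""
    deg = A.sum(axis=1)
    v = np.zeros(A.shape[0])
    v[int(np.argmax(deg))] = 1.0
    for _ in range(max_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return v
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    return np.clip(v, 0.0, None)


def extract_tight_clusters(C: CoclusterMatrix,
                           membership_threshold: float = 0.7,
                           min_size: int = 3) -> TightClusterSet:
    """Iterative spectral peeling of tight clusters.

    Defaults: ``membership_threshold`` 0.7 and ``min_size`` 3 (the smallest
    module size worth reporting).  Every accepted cluster has mean pairwise
    co-clustering frequency >= 0.5; clusters are disjoint.

    Known degenerate case: two blocks of identical size and density coupled
    by a uniform background frequency produce an exactly symmetric dominant
    eigenvector and cannot be separated by any threshold; real ensembles
    break this symmetry.
    """
    if not (0.0 < membership_threshold <= 1.0):
        raise ValueError("membership_threshold must be in (0, 1]")
    work = C.F.copy()
    n = work.shape[0]
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[str]] = []
    while remaining.sum() >= max(min_size, 1):
        v = _dominant_eigenvector(work)
        vmax = v.max()
        if vmax <= 0.0:
            break
        cand = np.flatnonzero(v >= membership_threshold * vmax)
        cand = cand[remaining[cand]]
        if cand.size < min_size:
            break
        sub = C.F[np.ix_(cand, cand)]
        off = sub.size - cand.size
        mean_freq = (sub.sum() - np.trace(sub)) / off if off > 0 else 1.0
        if mean_freq < 0.5:
            break
        clusters.append([C.ids[i] for i in cand])
        remaining[cand] = False
        work[cand, :] = 0.0
        work[:, cand] = 0.0
    return TightClusterSet(clusters, min_size)
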