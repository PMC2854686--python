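"""Random-regulator null, score cutoff and true-vs-random histograms.

The statistical confidence of an assigned regulator is judged against a
null distribution obtained by pushing uniformly drawn regulators through the
*identical* scoring path at uniformly drawn (module, node) positions: only
the regulator identity is randomized, never the machinery.  The reported
regulator calls use a stringent quantile cutoff on the true interaction
scores (the default keeps the top 2% of scored interactions); the maximum
null score is reported alongside as the separation sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CandidateRegulatorSet, ExpressionMatrix, standardize_rows
from .programs import RegulatoryPrograms, node_regulator_score


@dataclass
class NullScoreSet:
    """Global scores of randomly assigned regulators."""

    scores: np.ndarray
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != self.n_draws:
            raise ValueError("score count does not match n_draws")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("null scores must be >= 0")

    @property
    def max_score(self) -> float:
        return float(self.scores.max()) if self.scores.size else 0.0


@dataclass
class RegulatorCalls:
    """Score table with the cutoff applied.

    ``passes_cutoff`` is ``score >= cutoff_score``; ties at the cutoff are
    all retained.
    """

    table: pd.DataFrame  # module, regulator, global_score, sign, passes_cutoff
    cutoff_score: float
    max_null_score: float
    quantile_used: float


def null_scores(programs: RegulatoryPrograms, matrix: ExpressionMatrix,
                candidates: CandidateRegulatorSet, n_draws: int = 1000,
                seed: int = 0) -> NullScoreSet:
    """Score ``n_draws`` random (regulator, module-node) assignments.

    Each draw picks a regulator uniformly from the candidate set and a node
    uniformly from all recorded (module, tree, node) positions, scores it
    through :func:`~modulenet.programs.node_regulator_score` and aggregates
    exactly as the global score does for a single assignment:
    ``max(0, w * (s - mean_topK))``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not programs.assignments:
        raise ValueError("programs contain no scored nodes")
    rng = np.random.default_rng(seed)
    cand_ids = candidates.sorted_ids()
    cand_rows = np.array([matrix.row_index(r) for r in cand_ids])
    x_std = standardize_rows(matrix.values[cand_rows])
    col_index = {c: j for j, c in enumerate(matrix.col_ids)}
    n_nodes = len(programs.assignments)
    scores = np.empty(n_draws)
    for i in range(n_draws):
        ri = int(rng.integers(len(cand_ids)))
        ai = int(rng.integers(n_nodes))
        a = programs.assignments[ai]
        s, _sign = node_regulator_score(a, x_std[ri], col_index, programs.beta)
        scores[i] = max(0.0, a.weight * (s - a.mean_top_score))
    return NullScoreSet(scores, n_draws, seed)


def apply_cutoff(table: pd.DataFrame, null: NullScoreSet | None,
                 quantile: float = 0.02) -> RegulatorCalls:
    """Flag the top ``quantile`` fraction of scored interactions.

    The cutoff is the ``ceil(quantile * N)``-th largest true score, so
    exactly that many interactions pass unless ties at the cutoff add more
    (ties are all retained).  ``quantile = 1`` keeps everything.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty score table")
    scores = np.sort(np.asarray(table["global_score"], dtype=float))[::-1]
    k = int(np.ceil(quantile * scores.size))
    cutoff = float(scores[k - 1])
    out = table.copy()
    out["passes_cutoff"] = out["global_score"] >= cutoff
    return RegulatorCalls(out, cutoff,
                          null.max_score if null is not None else float("nan"),
                          quantile)


def score_histogram(table: pd.DataFrame, null: NullScoreSet,
                    tsv_path: str | Path, png_path: str | Path | None = None,
                    bins: int = 30) -> pd.DataFrame:
    """Binned counts of true vs random regulator scores (the two-color
    separation plot), written as TSV and optionally rendered to PNG."""
    true_scores = np.asarray(table["global_score"], dtype=float)
    lo = 0.0
    hi = max(true_scores.max() if true_scores.size else 1.0,
             null.scores.max() if null.scores.size else 1.0, 1e-9)
    edges = np.linspace(lo, hi, bins + 1)
    true_counts, _ = np.histogram(true_scores, bins=edges)
    null_counts, _ = np.histogram(null.scores, bins=edges)
    hist = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "true_count": true_counts,
        "null_count": null_counts,
    })
    hist.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        width = edges[1] - edges[0]
        ax.bar(edges[:-1], null_counts, width=width, align="edge",
               color="tab:green", alpha=0.6, label="random regulators")
        ax.bar(edges[:-1], true_counts, width=width, align="edge",
               color="gold", alpha=0.6, label="true regulators")
        ax.set_xlabel("global regulator score")
        ax.set_ylabel("count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return hist
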