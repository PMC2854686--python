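"""Normal-gamma marginal likelihood of expression blocks.

The clustering model assumes that within one (gene cluster x condition
cluster) block all expression values are draws from a single Gaussian with
unknown mean mu and precision tau, with a conjugate normal-gamma prior

    mu | tau ~ N(mu0, 1 / (lambda0 * tau)),     tau ~ Gamma(alpha0, beta0).

Integrating (mu, tau) out gives a closed-form log marginal likelihood per
block; the score of a full two-way clustering is the sum of block scores.
Only the sufficient statistics (n, sum, sum of squares) of a block are
needed, which is what makes incremental Gibbs moves cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import gammaln

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NormalGammaPrior:
    """Conjugate prior on the (mean, precision) of a block Gaussian.

    Defaults are weakly informative; :meth:`from_matrix` adapts the prior
    location and scale to the data (grand mean / grand variance), which keeps
    the score meaningful for matrices on arbitrary log scales.
    """

    mu0: float = 0.0
    lambda0: float = 0.1
    alpha0: float = 0.1
    beta0: float = 0.1

    def __post_init__(self) -> None:
        if not (self.lambda0 > 0 and self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("lambda0, alpha0, beta0 must all be > 0")

    @classmethod
    def from_matrix(cls, matrix, lambda0: float = 0.1, alpha0: float = 0.1,
                    beta_scale: float = 0.1) -> "NormalGammaPrior":
        values = np.asarray(matrix.values, dtype=float)
        var = float(values.var())
        if var <= 0.0:
            var = 1.0
        return cls(mu0=float(values.mean()), lambda0=lambda0, alpha0=alpha0,
                   beta0=beta_scale * var)


@dataclass(frozen=True)
class BlockStats:
    """Sufficient statistics of one block: count, sum, sum of squares."""

    n: int
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n == 0 and (self.s1 != 0.0 or self.s2 != 0.0):
            raise ValueError("empty block must have zero sums")
        if self.n > 0:
            # Cauchy-Schwarz: n * s2 >= s1^2 (up to rounding)
            slack = self.n * self.s2 - self.s1 ** 2
            tol = 1e-9 * max(1.0, abs(self.s2) * self.n)
            if slack < -tol:
                raise ValueError("inconsistent block statistics: n*s2 < s1^2")

    @classmethod
    def from_values(cls, values) -> "BlockStats":
        x = np.asarray(values, dtype=float).ravel()
        return cls(int(x.size), float(x.sum()), float((x * x).sum()))

    def __add__(self, other: "BlockStats") -> "BlockStats":
        return BlockStats(self.n + other.n, self.s1 + other.s1, self.s2 + other.s2)


def block_logml_arrays(n, s1, s2, prior: NormalGammaPrior) -> np.ndarray:
    """Vectorized block log marginal likelihood.

    Entries with ``n == 0`` contribute exactly 0 (empty product), so padded
    or absent blocks are harmless.
    """
    n = np.asarray(n, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    nz = n > 0
    nsafe = np.where(nz, n, 1.0)
    m = s1 / nsafe
    ssd = s2 - nsafe * m * m  # within-block sum of squared deviations
    # rounding can push ssd slightly negative for (near-)constant blocks
    ssd = np.maximum(ssd, 0.0)
    lam_n = prior.lambda0 + n
    alpha_n = prior.alpha0 + 0.5 * n
    beta_n = (prior.beta0 + 0.5 * ssd
              + prior.lambda0 * n * (m - prior.mu0) ** 2 / (2.0 * lam_n))
    if np.any(beta_n[nz] <= 0.0):
        raise ValueError("non-positive posterior beta: inconsistent statistics")
    out = (-0.5 * n * _LN2PI
           + 0.5 * (np.log(prior.lambda0) - np.log(lam_n))
           + gammaln(alpha_n) - gammaln(prior.alpha0)
           + prior.alpha0 * np.log(prior.beta0) - alpha_n * np.log(beta_n))
    return np.where(nz, out, 0.0)


def block_logml(stats: BlockStats, prior: NormalGammaPrior) -> float:
    """Log marginal likelihood of one block under the normal-gamma model."""
    return float(block_logml_arrays(stats.n, stats.s1, stats.s2, prior))


def partition_logml(matrix, solution, prior: NormalGammaPrior) -> float:
    """Score of a full two-way clustering: sum of block scores.

    ``solution`` must provide ``gene_assignment`` (row id -> gene cluster)
    covering every matrix row and, per gene cluster, ``condition_assignment``
    (column id -> condition cluster) covering every column.  Each block pools
    all values of the cluster's genes in the cluster's conditions ("tightly
    co-expressed" semantics: genes of a cluster share the block mean and
    precision).
    """
    gene_assignment: Mapping[str, int] = solution.gene_assignment
    condition_assignment: Mapping[int, Mapping[str, int]] = solution.condition_assignment

    if set(gene_assignment) != set(matrix.row_ids):
        raise ValueError("gene assignment does not cover the matrix rows")

    clusters: dict[int, list[int]] = {}
    for rid, k in gene_assignment.items():
        clusters.setdefault(k, []).append(matrix.row_index(rid))

    col_set = set(matrix.col_ids)
    total = 0.0
    for k, rows in clusters.items():
        if k not in condition_assignment:
            raise ValueError(f"no condition assignment for gene cluster {k}")
        cond = condition_assignment[k]
        if set(cond) != col_set:
            raise ValueError(
                f"condition assignment of cluster {k} does not cover all columns"
            )
        groups: dict[int, list[int]] = {}
        for cid, c in cond.items():
            groups.setdefault(c, []).append(matrix.col_index(cid))
        sub = matrix.values[np.asarray(rows)]
        for cols in groups.values():
            block = sub[:, np.asarray(cols)]
            total += block_logml(BlockStats.from_values(block), prior)
    return total
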