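"""Two-way Gibbs sampling of gene and condition clusters.

One run of :func:`sample_solution` starts from singleton gene clusters and
alternates full sweeps of (i) per-cluster condition reassignment -- each
column, in random order, is moved among a cluster's existing condition
clusters plus one empty cluster with probability proportional to
``exp(delta log-marginal-likelihood)`` -- and (ii) gene reassignment, the
same scheme applied to genes across gene clusters.  Conditions are swept
first so that gene moves are always evaluated against informative condition
partitions.  The number of clusters is
open-ended (Chinese-restaurant style): the empty-cluster option carries a
concentration weight ``gamma`` and empty clusters are pruned.  The best
(maximum a posteriori over all visited states) solution is returned; the
run is a point estimate, not a posterior sample.

Repeated runs with distinct seeds (:func:`run_ensemble`) form the ensemble
that the consensus step averages into tight clusters.

The sufficient-statistic bookkeeping lives in :class:`GibbsState`, which also
exposes the exact incremental score change of a single gene move
(:meth:`GibbsState.delta_move_gene`) for auditing against full
recomputation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .normal_gamma import NormalGammaPrior, partition_logml

NEW_CLUSTER = -1  # sentinel target for "open a new cluster"


@dataclass
class ClusterSolution:
    """One run's two-way clustering.

    ``gene_assignment`` maps row id -> gene cluster index;
    ``condition_assignment`` maps gene cluster index -> (column id ->
    condition cluster index).  ``logml`` is the normal-gamma score of the
    stored assignment.
    """

    gene_assignment: dict[str, int]
    condition_assignment: dict[int, dict[str, int]]
    logml: float
    seed: int
    n_sweeps: int

    def n_gene_clusters(self) -> int:
        return len(set(self.gene_assignment.values()))

    def gene_clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for rid, k in self.gene_assignment.items():
            out.setdefault(k, []).append(rid)
        return out

    def to_dict(self) -> dict:
        return {
            "gene_assignment": self.gene_assignment,
            "condition_assignment": {str(k): v for k, v in self.condition_assignment.items()},
            "logml": self.logml,
            "seed": self.seed,
            "n_sweeps": self.n_sweeps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterSolution":
        return cls(
            gene_assignment={str(k): int(v) for k, v in d["gene_assignment"].items()},
            condition_assignment={
                int(k): {str(c): int(v) for c, v in cv.items()}
                for k, cv in d["condition_assignment"].items()
            },
            logml=float(d["logml"]),
            seed=int(d["seed"]),
            n_sweeps=int(d["n_sweeps"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ClusterSolution":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


class GibbsState:
    """Padded-array sufficient statistics of a two-way clustering.

    Gene clusters occupy "slots"; each slot carries its own condition
    partition of the columns plus, per condition cluster, the pooled block
    statistics (count, sum, sum of squares).  All score deltas are computed
    from these statistics without touching the raw data matrix, which is
    what makes Gibbs moves cheap.
    """

    def __init__(self, matrix, prior: NormalGammaPrior,
                 gene_labels=None, cond_labels=None, gamma: float = 1.0):
        self.matrix = matrix
        self.prior = prior
        self.gamma = float(gamma)
        self.X = np.asarray(matrix.values, dtype=float)
        self.X2 = self.X * self.X
        self.G, self.Cn = self.X.shape
        self.rowsum = self.X.sum(axis=1)
        self.rowsumsq = self.X2.sum(axis=1)

        # log-marginal-likelihood constants: logml(n,s1,s2) = const[n] - alpha_n*ln(beta_n)
        # largest count a candidate block can reach: the full matrix plus one
        # extra gene row or column during a proposed move
        nmax = self.G * self.Cn + max(self.G, self.Cn)
        narr = np.arange(nmax + 1, dtype=float)
        self._const = (-0.5 * narr * np.log(2.0 * np.pi)
                       + 0.5 * (np.log(prior.lambda0) - np.log(prior.lambda0 + narr))
                       + gammaln(prior.alpha0 + 0.5 * narr) - gammaln(prior.alpha0)
                       + prior.alpha0 * np.log(prior.beta0))
        self._constl = self._const.tolist()  # python floats for the scalar path
        self._mu0 = prior.mu0
        self._lam0 = prior.lambda0
        self._alpha0 = prior.alpha0
        self._beta0 = prior.beta0

        if gene_labels is None:
            gene_labels = np.zeros(self.G, dtype=np.int64)
        gene_labels = np.asarray(gene_labels, dtype=np.int64)
        if gene_labels.shape != (self.G,):
            raise ValueError("gene_labels must have one entry per matrix row")

        n_slots = int(gene_labels.max()) + 1
        self.Kcap = max(8, 2 * n_slots)
        self.Cm = 4
        if cond_labels is not None:
            for lab in cond_labels.values():
                self.Cm = max(self.Cm, int(np.max(lab)) + 2)
        self._alloc_arrays()
        self.gene_label = gene_labels.copy()

        for k in range(n_slots):
            members = np.flatnonzero(self.gene_label == k)
            if members.size == 0:
                continue
            self.active[k] = True
            self.nk[k] = members.size
            if cond_labels is not None and k in cond_labels:
                lab = np.asarray(cond_labels[k], dtype=np.int64)
                if lab.shape != (self.Cn,):
                    raise ValueError("condition labels must cover all columns")
            else:
                lab = np.zeros(self.Cn, dtype=np.int64)
            self.cond_label[k] = lab
            nc = int(lab.max()) + 1
            self.ncond[k] = nc
            for c in range(nc):
                cols = lab == c
                self.csize[k, c] = int(cols.sum())
                sub = self.X[np.ix_(members, np.flatnonzero(cols))]
                self.Nb[k, c] = sub.size
                self.S1b[k, c] = sub.sum()
                self.S2b[k, c] = (sub * sub).sum()
        self.refresh_projections()
        self.recompute_cached_scores()
        self.best_total = self.total
        self.best_snap = self.snapshot()

    # ------------------------------------------------------------------
    # storage management
    # ------------------------------------------------------------------
    def _alloc_arrays(self) -> None:
        K, Cm, G, Cn = self.Kcap, self.Cm, self.G, self.Cn
        self.active = np.zeros(K, dtype=bool)
        self.nk = np.zeros(K, dtype=np.int64)
        self.ncond = np.zeros(K, dtype=np.int64)
        self.csize = np.zeros((K, Cm), dtype=np.int64)
        self.Nb = np.zeros((K, Cm), dtype=np.int64)
        self.S1b = np.zeros((K, Cm), dtype=float)
        self.S2b = np.zeros((K, Cm), dtype=float)
        self.cond_label = np.zeros((K, Cn), dtype=np.int64)
        self.blocksum = np.zeros(K, dtype=float)
        self.P1 = np.zeros((K, G, Cm), dtype=float)
        self.P2 = np.zeros((K, G, Cm), dtype=float)

    def _grow_K(self) -> None:
        add = self.Kcap
        self.active = np.concatenate([self.active, np.zeros(add, dtype=bool)])
        self.nk = np.concatenate([self.nk, np.zeros(add, dtype=np.int64)])
        self.ncond = np.concatenate([self.ncond, np.zeros(add, dtype=np.int64)])
        for name in ("csize", "Nb"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros((add, self.Cm), dtype=arr.dtype)]))
        for name in ("S1b", "S2b"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros((add, self.Cm))]))
        self.cond_label = np.concatenate(
            [self.cond_label, np.zeros((add, self.Cn), dtype=np.int64)])
        self.blocksum = np.concatenate([self.blocksum, np.zeros(add)])
        self.P1 = np.concatenate([self.P1, np.zeros((add, self.G, self.Cm))])
        self.P2 = np.concatenate([self.P2, np.zeros((add, self.G, self.Cm))])
        self.Kcap += add

    def _grow_C(self) -> None:
        add = self.Cm
        for name in ("csize", "Nb"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate(
                [arr, np.zeros((self.Kcap, add), dtype=arr.dtype)], axis=1))
        for name in ("S1b", "S2b"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros((self.Kcap, add))], axis=1))
        self.P1 = np.concatenate([self.P1, np.zeros((self.Kcap, self.G, add))], axis=2)
        self.P2 = np.concatenate([self.P2, np.zeros((self.Kcap, self.G, add))], axis=2)
        self.Cm += add

    def _alloc_slot(self) -> int:
        free = np.flatnonzero(~self.active)
        if free.size == 0:
            self._grow_K()
            free = np.flatnonzero(~self.active)
        return int(free[0])

    # ------------------------------------------------------------------
    # scoring primitives
    # ------------------------------------------------------------------
    def _logml(self, n, s1, s2):
        """Vectorized block log marginal likelihood; n == 0 gives exactly 0."""
        n = np.asarray(n)
        nsafe = np.maximum(n, 1)
        m = s1 / nsafe
        ssd = np.maximum(s2 - s1 * m, 0.0)
        beta_n = (self._beta0 + 0.5 * ssd
                  + self._lam0 * n * (m - self._mu0) ** 2 / (2.0 * (self._lam0 + n)))
        return self._const[n] - (self._alpha0 + 0.5 * n) * np.log(beta_n)

    def _logml1(self, n: int, s1: float, s2: float) -> float:
        """Scalar block log marginal likelihood (pure-Python fast path)."""
        if n == 0:
            return 0.0
        m = s1 / n
        ssd = s2 - s1 * m
        if ssd < 0.0:
            ssd = 0.0
        d = m - self._mu0
        beta_n = (self._beta0 + 0.5 * ssd
                  + self._lam0 * n * d * d / (2.0 * (self._lam0 + n)))
        return self._constl[n] - (self._alpha0 + 0.5 * n) * math.log(beta_n)

    def refresh_projections(self) -> None:
        """Recompute per-gene, per-condition-cluster partial sums.

        Valid only while the condition partitions stay fixed (i.e. during a
        gene sweep); the condition sweep invalidates them.
        """
        for k in np.flatnonzero(self.active):
            nc = int(self.ncond[k])
            onehot = (self.cond_label[k, :, None] == np.arange(nc)[None, :]).astype(float)
            self.P1[k, :, :nc] = self.X @ onehot
            self.P1[k, :, nc:] = 0.0
            self.P2[k, :, :nc] = self.X2 @ onehot
            self.P2[k, :, nc:] = 0.0

    def recompute_cached_scores(self) -> None:
        for k in np.flatnonzero(self.active):
            self.blocksum[k] = float(self._logml(self.Nb[k], self.S1b[k], self.S2b[k]).sum())
        self.total = float(self.blocksum[self.active].sum())

    def snapshot(self) -> dict:
        return {
            "gene_label": self.gene_label.copy(),
            "cond_label": self.cond_label.copy(),
            "active": self.active.copy(),
            "total": self.total,
        }

    def _maybe_track_best(self) -> None:
        if self.total > self.best_total + 1e-12:
            self.best_total = self.total
            self.best_snap = self.snapshot()

    # ------------------------------------------------------------------
    # cache integrity
    # ------------------------------------------------------------------
    def check_cache(self) -> None:
        """Cheap checksum of the sufficient-statistic cache; raises
        ``RuntimeError`` if the cache is stale (e.g. tampered with)."""
        if int(self.nk[self.active].sum()) != self.G:
            raise RuntimeError("stale statistics cache: gene counts do not sum to G")
        act = np.flatnonzero(self.active)
        if not np.array_equal(self.Nb[act].sum(axis=1), self.nk[act] * self.Cn):
            raise RuntimeError("stale statistics cache: block counts inconsistent")
        if not np.array_equal(self.csize[act].sum(axis=1),
                              np.full(act.size, self.Cn, dtype=np.int64)):
            raise RuntimeError("stale statistics cache: condition sizes inconsistent")

    # ------------------------------------------------------------------
    # gene moves
    # ------------------------------------------------------------------
    def _gene_move_pieces(self, g: int):
        cur = int(self.gene_label[g])
        act = np.flatnonzero(self.active)
        rn = self.Nb[cur] - self.csize[cur]
        rs1 = self.S1b[cur] - self.P1[cur, g]
        rs2 = self.S2b[cur] - self.P2[cur, g]
        rem_sum = float(self._logml(rn, rs1, rs2).sum())
        loss = rem_sum - self.blocksum[cur]

        n2 = self.Nb[act] + self.csize[act]
        a1 = self.S1b[act] + self.P1[act, g]
        a2 = self.S2b[act] + self.P2[act, g]
        add_sums = self._logml(n2, a1, a2).sum(axis=1)
        deltas = loss + add_sums - self.blocksum[act]
        cur_pos = int(np.searchsorted(act, cur))
        deltas[cur_pos] = 0.0
        dnew = loss + self._logml1(self.Cn, self.rowsum[g], self.rowsumsq[g])
        return cur, cur_pos, act, deltas, dnew, (rn, rs1, rs2, rem_sum, add_sums)

    def delta_move_gene(self, gene_id: str, target: int) -> float:
        """Exact score change of moving one gene to ``target`` (cluster slot
        index, or :data:`NEW_CLUSTER` for a fresh cluster), without mutating
        the state.  Moving a gene to its own cluster returns 0."""
        self.check_cache()
        g = self.matrix.row_index(gene_id)
        cur, cur_pos, act, deltas, dnew, _ = self._gene_move_pieces(g)
        if target == NEW_CLUSTER:
            return float(dnew)
        if target == cur:
            return 0.0
        pos = np.flatnonzero(act == target)
        if pos.size == 0:
            raise ValueError(f"target cluster {target} is not active")
        return float(deltas[int(pos[0])])

    def move_gene(self, gene_id: str, target: int) -> float:
        """Apply a gene move and return its score delta."""
        g = self.matrix.row_index(gene_id)
        cur, cur_pos, act, deltas, dnew, pieces = self._gene_move_pieces(g)
        if target == cur:
            return 0.0
        if target == NEW_CLUSTER:
            self._apply_gene_move(g, cur, NEW_CLUSTER, None, dnew, pieces)
            return float(dnew)
        pos = np.flatnonzero(act == target)
        if pos.size == 0:
            raise ValueError(f"target cluster {target} is not active")
        delta = float(deltas[int(pos[0])])
        self._apply_gene_move(g, cur, target, int(pos[0]), delta, pieces)
        return delta

    def _apply_gene_move(self, g: int, cur: int, target: int, target_pos,
                         delta: float, pieces) -> None:
        rn, rs1, rs2, rem_sum, add_sums = pieces
        # remove from the current cluster
        self.Nb[cur] = rn
        self.S1b[cur] = rs1
        self.S2b[cur] = rs2
        self.blocksum[cur] = rem_sum
        self.nk[cur] -= 1
        if self.nk[cur] == 0:
            self.active[cur] = False
            self.ncond[cur] = 0
            self.csize[cur] = 0
            self.Nb[cur] = 0
            self.S1b[cur] = 0.0
            self.S2b[cur] = 0.0
            self.cond_label[cur] = 0
            self.blocksum[cur] = 0.0
        if target == NEW_CLUSTER:
            k = self._alloc_slot()
            self.active[k] = True
            self.nk[k] = 1
            self.ncond[k] = 1
            self.cond_label[k] = 0
            self.csize[k] = 0
            self.csize[k, 0] = self.Cn
            self.Nb[k] = 0
            self.Nb[k, 0] = self.Cn
            self.S1b[k] = 0.0
            self.S2b[k] = 0.0
            self.S1b[k, 0] = self.rowsum[g]
            self.S2b[k, 0] = self.rowsumsq[g]
            self.P1[k] = 0.0
            self.P2[k] = 0.0
            self.P1[k, :, 0] = self.rowsum
            self.P2[k, :, 0] = self.rowsumsq
            self.blocksum[k] = self._logml1(self.Cn, self.rowsum[g], self.rowsumsq[g])
            self.gene_label[g] = k
        else:
            self.Nb[target] += self.csize[target]
            self.S1b[target] += self.P1[target, g]
            self.S2b[target] += self.P2[target, g]
            self.blocksum[target] = float(add_sums[target_pos])
            self.nk[target] += 1
            self.gene_label[g] = target
        self.total += delta
        self._maybe_track_best()

    def gene_sweep(self, rng: np.random.Generator) -> None:
        self.refresh_projections()
        for g in rng.permutation(self.G):
            cur, cur_pos, act, deltas, dnew, pieces = self._gene_move_pieces(int(g))
            # a gene alone in its cluster IS the new-cluster state: offering
            # a separate empty-cluster option would double-count it
            allow_new = self.nk[cur] > 1
            dall = np.append(deltas, dnew) if allow_new else deltas
            w = np.exp(dall - dall.max())
            if allow_new:
                w[-1] *= self.gamma
            w_sum = w.sum()
            u = rng.random() * w_sum
            choice = int(np.searchsorted(np.cumsum(w), u))
            choice = min(choice, w.size - 1)
            if choice == deltas.size:
                self._apply_gene_move(int(g), cur, NEW_CLUSTER, None, float(dnew), pieces)
            elif choice != cur_pos:
                target = int(act[choice])
                self._apply_gene_move(int(g), cur, target, choice, float(deltas[choice]), pieces)

    # ------------------------------------------------------------------
    # condition moves
    # ------------------------------------------------------------------
    def condition_sweep(self, rng: np.random.Generator) -> None:
        for k in np.flatnonzero(self.active):
            self._condition_sweep_cluster(int(k), rng)

    def _condition_sweep_cluster(self, k: int, rng: np.random.Generator) -> None:
        members = np.flatnonzero(self.gene_label == k)
        mk = int(members.size)
        colsum = self.X[members].sum(axis=0).tolist()
        colsumsq = self.X2[members].sum(axis=0).tolist()
        labels = self.cond_label[k]
        # cluster-local statistics as plain lists: the inner loop is scalar
        nc = int(self.ncond[k])
        nb = self.Nb[k, :].tolist()
        s1b = self.S1b[k, :].tolist()
        s2b = self.S2b[k, :].tolist()
        cs = self.csize[k, :].tolist()
        lm = ([self._logml1(int(nb[c]), s1b[c], s2b[c]) for c in range(nc)]
              + [0.0] * (len(nb) - nc))
        gamma = self.gamma
        logml1 = self._logml1
        for j in rng.permutation(self.Cn):
            j = int(j)
            c = int(labels[j])
            rn = int(nb[c]) - mk
            rs1 = s1b[c] - colsum[j]
            rs2 = s2b[c] - colsumsq[j]
            after_c = logml1(rn, rs1, rs2)
            loss = after_c - lm[c]

            deltas = []
            adds = []
            for d in range(nc):
                if d == c:
                    deltas.append(0.0)
                    adds.append(lm[c])
                    continue
                a = logml1(int(nb[d]) + mk, s1b[d] + colsum[j], s2b[d] + colsumsq[j])
                deltas.append(loss + a - lm[d])
                adds.append(a)
            # a column alone in its condition cluster IS the new-cluster
            # state: only offer the empty option when it shares its cluster
            allow_new = cs[c] > 1
            if allow_new:
                a_new = logml1(mk, colsum[j], colsumsq[j])
                deltas.append(loss + a_new)
                adds.append(a_new)

            mx = max(deltas)
            w = [math.exp(x - mx) for x in deltas]
            if allow_new:
                w[-1] *= gamma
            u = rng.random() * sum(w)
            acc = 0.0
            choice = len(w) - 1
            for i, wi in enumerate(w):
                acc += wi
                if u < acc:
                    choice = i
                    break
            if choice == c:
                continue
            delta = deltas[choice]
            if choice == nc:  # new condition cluster
                t = nc
                nc += 1
                if nc > len(nb):
                    nb.append(0); s1b.append(0.0); s2b.append(0.0)
                    cs.append(0); lm.append(0.0)
                else:
                    nb[t] = 0; s1b[t] = 0.0; s2b[t] = 0.0; cs[t] = 0
            else:
                t = choice
            nb[c] = rn; s1b[c] = rs1; s2b[c] = rs2; cs[c] -= 1
            lm[c] = after_c
            nb[t] = int(nb[t]) + mk
            s1b[t] += colsum[j]
            s2b[t] += colsumsq[j]
            cs[t] += 1
            lm[t] = adds[choice]
            labels[j] = t
            self.blocksum[k] += delta
            self.total += delta
            if cs[c] == 0:  # compact: move the last condition cluster into c
                last = nc - 1
                if c != last:
                    nb[c], s1b[c], s2b[c], cs[c], lm[c] = (
                        nb[last], s1b[last], s2b[last], cs[last], lm[last])
                    labels[labels == last] = c
                nb[last] = 0; s1b[last] = 0.0; s2b[last] = 0.0
                cs[last] = 0; lm[last] = 0.0
                nc -= 1
            self._maybe_track_best()
        # write cluster-local statistics back to the padded arrays
        if nc > self.Cm:
            while nc > self.Cm:
                self._grow_C()
        pad = self.Cm - nc
        self.ncond[k] = nc
        self.Nb[k, :] = nb[:nc] + [0] * pad
        self.S1b[k, :] = s1b[:nc] + [0.0] * pad
        self.S2b[k, :] = s2b[:nc] + [0.0] * pad
        self.csize[k, :] = cs[:nc] + [0] * pad
        self.blocksum[k] = float(sum(lm[:nc]))


def _solution_from_snapshot(matrix, snap: dict, seed: int, n_sweeps: int,
                            prior: NormalGammaPrior) -> ClusterSolution:
    gene_label = snap["gene_label"]
    cond_label = snap["cond_label"]
    # relabel gene clusters in order of first occurrence along the row order
    relabel: dict[int, int] = {}
    gene_assignment: dict[str, int] = {}
    for i, rid in enumerate(matrix.row_ids):
        slot = int(gene_label[i])
        if slot not in relabel:
            relabel[slot] = len(relabel)
        gene_assignment[rid] = relabel[slot]
    condition_assignment: dict[int, dict[str, int]] = {}
    for slot, k in relabel.items():
        labels = cond_label[slot]
        cmap: dict[int, int] = {}
        cond: dict[str, int] = {}
        for j, cid in enumerate(matrix.col_ids):
            c = int(labels[j])
            if c not in cmap:
                cmap[c] = len(cmap)
            cond[cid] = cmap[c]
        condition_assignment[k] = cond
    sol = ClusterSolution(gene_assignment, condition_assignment, 0.0, seed, n_sweeps)
    sol.logml = partition_logml(matrix, sol, prior)
    return sol


def sample_solution(matrix, prior: NormalGammaPrior | None = None,
                    n_sweeps: int = 100, seed: int = 0, *,
                    gamma: float = 1.0,
                    update_genes: bool = True,
                    update_conditions: bool = True) -> ClusterSolution:
    """Run one Gibbs chain and return the best-scoring visited state.

    ``update_genes=False`` freezes the gene partition (all genes pooled in
    one cluster) and clusters columns only -- the mode the condition-tree
    builder uses.  ``update_conditions=False`` freezes every condition
    partition at a single cluster and samples the gene partition only.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    min_rows = 2 if update_genes else 1
    if matrix.n_rows < min_rows or matrix.n_cols < 2:
        raise ValueError(
            f"matrix too small to cluster: {matrix.n_rows} x {matrix.n_cols}")
    if prior is None:
        prior = NormalGammaPrior.from_matrix(matrix)
    rng = np.random.default_rng(seed)
    init = np.arange(matrix.n_rows) if update_genes else np.zeros(matrix.n_rows, int)
    state = GibbsState(matrix, prior, gene_labels=init, gamma=gamma)
    for _ in range(n_sweeps):
        if update_conditions:
            state.condition_sweep(rng)
        if update_genes:
            state.gene_sweep(rng)
        state.recompute_cached_scores()
        state._maybe_track_best()
    return _solution_from_snapshot(matrix, state.best_snap, seed, n_sweeps, prior)


def run_ensemble(matrix, prior: NormalGammaPrior | None = None,
                 n_runs: int = 30, n_sweeps: int = 100,
                 base_seed: int = 0, **kwargs) -> list[ClusterSolution]:
    """Independent clustering runs with seeds ``base_seed + i``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [sample_solution(matrix, prior, n_sweeps, base_seed + i, **kwargs)
            for i in range(n_runs)]
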