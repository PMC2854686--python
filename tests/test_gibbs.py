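import numpy as np
import pytest

from modulenet.expression import ExpressionMatrix
from modulenet.gibbs import (NEW_CLUSTER, ClusterSolution, GibbsState,
                             run_ensemble, sample_solution)
from modulenet.normal_gamma import NormalGammaPrior, partition_logml

PRIOR = NormalGammaPrior(0.0, 0.5, 1.0, 1.0)


def _state_from_solution(matrix, sol, prior=PRIOR):
    return GibbsState(
        matrix, prior,
        gene_labels=np.array([sol.gene_assignment[g] for g in matrix.row_ids]),
        cond_labels={k: np.array([v[c] for c in matrix.col_ids])
                     for k, v in sol.condition_assignment.items()})


def _brute_force_delta(matrix, sol, gene_id, target, prior=PRIOR):
    base = partition_logml(matrix, sol, prior)
    ga = dict(sol.gene_assignment)
    ca = {k: dict(v) for k, v in sol.condition_assignment.items()}
    old = ga[gene_id]
    if target == NEW_CLUSTER:
        newk = max(ca) + 1
        ga[gene_id] = newk
        ca[newk] = {c: 0 for c in matrix.col_ids}
    else:
        ga[gene_id] = target
    if old not in set(ga.values()):
        del ca[old]
    after = ClusterSolution(ga, ca, 0.0, 0, 0)
    return partition_logml(matrix, after, prior) - base


class TestDeltaMoveGene:
    def test_matches_brute_force_recomputation(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=10, seed=1)
        state = _state_from_solution(small_matrix, sol)
        targets = sorted(set(sol.gene_assignment.values())) + [NEW_CLUSTER]
        for gid in small_matrix.row_ids:
            for t in targets:
                got = state.delta_move_gene(gid, t)
                ref = _brute_force_delta(small_matrix, sol, gid, t)
                assert got == pytest.approx(ref, abs=1e-9)

    def test_move_to_own_cluster_is_zero(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=5, seed=2)
        state = _state_from_solution(small_matrix, sol)
        gid = small_matrix.row_ids[0]
        assert state.delta_move_gene(gid, sol.gene_assignment[gid]) == 0.0

    def test_reverse_move_negates_delta(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=10, seed=3)
        state = _state_from_solution(small_matrix, sol)
        gid = small_matrix.row_ids[0]
        home = sol.gene_assignment[gid]
        others = [k for k in set(sol.gene_assignment.values()) if k != home]
        if not others:
            pytest.skip("single-cluster solution sampled")
        fwd = state.move_gene(gid, others[0])
        back = state.delta_move_gene(gid, home)
        assert back == pytest.approx(-fwd, abs=1e-9)

    def test_stale_cache_detected(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=5, seed=4)
        state = _state_from_solution(small_matrix, sol)
        state.Nb[int(state.gene_label[0]), 0] += 1
        with pytest.raises(RuntimeError, match="stale"):
            state.delta_move_gene(small_matrix.row_ids[0], NEW_CLUSTER)


class TestSampleSolution:
    def test_solution_invariants(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=10, seed=5)
        assert set(sol.gene_assignment) == set(small_matrix.row_ids)
        for k in set(sol.gene_assignment.values()):
            assert set(sol.condition_assignment[k]) == set(small_matrix.col_ids)
        assert sol.logml == pytest.approx(
            partition_logml(small_matrix, sol, PRIOR), abs=1e-6)

    def test_duplicate_profiles_always_coclustered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 2.0, (3, 12))
        vals = np.vstack([base, base])  # 6 genes = 2 exact copies of 3 profiles
        m = ExpressionMatrix([f"g{i}" for i in range(6)],
                             [f"s{j}" for j in range(12)], vals)
        for seed in range(5):
            sol = sample_solution(m, n_sweeps=40, seed=seed)
            for i in range(3):
                assert (sol.gene_assignment[f"g{i}"]
                        == sol.gene_assignment[f"g{i + 3}"])

    def test_identical_genes_collapse_to_one_cluster(self):
        vals = np.tile(np.linspace(-1, 1, 8), (5, 1))
        m = ExpressionMatrix([f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(8)], vals)
        ones = sum(sample_solution(m, n_sweeps=30, seed=s).n_gene_clusters() == 1
                   for s in range(20))
        assert ones >= 19  # >= 95% of 20 seeds

    def test_n_sweeps_validation(self, small_matrix):
        with pytest.raises(ValueError):
            sample_solution(small_matrix, PRIOR, n_sweeps=0, seed=0)

    def test_conditions_only_mode_keeps_single_gene_cluster(self, small_matrix):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=10, seed=6,
                              update_genes=False)
        assert sol.n_gene_clusters() == 1


class TestRunEnsemble:
    def test_thirty_runs_with_deterministic_order(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix([f"g{i}" for i in range(6)],
                             [f"s{j}" for j in range(6)], rng.normal(0, 1, (6, 6)))
        sols = run_ensemble(m, PRIOR, n_runs=30, n_sweeps=2, base_seed=7)
        assert len(sols) == 30
        assert [s.seed for s in sols] == list(range(7, 37))

    def test_identical_seeds_give_identical_solutions(self, small_matrix):
        a = sample_solution(small_matrix, PRIOR, n_sweeps=15, seed=11)
        b = sample_solution(small_matrix, PRIOR, n_sweeps=15, seed=11)
        assert a.gene_assignment == b.gene_assignment
        assert a.condition_assignment == b.condition_assignment
        assert a.logml == b.logml

    def test_n_runs_validation(self, small_matrix):
        with pytest.raises(ValueError):
            run_ensemble(small_matrix, PRIOR, n_runs=0, n_sweeps=1, base_seed=0)

    def test_solution_json_round_trip(self, small_matrix, tmp_path):
        sol = sample_solution(small_matrix, PRIOR, n_sweeps=5, seed=8)
        p = tmp_path / "sol.json"
        sol.save(p)
        assert ClusterSolution.load(p) == sol


class TestDetailedBalance:
    def test_two_gene_frequencies_match_score_ratios(self):
        """With conditions frozen the gene kernel is exact Gibbs on the two
        partitions of a 2-gene matrix; long-run state frequencies must match
        the exp(logml) ratio within 3 Monte-Carlo SDs."""
        m = ExpressionMatrix(["a", "b"], ["s1", "s2"],
                             np.array([[0.3, 1.1], [0.5, -0.2]]))
        prior = NormalGammaPrior(0.0, 1.0, 1.0, 1.0)

        def score(together):
            ga = {"a": 0, "b": 0} if together else {"a": 0, "b": 1}
            ca = ({0: {"s1": 0, "s2": 0}} if together
                  else {0: {"s1": 0, "s2": 0}, 1: {"s1": 0, "s2": 0}})
            return partition_logml(m, ClusterSolution(ga, ca, 0, 0, 0), prior)

        lt, la = score(True), score(False)
        p_together = np.exp(lt) / (np.exp(lt) + np.exp(la))
        rng = np.random.default_rng(0)
        state = GibbsState(m, prior, gene_labels=np.arange(2))
        n = 20000
        hits = 0
        for _ in range(n):
            state.gene_sweep(rng)
            hits += int(state.gene_label[0] == state.gene_label[1])
        # each sweep resamples both genes; successive states are near-iid,
        # use a conservative effective sample size of n/4
        se = np.sqrt(p_together * (1 - p_together) / (n / 4))
        assert abs(hits / n - p_together) < 3 * se
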