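import numpy as np
import pytest

from modulenet.consensus import TightClusterSet
from modulenet.expression import standardize_row
from modulenet.synthetic import (GroundTruth, SyntheticConfig, generate_dataset,
                                 recovery_metrics, strong_signal_config)


class TestGenerateDataset:
    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(seed=3)
        m1, c1, t1 = generate_dataset(cfg)
        m2, c2, t2 = generate_dataset(SyntheticConfig(seed=3))
        assert m1.row_ids == m2.row_ids
        assert np.array_equal(m1.values, m2.values)
        assert c1.ids == c2.ids
        assert t1.to_dict() == t2.to_dict()

    def test_zero_gene_noise_makes_module_rows_identical(self):
        cfg = SyntheticConfig(seed=1, gene_noise_sd=0.0)
        m, _c, truth = generate_dataset(cfg)
        for genes in truth.module_members.values():
            rows = np.vstack([m.row(g) for g in genes])
            assert np.allclose(rows, rows[0], atol=0)

    def test_direct_regulators_track_module_mean(self):
        """Strong signal: |r| between each standardized direct regulator and
        its module mean profile >= 0.9 for >= 95% of regulators, 50 seeds."""
        good = total = 0
        for seed in range(50):
            cfg = strong_signal_config(seed=seed, n_direct_regulators_per_module=2,
                                       n_indirect_regulators_per_module=0,
                                       n_decoy_regulators=0)
            m, _c, truth = generate_dataset(cfg)
            for reg in truth.regulators:
                genes = truth.module_members[reg.module]
                mean_profile = np.vstack([m.row(g) for g in genes]).mean(axis=0)
                r = np.corrcoef(standardize_row(m.row(reg.id)), mean_profile)[0, 1]
                total += 1
                good += int(abs(r) >= 0.9)
        assert good / total >= 0.95

    def test_candidates_exclude_hidden_intermediates(self):
        m, cands, truth = generate_dataset(SyntheticConfig(seed=2))
        hidden = set(truth.hidden_intermediates.values())
        assert hidden  # config plants indirect regulators
        assert hidden <= set(m.row_ids)
        assert not (hidden & cands.ids)
        planted = {r.id for r in truth.regulators}
        assert planted <= cands.ids

    def test_truth_invariants(self):
        m, cands, truth = generate_dataset(SyntheticConfig(seed=5))
        all_members = [g for genes in truth.module_members.values() for g in genes]
        assert len(all_members) == len(set(all_members))  # disjoint modules
        assert {r.id for r in truth.regulators} <= set(m.row_ids)
        for reg in truth.regulators:
            if reg.mode == "indirect":
                assert reg.id in truth.hidden_intermediates

    def test_divergence_noise_decorrelates_intermediate_only(self):
        """Growing indirect divergence decorrelates the emitted intermediate
        row from the module mean while the planted indirect regulator keeps
        tracking it (the hidden-TF scenario)."""
        def mean_abs_corrs(div_sd):
            ci, cr = [], []
            for seed in range(10):
                cfg = SyntheticConfig(seed=seed, indirect_divergence_sd=div_sd,
                                      n_direct_regulators_per_module=0,
                                      n_decoy_regulators=0)
                m, _c, truth = generate_dataset(cfg)
                for reg in truth.regulators:
                    genes = truth.module_members[reg.module]
                    mp = np.vstack([m.row(g) for g in genes]).mean(axis=0)
                    tf = truth.hidden_intermediates[reg.id]
                    ci.append(abs(np.corrcoef(m.row(tf), mp)[0, 1]))
                    cr.append(abs(np.corrcoef(m.row(reg.id), mp)[0, 1]))
            return np.mean(ci), np.mean(cr)

        tf_low, reg_low = mean_abs_corrs(0.3)
        tf_high, reg_high = mean_abs_corrs(5.0)
        assert tf_high < tf_low - 0.2  # intermediate decorrelates
        assert abs(reg_high - reg_low) < 0.05  # regulator unaffected

    def test_mirna_scale_only_affects_raw_values(self):
        base = dict(seed=9, mirna_fraction=1.0, n_direct_regulators_per_module=1,
                    n_indirect_regulators_per_module=0, n_decoy_regulators=0)
        m1, _c1, t1 = generate_dataset(SyntheticConfig(**base, mirna_scale=0.25))
        m2, _c2, t2 = generate_dataset(SyntheticConfig(**base, mirna_scale=4.0))
        for reg in t1.regulators:
            r1, r2 = m1.row(reg.id), m2.row(reg.id)
            assert not np.allclose(r1, r2)
            assert np.allclose(standardize_row(r1), standardize_row(r2), atol=1e-9)
            assert m1.kind_of(reg.id) == "mirna"

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_samples=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(n_modules=0, n_background=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(genes_per_module=(5, 2)).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(mirna_scale=0.0).validate()

    def test_truth_json_round_trip(self, tmp_path):
        _m, _c, truth = generate_dataset(SyntheticConfig(seed=4))
        p = tmp_path / "truth.json"
        truth.save(p)
        assert GroundTruth.load(p).to_dict() == truth.to_dict()


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        _m, _c, truth = generate_dataset(SyntheticConfig(seed=6))
        modules = TightClusterSet([list(g) for g in truth.module_members.values()], 3)
        rep = recovery_metrics(truth, modules)
        assert rep["ari"] == pytest.approx(1.0)
        assert all(j == pytest.approx(1.0) for j in rep["jaccard"].values())

    def test_random_partition_scores_near_zero_ari(self):
        _m, _c, truth = generate_dataset(SyntheticConfig(seed=7))
        genes = [g for gs in truth.module_members.values() for g in gs]
        sizes = [len(gs) for gs in truth.module_members.values()]
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            perm = list(rng.permutation(genes))
            clusters, start = [], 0
            for s in sizes:
                clusters.append(perm[start:start + s])
                start += s
            rep = recovery_metrics(truth, TightClusterSet(clusters, 3))
            aris.append(rep["ari"])
        assert abs(np.mean(aris)) < 0.05

    def test_top1_recovery_with_planted_regulator_first(self):
        import pandas as pd
        _m, _c, truth = generate_dataset(SyntheticConfig(seed=8))
        modules = TightClusterSet([list(g) for g in truth.module_members.values()], 3)
        rows = []
        for i, mname in enumerate(truth.module_members):
            planted = truth.regulators_of(mname)[0]
            rows.append({"module": f"module_{i + 1:02d}",
                         "regulator": planted.id, "global_score": 10.0,
                         "sign": planted.sign, "n_nodes_assigned": 1})
            rows.append({"module": f"module_{i + 1:02d}", "regulator": "decoy_x",
                         "global_score": 1.0, "sign": 1, "n_nodes_assigned": 1})
        rep = recovery_metrics(truth, modules, pd.DataFrame(rows))
        assert rep["top1_regulator_recovery"] == 1.0
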