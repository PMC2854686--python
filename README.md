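# modulenet

Module network inference from joint mRNA/miRNA expression data.

`modulenet` reconstructs a **module network** — clusters of tightly
co-expressed genes, each governed by a ranked *regulatory program* of
candidate regulators — from a single expression matrix in which messenger
RNAs and microRNAs are measured across the same samples.  Because regulator
scoring looks only at the *differential* expression of a regulator across
condition clusters (profiles are standardized first), transcription factors,
signal transducers and miRNAs compete on equal footing even though miRNAs
are measured on a different absolute scale.  The package is aimed at
computational biologists who want a transparent, fully reproducible
implementation of this analysis, together with a synthetic-data generator
that plants known modules and regulators (including *indirect* regulators
acting through a hidden intermediate TF) so every stage can be validated
against ground truth.

## Method

1. **Two-way Gibbs clustering.**  Genes are partitioned into clusters, and
   each gene cluster's samples into condition clusters.  A block of values
   (one gene cluster × one condition cluster) is modeled as i.i.d.
   N(μ, τ⁻¹) with a conjugate normal-gamma prior
   μ | τ ~ N(μ₀, (λ₀τ)⁻¹), τ ~ Gamma(α₀, β₀); integrating (μ, τ) out gives
   the closed-form block log marginal likelihood

   log p(x) = −(n/2)·ln 2π + ½·ln(λ₀/λₙ) + ln Γ(αₙ) − ln Γ(α₀)
              + α₀·ln β₀ − αₙ·ln βₙ,

   and the score of a clustering is the sum over blocks.  A Gibbs sampler
   with an open-ended (Chinese-restaurant style) number of clusters
   reassigns genes and columns with probability ∝ exp(Δ log-score); each
   run returns the best state it visited.
2. **Consensus tight clusters.**  30 independent runs are averaged into a
   co-clustering frequency matrix F; tight clusters are peeled off with a
   spectral method (dominant eigenvector of F, thresholded at 0.7 of its
   maximum, accepted when mean within-cluster frequency ≥ 0.5).
3. **Regulatory programs.**  Per module, 100 condition hierarchies are
   built (columns-only Gibbs + greedy agglomeration).  At every tree node
   splitting low-mean from high-mean samples, each standardized candidate
   regulator x is scored with a fuzzy split score
   max_z Σ_L ln σ(β(z−x_c)) + Σ_R ln σ(β(x_c−z)) (σ the logistic function,
   β = 2), in both orientations; up to 100 regulators are kept per node.
   Node contributions w·(s − s̄) (w = fraction of samples under the node,
   s̄ = the node's top-K mean) are summed into a non-negative global score
   per (module, regulator).
4. **Significance.**  1,000 randomly assigned regulators are pushed through
   the identical scoring path to form a null distribution; calls use the
   top-2% quantile of true interaction scores, with the maximum null score
   reported alongside.
5. **Enrichment.**  One-sided hypergeometric tests of module/gene-set
   overlap with Benjamini–Hochberg correction within each module
   (enriched at adjusted p < 0.05).

See `docs/methods.md` for model details, parameter defaults and the
synthetic-data design.

## Worked example

```python
from modulenet import (SyntheticConfig, generate_dataset, run_ensemble,
                       coclustering_matrix, extract_tight_clusters,
                       learn_programs, null_scores, apply_cutoff,
                       recovery_metrics)

cfg = SyntheticConfig(seed=42)          # 3 modules x 20 genes, 40 samples
matrix, candidates, truth = generate_dataset(cfg)
solutions = run_ensemble(matrix, n_runs=30, n_sweeps=100, base_seed=42)
modules = extract_tight_clusters(coclustering_matrix(solutions))
progs = learn_programs(modules, matrix, candidates, n_trees=100, base_seed=7)
null = null_scores(progs, matrix, candidates, n_draws=1000, seed=11)
calls = apply_cutoff(progs.table, null, quantile=0.02)
report = recovery_metrics(truth, modules, progs.table)
```

Output of this exact script:

```
matrix: 89 rows x 40 samples, 26 candidate regulators
tight clusters: [20, 20, 20, 15, 11, 3]
ARI: 1.0  top-1 regulator recovery: 1.0
cutoff: 3107.0  max null: 29.0
  module_01  ireg1_m01          3049.8  sign -1
  module_01  mir-dreg1_m01      2965.4  sign +1
  module_01  mir-decoy_016       385.1  sign -1
  module_01  decoy_019           211.9  sign -1
```

The three planted 20-gene modules are recovered exactly (adjusted Rand
index 1.0; the extra clusters collect the mutually co-expressed regulator
rows and the consistently co-clustered noise rows).  In every module the
top-ranked regulator is a planted one — here the indirect regulator
`ireg1_m01` (anti-correlated, sign −1) and the miRNA-kind direct regulator
`mir-dreg1_m01` lead module 1, with scores two orders of magnitude above
the best decoy and far above the strongest of 1,000 random-regulator null
scores (29.0): true and random score distributions are fully separated.

The same pipeline runs from the shell:

```bash
modulenet simulate --out-dir data --seed 42
modulenet cluster --matrix data/matrix.tsv --runs 30 --sweeps 100 --seed 42 --out runs/
modulenet consensus --runs runs/ --out modules.json
modulenet regulators --matrix data/matrix.tsv --modules modules.json \
    --candidates data/regulators.txt --out scores.tsv --programs-out programs.json
modulenet significance --programs programs.json --matrix data/matrix.tsv \
    --candidates data/regulators.txt --out calls.tsv --histogram hist.tsv
```

or end-to-end with one YAML config: `modulenet run-all --config cfg.yaml
--out-dir out/` (rerunning with the same config reproduces every output
byte for byte).

Real data enters through `read_expression_tsv` (tab-separated, `id` and
optional `kind` columns), a regulator id list, and optional GMT gene sets.

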