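# Methods

## Model

Expression values are log-scale intensities in a genes × samples matrix;
mRNA and miRNA rows are distinguished only by a `kind` label.  The
clustering model is a two-way block model: a partition of genes into
clusters and, per gene cluster, a partition of samples into condition
clusters.  All values of one (gene cluster, condition cluster) block are
treated as i.i.d. draws from a Gaussian with unknown mean μ and precision
τ under the conjugate normal-gamma prior

    μ | τ ~ N(μ0, 1/(λ0 τ)),    τ ~ Gamma(α0, rate β0).

Marginalizing (μ, τ) per block gives the closed-form block evidence (see
`modulenet.normal_gamma.block_logml`); a clustering's score is the sum over
blocks.  Pooling all genes of a cluster into one block per condition
cluster encodes the "tightly co-expressed" assumption: member genes share
the block mean and precision, so the model prefers clusters whose genes
move together across the same sample groups.

**Prior defaults** (`NormalGammaPrior.from_matrix`): μ0 = grand mean,
λ0 = 0.1 pseudo-observations, α0 = 0.1, β0 = 0.1 × grand variance.
Weakly informative and scale-adapted, so the same defaults work for
matrices on arbitrary log scales.  All four values are exposed under
`model:` in the pipeline YAML.

## Gibbs sampler

`sample_solution` starts from singleton gene clusters (each with a trivial
condition partition) and alternates, per sweep, (1) a condition sweep —
within each gene cluster every column, in random order, is reassigned among
the cluster's condition clusters plus one empty cluster with probability
∝ exp(Δ score) — and (2) a gene sweep of the same form over gene clusters.
Design notes:

* **Open-ended cluster number.**  The empty-cluster option carries a
  concentration weight γ = 1 folded into the move probability.  The empty
  option is offered only when the mover's current cluster has other
  members; for a singleton the fresh-cluster state is the current state,
  and offering it twice would double-count singleton states (this bias is
  measurable: a two-state chain settles at the wrong frequencies without
  the guard; the detailed-balance test in `tests/test_gibbs.py` checks the
  corrected kernel against exp(Δ log-evidence) ratios).
* **Condition sweep first.**  A freshly opened gene cluster starts with an
  unpartitioned condition set and therefore scores poorly until its columns
  are re-clustered.  Sweeping conditions before genes (and initializing
  with singletons) means gene moves are always evaluated against
  informative condition partitions; with the opposite order the chain can
  sit in the all-genes-together state indefinitely.
* **Best-state tracking, not posterior sampling.**  Each run returns the
  highest-scoring state visited (default 100 sweeps), i.e. a point
  estimate.  Burn-in/thinning are deliberately absent: downstream steps
  consume runs as members of an ensemble, not as posterior draws.
* Incremental moves use cached block sufficient statistics; their deltas
  are exact against full recomputation to ~1e-12 (tested), and cached
  totals are refreshed every sweep to prevent drift.

`run_ensemble` produces `n_runs` independent runs with seeds
`base_seed + i` (default 30 runs).

## Consensus tight clusters

The ensemble is averaged into a co-clustering frequency matrix F
(F_ij = fraction of runs where genes i and j share a cluster).  Tight
clusters are extracted by iterative spectral peeling: compute the dominant
eigenvector v of the remaining F, take the candidate {i : v_i ≥ 0.7·max v},
accept it if its mean pairwise frequency is ≥ 0.5 and it has ≥ 3 genes
(the smallest module size worth reporting), zero its rows and columns,
repeat until no acceptable cluster remains.

The eigenvector is computed by power iteration started from the
highest-degree gene rather than a generic dense eigensolver.  The reason is
degeneracy: a consensus matrix from well-separated data decomposes into
(nearly) disconnected blocks whose leading eigenvalues can coincide
exactly, and an arbitrary vector from the degenerate eigenspace mixes
blocks; a power iteration started inside one block of a disconnected graph
stays there.  Known limitation: two blocks of *identical* size and density
coupled by a uniform background produce an exactly block-symmetric dominant
eigenvector and cannot be separated at any threshold; real ensembles break
this symmetry, and unequal blocks separate cleanly (tested).

## Regulatory programs

For each module, `n_trees` = 100 condition hierarchies are built: a
columns-only Gibbs run (genes pooled; 50 sweeps by default) samples a
condition partition, whose clusters are then merged greedily, at each step
joining the pair whose pooled merge gains the most block evidence.  Each
merge is a node splitting a low-mean (left) from a high-mean (right) sample
set; node weight = number of samples under the node.

At every node, each candidate regulator's **standardized** profile x
(mean 0, population SD 1; constant rows map to zero and score as
uninformative) receives the fuzzy split score

    score(+) = max_z Σ_{c∈L} ln σ(β(z − x_c)) + Σ_{c∈R} ln σ(β(x_c − z)),

with σ the logistic function; orientation (−) swaps L and R, and the better
orientation defines the regulator's sign.  z is searched over a finite
deterministic grid (midpoints of sorted unique values plus the endpoints)
— no continuous optimizer, so results are exactly reproducible.  β = 2.0 on
standardized values, fixed rather than fitted, keeps scores comparable
across regulators.  Standardization is what makes miRNA and mRNA
regulators commensurable: only profile shape across samples enters the
score.  Scale invariance is exact to machine precision; for power-of-two
rescalings of a raw row the scores are bit-identical, and for general
affine transforms they agree to ≤ 1e-9 with identical rankings (the mean
subtraction rounds differently after an arbitrary shift — exact bit
equality for all affine maps is not achievable in floating point).

Up to `top_k` = 100 regulators are kept per node (ties broken by id).  The
global score of regulator r in a module is

    Σ_nodes w · (s_r − s̄)   over nodes where r is in the top-K,

with w = node weight / total samples and s̄ the node's top-K mean; negative
sums floor at 0.  Centering by the top-K mean converts raw log-likelihoods
into "strength above peers", which is what makes the random-regulator null
comparison meaningful.  The sign is the weighted majority of node signs.
A regulator may belong to the module it regulates (regulators are ordinary
matrix rows).

## Random-regulator null and cutoff

Each of `null_draws` = 1,000 draws samples a regulator uniformly from the
candidate set and a (module, tree, node) position uniformly from all
recorded nodes, scores it through the *same* code path as true assignments
(`node_regulator_score`; tested for exact equality), and aggregates as a
single-assignment global score max(0, w·(s − s̄)).  Calls use the
(1 − quantile) empirical quantile of true interaction scores — the default
quantile 0.02 keeps the top 2%, ceil(0.02·N) interactions with ties at the
cutoff all retained — while the maximum null score is reported alongside as
the separation diagnostic.  Whether random regulators should be matched
per node or pooled globally is underdetermined; uniform (module, node)
sampling is this package's choice.

## Enrichment

One-sided hypergeometric upper tails P(X ≥ k), computed as log-space sums
of exact log-pmf terms, for every (module, gene set) pair with non-zero
overlap; Benjamini–Hochberg correction within each module (per-module
regulator lists suggest per-module testing); enriched at adjusted
p < 0.05.  Gene sets are flat GMT lists; no ontology-hierarchy handling.
The universe defaults to all matrix rows.

## Synthetic data

`generate_dataset` plants the structure the analysis is designed to find:

* **Modules** (default 3 × 20 genes, 40 samples): per module, samples are
  assigned uniformly to 2–4 condition clusters whose means are i.i.d.
  N(0, cluster_mean_sd²); gene rows are the module's mean profile plus
  N(0, gene_noise_sd²) noise.  The strong-signal default
  (cluster_mean_sd = 2.0, gene_noise_sd = 0.3) makes condition structure
  dominate noise — chosen as the regime where recovery should be essentially
  perfect, so failures indicate implementation defects rather than
  statistical ambiguity.  `moderate_signal_config` (1.0/0.5) is provided
  for harder regimes.
* **Direct regulators** (1/module): sign · standardized module mean + noise.
* **Indirect regulators** (1/module): same construction — the regulator
  genuinely tracks the module — but the causal path runs through a hidden
  intermediate TF whose *emitted* row is the anti-correlated true
  intermediate profile blurred by N(0, indirect_divergence_sd²).  This
  reproduces the situation where a repressive TF links a miRNA to its
  module but the TF's own transcript profile has diverged, so the TF is
  neither clustered with the module nor selectable as a regulator while the
  miRNA still is.  Hidden intermediates are emitted as matrix rows but
  never enter the candidate set.
* **miRNA kind**: each regulator/decoy is miRNA-kind with probability
  `mirna_fraction`; miRNA rows are multiplied by `mirna_scale` (default
  0.25) to emulate a different absolute measurement scale.  Standardized
  profiles are scale-invariant, so downstream ranking must be unaffected
  (tested).
* **Decoys and background**: i.i.d. N(0, 1) rows.

Reproducibility: one `SeedSequence` per dataset, spawned deterministically
into per-entity substreams, so the same seed yields bit-identical output.

What the generator does *not* emulate: probe/batch effects, heavy-tailed
noise, correlated backgrounds, overlapping modules, tumor-class label
structure, or realistic regulator-to-target ratios.  Passing recovery
tests therefore demonstrates correctness of the machinery under the
planted model, not performance guarantees on real tumor compendia.

## Numerical choices

* Block evidence uses a per-prior lookup table of the count-dependent
  terms; candidate blocks with n = 0 score exactly 0.
* Within-block sums of squared deviations are clipped at 0 to absorb
  cancellation error in (near-)constant blocks; a negative posterior β is a
  hard error (it can only arise from corrupted statistics).
* Move sampling uses exp(Δ − max Δ) normalization; ties are resolved by
  the sampler itself (no argmax).
* Agglomerative merges break exact ties toward the earlier cluster pair in
  iteration order; node orientation puts the lower-mean side left, with
  ties keeping merge order.
* Degenerate inputs: constant regulator rows score as uninformative rather
  than erroring; a constant module yields single-leaf trees (no nodes);
  empty score tables and zero-row filters are hard errors.

## Problem sizes

Defaults throughout (30 runs × 100 sweeps, 100 trees, top-100 per node,
1,000 null draws) are the reference workflow's parameters.  The test suite
and `scripts/acceptance.py` run them on the 3 × 20-gene / 40-sample
synthetic conditions, where the full analysis completes in minutes on one
CPU; the implementation is O(moves × clusters) per sweep and has been run
on matrices of a few hundred rows comfortably.  Very large compendia
(10⁴ genes) would need longer runtimes but no algorithmic changes.

## Known limitations

* The tight-cluster step cannot split exactly symmetric equal blocks (see
  above).
* Consistently co-clustered noise rows can form their own "background"
  tight cluster; such clusters carry near-zero regulator scores and no
  enrichment, but are reported.
* The joint gene/condition kernel is exact Gibbs in each coordinate block,
  but creating/destroying a cluster forgets its condition partition, so the
  full two-way chain is not exactly reversible; runs are used as point
  estimates, where this is immaterial.
* Global scores are comparable within a dataset and parameter setting, not
  across datasets.
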