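"""Gene-set over-representation of modules.

One-sided hypergeometric tests (is the overlap between a module and a gene
set larger than chance, given the universe?) with Benjamini-Hochberg
correction applied within each module.  Gene sets are flat id lists; no
ontology hierarchy handling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import GeneSetCollection


def hypergeom_pval(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` = overlap, ``n`` = module size, ``K`` = set size, ``N`` = universe
    size.  Computed as a log-space sum of exact log pmf terms.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    if support.size == 0:
        return 0.0
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(modules, sets: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Test every (module, gene set) pair with non-zero overlap.

    ``modules`` is a :class:`~modulenet.consensus.TightClusterSet` or a
    mapping module id -> gene list.  Module genes outside the universe are
    dropped with a warning.  Returns a table with raw and BH-adjusted
    p-values (adjusted within each module) and an ``enriched`` flag for
    ``p_adj < alpha``.
    """
    if not sets.universe:
        raise ValueError("empty gene universe")
    module_map = modules.as_dict() if hasattr(modules, "as_dict") else dict(modules)
    universe = set(sets.universe)
    N = len(universe)
    set_members = {name: set(m) for name, m in sets.sets.items()}

    rows = []
    for mid, genes in module_map.items():
        mset = set(genes)
        outside = mset - universe
        if outside:
            warnings.warn(
                f"module {mid}: {len(outside)} genes outside the universe dropped",
                stacklevel=2)
            mset -= outside
        n = len(mset)
        if n == 0:
            continue
        tested = []
        for name, members in set_members.items():
            k = len(mset & members)
            if k == 0:
                continue
            p = hypergeom_pval(k, n, len(members), N)
            tested.append({"module": mid, "set": name, "k": k, "n": n,
                           "K": len(members), "N": N, "p_raw": p})
        if not tested:
            continue
        padj = bh_adjust([t["p_raw"] for t in tested])
        for t, pa in zip(tested, padj):
            t["p_adj"] = float(pa)
            t["enriched"] = bool(pa < alpha)
            rows.append(t)
    cols = ["module", "set", "k", "n", "K", "N", "p_raw", "p_adj", "enriched"]
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values(["module", "p_adj", "set"]).reset_index(drop=True)
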