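"""Tissue-specificity indices and gene-set enrichment statistics.

Tau (Yanai-style index, 0 = ubiquitous, 1 = single-tissue) and Shannon
entropy (bits) score how restricted a gene's expression is across a panel of
tissues. Catalogue enrichment (e.g. against a cell-cycle periodic gene list)
uses a permutation test on overlap size; set-vs-set intersection is compared
to its expected size with a Pearson chi-square on the 2x2 membership table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_PERM = 10_000


def tau_score(expression) -> float:
    """Tau = sum_i (1 - x_i / x_max) / (n - 1); 0 when uniform, 1 when a
    single tissue carries all expression."""
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression must be a vector over >= 2 tissues")
    if (x < 0).any() or x.max() <= 0:
        raise ValueError("expression must be non-negative with positive max")
    return float((1.0 - x / x.max()).sum() / (x.size - 1))


def entropy_score(expression) -> float:
    """Shannon entropy (bits) of the normalized expression distribution;
    0 * log 0 := 0."""
    x = np.asarray(expression, dtype=float)
    if (x < 0).any() or x.sum() <= 0:
        raise ValueError("expression must be non-negative with positive sum")
    p = x / x.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def specificity_table(expr: pd.DataFrame) -> pd.DataFrame:
    """Tau and entropy per gene of a gene x tissue expression matrix
    (genes with all-zero expression are dropped)."""
    expr = expr.loc[expr.max(axis=1) > 0]
    return pd.DataFrame({
        "gene_id": expr.index,
        "tau": [tau_score(r) for r in expr.to_numpy()],
        "entropy": [entropy_score(r) for r in expr.to_numpy()],
    }).set_index("gene_id")


def permutation_enrichment(query: set, catalogue: set, universe: set,
                           n_perm: int = DEFAULT_N_PERM,
                           seed: int | np.random.Generator = 0
                           ) -> dict:
    """Permutation test for catalogue overlap of a gene set.

    Draws ``n_perm`` random query-sized sets from the universe without
    replacement and compares their catalogue overlaps with the observed one:
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    query, catalogue, universe = set(query), set(catalogue), set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    uni = np.array(sorted(universe))
    in_cat = np.isin(uni, sorted(catalogue & universe))
    observed = len(query & catalogue)
    k = len(query)
    perm_overlaps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(uni.size, size=k, replace=False)
        perm_overlaps[i] = int(in_cat[idx].sum())
    p = (1 + int((perm_overlaps >= observed).sum())) / (n_perm + 1)
    return {"observed_overlap": observed, "query_size": k,
            "catalogue_in_universe": int(in_cat.sum()),
            "universe_size": uni.size, "n_perm": n_perm,
            "expected_overlap": float(perm_overlaps.mean()),
            "p_value": float(p)}


def overlap_chisq(set_a: set, set_b: set, universe: set) -> dict:
    """Expected intersection size and Pearson chi-square (no continuity
    correction) for the overlap of two gene sets within a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    n = len(universe)
    a_and_b = len(set_a & set_b)
    a_not_b = len(set_a) - a_and_b
    b_not_a = len(set_b) - a_and_b
    neither = n - a_and_b - a_not_b - b_not_a
    expected = len(set_a) * len(set_b) / n
    table = np.array([[a_and_b, a_not_b], [b_not_a, neither]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"observed_overlap": a_and_b, "expected_overlap": float(expected),
            "chi_square": float(chi2), "p_value": float(p)}


def read_gene_set(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")}


def map_orthologs(genes: set[str], mapping: pd.DataFrame) -> set[str]:
    """Translate gene ids through a two-column mapping table
    (columns: source, target); one-to-many mappings expand."""
    src, tgt = mapping.columns[:2]
    sub = mapping[mapping[src].isin(genes)]
    return set(sub[tgt])
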