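"""Hypergeometric term enrichment with BH correction and a permutation check.

Over-representation of each term among a gene set is tested with the
hypergeometric upper tail P[X >= k] (equivalently one-sided Fisher), where
k = set genes with the term, K = background genes with the term, n = set
size, N = background size.  p values are Benjamini-Hochberg adjusted over
the tested-term universe (terms with K >= 1 and k >= 1, the convention of
common over-representation tools); terms with q < alpha are significant.

The permutation check redraws random gene sets of the same size and counts
how often each observed significant term is also significant in them --
truly enriched terms should essentially never recur.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    gene_set,
    term_map: pd.DataFrame,
    background,
    alpha: float = 0.05,
    test_universe: str = "observed",
) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` against ``background``.

    ``term_map`` needs columns gene_id/term_id (term_name optional).
    ``test_universe="observed"`` tests terms with K >= 1 and k >= 1;
    ``"annotated"`` tests every term with K >= 1.
    """
    background = sorted(set(background))
    gene_set = sorted(set(gene_set))
    offenders = sorted(set(gene_set) - set(background))
    if offenders:
        raise ValueError(f"genes absent from background: {offenders}")
    N, n = len(background), len(gene_set)
    tm = term_map[term_map["gene_id"].isin(background)]
    names = tm.drop_duplicates("term_id").set_index("term_id")
    by_term = tm.groupby("term_id")["gene_id"].agg(set)
    in_set = set(gene_set)
    rows = []
    for term_id, genes in by_term.items():
        K = len(genes)
        k = len(genes & in_set)
        if K == 0 or (test_universe == "observed" and k == 0):
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        name = names.at[term_id, "term_name"] if "term_name" in names.columns else term_id
        rows.append((term_id, name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"])
    if len(table):
        table = table.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < alpha
    else:
        table["q_value"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def enrichment_permutation(
    term_map: pd.DataFrame,
    background,
    set_size: int,
    observed_significant,
    n_perm: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
    test_universe: str = "observed",
) -> dict[str, int]:
    """How often each observed significant term is significant in random sets.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the background and reruns the full enrichment (including BH).
    """
    if seed is None:
        raise ValueError("a seed is required: permutation runs must be reproducible")
    background = sorted(set(background))
    if set_size > len(background):
        raise ValueError("set_size larger than background")
    rng = np.random.default_rng(seed)
    recurrence = {t: 0 for t in observed_significant}
    if not recurrence or n_perm == 0:
        return recurrence
    bg = np.asarray(background, dtype=object)
    for _ in range(n_perm):
        draw = bg[rng.choice(len(bg), size=set_size, replace=False)]
        table = hypergeometric_enrichment(draw, term_map, background, alpha=alpha,
                                          test_universe=test_universe)
        sig = set(table.loc[table["significant"], "term_id"])
        for t in recurrence:
            if t in sig:
                recurrence[t] += 1
    return recurrence
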