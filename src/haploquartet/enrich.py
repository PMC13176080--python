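"""Fisher's-exact over-representation of functional terms.

Given a study gene set (tissue-enriched genes, DEGs, strong-bias or
rank-switch quartet members), a background population, and a gene -> term
map, each term's 2x2 table is tested one-sided (over-representation, i.e.
the hypergeometric upper tail) and BH-adjusted.  Terms are flat opaque
labels; no ontology-graph propagation is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ase import bh_adjust


def fisher_enrichment(
    study,
    population,
    terms: dict[str, set[str]],
    min_k: int = 1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Term over-representation in ``study`` against ``population``.

    For each term with at least ``min_k`` study genes the 2x2 table
    (study/non-study x term/non-term) is tested with Fisher's exact test,
    one-sided toward over-representation by default.  The sample odds ratio
    k(N-n-K+k) / ((n-k)(K-k)) is reported as inf when a denominator cell is
    zero.  Rows are BH-adjusted and sorted by (q, p, term).
    """
    study = set(study)
    population = set(population)
    extra = sorted(study - population)
    if extra:
        raise ValueError(f"study genes outside the population: {extra[:10]}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    N, n = len(population), len(study)
    rows = []
    term_genes: dict[str, set[str]] = {}
    for g in population:
        for t in terms.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    for term in sorted(term_genes):
        genes = term_genes[term]
        K = len(genes)
        k = len(genes & study)
        if k < min_k:
            continue
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - n - K + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        num = k * (N - n - K + k)
        den = (n - k) * (K - k)
        odds = float("inf") if den == 0 else num / den
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "odds_ratio": odds, "p_value": p}
        )
    out = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "odds_ratio", "p_value"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(
            ["q_value", "p_value", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
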