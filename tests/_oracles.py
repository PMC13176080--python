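"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal route available —
explicit loops, exhaustive enumeration, closed forms — and deliberately
shares no code with the package's implementations.
"""

from __future__ import annotations

import math


def bh_step_up(p_values: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up on a plain list of p-values."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    scaled = [p_values[i] * m / (rank + 1) for rank, i in enumerate(indexed)]
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, scaled[rank])
        q_sorted[rank] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(indexed):
        q[i] = q_sorted[rank]
    return q


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by explicit tail summation."""
    denom = math.comb(N, n)
    total = 0.0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        total += math.comb(K, j) * math.comb(N - K, n - j) / denom
    return total


def pearson_chi2(table: list[list[float]]) -> tuple[float, int]:
    """Sum (O-E)^2/E over a contingency table, with its df."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    grand = sum(rows)
    stat = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            e = rows[i] * cols[j] / grand
            stat += (o - e) ** 2 / e
    return stat, (len(rows) - 1) * (len(cols) - 1)


def classify_orthogroup(lists: list[list[str]], mode: str) -> str | None:
    """Retention class of one orthogroup, or None if excluded."""
    sizes = [len(l) for l in lists]
    arity = sum(1 for s in sizes if s > 0)
    if arity == 0:
        return None
    if mode == "strict" and any(s > 1 for s in sizes):
        return None
    return {4: "tetra", 3: "tri", 2: "bi", 1: "mono"}[arity]


def evaluate_filters(
    quartet_counts: dict[str, dict[str, int]],
    condition_of: dict[str, str],
    conditions: tuple[str, str],
    thr,
    per_gene_scope: str,
) -> bool:
    """Rule-by-rule read-support filter evaluation for one quartet.

    ``quartet_counts`` maps gene -> sample -> count over the contrast's
    samples only.
    """
    samples = [s for s in condition_of if condition_of[s] in conditions]
    genes = list(quartet_counts)

    grand = sum(quartet_counts[g][s] for g in genes for s in samples)
    if grand < thr.min_total_reads:
        return False
    for c in conditions:
        cond_sum = sum(
            quartet_counts[g][s] for g in genes for s in samples if condition_of[s] == c
        )
        if cond_sum < thr.min_reads_per_condition:
            return False
    if per_gene_scope == "overall":
        for g in genes:
            if sum(quartet_counts[g][s] for s in samples) < thr.min_reads_per_gene:
                return False
    else:
        for g in genes:
            for c in conditions:
                tot = sum(
                    quartet_counts[g][s] for s in samples if condition_of[s] == c
                )
                if tot < thr.min_reads_per_gene:
                    return False
    for c in conditions:
        detected = 0
        for s in samples:
            if condition_of[s] != c:
                continue
            if sum(quartet_counts[g][s] for g in genes) >= thr.detect_count:
                detected += 1
        if detected < thr.min_detected_replicates:
            return False
    return True


def median_of_ratios(matrix: list[list[float]]) -> list[float]:
    """Size factors by median-of-ratios over all-positive genes, rescaled to
    median 1 (plain-python reimplementation)."""
    import statistics

    usable = [row for row in matrix if all(v > 0 for v in row)]
    log_ref = [sum(math.log(v) for v in row) / len(row) for row in usable]
    n_samples = len(matrix[0])
    factors = []
    for j in range(n_samples):
        ratios = [math.log(row[j]) - lr for row, lr in zip(usable, log_ref)]
        factors.append(math.exp(statistics.median(ratios)))
    med = statistics.median(factors)
    return [f / med for f in factors]
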