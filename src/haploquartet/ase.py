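"""Allele-specific expression statistics over haplotype quartets.

For each quartet the reads of the four haplotype copies are pooled within a
condition and expressed as proportions of the quartet total (the four
proportions sum to 1).  Allelic bias within a condition is the spread
max - min of those proportions: below 0.25 balanced, 0.25-0.5 mild
dominance, above 0.5 strong dominance of a single allele.  Control-vs-stress
shifts in haplotype ratios are tested with a Pearson chi-square on the 2x4
pooled-count table (BH-adjusted, FDR < 0.05); "rank switching" records a
change of the top-expressing haplotype between conditions, and the effect
size delta is the change in the maximum haplotype proportion
(>= 0.10 moderate, >= 0.20 pronounced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HAPLOTYPES, CountsMatrix, SampleSheet
from .quartets import Quartet

BIAS_MILD = 0.25
BIAS_STRONG = 0.50
DELTA_MODERATE = 0.10
DELTA_PRONOUNCED = 0.20
ASE_FDR = 0.05


@dataclass
class ProportionVector:
    """Per-haplotype read proportions within one condition (sum to 1)."""

    p: np.ndarray  # length 4, order A-D
    pooled_total: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.pooled_total <= 0:
            raise ValueError("proportions undefined for pooled total 0")
        if not math.isclose(float(self.p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HAPLOTYPES, self.p))


@dataclass
class BiasResult:
    bias: float
    dominance_class: str  # balanced | mild | strong


def condition_proportions(
    quartet: Quartet, counts: CountsMatrix, samples: SampleSheet, condition: str
) -> ProportionVector:
    """Pool each haplotype's reads over the condition's replicates and
    divide by the quartet total."""
    cols = samples.samples_for(condition)
    if not cols:
        raise ValueError(f"condition {condition!r} absent from sample sheet")
    pooled = counts.counts.loc[list(quartet.genes), cols].sum(axis=1).to_numpy()
    total = int(pooled.sum())
    if total == 0:
        raise ValueError(
            f"quartet {quartet.orthogroup_id!r} has zero pooled reads in "
            f"condition {condition!r}"
        )
    return ProportionVector(pooled / total, total)


def pooled_counts(
    quartet: Quartet, counts: CountsMatrix, samples: SampleSheet, condition: str
) -> np.ndarray:
    """Per-haplotype read counts pooled over a condition's replicates."""
    cols = samples.samples_for(condition)
    return counts.counts.loc[list(quartet.genes), cols].sum(axis=1).to_numpy()


def allelic_bias(p: ProportionVector | np.ndarray) -> BiasResult:
    """Spread (max - min) of the haplotype proportions and its dominance class.

    Boundaries: bias < 0.25 balanced; 0.25 <= bias <= 0.5 mild; bias > 0.5
    strong (strong dominance requires strictly more than 0.5).
    """
    vec = p.p if isinstance(p, ProportionVector) else np.asarray(p, dtype=float)
    bias = float(vec.max() - vec.min())
    if bias < BIAS_MILD:
        cls = "balanced"
    elif bias <= BIAS_STRONG:
        cls = "mild"
    else:
        cls = "strong"
    return BiasResult(bias=bias, dominance_class=cls)


def contrast_chi_square(
    pooled_control: np.ndarray, pooled_stress: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square of independence on the 2x4 condition-by-haplotype
    table, no continuity correction.

    Haplotype columns with zero reads in BOTH conditions are dropped and the
    degrees of freedom reduced accordingly.  If fewer than two columns
    remain (or a condition has no reads) the test is undefined and
    (nan, 0, nan) is returned; callers exclude such quartets from FDR.
    """
    a = np.asarray(pooled_control, dtype=float)
    b = np.asarray(pooled_stress, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("pooled counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if keep.sum() < 2 or a.sum() == 0 or b.sum() == 0:
        return (float("nan"), 0, float("nan"))
    table = np.vstack([a, b])
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = table.shape[1] - 1
    return (stat, dof, float(stats.chi2.sf(stat, dof)))


def expected_min_cell(pooled_control: np.ndarray, pooled_stress: np.ndarray) -> float:
    """Smallest expected cell count of the contingency table (audit flag)."""
    a = np.asarray(pooled_control, dtype=float)
    b = np.asarray(pooled_stress, dtype=float)
    keep = (a + b) > 0
    table = np.vstack([a[keep], b[keep]])
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return float("nan")
    expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / table.sum()
    return float(expected.min())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    NaN entries (undefined tests) are excluded from the adjustment and
    reinserted as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m:
        order = np.argsort(pf, kind="mergesort")
        scaled = pf[order] * m / np.arange(1, m + 1)
        qs = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        out = np.empty(m)
        out[order] = qs
        q[finite] = out
    return q


def rank_and_delta(
    p_control: ProportionVector | np.ndarray, p_stress: ProportionVector | np.ndarray
) -> dict:
    """Top haplotype per condition, rank-switch flag, and the delta effect.

    Ties at the top are broken alphabetically (A before B ...) and flagged.
    delta is the absolute difference of the two conditions' maximum
    proportions; effect class: < 0.10 none, 0.10-0.20 moderate, >= 0.20
    pronounced.
    """
    pc = p_control.p if isinstance(p_control, ProportionVector) else np.asarray(p_control, float)
    ps = p_stress.p if isinstance(p_stress, ProportionVector) else np.asarray(p_stress, float)
    ic, is_ = int(np.argmax(pc)), int(np.argmax(ps))
    tie_c = int((pc == pc[ic]).sum()) > 1
    tie_s = int((ps == ps[is_]).sum()) > 1
    delta = float(abs(ps[is_] - pc[ic]))
    if delta < DELTA_MODERATE:
        effect = "none"
    elif delta < DELTA_PRONOUNCED:
        effect = "moderate"
    else:
        effect = "pronounced"
    return {
        "top_control": HAPLOTYPES[ic],
        "top_stress": HAPLOTYPES[is_],
        "rank_switch": ic != is_,
        "tie_control": tie_c,
        "tie_stress": tie_s,
        "delta": delta,
        "effect_class": effect,
    }


def _bias_cdf(values: np.ndarray) -> list[tuple[float, float]]:
    """Empirical CDF coordinates of a bias distribution (plot-ready)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    return [(float(x), (i + 1) / n) for i, x in enumerate(v)]


def run_ase(
    quartets: list[Quartet],
    counts: CountsMatrix,
    samples: SampleSheet,
    contrast: tuple[str, str],
    fdr: float = ASE_FDR,
    strict_ties: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full per-quartet ASE contrast: proportions, bias classes, chi-square
    with BH FDR (computed within this contrast), rank switching and delta.

    ``contrast`` is (control_label, stress_label).  Quartets are assumed to
    have passed :func:`filter_quartets` for this contrast.  With
    ``strict_ties`` quartets whose top haplotype is tied are excluded from
    the rank-switch count (default: included, tie flag set).

    Returns the per-quartet table and a summary dict (quartet counts,
    dominance-class counts per condition, rank-switch and delta-threshold
    counts, the strong-bias / pronounced-delta intersection, significant-q
    count, and per-condition bias CDF coordinates).
    """
    control, stress = contrast
    if not quartets:
        import warnings

        warnings.warn("run_ase called with an empty quartet set", stacklevel=2)
        return pd.DataFrame(), {"n_quartets": 0}

    # pool replicate counts per condition for all quartets at once
    gene_list = [g for q in quartets for g in q.genes]
    nq = len(quartets)
    pools = {}
    for cond in (control, stress):
        cols = samples.samples_for(cond)
        arr = counts.counts.loc[gene_list, cols].to_numpy()
        pools[cond] = arr.reshape(nq, 4, len(cols)).sum(axis=2)

    rows = []
    for i, q in enumerate(quartets):
        pool_c = pools[control][i]
        pool_s = pools[stress][i]
        pv_c = ProportionVector(pool_c / pool_c.sum(), int(pool_c.sum()))
        pv_s = ProportionVector(pool_s / pool_s.sum(), int(pool_s.sum()))
        bias_c = allelic_bias(pv_c)
        bias_s = allelic_bias(pv_s)
        stat, dof, p = contrast_chi_square(pool_c, pool_s)
        rd = rank_and_delta(pv_c, pv_s)
        row = {
            "orthogroup_id": q.orthogroup_id,
            **{f"gene_{h}": g for h, g in zip(HAPLOTYPES, q.genes)},
            **{f"p{h}_control": v for h, v in pv_c.as_dict().items()},
            **{f"p{h}_stress": v for h, v in pv_s.as_dict().items()},
            "total_control": pv_c.pooled_total,
            "total_stress": pv_s.pooled_total,
            "bias_control": bias_c.bias,
            "class_control": bias_c.dominance_class,
            "bias_stress": bias_s.bias,
            "class_stress": bias_s.dominance_class,
            "chi2_stat": stat,
            "df": dof,
            "p_value": p,
            "low_expected": expected_min_cell(pool_c, pool_s) < 1.0,
            **rd,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < fdr

    switch_mask = table["rank_switch"]
    if strict_ties:
        switch_mask = switch_mask & ~(table["tie_control"] | table["tie_stress"])
    strong_any = (table["class_control"] == "strong") | (
        table["class_stress"] == "strong"
    )
    summary = {
        "contrast": {"control": control, "stress": stress},
        "n_quartets": int(len(table)),
        "dominance_counts": {
            "control": table["class_control"].value_counts().to_dict(),
            "stress": table["class_stress"].value_counts().to_dict(),
        },
        "n_rank_switch": int(switch_mask.sum()),
        "frac_switch_delta_lt_0.1": (
            float((table.loc[switch_mask, "delta"] < DELTA_MODERATE).mean())
            if switch_mask.any()
            else float("nan")
        ),
        "n_delta_ge_0.10": int((table["delta"] >= DELTA_MODERATE).sum()),
        "n_delta_ge_0.20": int((table["delta"] >= DELTA_PRONOUNCED).sum()),
        "n_strong_and_delta_ge_0.20": int(
            (strong_any & (table["delta"] >= DELTA_PRONOUNCED)).sum()
        ),
        "n_significant_q": int(table["significant"].sum()),
        "n_undefined_tests": int(table["p_value"].isna().sum()),
        "bias_cdf": {
            "control": _bias_cdf(table["bias_control"].to_numpy()),
            "stress": _bias_cdf(table["bias_stress"].to_numpy()),
        },
    }
    return table, summary
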