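"""Tissue-enrichment atlas: expressed/stable gene criteria, tissue
collapsing, tissue-factor likelihood-ratio tests, and the max-vs-second
assignment rule.

A gene counts as *expressed* when its CPM is >= 1 in at least 2 libraries,
and as *stable* when the coefficient of variation of its
variance-stabilised values across all samples is <= 0.20 (stricter tiers at
< 0.15 and < 0.10 — the mixed boundary operators are intentional and
preserved).  Closely related tissues are collapsed into broader categories
before testing (young leaves, mature leaves, roots, ...), each gene is
tested with an NB LRT of the tissue factor against an intercept-only model,
assigned to its highest-expressing category, and called enriched when the
BH-adjusted LRT p is < 0.01 and the top category exceeds the second by a
log2 fold-change of at least 1 on the variance-stabilised scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountsMatrix, SampleSheet
from .ase import bh_adjust
from . import nbglm

logger = logging.getLogger(__name__)

ATLAS_FDR = 0.01
ATLAS_MIN_LFC = 1.0
CV_TIERS = (0.20, 0.15, 0.10)

#: The nine raw tissue labels of a full developmental atlas.
DEFAULT_TISSUES = (
    "emerging_leaves",
    "developing_leaves",
    "first_expanded_leaves",
    "third_expanded_leaves",
    "stem",
    "floral_buds",
    "open_flowers",
    "root_crown",
    "root_tips",
)

#: Default collapsing of the nine raw tissues into six broader categories.
DEFAULT_TISSUE_SCHEME = {
    "emerging_leaves": "young_leaves",
    "developing_leaves": "young_leaves",
    "first_expanded_leaves": "mature_leaves",
    "third_expanded_leaves": "mature_leaves",
    "root_crown": "roots",
    "root_tips": "roots",
    "stem": "stem",
    "floral_buds": "floral_buds",
    "open_flowers": "open_flowers",
}


def cpm_matrix(counts: CountsMatrix) -> pd.DataFrame:
    """Counts per million: count / library total * 1e6, per sample."""
    df = counts.counts
    totals = df.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = df.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero library total")
    return df / totals * 1e6


def vst_like(counts: CountsMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilising stand-in: log2(count / size_factor + 1).

    Monotone in counts, non-negative, and invariant to jointly scaling a
    sample's counts and its factor.
    """
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    f = factors.reindex(df.columns).to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(df / f + 1.0)


def collapse_tissues(
    samples: SampleSheet, scheme: dict[str, str] | None = None, strict: bool = True
) -> SampleSheet:
    """Replace raw tissue labels by their collapsed categories.

    Unmapped labels map to themselves unless ``strict``, in which case they
    raise.  Sample ids, conditions and replicate indices are untouched.
    """
    scheme = DEFAULT_TISSUE_SCHEME if scheme is None else scheme
    t = samples.table.copy()
    unmapped = sorted(set(t["tissue"]) - set(scheme))
    if unmapped and strict and scheme is not DEFAULT_TISSUE_SCHEME:
        raise ValueError(f"tissue label(s) {unmapped} not covered by the scheme")
    t["tissue"] = t["tissue"].map(lambda x: scheme.get(x, x))
    return SampleSheet(t)


@dataclass
class ExpressionFlags:
    gene_id: str
    expressed: bool
    cv: float
    tier: str  # none | cv20 | cv15 | cv10


def expression_flags(
    counts: CountsMatrix,
    min_cpm: float = 1.0,
    min_libs: int = 2,
    cv_tiers: tuple[float, float, float] = CV_TIERS,
    cv_on_vst: bool = True,
) -> pd.DataFrame:
    """Expressed flag and stability tier per gene.

    CV = sd/mean of the variance-stabilised values across ALL samples
    (raw-normalised scale with ``cv_on_vst=False``).  Tier boundaries are
    <= tiers[0], < tiers[1], < tiers[2] (nested; the strictest satisfied tier
    is reported).  Genes with zero mean have undefined CV and tier "none".
    """
    df = counts.counts
    expressed = nbglm.expressed_mask(df, min_cpm=min_cpm, min_libs=min_libs)
    if cv_on_vst:
        vals = vst_like(df, nbglm.size_factors(df)).to_numpy(dtype=float)
    else:
        vals = (df / nbglm.size_factors(df)).to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    t20, t15, t10 = cv_tiers
    tier = np.full(len(df), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        tier[(~np.isnan(cv)) & (cv <= t20)] = "cv20"
        tier[(~np.isnan(cv)) & (cv < t15)] = "cv15"
        tier[(~np.isnan(cv)) & (cv < t10)] = "cv10"
    return pd.DataFrame(
        {"gene_id": df.index, "expressed": expressed.to_numpy(), "cv": cv, "tier": tier}
    ).reset_index(drop=True)


def tissue_enrichment(
    counts: CountsMatrix,
    samples: SampleSheet,
    scheme: dict[str, str] | None = None,
    fdr: float = ATLAS_FDR,
    min_lfc: float = ATLAS_MIN_LFC,
    min_cpm: float = 1.0,
    min_libs: int = 2,
) -> pd.DataFrame:
    """Per-gene tissue-enrichment calls over the collapsed atlas.

    For each expressed gene an NB LRT compares the full model (tissue factor)
    to the intercept-only model (df = categories - 1); p-values are
    BH-adjusted across tested genes.  Each gene is assigned to the category
    with the highest mean variance-stabilised expression; ``enriched`` is
    q < 0.01 together with a top-vs-second margin of >= 1 on the log2 scale.
    """
    collapsed = collapse_tissues(samples, scheme)
    cats = collapsed.tissues()
    if len(cats) < 2:
        raise ValueError("need at least 2 collapsed tissue categories")
    reps = collapsed.table.groupby("tissue")["sample_id"].count()
    thin = reps[reps < 2]
    if len(thin):
        raise ValueError(f"tissue category {thin.index[0]!r} has < 2 replicates")

    order = collapsed.table["sample_id"].tolist()
    df = counts.counts[order]
    labels = collapsed.table["tissue"].tolist()
    sf = nbglm.size_factors(df)
    offset = np.log(sf.to_numpy())
    X_full, levels = nbglm.design_from_labels(labels)
    X_red = np.ones((len(order), 1))
    dof = X_full.shape[1] - 1

    keep = nbglm.expressed_mask(df, min_cpm=min_cpm, min_libs=min_libs)
    tested = df.loc[keep]
    vst = vst_like(tested, sf)
    cat_means = vst.T.groupby(pd.Series(labels, index=vst.columns)).mean().T

    stats_, ps, ok = [], [], []
    for i in range(len(tested)):
        try:
            full, red, stat, p = nbglm.nb_lrt_gene(
                tested.iloc[i].to_numpy(), X_full, X_red, offsets=offset
            )
            good = full.converged and red.converged
        except Exception:
            stat, p, good = np.nan, np.nan, False
        if not good:
            stat, p = np.nan, np.nan
        stats_.append(stat)
        ps.append(p)
        ok.append(good)
    n_failed = len(ok) - int(np.sum(ok))
    if n_failed:
        logger.info("tissue_enrichment: %d gene(s) excluded for non-convergence", n_failed)

    means = cat_means.to_numpy(dtype=float)
    # argsort descending; ties resolved by category order for determinism
    top_idx = np.argmax(means, axis=1)
    masked = means.copy()
    masked[np.arange(len(means)), top_idx] = -np.inf
    second_idx = np.argmax(masked, axis=1)
    cats_arr = np.array(cat_means.columns)
    lfc = means[np.arange(len(means)), top_idx] - means[np.arange(len(means)), second_idx]

    out = pd.DataFrame(
        {
            "gene_id": tested.index,
            "lrt_stat": stats_,
            "p_value": ps,
            "top_tissue": cats_arr[top_idx],
            "second_tissue": cats_arr[second_idx],
            "log2fc_top_vs_second": lfc,
        }
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = (out["q_value"] < fdr) & (out["log2fc_top_vs_second"] >= min_lfc)
    out["enriched"] = out["enriched"].fillna(False)
    return out.reset_index(drop=True)
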