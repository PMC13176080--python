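"""Quartet construction: haplotype assignment, allelic-retention
classification, 1:1:1:1 orthogroup selection and read-support filtering.

In the autotetraploid genome each gene lives on one of four homologous
chromosome copies, identified by the trailing letter of its chromosome name
(``chr1a`` .. ``chr7d``).  Orthogroups computed across the four haplotype
pseudo-species are classified by how many haplotypes retain a member
(tetra/tri/bi/mono-allelic), and the 1:1:1:1 groups — exactly one gene per
haplotype — form the quartets on which allele-specific expression is
measured.  Before testing, quartets must show sufficient read support in the
control-vs-stress contrast under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HAPLOTYPES, CountsMatrix, OrthogroupTable, SampleSheet

UNPLACED = "UNPLACED"

RETENTION_CLASSES = {4: "tetra", 3: "tri", 2: "bi", 1: "mono"}


def haplotype_of(chrom: str) -> str:
    """Map a chromosome identifier to its haplotype letter.

    The trailing letter a/b/c/d (case-insensitive) names the haplotype;
    identifiers ending in "un" (unanchored) or anything else are UNPLACED.
    Total function: never raises.
    """
    if not chrom:
        return UNPLACED
    if chrom[-2:].lower() == "un":
        return UNPLACED
    last = chrom[-1].lower()
    if last in "abcd":
        return last.upper()
    return UNPLACED


@dataclass
class RetentionSummary:
    """Allelic-retention breakdown of an orthogroup table."""

    mode: str  # "strict" or "lenient"
    n_orthogroups: int
    counts: dict[str, int]  # class name -> count
    proportions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.mode,
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "proportion": [self.proportions[c] for c in self.counts],
            }
        )


def classify_retention(og: OrthogroupTable, mode: str = "strict") -> RetentionSummary:
    """Classify orthogroups as tetra/tri/bi/mono-allelic.

    strict: only orthogroups whose every non-empty haplotype list has exactly
    one member are counted (within-haplotype duplicates disqualify).
    lenient: every orthogroup with at least one member is counted, duplicates
    tolerated.  In both modes the class is the number of haplotypes with at
    least one member; empty orthogroups are excluded.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    counts = {name: 0 for name in RETENTION_CLASSES.values()}
    n = 0
    for _, by_hap in og.items():
        sizes = [len(by_hap.get(h, [])) for h in HAPLOTYPES]
        arity = sum(s > 0 for s in sizes)
        if arity == 0:
            continue
        if mode == "strict" and any(s > 1 for s in sizes):
            continue
        counts[RETENTION_CLASSES[arity]] += 1
        n += 1
    props = {c: (counts[c] / n if n else 0.0) for c in counts}
    return RetentionSummary(mode=mode, n_orthogroups=n, counts=counts, proportions=props)


@dataclass(frozen=True)
class Quartet:
    """A 1:1:1:1 orthogroup: exactly one gene per haplotype A-D."""

    orthogroup_id: str
    genes: tuple[str, str, str, str]  # ordered A, B, C, D

    def __post_init__(self) -> None:
        if len(set(self.genes)) != 4:
            raise ValueError(
                f"quartet {self.orthogroup_id!r} must hold 4 distinct genes"
            )

    def gene_for(self, hap: str) -> str:
        return self.genes[HAPLOTYPES.index(hap)]


def select_quartets(og: OrthogroupTable) -> list[Quartet]:
    """Return the 1:1:1:1 orthogroups as quartets, in input order."""
    out = []
    for og_id, by_hap in og.items():
        lists = [by_hap.get(h, []) for h in HAPLOTYPES]
        if all(len(l) == 1 for l in lists):
            out.append(Quartet(og_id, tuple(l[0] for l in lists)))
    return out


@dataclass
class FilterThresholds:
    """Read-support thresholds for a control-vs-stress contrast.

    Defaults follow the read-support rule set used throughout: >= 50 total
    reads across the four haplotypes, >= 20 reads per condition, >= 10 reads
    per gene, and at least 2 replicates with detectable expression in each
    condition (detectable = quartet-level count >= ``detect_count``).
    """

    min_total_reads: int = 50
    min_reads_per_condition: int = 20
    min_reads_per_gene: int = 10
    min_detected_replicates: int = 2
    detect_count: int = 1

    def __post_init__(self) -> None:
        for name in (
            "min_total_reads",
            "min_reads_per_condition",
            "min_reads_per_gene",
            "min_detected_replicates",
            "detect_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# failure codes emitted in the filter report
F_TOTAL = "F1"  # grand total below min_total_reads
F_CONDITION = "F2"  # a condition total below min_reads_per_condition
F_GENE = "F3"  # a member gene below min_reads_per_gene
F_DETECT = "F4"  # too few detected replicates in a condition


def filter_quartets(
    quartets: list[Quartet],
    counts: CountsMatrix,
    samples: SampleSheet,
    thresholds: FilterThresholds | None = None,
    conditions: tuple[str, str] | None = None,
    per_gene_scope: str = "overall",
) -> tuple[list[Quartet], pd.DataFrame]:
    """Apply the read-support filters for one contrast.

    A quartet is kept iff all four rules hold over the contrast's samples:
    (F1) grand total across the 4 genes >= min_total_reads; (F2) per-condition
    quartet total >= min_reads_per_condition in every condition; (F3) each
    member gene's total >= min_reads_per_gene (``per_gene_scope`` chooses
    whether that total is over all contrast samples, "overall", or must hold
    within each condition, "per-condition"); (F4) in every condition at least
    min_detected_replicates replicates have quartet-level count >=
    detect_count.

    Returns the kept quartets (input order) and a per-quartet report listing
    which rule(s) failed.
    """
    thr = thresholds or FilterThresholds()
    if per_gene_scope not in ("overall", "per-condition"):
        raise ValueError(f"per_gene_scope must be 'overall' or 'per-condition'")
    conds = list(conditions) if conditions else samples.conditions()
    if len(conds) < 2:
        raise ValueError("filtering requires at least 2 conditions in the contrast")
    cond_samples = {c: samples.samples_for(c) for c in conds}
    all_samples = [s for c in conds for s in cond_samples[c]]

    df = counts.counts
    missing = sorted(
        {g for q in quartets for g in q.genes if g not in df.index}
    )
    if missing:
        raise KeyError(f"quartet gene(s) missing from counts matrix: {missing[:5]}")

    nq = len(quartets)
    if nq == 0:
        return [], pd.DataFrame(
            columns=["orthogroup_id", "kept", "failed_rules", "grand_total"]
        )
    # all quartets hold exactly 4 genes: evaluate the rules vectorised on an
    # (nq, 4, n_samples) stack
    gene_list = [g for q in quartets for g in q.genes]
    sub = df.loc[gene_list, all_samples].to_numpy()
    stack = sub.reshape(nq, 4, len(all_samples))
    cond_slices = {}
    start = 0
    for c in conds:
        cond_slices[c] = slice(start, start + len(cond_samples[c]))
        start += len(cond_samples[c])

    grand = stack.sum(axis=(1, 2))
    fail_total = grand < thr.min_total_reads
    fail_cond = np.zeros(nq, dtype=bool)
    fail_detect = np.zeros(nq, dtype=bool)
    for c in conds:
        cstack = stack[:, :, cond_slices[c]]
        fail_cond |= cstack.sum(axis=(1, 2)) < thr.min_reads_per_condition
        rep_tot = cstack.sum(axis=1)  # (nq, n_reps)
        fail_detect |= (rep_tot >= thr.detect_count).sum(axis=1) < thr.min_detected_replicates
    if per_gene_scope == "overall":
        fail_gene = (stack.sum(axis=2) < thr.min_reads_per_gene).any(axis=1)
    else:
        fail_gene = np.zeros(nq, dtype=bool)
        for c in conds:
            gt = stack[:, :, cond_slices[c]].sum(axis=2)
            fail_gene |= (gt < thr.min_reads_per_gene).any(axis=1)

    kept: list[Quartet] = []
    rows = []
    for i, q in enumerate(quartets):
        failures = []
        if fail_total[i]:
            failures.append(F_TOTAL)
        if fail_cond[i]:
            failures.append(F_CONDITION)
        if fail_gene[i]:
            failures.append(F_GENE)
        if fail_detect[i]:
            failures.append(F_DETECT)
        if not failures:
            kept.append(q)
        rows.append(
            {
                "orthogroup_id": q.orthogroup_id,
                "kept": not failures,
                "failed_rules": ";".join(failures),
                "grand_total": int(grand[i]),
            }
        )
    return kept, pd.DataFrame(rows)
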