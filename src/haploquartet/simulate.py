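"""Synthetic haplotype-quartet and tissue-atlas count data with ground truth.

The quartet generator emulates the statistical structure the ASE pipeline
assumes: per quartet and condition a single true haplotype-proportion vector
is drawn from a Dirichlet (or constructed to carry a planted effect), and in
every replicate an overdispersed negative-binomial total read count is split
multinomially across the four haplotype genes — i.e. allele counts are
Dirichlet-multinomial across quartets, multinomial within a quartet.
Because the truth is fixed per quartet, the null generator (identical
proportions in both conditions) yields pooled 2x4 tables whose chi-square
p-values are uniform, which is exactly what a type-I-error harness needs.

Planted effects are defined on TRUE proportions so recovery is well-posed:
"strong" quartets have max - min >= 0.55, "mild" sit in [0.25, 0.5], and
"switch" quartets change the top haplotype between conditions with the
maximum proportion changing by exactly ``delta_planted``.

The atlas generator draws per-gene NB counts across tissues and replicates,
multiplying one tissue's mean by 2^planted_lfc for enriched genes.

Every output is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HAPLOTYPES, CountsMatrix, OrthogroupTable, SampleSheet
from .atlas import DEFAULT_TISSUES

_CHROM_LETTERS = ("a", "b", "c", "d")


@dataclass
class QuartetSimConfig:
    """Configuration of the haplotype-quartet simulator.

    Defaults reflect the study design the pipeline targets: 4 biological
    replicates per condition, a control/stress contrast, and a sequencing
    depth (~500 reads per quartet per replicate) at which the read-support
    filters are typically passed.  ``concentration`` controls how tightly
    balanced quartets hug (1/4, 1/4, 1/4, 1/4).
    """

    n_quartets: int = 100
    n_replicates: int = 4
    conditions: tuple[str, str] = ("control", "stress")
    depth_mean: float = 500.0
    depth_dispersion: float = 0.1
    concentration: float = 30.0
    frac_strong_bias: float = 0.0
    frac_mild_bias: float = 0.0
    frac_switch: float = 0.0
    delta_planted: float = 0.25
    seed: int = 0
    # optional arity noise: fractions of orthogroups rendered non-1:1:1:1
    frac_tri: float = 0.0
    frac_bi: float = 0.0
    frac_mono: float = 0.0
    frac_dup: float = 0.0

    def __post_init__(self) -> None:
        eff = self.frac_strong_bias + self.frac_mild_bias + self.frac_switch
        noise = self.frac_tri + self.frac_bi + self.frac_mono + self.frac_dup
        for name, v in (("effect", eff), ("arity-noise", noise)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fractions must lie in [0, 1] and sum <= 1")
        if self.depth_mean <= 0 or self.concentration <= 0:
            raise ValueError("depth_mean and concentration must be positive")
        if self.n_quartets < 0 or self.n_replicates <= 0:
            raise ValueError("n_quartets >= 0 and n_replicates >= 1 required")


@dataclass
class AtlasSimConfig:
    """Configuration of the tissue-atlas simulator.

    Per-gene baselines are drawn lognormally around ``baseline_mean`` so the
    matrix carries a realistic spread of expression levels; enriched genes
    have one tissue's mean multiplied by 2^planted_lfc and stable genes are
    generated with a tenfold-smaller dispersion.
    """

    n_genes: int = 500
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 4
    baseline_mean: float = 100.0
    baseline_log_sd: float = 0.6
    nb_dispersion: float = 0.05
    frac_enriched: float = 0.0
    planted_lfc: float = 2.0
    frac_stable: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_enriched + self.frac_stable <= 1.0:
            raise ValueError("fractions must lie in [0, 1] and sum <= 1")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be positive")
        if self.baseline_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("baseline_mean > 0 and nb_dispersion >= 0 required")


def _nb_totals(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def _draw_strong(rng: np.random.Generator) -> np.ndarray:
    """True proportions with max - min >= 0.55 (single dominant allele)."""
    for _ in range(1000):
        dom = rng.uniform(0.65, 0.90)
        rest = rng.dirichlet(np.ones(3)) * (1.0 - dom)
        p = np.concatenate([[dom], rest])
        rng.shuffle(p)
        if p.max() - p.min() >= 0.55:
            return p
    raise RuntimeError("strong-bias rejection sampling failed")


def _draw_mild(rng: np.random.Generator) -> np.ndarray:
    """True proportions with bias in [0.25, 0.5] (mild dominance)."""
    for _ in range(1000):
        dom = rng.uniform(0.40, 0.50)
        rest = rng.dirichlet(np.ones(3) * 3.0) * (1.0 - dom)
        p = np.concatenate([[dom], rest])
        rng.shuffle(p)
        bias = p.max() - p.min()
        if 0.25 <= bias <= 0.5:
            return p
    raise RuntimeError("mild-bias rejection sampling failed")


def _draw_switch(rng: np.random.Generator, concentration: float, delta: float):
    """Control proportions plus a stress vector whose top haplotype differs
    and whose maximum proportion is exactly max(control) + delta."""
    for _ in range(1000):
        pc = rng.dirichlet(np.full(4, concentration))
        m = pc.max()
        if m + delta < 0.95:
            break
    else:
        raise RuntimeError("switch construction failed: delta too large")
    top_c = int(np.argmax(pc))
    others = [i for i in range(4) if i != top_c]
    new_top = int(rng.choice(others))
    ps = np.empty(4)
    ps[new_top] = m + delta
    rest = [i for i in range(4) if i != new_top]
    w = pc[rest] / pc[rest].sum()
    ps[rest] = (1.0 - ps[new_top]) * w
    return pc, ps


def _quartet_ids(k: int) -> tuple[str, list[str], list[str]]:
    og_id = f"OG{k:05d}"
    genes = [f"OVQ{k:05d}_{l}" for l in _CHROM_LETTERS]
    chroms = [f"chr{(k % 7) + 1}{l}" for l in _CHROM_LETTERS]
    return og_id, genes, chroms


def simulate_quartets(
    cfg: QuartetSimConfig,
) -> tuple[CountsMatrix, SampleSheet, OrthogroupTable, dict[str, str], pd.DataFrame]:
    """Generate a quartet count dataset with ground truth.

    Returns (counts, sample sheet, orthogroup table, gene -> chromosome map,
    truth table).  The truth table has one row per orthogroup with its
    planted class (balanced/mild/strong/switch), arity, the true per-condition
    proportion vectors and the true delta.
    """
    rng = np.random.default_rng(cfg.seed)
    control, stress = cfg.conditions
    sample_rows = []
    for cond in cfg.conditions:
        for r in range(1, cfg.n_replicates + 1):
            sample_rows.append(
                {"sample_id": f"{cond}_rep{r}", "condition": cond,
                 "tissue": "leaf", "replicate": r}
            )
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    sample_ids = sheet.sample_ids

    n = cfg.n_quartets
    n_strong = int(round(cfg.frac_strong_bias * n))
    n_mild = int(round(cfg.frac_mild_bias * n))
    n_switch = int(round(cfg.frac_switch * n))
    n_tri = int(round(cfg.frac_tri * n))
    n_bi = int(round(cfg.frac_bi * n))
    n_mono = int(round(cfg.frac_mono * n))
    n_dup = int(round(cfg.frac_dup * n))
    classes = (
        ["strong"] * n_strong
        + ["mild"] * n_mild
        + ["switch"] * n_switch
        + ["balanced"] * (n - n_strong - n_mild - n_switch)
    )
    rng.shuffle(classes)
    arities = (
        ["tri"] * n_tri + ["bi"] * n_bi + ["mono"] * n_mono + ["dup"] * n_dup
        + ["quartet"] * (n - n_tri - n_bi - n_mono - n_dup)
    )
    rng.shuffle(arities)

    gene_rows: list[str] = []
    count_rows: list[np.ndarray] = []
    groups: dict[str, dict[str, list[str]]] = {}
    gene_map: dict[str, str] = {}
    truth_rows = []

    for k in range(n):
        og_id, genes, chroms = _quartet_ids(k)
        cls = classes[k]
        arity = arities[k]
        if cls == "strong":
            pc = _draw_strong(rng)
            ps = pc.copy()
        elif cls == "mild":
            pc = _draw_mild(rng)
            ps = pc.copy()
        elif cls == "switch":
            pc, ps = _draw_switch(rng, cfg.concentration, cfg.delta_planted)
        else:
            pc = rng.dirichlet(np.full(4, cfg.concentration))
            ps = pc.copy()
        delta_true = abs(ps.max() - pc.max())

        # haplotype membership under the requested arity
        by_hap = {h: [g] for h, g in zip(HAPLOTYPES, genes)}
        active = list(range(4))
        if arity == "tri":
            drop = int(rng.integers(4))
            by_hap[HAPLOTYPES[drop]] = []
            active.remove(drop)
        elif arity == "bi":
            drops = rng.choice(4, size=2, replace=False)
            for d in drops:
                by_hap[HAPLOTYPES[int(d)]] = []
                active.remove(int(d))
        elif arity == "mono":
            keep = int(rng.integers(4))
            for i in range(4):
                if i != keep:
                    by_hap[HAPLOTYPES[i]] = []
            active = [keep]
        elif arity == "dup":
            h = int(rng.integers(4))
            extra = f"OVQ{k:05d}_{_CHROM_LETTERS[h]}2"
            by_hap[HAPLOTYPES[h]] = [by_hap[HAPLOTYPES[h]][0], extra]
            genes = genes + [extra]
            chroms = chroms + [f"chr{(k % 7) + 1}{_CHROM_LETTERS[h]}"]
        groups[og_id] = by_hap

        member_genes = [g for h in HAPLOTYPES for g in by_hap[h]]
        member_idx: list[int] = []
        for h_i, h in enumerate(HAPLOTYPES):
            member_idx.extend([h_i] * len(by_hap[h]))

        mat = np.zeros((len(member_genes), len(sample_ids)), dtype=np.int64)
        col = 0
        for cond, p in ((control, pc), (stress, ps)):
            # restrict truth proportions to the active haplotypes; duplicate
            # members split their haplotype's share evenly
            weights = np.zeros(len(member_genes))
            for j, h_i in enumerate(member_idx):
                if h_i in active:
                    n_members = member_idx.count(h_i)
                    weights[j] = p[h_i] / n_members
            weights = weights / weights.sum()
            for _ in range(cfg.n_replicates):
                total = int(_nb_totals(rng, cfg.depth_mean, cfg.depth_dispersion, None))
                mat[:, col] = rng.multinomial(total, weights)
                col += 1
        for g, c, row in zip(member_genes, [chroms[genes.index(g)] for g in member_genes], mat):
            gene_rows.append(g)
            count_rows.append(row)
            gene_map[g] = c

        truth_rows.append(
            {
                "orthogroup_id": og_id,
                "class": cls,
                "arity": arity,
                **{f"p{h}_control": v for h, v in zip(HAPLOTYPES, pc)},
                **{f"p{h}_stress": v for h, v in zip(HAPLOTYPES, ps)},
                "delta_true": delta_true,
            }
        )

    counts = CountsMatrix(
        pd.DataFrame(
            np.vstack(count_rows) if count_rows else np.zeros((0, len(sample_ids)), dtype=np.int64),
            index=pd.Index(gene_rows, name="gene_id"),
            columns=sample_ids,
        )
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "orthogroup_id", "class", "arity",
            *[f"p{h}_control" for h in HAPLOTYPES],
            *[f"p{h}_stress" for h in HAPLOTYPES],
            "delta_true",
        ],
    )
    return counts, sheet, OrthogroupTable(groups), gene_map, truth


def simulate_null_contrast(
    cfg: QuartetSimConfig,
) -> tuple[CountsMatrix, SampleSheet, OrthogroupTable, dict[str, str], pd.DataFrame]:
    """Null-contrast harness: identical true proportions in both conditions.

    Equivalent to :func:`simulate_quartets` with every effect fraction zero;
    chi-square p-values computed on its output are uniform under the model.
    """
    from dataclasses import replace

    null_cfg = replace(cfg, frac_strong_bias=0.0, frac_mild_bias=0.0, frac_switch=0.0)
    return simulate_quartets(null_cfg)


def simulate_atlas(
    cfg: AtlasSimConfig,
) -> tuple[CountsMatrix, SampleSheet, pd.DataFrame]:
    """Generate a tissue-atlas count dataset with ground truth.

    Returns (counts, sample sheet, truth).  Truth lists each gene's baseline
    mean, its enriched tissue (empty when none) and its stability flag.
    """
    rng = np.random.default_rng(cfg.seed)
    tissues = list(cfg.tissues)
    sample_rows = []
    for t in tissues:
        for r in range(1, cfg.n_replicates + 1):
            sample_rows.append(
                {"sample_id": f"{t}_rep{r}", "condition": "atlas",
                 "tissue": t, "replicate": r}
            )
    sheet = SampleSheet(pd.DataFrame(sample_rows))

    n = cfg.n_genes
    n_enriched = int(round(cfg.frac_enriched * n))
    n_stable = int(round(cfg.frac_stable * n))
    status = ["enriched"] * n_enriched + ["stable"] * n_stable + [
        "plain"
    ] * (n - n_enriched - n_stable)
    rng.shuffle(status)

    genes = [f"ATG{i:05d}" for i in range(n)]
    baselines = cfg.baseline_mean * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=n)
    )
    mult = 2.0**cfg.planted_lfc
    mat = np.zeros((n, len(sheet.sample_ids)), dtype=np.int64)
    truth_rows = []
    for i in range(n):
        enr_tissue = ""
        disp = cfg.nb_dispersion
        if status[i] == "enriched":
            enr_tissue = tissues[int(rng.integers(len(tissues)))]
        elif status[i] == "stable":
            disp = cfg.nb_dispersion / 10.0
        col = 0
        for t in tissues:
            mean = baselines[i] * (mult if t == enr_tissue else 1.0)
            draws = _nb_totals(rng, mean, disp, cfg.n_replicates)
            mat[i, col : col + cfg.n_replicates] = draws
            col += cfg.n_replicates
        truth_rows.append(
            {
                "gene_id": genes[i],
                "baseline_mean": baselines[i],
                "enriched_tissue": enr_tissue,
                "stable": status[i] == "stable",
            }
        )
    counts = CountsMatrix(
        pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                     columns=sheet.sample_ids)
    )
    return counts, sheet, pd.DataFrame(truth_rows)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")
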