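# haploquartet

Allele-specific expression (ASE) across haplotype quartets, tissue-enriched
expression calling, and stress differential expression for **autotetraploid
RNA-Seq count data** — with a fully seeded synthetic-data generator that
carries ground truth for every planted effect.

## The problem

In an autotetraploid genome with resolved haplotypes, every locus can retain
up to four allelic gene copies, one per homologous chromosome (named by the
chromosome suffix, `chr1a` … `chr7d`). Three questions drive the analysis:

1. **Do the four alleles of a locus share the transcriptional load?**
   Orthogroups computed across the four haplotypes (treated as
   pseudo-species) are classified by allelic retention (tetra/tri/bi/mono),
   and the 1:1:1:1 groups — *quartets* — are scored for allelic bias.
2. **Does stress re-balance the alleles?** Haplotype ratios are contrasted
   between control and stress, rank switching of the top allele is recorded,
   and effect sizes are summarized as the change in the maximum allele
   proportion.
3. **Which genes mark each tissue, and which respond to stress?** A
   negative-binomial GLM engine drives a tissue-factor likelihood-ratio test
   and two-group differential expression, and Fisher's exact test connects
   the resulting gene sets to functional terms.

## The statistics

For a quartet with pooled per-haplotype read counts
$(n_A, n_B, n_C, n_D)$ in one condition, the haplotype proportions are
$p_h = n_h / \sum_k n_k$ (so $\sum_h p_h = 1$) and the **allelic bias** is

$$b = \max_h p_h - \min_h p_h,$$

classified *balanced* ($b < 0.25$), *mild dominance* ($0.25 \le b \le 0.5$)
or *strong dominance* ($b > 0.5$). Control-vs-stress ratio shifts are tested
with a Pearson chi-square on the $2 \times 4$ pooled-count table (df = 3, no
continuity correction; columns empty in both conditions are dropped),
BH-adjusted at FDR < 0.05. **Rank switching** flags a change of
$\arg\max_h p_h$ between conditions, and the effect size

$$\Delta = \left| \max_h p_h^{\text{stress}} - \max_h p_h^{\text{control}} \right|$$

is *moderate* at $\Delta \ge 0.10$ and *pronounced* at $\Delta \ge 0.20$.
Quartets enter the analysis only with sufficient read support (≥ 50 total
reads, ≥ 20 per condition, ≥ 10 per gene, ≥ 2 detected replicates per
condition).

Tissue enrichment fits a gene-wise NB2 GLM (log link, median-of-ratios
offsets, Cox–Reid adjusted profile-ML dispersion) and compares the tissue
model to an intercept model by LRT; a gene is *tissue-enriched* when the
BH-adjusted p is < 0.01 **and** its top tissue exceeds the second by ≥ 1 on
the log2 variance-stabilised scale. DEGs require adjusted p ≤ 0.05 and
|log2FC| ≥ 1. Term over-representation is a one-sided Fisher's exact test
(hypergeometric upper tail) with BH correction.

## Worked example

```python
from haploquartet import (QuartetSimConfig, simulate_quartets,
                          select_quartets, filter_quartets, run_ase)

cfg = QuartetSimConfig(n_quartets=1000, frac_strong_bias=0.05,
                       frac_mild_bias=0.10, frac_switch=0.10,
                       delta_planted=0.25, seed=2)
counts, sheet, orthogroups, gene_map, truth = simulate_quartets(cfg)
kept, _ = filter_quartets(select_quartets(orthogroups), counts, sheet)
table, summary = run_ase(kept, counts, sheet, ("control", "stress"))
```

Running `python examples/02_allele_specific_expression.py` (this script)
prints:

```
analyzed 996 quartets
dominance classes (control): {'balanced': 852, 'mild': 98, 'strong': 46}
rank-switch quartets: 236 (58.5% of them with delta < 0.1)
delta >= 0.10: 100   delta >= 0.20: 100
strong bias and delta >= 0.20: 7
significant haplotype-ratio shifts (q < 0.05): 106
planted switches detected: 98.0% of 100 (mean |delta error| 0.012)
```

Reading it: of 1000 simulated quartets, 996 pass the read-support filters;
the dominance classes recover the planted 5% strong / 10% mild mixture; the
106 significant chi-square contrasts track the planted 10% of quartets with
a true proportion shift, every one of which carries Δ ≥ 0.10 (planted
Δ = 0.25, estimated with ≈ 0.01 absolute error); the remaining "switches"
are the noise-level top-allele flips expected among balanced quartets, which
is why most of them sit below Δ = 0.1.

The other scripts in `examples/` cover quartet construction and retention
(`01`), the tissue atlas (`03`), stress DE and DEG overlap (`04`), and term
enrichment (`05`). Each runs in seconds and prints what the numbers mean.

## Command line

Every stage is also a subcommand writing TSV/JSON outputs (exit 0 success, 1
data error, 2 usage error); reruns with the same seed and configuration are
byte-identical:

```bash
haploquartet simulate --preset quartet-effects --seed 7 -o sim/
haploquartet ase --orthogroups sim/orthogroups.tsv --counts sim/counts.tsv \
    --samples sim/samples.tsv --contrast control:stress -o ase_out/
haploquartet atlas --counts atlas/counts.tsv --samples atlas/samples.tsv -o atlas_out/
```

Subcommands: `simulate`, `retention`, `quartets`, `ase`, `atlas`, `de`,
`de-overlap`, `enrich`. A YAML file passed as `--config` overrides any
threshold or simulator parameter by name.

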