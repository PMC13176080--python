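"""Generate a haplotype-quartet dataset and apply the read-support filters.

Simulates 300 orthogroups over a control/stress contrast with some
non-1:1:1:1 arity noise, classifies allelic retention, selects the 1:1:1:1
quartets and filters them for read support.
"""

from haploquartet import (
    QuartetSimConfig,
    classify_retention,
    filter_quartets,
    select_quartets,
    simulate_quartets,
)

cfg = QuartetSimConfig(
    n_quartets=300, frac_tri=0.10, frac_bi=0.05, frac_mono=0.02, frac_dup=0.08,
    seed=1,
)
counts, sheet, orthogroups, gene_map, truth = simulate_quartets(cfg)

print(f"simulated {len(orthogroups)} orthogroups, "
      f"{len(counts.gene_ids)} genes x {len(counts.sample_ids)} samples")

for mode in ("strict", "lenient"):
    s = classify_retention(orthogroups, mode)
    shares = ", ".join(f"{c}: {p:.1%}" for c, p in s.proportions.items())
    print(f"{mode:>7} retention over n={s.n_orthogroups}: {shares}")

quartets = select_quartets(orthogroups)
kept, report = filter_quartets(quartets, counts, sheet)
print(f"{len(quartets)} quartets selected (1:1:1:1), {len(kept)} pass the "
      f"read-support filters (>=50 total, >=20/condition, >=10/gene, "
      f">=2 detected replicates)")
# The retention shares say how many loci keep all four alleles; the filter
# count is the number of quartets deep enough to test for allelic bias.
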