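import numpy as np
import pandas as pd
import pytest

from haploquartet import CountsMatrix, Quartet, SampleSheet

CONTROL_SAMPLES = [f"control_rep{i}" for i in range(1, 5)]
STRESS_SAMPLES = [f"stress_rep{i}" for i in range(1, 5)]


@pytest.fixture
def contrast_sheet() -> SampleSheet:
    rows = [
        {"sample_id": s, "condition": c, "tissue": "leaf", "replicate": i}
        for c, names in (("control", CONTROL_SAMPLES), ("stress", STRESS_SAMPLES))
        for i, s in enumerate(names, start=1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def _quartet(k: int) -> Quartet:
    return Quartet(f"OG{k:03d}", tuple(f"q{k:03d}_{h}" for h in "abcd"))


@pytest.fixture
def crafted_filter_fixture() -> tuple[list[Quartet], CountsMatrix]:
    """Twelve quartets crafted to probe every read-support rule and its
    boundaries: zero counts, grand totals of 49/50, condition totals of
    19/20, per-gene totals of 0/9/10 (including an 8/2 condition split that
    separates the two per-gene scopes), and replicate-detection patterns of
    1 vs exactly 2 detected replicates per condition."""
    rows: dict[str, list[int]] = {}

    def add(k: int, per_gene_rows: list[list[int]]):
        q = _quartet(k)
        for g, r in zip(q.genes, per_gene_rows):
            assert len(r) == 8
            rows[g] = r
        return q

    quartets = [
        # 1: all zero -> fails every rule
        add(1, [[0] * 8 for _ in range(4)]),
        # 2: control replicate quartet totals (30,30,0,0), stress (30,30,30,30)
        add(2, [
            [10, 5, 0, 0, 10, 10, 10, 10],
            [10, 5, 0, 0, 10, 10, 10, 10],
            [5, 10, 0, 0, 5, 5, 5, 5],
            [5, 10, 0, 0, 5, 5, 5, 5],
        ]),
        # 3: grand total 49, per-gene totals 13/12/12/12 -> F1 only
        add(3, [
            [2, 2, 2, 2, 2, 2, 1, 0],
            [2, 2, 1, 1, 2, 2, 1, 1],
            [1, 2, 2, 1, 2, 1, 2, 1],
            [1, 2, 2, 2, 1, 2, 1, 1],
        ]),
        # 4: grand total exactly 50 (25 per condition), all rules pass
        add(4, [
            [2, 2, 2, 1, 2, 2, 2, 1],
            [2, 1, 2, 1, 2, 1, 2, 1],
            [1, 2, 1, 2, 1, 2, 1, 2],
            [2, 1, 1, 2, 2, 1, 1, 2],
        ]),
        # 5: stress condition total 19 -> F2
        add(5, [
            [10, 10, 10, 10, 2, 2, 1, 1],
            [5, 5, 5, 5, 2, 2, 1, 1],
            [5, 5, 5, 5, 2, 1, 1, 1],
            [5, 5, 5, 5, 1, 1, 0, 0],
        ]),
        # 6: one gene totals 9 -> F3 in both scopes
        add(6, [
            [3, 2, 2, 2, 0, 0, 0, 0],
            [10, 10, 10, 10, 10, 10, 10, 10],
            [10, 10, 10, 10, 10, 10, 10, 10],
            [10, 10, 10, 10, 10, 10, 10, 10],
        ]),
        # 7: gene total 10 overall but 8/2 across conditions -> scope-dependent
        add(7, [
            [4, 4, 0, 0, 1, 1, 0, 0],
            [10, 10, 10, 10, 10, 10, 10, 10],
            [10, 10, 10, 10, 10, 10, 10, 10],
            [10, 10, 10, 10, 10, 10, 10, 10],
        ]),
        # 8: control reads all in one replicate -> F4
        add(8, [
            [40, 0, 0, 0, 10, 10, 10, 10],
            [30, 0, 0, 0, 10, 10, 10, 10],
            [20, 0, 0, 0, 5, 5, 5, 5],
            [10, 0, 0, 0, 5, 5, 5, 5],
        ]),
        # 9: exactly 2 detected replicates in each condition, all else passing
        add(9, [
            [15, 15, 0, 0, 15, 15, 0, 0],
            [10, 10, 0, 0, 10, 10, 0, 0],
            [5, 5, 0, 0, 5, 5, 0, 0],
            [5, 5, 0, 0, 5, 5, 0, 0],
        ]),
        # 10: stress has 5 reads in a single replicate -> F2 and F4
        add(10, [
            [20, 20, 20, 20, 5, 0, 0, 0],
            [10, 10, 10, 10, 0, 0, 0, 0],
            [10, 10, 10, 10, 0, 0, 0, 0],
            [10, 10, 10, 10, 0, 0, 0, 0],
        ]),
        # 11: comfortable pass
        add(11, [
            [50, 40, 60, 45, 55, 42, 61, 38],
            [30, 25, 33, 28, 29, 27, 31, 26],
            [20, 22, 18, 21, 19, 23, 17, 22],
            [10, 12, 9, 11, 10, 13, 8, 12],
        ]),
        # 12: one silent gene -> F3 only
        add(12, [
            [0, 0, 0, 0, 0, 0, 0, 0],
            [30, 30, 30, 30, 30, 30, 30, 30],
            [30, 30, 30, 30, 30, 30, 30, 30],
            [30, 30, 30, 30, 30, 30, 30, 30],
        ]),
    ]
    counts = CountsMatrix(
        pd.DataFrame.from_dict(
            rows, orient="index", columns=CONTROL_SAMPLES + STRESS_SAMPLES
        ).astype(np.int64)
    )
    return quartets, counts
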