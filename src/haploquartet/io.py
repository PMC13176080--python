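"""Readers and writers for the tabular formats the pipeline consumes.

All tables are plain TSV.  The gene-count matrix follows the StringTie /
featureCounts convention (first column gene id, one column per sample);
orthogroups follow the OrthoFinder ``Orthogroups.tsv`` dialect with the four
haplotypes of the autotetraploid genome treated as pseudo-species columns.

Everything is read and written as UTF-8; CRLF line endings are tolerated on
read, Unix newlines are emitted on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HAPLOTYPES = ("A", "B", "C", "D")

__all__ = [
    "HAPLOTYPES",
    "CountsMatrix",
    "SampleSheet",
    "OrthogroupTable",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
    "read_gene_map",
    "write_gene_map",
    "read_term_map",
    "write_term_map",
]


class DataError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class CountsMatrix:
    """Non-negative integer gene x sample read counts.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample id.  Identifiers must be unique and every cell a non-negative
    integer; fractional counts are rejected rather than rounded.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r} in counts matrix")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r} in counts matrix")
        arr = df.to_numpy()
        if arr.dtype.kind == "f":
            frac = arr != np.floor(arr)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise DataError(
                    f"non-integer count {arr[i, j]} at gene {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            arr = arr.astype(np.int64)
            self.counts = pd.DataFrame(arr, index=df.index, columns=df.columns)
        elif arr.dtype.kind not in "iu":
            raise DataError(f"counts matrix must be numeric, got dtype {arr.dtype}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count {arr[i, j]} at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountsMatrix) and self.counts.equals(other.counts)


@dataclass
class SampleSheet:
    """Sample metadata: one record per library.

    ``table`` has columns sample_id, condition, tissue, replicate.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "tissue", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"sample sheet missing column(s) {missing}")
        t = self.table.reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample id {dup!r} in sample sheet")
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] <= 0).any():
            raise DataError("replicate indices must be positive")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, condition: str) -> list[str]:
        sel = self.table["condition"] == condition
        return list(self.table.loc[sel, "sample_id"])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.table["tissue"]))


@dataclass
class OrthogroupTable:
    """Orthogroups with per-haplotype (pseudo-species) gene lists.

    ``groups`` maps orthogroup id -> dict haplotype -> list of gene ids, in
    file order.  A gene may belong to at most one orthogroup.
    """

    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og_id, by_hap in self.groups.items():
            for hap in HAPLOTYPES:
                for g in by_hap.get(hap, []):
                    if g in seen:
                        raise DataError(
                            f"gene {g!r} listed in two orthogroups "
                            f"({seen[g]!r} and {og_id!r})"
                        )
                    seen[g] = og_id

    def __len__(self) -> int:
        return len(self.groups)

    def items(self):
        return self.groups.items()


def _read_table(path, **kw) -> pd.DataFrame:
    # engine="python" tolerates CRLF transparently; dtype str defers typing
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)


def read_counts_tsv(path) -> CountsMatrix:
    """Read a gene x sample count matrix (first column gene id, header row)."""
    df = _read_table(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric count {df.iloc[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return CountsMatrix(numeric)


def write_counts_tsv(cm: CountsMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path, known_conditions: list[str] | None = None) -> SampleSheet:
    """Read the sample sheet (sample_id, condition, tissue, replicate)."""
    df = _read_table(path)
    sheet = SampleSheet(df)
    if known_conditions is not None:
        unknown = sorted(set(sheet.table["condition"]) - set(known_conditions))
        if unknown:
            warnings.warn(
                f"sample sheet contains condition label(s) {unknown} outside "
                f"the configured vocabulary {sorted(known_conditions)}",
                stacklevel=2,
            )
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _split_gene_cell(cell: str) -> list[str]:
    """Split an OrthoFinder gene-list cell: comma+space or plain comma."""
    cell = cell.strip()
    if not cell:
        return []
    return [g.strip() for g in cell.split(",") if g.strip()]


def read_orthogroups_tsv(
    path, species_columns: dict[str, str] | None = None
) -> OrthogroupTable:
    """Read an OrthoFinder-style Orthogroups.tsv with haplotype pseudo-species.

    Parameters
    ----------
    species_columns
        Optional mapping haplotype letter -> column name in the file.  By
        default the columns are expected to be named A, B, C, D (any order).
    """
    df = _read_table(path)
    og_col = df.columns[0]
    colmap = species_columns or {h: h for h in HAPLOTYPES}
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise DataError(
            f"orthogroup table needs 4 pseudo-species columns; missing {missing}"
        )
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og_id = row[og_col]
        if og_id in groups:
            raise DataError(f"duplicate orthogroup id {og_id!r}")
        groups[og_id] = {h: _split_gene_cell(row[col]) for h, col in colmap.items()}
    return OrthogroupTable(groups)


def write_orthogroups_tsv(og: OrthogroupTable, path) -> None:
    rows = []
    for og_id, by_hap in og.items():
        rows.append(
            {"Orthogroup": og_id}
            | {h: ", ".join(by_hap.get(h, [])) for h in HAPLOTYPES}
        )
    pd.DataFrame(rows, columns=["Orthogroup", *HAPLOTYPES]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gene_map(path) -> dict[str, str]:
    """Read a gene_id -> chromosome map (two-column TSV with header)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise DataError("gene map must have at least two columns")
    genes = df.iloc[:, 0]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise DataError(f"duplicate gene id {dup!r} in gene map")
    return dict(zip(genes, df.iloc[:, 1]))


def write_gene_map(gene_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"gene_id": list(gene_map), "chromosome": list(gene_map.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_term_map(path) -> dict[str, set[str]]:
    """Read a gene_id -> functional-term map (terms comma-separated)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise DataError("term map must have at least two columns")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        terms = {t.strip() for t in str(row.iloc[1]).split(",") if t.strip()}
        out.setdefault(row.iloc[0], set()).update(terms)
    return out


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(term_map),
            "terms": [",".join(sorted(v)) for v in term_map.values()],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
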