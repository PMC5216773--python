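"""Readers and writers for the package's plain-text formats.

Everything round-trips: synthetic fixtures are emitted through these
writers and re-read through the real parsers, so the file formats are part
of the tested surface.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import AssociationMatrix
from .mesh import MeshDescriptor, DiseaseDAG

__all__ = [
    "write_mesh_ascii",
    "read_association_table",
    "write_association_table",
    "association_from_pairs",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_dag_edges",
    "write_expression_tsv",
    "read_expression_tsv",
]


def write_mesh_ascii(descriptors, path) -> None:
    """Write descriptors in the MeSH ASCII ``*NEWRECORD`` layout."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in descriptors:
            fh.write("*NEWRECORD\n")
            fh.write(f"MH = {d.heading}\n")
            for tn in d.tree_numbers:
                fh.write(f"MN = {tn}\n")
            fh.write(f"UI = {d.unique_id}\n")
            fh.write("\n")


def association_from_pairs(pairs) -> AssociationMatrix:
    """Build the binary matrix from (lncRNA, disease) pairs.

    Duplicate pairs (the same association backed by different evidence
    lines) collapse to a single entry.  Row/column order follows first
    appearance.
    """
    lncs: list[str] = []
    diseases: list[str] = []
    seen_l: dict[str, int] = {}
    seen_d: dict[str, int] = {}
    entries = []
    for lnc, dis in pairs:
        if lnc not in seen_l:
            seen_l[lnc] = len(lncs)
            lncs.append(lnc)
        if dis not in seen_d:
            seen_d[dis] = len(diseases)
            diseases.append(dis)
        entries.append((seen_l[lnc], seen_d[dis]))
    if not entries:
        raise ValueError("no associations in input")
    values = np.zeros((len(lncs), len(diseases)), dtype=np.int8)
    for i, j in entries:
        values[i, j] = 1
    return AssociationMatrix(lncs, diseases, values)


def read_association_table(path) -> AssociationMatrix:
    """Read a 2-column (lncRNA, disease) TSV; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    return association_from_pairs(df.iloc[:, :2].itertuples(index=False, name=None))


def write_association_table(assoc: AssociationMatrix, path) -> None:
    rows = [
        (assoc.lncrna_ids[i], assoc.disease_ids[j])
        for i, j in np.argwhere(assoc.values == 1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    """Read a square matrix TSV with a shared header row/column of names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column names differ")
    return list(df.index), df.to_numpy(dtype=float)


def write_matrix_tsv(ids, values, path) -> None:
    pd.DataFrame(np.asarray(values), index=ids, columns=ids).to_csv(path, sep="\t")


def write_dag_edges(dag: DiseaseDAG, path) -> None:
    """Dump a disease DAG as a ``child<TAB>parent`` edge list."""
    edges = sorted((child, parent) for parent, child in dag.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def write_expression_tsv(ids, matrix, path) -> None:
    cols = [f"sample_{i + 1}" for i in range(np.asarray(matrix).shape[1])]
    pd.DataFrame(np.asarray(matrix), index=ids, columns=cols).to_csv(path, sep="\t")


def read_expression_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
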