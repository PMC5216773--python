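"""LncRNA functional similarity from disease-group semantic similarity.

Each lncRNA is represented by the group of diseases it is associated with.
The similarity of two lncRNAs is the best-match group average: every
disease in one group is matched to its most similar disease in the other
group, and the matched scores are averaged over both directions, weighted
by group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fuzzy import DiseaseSimilarityMatrix

__all__ = [
    "DiseaseGroup",
    "LncSimilarityMatrix",
    "term_group_similarity",
    "lncrna_functional_similarity",
    "build_lnc_similarity_matrix",
]


@dataclass(frozen=True)
class DiseaseGroup:
    """The disease set G(i) associated with one lncRNA."""

    lncrna_id: str
    diseases: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.diseases)


@dataclass
class LncSimilarityMatrix:
    lncrna_ids: list[str]
    values: np.ndarray


def term_group_similarity(
    d: str, group: DiseaseGroup, fs: DiseaseSimilarityMatrix
) -> float:
    """Best match of disease ``d`` against a disease group: max FS(d, .)."""
    if group.size == 0:
        raise ValueError(f"empty disease group for {group.lncrna_id!r}")
    di = fs.disease_ids.index(d)
    idx = [fs.disease_ids.index(dj) for dj in group.diseases]
    return float(fs.values[di, idx].max())


def lncrna_functional_similarity(
    gi: DiseaseGroup, gj: DiseaseGroup, fs: DiseaseSimilarityMatrix
) -> float:
    """Best-match group average between the disease groups of two lncRNAs.

    S = [sum over di in G(i) of max_j FS(di, dj)
         + sum over dj in G(j) of max_i FS(dj, di)] / (|G(i)| + |G(j)|)
    """
    if gi.size == 0 or gj.size == 0:
        raise ValueError("both disease groups must be nonempty")
    order = {d: k for k, d in enumerate(fs.disease_ids)}
    ii = [order[d] for d in gi.diseases]
    jj = [order[d] for d in gj.diseases]
    block = fs.values[np.ix_(ii, jj)]
    total = block.max(axis=1).sum() + block.max(axis=0).sum()
    return float(total / (gi.size + gj.size))


def build_lnc_similarity_matrix(
    groups, fs: DiseaseSimilarityMatrix
) -> LncSimilarityMatrix:
    """Fill all unordered lncRNA pairs; the diagonal is 1 by definition."""
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one lncRNA group")
    order = {d: k for k, d in enumerate(fs.disease_ids)}
    idx = [np.array([order[d] for d in g.diseases], dtype=int) for g in groups]
    n = len(groups)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            block = fs.values[np.ix_(idx[i], idx[j])]
            total = block.max(axis=1).sum() + block.max(axis=0).sum()
            s[i, j] = s[j, i] = total / (len(idx[i]) + len(idx[j]))
    np.clip(s, 0.0, 1.0, out=s)
    return LncSimilarityMatrix(lncrna_ids=[g.lncrna_id for g in groups], values=s)
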