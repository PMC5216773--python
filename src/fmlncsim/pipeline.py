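"""End-to-end glue: MeSH descriptors + association table -> similarity and scores."""

from __future__ import annotations

import logging

from .fuzzy import (
    DiseaseSimilarityMatrix,
    build_disease_similarity_matrix,
    density_sets_from_dags,
)
from .funcsim import DiseaseGroup, build_lnc_similarity_matrix, LncSimilarityMatrix
from .kernels import AssociationMatrix
from .mesh import DiseaseNameMap, build_disease_dag, map_disease_names, _tree_number_index
from .predict import ModelConfig

logger = logging.getLogger(__name__)


def disease_similarity_from_mesh(
    descriptors,
    disease_names,
    cap: float = 0.999,
    log_base: float | None = None,
) -> tuple[DiseaseSimilarityMatrix, DiseaseNameMap]:
    """Semantic similarity matrix for the diseases of an association table.

    Disease names are reconciled with MeSH headings; names with no heading
    are reported in the returned map and excluded from the matrix (the
    predictor substitutes kernel similarity for them).  The IC corpus is
    the set of DAGs of the mapped diseases, i.e. the disease universe is
    the dataset, not all of MeSH.
    """
    import math

    descriptors = list(descriptors)
    name_map = map_disease_names(disease_names, descriptors)
    if name_map.unmapped:
        logger.warning(
            "%d disease name(s) not found in MeSH: %s",
            len(name_map.unmapped),
            ", ".join(name_map.unmapped[:10]),
        )
    by_heading = {d.heading: d for d in descriptors}
    index = _tree_number_index(descriptors)
    dags = {}
    for raw, heading in name_map.mapping.items():
        if heading not in dags:
            dags[heading] = build_disease_dag(
                by_heading[heading], descriptors, _index=index
            )
    if not dags:
        raise ValueError("no disease name could be mapped to a MeSH heading")
    sets = density_sets_from_dags(
        dags, cap=cap, base=log_base if log_base is not None else math.e
    )
    fs = build_disease_similarity_matrix(sets.values())
    return fs, name_map


def lncrna_similarity_from_associations(
    assoc: AssociationMatrix,
    fs: DiseaseSimilarityMatrix,
    name_map: DiseaseNameMap | None = None,
) -> tuple[LncSimilarityMatrix, list[str]]:
    """Group-based functional similarity for every lncRNA with scorable diseases.

    Returns the matrix over lncRNAs whose disease group retains at least
    one semantically scored disease, plus the ids of excluded lncRNAs.
    """
    rename = name_map.mapping if name_map is not None else {}
    scored = set(fs.disease_ids)
    groups = []
    excluded = []
    for i, lnc in enumerate(assoc.lncrna_ids):
        diseases = {
            rename.get(d, d)
            for j, d in enumerate(assoc.disease_ids)
            if assoc.values[i, j] == 1
        } & scored
        if diseases:
            groups.append(DiseaseGroup(lncrna_id=lnc, diseases=frozenset(diseases)))
        else:
            excluded.append(lnc)
    if not groups:
        raise ValueError("no lncRNA has a semantically scored disease group")
    if excluded:
        logger.warning(
            "%d lncRNA(s) have no scorable disease group: %s",
            len(excluded),
            ", ".join(excluded[:10]),
        )
    return build_lnc_similarity_matrix(groups, fs), excluded


def rename_association_diseases(
    assoc: AssociationMatrix, name_map: DiseaseNameMap
) -> AssociationMatrix:
    """Replace raw disease names by their MeSH headings where mapped."""
    new_ids = [name_map.mapping.get(d, d) for d in assoc.disease_ids]
    return AssociationMatrix(list(assoc.lncrna_ids), new_ids, assoc.values.copy())


__all__ = [
    "disease_similarity_from_mesh",
    "lncrna_similarity_from_associations",
    "rename_association_diseases",
    "ModelConfig",
]
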