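"""Seeded synthetic corpora: MeSH-like term forests, block associations.

The generator emulates the inputs of the pipeline so every stage runs
without external downloads: a rooted forest of disease terms encoded as
dotted tree numbers, a set of diseases grouped into DAG-coherent blocks
(diseases in a block descend from a common subtree anchor), a sparse
binary lncRNA x disease association matrix whose entries are enriched
within blocks, and block-structured expression profiles.  The planted
block structure instantiates the modelling assumption that functionally
similar lncRNAs associate with semantically similar diseases, which is
what gives cross-validation on these corpora a recoverable signal.

All randomness flows from the single integer seed in ``FixtureConfig``
through one ``numpy`` generator; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshDescriptor
from .kernels import AssociationMatrix

__all__ = [
    "FixtureConfig",
    "SyntheticCorpus",
    "generate_term_forest",
    "generate_block_associations",
    "generate_expression",
    "generate_corpus",
    "shuffle_associations",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic corpus.

    The default association geometry (40 lncRNAs x 25 diseases in 5
    blocks, within-block association probability 0.6 against a 0.02
    background) gives a sparse matrix with strong planted signal at a size
    where a full leave-one-out run remains cheap.
    """

    seed: int = 0
    n_terms: int = 120
    max_depth: int = 4
    branching: int = 4
    n_diseases: int = 25
    n_lncrnas: int = 40
    n_blocks: int = 5
    within_block_assoc_prob: float = 0.6
    background_assoc_prob: float = 0.02
    n_expr_samples: int = 12
    expr_noise: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.within_block_assoc_prob, self.background_assoc_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        for c in (
            self.n_terms,
            self.max_depth,
            self.branching,
            self.n_diseases,
            self.n_lncrnas,
            self.n_blocks,
            self.n_expr_samples,
        ):
            if c < 1:
                raise ValueError("all counts must be at least 1")


@dataclass
class SyntheticCorpus:
    descriptors: list[MeshDescriptor]
    association: AssociationMatrix
    expression: np.ndarray
    lnc_blocks: np.ndarray
    disease_blocks: np.ndarray
    resampled: list[str] = field(default_factory=list)


def generate_term_forest(cfg: FixtureConfig, rng=None) -> list[MeshDescriptor]:
    """Grow a rooted forest of disease terms with dotted tree numbers.

    Roots are ``C01, C02, ...``; each non-root attaches to a uniformly
    chosen existing node with spare fan-out and depth below ``max_depth``.
    Every descriptor carries exactly one tree number, so per-term DAGs are
    chains, while the corpus as a whole is a forest.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_roots = max(1, min(cfg.branching, cfg.n_terms // max(1, cfg.max_depth)))
    n_roots = min(n_roots, cfg.n_terms)
    tree_numbers: list[str] = [f"C{r + 1:02d}" for r in range(n_roots)]
    children: dict[str, int] = {tn: 0 for tn in tree_numbers}
    while len(tree_numbers) < cfg.n_terms:
        open_nodes = [
            tn
            for tn in tree_numbers
            if children[tn] < cfg.branching and tn.count(".") + 1 < cfg.max_depth
        ]
        if not open_nodes:
            break
        parent = open_nodes[rng.integers(len(open_nodes))]
        children[parent] += 1
        tn = f"{parent}.{children[parent]:03d}"
        tree_numbers.append(tn)
        children[tn] = 0
    return [
        MeshDescriptor(
            heading=f"Disease {i:04d}",
            unique_id=f"D{i:06d}",
            tree_numbers=(tn,),
        )
        for i, tn in enumerate(tree_numbers)
    ]


def _pick_block_diseases(
    cfg: FixtureConfig, descriptors: list[MeshDescriptor], rng
) -> tuple[list[str], np.ndarray]:
    """Choose diseases in DAG-coherent blocks (shared subtree ancestor).

    Block anchors are the deepest forest nodes whose subtree is large
    enough to host a block; diseases are drawn from each anchor's subtree.
    """
    if cfg.n_blocks > cfg.n_diseases:
        raise ValueError("more blocks than diseases")
    by_tn = {d.tree_numbers[0]: d.heading for d in descriptors}
    tns = sorted(by_tn)
    per_block = cfg.n_diseases // cfg.n_blocks
    extra = cfg.n_diseases % cfg.n_blocks
    subtree = {
        tn: [t for t in tns if t == tn or t.startswith(tn + ".")] for tn in tns
    }
    need = per_block + (1 if extra else 0)
    anchors = [tn for tn in tns if len(subtree[tn]) >= need]
    anchors.sort(key=lambda tn: (-tn.count("."), tn))
    chosen: list[str] = []
    used: set[str] = set()
    for tn in anchors:
        if len(chosen) == cfg.n_blocks:
            break
        if any(t in used for t in subtree[tn]):
            continue
        chosen.append(tn)
        used.update(subtree[tn])
    if len(chosen) < cfg.n_blocks:
        raise ValueError(
            "forest has too few disjoint subtrees for the requested blocks; "
            "increase n_terms or branching"
        )
    diseases: list[str] = []
    blocks: list[int] = []
    for bi, tn in enumerate(chosen):
        take = per_block + (1 if bi < extra else 0)
        pool = subtree[tn]
        pick = rng.choice(len(pool), size=take, replace=False)
        for p in sorted(pick):
            diseases.append(by_tn[pool[p]])
            blocks.append(bi)
    return diseases, np.asarray(blocks)


def generate_block_associations(
    cfg: FixtureConfig,
    diseases: list[str],
    disease_blocks: np.ndarray,
    rng=None,
) -> tuple[AssociationMatrix, np.ndarray, list[str]]:
    """Sample the binary association matrix with planted block enrichment.

    Entry (i, j) is 1 with the within-block probability when lncRNA i and
    disease j share a block and the background probability otherwise.
    lncRNAs or diseases left with an all-zero profile are resampled once
    and reported if still isolated.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_blocks > cfg.n_lncrnas:
        raise ValueError("more blocks than lncRNAs")
    lnc_blocks = np.sort(np.arange(cfg.n_lncrnas) % cfg.n_blocks)
    same = lnc_blocks[:, None] == np.asarray(disease_blocks)[None, :]
    prob = np.where(same, cfg.within_block_assoc_prob, cfg.background_assoc_prob)
    y = (rng.random(prob.shape) < prob).astype(np.int8)
    resampled: list[str] = []
    lnc_ids = [f"lnc-{i:03d}" for i in range(cfg.n_lncrnas)]
    for i in np.flatnonzero(y.sum(axis=1) == 0):
        y[i] = (rng.random(prob.shape[1]) < prob[i]).astype(np.int8)
        if y[i].sum() == 0:
            resampled.append(lnc_ids[i])
    for j in np.flatnonzero(y.sum(axis=0) == 0):
        y[:, j] = (rng.random(prob.shape[0]) < prob[:, j]).astype(np.int8)
        if y[:, j].sum() == 0:
            resampled.append(diseases[j])
    assoc = AssociationMatrix(lnc_ids, list(diseases), y)
    return assoc, lnc_blocks, resampled


def generate_expression(
    cfg: FixtureConfig, lnc_blocks: np.ndarray, rng=None
) -> np.ndarray:
    """Block-mean expression profiles plus Gaussian noise.

    Same-block lncRNAs share a mean profile, so their expected Spearman
    similarity rises as ``expr_noise`` falls.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lnc_blocks = np.asarray(lnc_blocks)
    means = rng.normal(size=(lnc_blocks.max() + 1, cfg.n_expr_samples))
    noise = rng.normal(
        scale=cfg.expr_noise, size=(len(lnc_blocks), cfg.n_expr_samples)
    )
    return means[lnc_blocks] + noise


def shuffle_associations(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Permutation null: scatter the association labels uniformly.

    Keeps the number of positives but destroys the planted block structure
    (and with it any alignment between association patterns and disease
    semantics), so cross-validation on the shuffled matrix measures the
    no-signal baseline.
    """
    rng = np.random.default_rng(seed)
    flat = assoc.values.flatten()
    rng.shuffle(flat)
    return AssociationMatrix(
        list(assoc.lncrna_ids), list(assoc.disease_ids), flat.reshape(assoc.values.shape)
    )


def generate_corpus(cfg: FixtureConfig) -> SyntheticCorpus:
    """Generate the full synthetic corpus from one seed."""
    rng = np.random.default_rng(cfg.seed)
    descriptors = generate_term_forest(cfg, rng=rng)
    diseases, disease_blocks = _pick_block_diseases(cfg, descriptors, rng)
    assoc, lnc_blocks, resampled = generate_block_associations(
        cfg, diseases, disease_blocks, rng=rng
    )
    expression = generate_expression(cfg, lnc_blocks, rng=rng)
    return SyntheticCorpus(
        descriptors=descriptors,
        association=assoc,
        expression=expression,
        lnc_blocks=lnc_blocks,
        disease_blocks=disease_blocks,
        resampled=resampled,
    )
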