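"""Interaction-profile kernels and similarity integration.

The Gaussian interaction profile kernel treats each lncRNA's (or
disease's) binary association vector as its "interaction profile" and
compares profiles with an RBF kernel whose bandwidth is normalized by the
mean squared profile norm.  Semantic/functional similarities and kernels
are then fused by an unweighted entry-wise mean, with per-entity fallback
to the kernel where the semantic score is unavailable (e.g. a disease name
that failed MeSH mapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import warnings

from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

__all__ = [
    "AssociationMatrix",
    "KernelMatrix",
    "gaussian_profile_kernel",
    "spearman_expression_similarity",
    "integrate_disease_similarity",
    "integrate_lncrna_similarity",
]


@dataclass
class AssociationMatrix:
    """Binary lncRNA x disease adjacency with name indices."""

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.lncrna_ids), list(self.disease_ids), self.values.copy()
        )


@dataclass
class KernelMatrix:
    ids: list[str]
    values: np.ndarray
    flagged: list[str] = field(default_factory=list)


def gaussian_profile_kernel(
    assoc: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> KernelMatrix:
    """Gaussian interaction profile kernel over association rows or columns.

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with
    gamma = gamma_prime / mean_i ||IP(i)||^2.  All-zero profiles contribute
    0 to the bandwidth mean and sit at distance 0 from each other.
    """
    if axis == "lncrna":
        profiles = assoc.values.astype(float)
        ids = assoc.lncrna_ids
    elif axis == "disease":
        profiles = assoc.values.T.astype(float)
        ids = assoc.disease_ids
    else:
        raise ValueError(f"axis must be 'lncrna' or 'disease', got {axis!r}")
    norm_sq = (profiles**2).sum(axis=1)
    mean_norm = norm_sq.mean()
    if mean_norm == 0:
        raise ValueError("every interaction profile is all-zero; gamma undefined")
    gamma = gamma_prime / mean_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    k = np.exp(-gamma * sq_dists)
    np.fill_diagonal(k, 1.0)
    return KernelMatrix(ids=list(ids), values=k)


def spearman_expression_similarity(
    expr: np.ndarray, ids=None, mapping: str = "affine"
) -> KernelMatrix:
    """Pairwise Spearman rank correlation of expression profiles (rows).

    The correlation in [-1, 1] is mapped to [0, 1] either affinely,
    (r + 1) / 2 (default, keeps anticorrelation ordered below independence),
    or by clamping negatives to 0.  Constant profiles have undefined rank
    correlation; their off-diagonal similarities are set to 0 and the
    lncRNA is flagged.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples per profile")
    n = expr.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    constant = expr.std(axis=1) == 0
    # Spearman = Pearson on ranks; scipy's spearmanr degenerates to a
    # scalar NaN whenever any profile is constant, so correlate ranks
    # directly and handle constant rows explicitly.
    ranks = np.apply_along_axis(rankdata, 1, expr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(ranks)
    r = np.clip(np.nan_to_num(np.atleast_2d(r), nan=0.0), -1.0, 1.0)
    if mapping == "affine":
        sim = (r + 1.0) / 2.0
    elif mapping == "clamp":
        sim = np.clip(r, 0.0, 1.0)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    sim[constant, :] = 0.0
    sim[:, constant] = 0.0
    np.fill_diagonal(sim, 1.0)
    return KernelMatrix(
        ids=ids, values=sim, flagged=[ids[i] for i in np.flatnonzero(constant)]
    )


def _masked_mean(components: list[np.ndarray], has_score: np.ndarray) -> np.ndarray:
    """Entry-wise mean of similarity components with kernel-only fallback.

    ``components[0]`` is the kernel (always available); the rest are scored
    components that are only meaningful where ``has_score`` is True for
    both entities of the entry.
    """
    kernel = components[0]
    both = np.outer(has_score, has_score)
    out = np.mean(components, axis=0)
    return np.where(both, out, kernel)


def integrate_disease_similarity(
    fs_values: np.ndarray,
    kd: np.ndarray,
    semantic_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Average semantic and kernel disease similarity entry-wise.

    Entries involving a disease without a semantic score (``semantic_mask``
    False) take the kernel value alone.
    """
    fs_values = np.asarray(fs_values, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if fs_values.shape != kd.shape:
        raise ValueError("disease similarity matrices have mismatched shapes")
    if semantic_mask is None:
        semantic_mask = np.ones(kd.shape[0], dtype=bool)
    return _masked_mean([kd, fs_values], np.asarray(semantic_mask, dtype=bool))


def integrate_lncrna_similarity(
    s_func: np.ndarray,
    kl: np.ndarray,
    s_expr: np.ndarray | None = None,
    functional_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Average functional, kernel and (optional) expression lncRNA similarity.

    The mean runs over the provided components (three with expression, two
    without); entries involving a lncRNA with no functional score fall back
    to the kernel alone.
    """
    s_func = np.asarray(s_func, dtype=float)
    kl = np.asarray(kl, dtype=float)
    if s_func.shape != kl.shape:
        raise ValueError("lncRNA similarity matrices have mismatched shapes")
    components = [kl, s_func]
    if s_expr is not None:
        s_expr = np.asarray(s_expr, dtype=float)
        if s_expr.shape != kl.shape:
            raise ValueError("expression similarity has mismatched shape")
        components.append(s_expr)
    if functional_mask is None:
        functional_mask = np.ones(kl.shape[0], dtype=bool)
    return _masked_mean(components, np.asarray(functional_mask, dtype=bool))
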