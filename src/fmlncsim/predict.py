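"""Association scoring and cross-validation.

Candidate lncRNA-disease pairs are scored with a Laplacian-regularized
least-squares classifier run in both similarity spaces: once over the
integrated lncRNA similarity and once over the integrated disease
similarity, with the two score matrices averaged.  Evaluation follows the
link-prediction convention: each known association is withheld (one at a
time for global LOOCV, fold-wise for repeated k-fold CV), every similarity
component that depends on the association matrix is recomputed from the
masked training matrix, and the held-out pair is ranked against all pairs
never observed as associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
from scipy.linalg import solve, LinAlgError

from .fuzzy import DiseaseSimilarityMatrix
from .kernels import (
    AssociationMatrix,
    gaussian_profile_kernel,
    integrate_disease_similarity,
    integrate_lncrna_similarity,
)

__all__ = [
    "ModelConfig",
    "CVResult",
    "laplacian_rls_score",
    "combine_space_scores",
    "score_associations",
    "global_loocv",
    "kfold_cv",
    "rank_candidates",
    "align_disease_similarity",
    "roc_from_rank_counts",
]


@dataclass(frozen=True)
class ModelConfig:
    """Every tunable of the integrated model, snapshot-able as provenance.

    cap
        Fuzzy-density cap keeping densities strictly below 1.
    gamma_prime
        Gaussian-kernel bandwidth before profile-norm normalization.
    eta_lnc, eta_dis
        Laplacian regularization strength per space.
    w
        Weight of the lncRNA-space scores in the combination.
    """

    cap: float = 0.999
    log_base: float = math.e
    gamma_prime: float = 1.0
    eta_lnc: float = 1.0
    eta_dis: float = 1.0
    w: float = 0.5
    expr_mapping: str = "affine"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVResult:
    auc: float
    roc_points: list[tuple[float, float]]
    per_repeat_aucs: list[float] = field(default_factory=list)
    mean_auc: float = float("nan")
    sd_auc: float = float("nan")
    n_test: int = 0
    n_candidates: int = 0
    config: dict = field(default_factory=dict)


def laplacian_rls_score(
    sim: np.ndarray, y: np.ndarray, eta: float, axis: str = "lncrna"
) -> np.ndarray:
    """Solve the Laplacian-RLS system ``F = (I + eta L)^-1 Y`` in one space.

    L is the symmetric-normalized graph Laplacian of ``sim``; a zero-sum
    row (an entity with no similarity edges) falls back to the identity so
    its labels pass through unsmoothed.  For the disease space the label
    matrix is transposed in and the scores transposed back.
    """
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    sim = np.asarray(sim, dtype=float)
    y = np.asarray(y, dtype=float)
    if axis == "disease":
        y = y.T
    elif axis != "lncrna":
        raise ValueError(f"axis must be 'lncrna' or 'disease', got {axis!r}")
    n = sim.shape[0]
    if sim.shape != (n, n) or y.shape[0] != n:
        raise ValueError("similarity and label shapes are inconsistent")
    d = sim.sum(axis=1)
    zero = d <= 0
    with np.errstate(divide="ignore"):
        dinv = np.where(zero, 0.0, 1.0 / np.sqrt(np.where(zero, 1.0, d)))
    s_norm = dinv[:, None] * sim * dinv[None, :]
    s_norm[zero, zero] = 1.0  # identity fallback: no smoothing without edges
    lap = np.eye(n) - s_norm
    try:
        f = solve(np.eye(n) + eta * lap, y, assume_a="pos")
    except LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular Laplacian-RLS system: {exc}") from exc
    return f.T if axis == "disease" else f


def combine_space_scores(
    f_lnc: np.ndarray, f_dis: np.ndarray, w: float = 0.5
) -> np.ndarray:
    """Weighted average of the two per-space score matrices."""
    f_lnc = np.asarray(f_lnc, dtype=float)
    f_dis = np.asarray(f_dis, dtype=float)
    if f_lnc.shape != f_dis.shape:
        raise ValueError("score matrices have mismatched shapes")
    if not 0 <= w <= 1:
        raise ValueError(f"combination weight must be in [0, 1], got {w}")
    return w * f_lnc + (1.0 - w) * f_dis


def align_disease_similarity(
    fs: DiseaseSimilarityMatrix, disease_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Embed a semantic similarity matrix into the association's disease order.

    Returns the full D x D matrix (zero where unscored) and the boolean
    mask of diseases that do have a semantic score.
    """
    pos = {d: i for i, d in enumerate(fs.disease_ids)}
    n = len(disease_ids)
    mask = np.array([d in pos for d in disease_ids], dtype=bool)
    out = np.zeros((n, n))
    idx = [pos[d] for d in disease_ids if d in pos]
    where = np.flatnonzero(mask)
    out[np.ix_(where, where)] = fs.values[np.ix_(idx, idx)]
    return out, mask


def _functional_similarity_values(
    y: np.ndarray, fs_values: np.ndarray, semantic_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best-match group-average lncRNA similarity from a training matrix.

    Vectorized over lncRNA pairs: M[:, j] holds, for every disease d, the
    best semantic match of d inside lncRNA j's disease group, so the
    numerator of the group average is a single matrix product.
    """
    n_lnc, n_dis = y.shape
    member = (y > 0) & semantic_mask[None, :]
    sizes = member.sum(axis=1)
    has = sizes > 0
    best = np.zeros((n_dis, n_lnc))
    for j in np.flatnonzero(has):
        best[:, j] = fs_values[:, member[j]].max(axis=1)
    num = member.astype(float) @ best  # num[i, j] = sum_{d in G(i)} Sd(d, G(j))
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (num + num.T) / np.where(denom > 0, denom, 1), 0.0)
    s[~has, :] = 0.0
    s[:, ~has] = 0.0
    np.fill_diagonal(s, 1.0)
    np.clip(s, 0.0, 1.0, out=s)
    return s, has


def score_associations(
    assoc: AssociationMatrix,
    fs: DiseaseSimilarityMatrix | None = None,
    expr_sim: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
    _aligned: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Score every lncRNA-disease pair from a training association matrix.

    Rebuilds everything that depends on the association matrix (Gaussian
    kernels in both spaces and the group-based lncRNA functional
    similarity), integrates the similarity components, and runs the
    two-space Laplacian-RLS combination.
    """
    y = assoc.values.astype(float)
    n_dis = len(assoc.disease_ids)
    if _aligned is not None:
        fs_values, sem_mask = _aligned
    elif fs is not None:
        fs_values, sem_mask = align_disease_similarity(fs, assoc.disease_ids)
    else:
        fs_values = np.zeros((n_dis, n_dis))
        sem_mask = np.zeros(n_dis, dtype=bool)

    kl = gaussian_profile_kernel(assoc, "lncrna", config.gamma_prime).values
    kd = gaussian_profile_kernel(assoc, "disease", config.gamma_prime).values
    s_func, func_mask = _functional_similarity_values(y, fs_values, sem_mask)
    sim_l = integrate_lncrna_similarity(s_func, kl, expr_sim, func_mask)
    sim_d = integrate_disease_similarity(fs_values, kd, sem_mask)
    f_l = laplacian_rls_score(sim_l, y, config.eta_lnc, axis="lncrna")
    f_d = laplacian_rls_score(sim_d, y, config.eta_dis, axis="disease")
    return combine_space_scores(f_l, f_d, config.w)


def roc_from_rank_counts(b, t, m: int) -> tuple[list[tuple[float, float]], float]:
    """ROC polyline and trapezoidal AUC from held-out rank statistics.

    For held-out positive i, ``b[i]`` candidates scored strictly above it
    and ``t[i]`` tied with it among ``m`` candidates.  Each positive
    contributes a step (or, under ties, a ramp spread across the tied
    block, which is the half-credit convention) in false-positive-rate
    space; the ROC is the average of these curves, so its trapezoidal area
    equals the mean rank statistic exactly.
    """
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    if m <= 0 or b.size == 0:
        raise ValueError("need at least one candidate and one positive")
    starts = b / m
    ends = (b + t) / m
    xs = np.unique(np.concatenate(([0.0, 1.0], starts, ends)))
    ties = t > 0

    def tpr(x: float, side: str) -> float:
        with np.errstate(invalid="ignore", divide="ignore"):
            ramp = np.clip((x * m - b) / np.where(ties, t, 1.0), 0.0, 1.0)
        if side == "left":
            step = (x > starts).astype(float)
        else:
            step = (x >= starts).astype(float)
        return float(np.where(ties, ramp, step).mean())

    points: list[tuple[float, float]] = []
    for x in xs:
        left, right = tpr(x, "left"), tpr(x, "right")
        points.append((float(x), left))
        if right != left:
            points.append((float(x), right))
    arr = np.asarray(points)
    auc = float(np.trapezoid(arr[:, 1], arr[:, 0]))
    return points, auc


def _rank_counts(score: float, cand_scores: np.ndarray) -> tuple[int, int]:
    return int((cand_scores > score).sum()), int((cand_scores == score).sum())


def global_loocv(
    assoc: AssociationMatrix,
    fs: DiseaseSimilarityMatrix | None = None,
    expr_sim: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
    scorer=None,
) -> CVResult:
    """Global leave-one-out cross validation over known associations.

    Each known pair is zeroed in the training matrix in turn, the model is
    refit (kernels and functional similarity recomputed from the masked
    matrix), and the pair is ranked against the global candidate set: all
    pairs without recorded association evidence.  ``scorer`` may replace
    the model for harness testing; it maps a training AssociationMatrix to
    a score matrix.
    """
    y = assoc.values
    positives = np.argwhere(y == 1)
    if len(positives) < 2:
        raise ValueError("need at least two known associations for LOOCV")
    cand_mask = y == 0
    m = int(cand_mask.sum())
    aligned = (
        align_disease_similarity(fs, assoc.disease_ids) if fs is not None else None
    )

    def run(train: AssociationMatrix) -> np.ndarray:
        if scorer is not None:
            return np.asarray(scorer(train), dtype=float)
        return score_associations(
            train, expr_sim=expr_sim, config=config, _aligned=aligned
        )

    bs, ts = [], []
    for i, j in positives:
        train = assoc.copy()
        train.values[i, j] = 0
        scores = run(train)
        b, t = _rank_counts(scores[i, j], scores[cand_mask])
        bs.append(b)
        ts.append(t)
    points, auc = roc_from_rank_counts(bs, ts, m)
    return CVResult(
        auc=auc,
        roc_points=points,
        n_test=len(positives),
        n_candidates=m,
        config=config.to_dict(),
    )


def kfold_cv(
    assoc: AssociationMatrix,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    fs: DiseaseSimilarityMatrix | None = None,
    expr_sim: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
    scorer=None,
) -> CVResult:
    """Repeated k-fold cross validation over known associations.

    Per repeat the known associations are partitioned into k disjoint
    folds; each fold is removed from training and its pairs are ranked
    against the never-associated candidate set.  Fully reproducible from
    ``seed``.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    y = assoc.values
    positives = np.argwhere(y == 1)
    n_pos = len(positives)
    if n_pos < k:
        raise ValueError(f"{n_pos} known associations cannot fill {k} folds")
    cand_mask = y == 0
    m = int(cand_mask.sum())
    rng = np.random.default_rng(seed)
    aligned = (
        align_disease_similarity(fs, assoc.disease_ids) if fs is not None else None
    )

    def run(train: AssociationMatrix) -> np.ndarray:
        if scorer is not None:
            return np.asarray(scorer(train), dtype=float)
        return score_associations(
            train, expr_sim=expr_sim, config=config, _aligned=aligned
        )

    per_repeat = []
    all_b: list[int] = []
    all_t: list[int] = []
    for _ in range(repeats):
        order = rng.permutation(n_pos)
        folds = np.array_split(order, k)
        bs, ts = [], []
        for fold in folds:
            train = assoc.copy()
            held = positives[fold]
            train.values[held[:, 0], held[:, 1]] = 0
            scores = run(train)
            cand_scores = scores[cand_mask]
            for i, j in held:
                b, t = _rank_counts(scores[i, j], cand_scores)
                bs.append(b)
                ts.append(t)
        _, rep_auc = roc_from_rank_counts(bs, ts, m)
        per_repeat.append(rep_auc)
        all_b.extend(bs)
        all_t.extend(ts)
    points, auc = roc_from_rank_counts(all_b, all_t, m)
    per = np.asarray(per_repeat)
    return CVResult(
        auc=auc,
        roc_points=points,
        per_repeat_aucs=per.tolist(),
        mean_auc=float(per.mean()),
        sd_auc=float(per.std(ddof=1)) if repeats > 1 else 0.0,
        n_test=n_pos,
        n_candidates=m,
        config=config.to_dict(),
    )


def rank_candidates(
    disease_id: str,
    scores: np.ndarray,
    assoc: AssociationMatrix,
    top_n: int = 10,
) -> list[tuple[str, float, int]]:
    """Rank unassociated lncRNAs for one disease by descending score.

    Ties are broken lexicographically on lncRNA id so output files are
    byte-reproducible.
    """
    try:
        j = assoc.disease_ids.index(disease_id)
    except ValueError:
        raise ValueError(f"unknown disease {disease_id!r}") from None
    scores = np.asarray(scores, dtype=float)
    cands = [
        (assoc.lncrna_ids[i], float(scores[i, j]))
        for i in range(len(assoc.lncrna_ids))
        if assoc.values[i, j] == 0
    ]
    cands.sort(key=lambda c: (-c[1], c[0]))
    return [(name, s, r + 1) for r, (name, s) in enumerate(cands[:top_n])]
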